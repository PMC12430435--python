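"""Accuracy assessment and area/elevation summaries.

Confusion matrices are oriented rows = mapped class, columns = reference
class, so user's accuracy (1 - commission) lives on rows and producer's
accuracy (1 - omission) on columns.  Overall accuracy is the diagonal
fraction and kappa the chance-corrected agreement
``(p_o - p_e) / (1 - p_e)`` with ``p_e = sum_c row_c * col_c / total^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .core_io import RasterGrid


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                 # (K, K): rows mapped, cols reference
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"mapped_{c}" for c in self.class_names],
                            columns=[f"ref_{c}" for c in self.class_names])


@dataclass
class AccuracyReport:
    oa: float
    kappa: float
    ua: dict[str, float]
    pa: dict[str, float]
    commission: dict[str, float] = field(init=False)
    omission: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.commission = {c: 1.0 - v for c, v in self.ua.items()}
        self.omission = {c: 1.0 - v for c, v in self.pa.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c, "UA": self.ua[c], "PA": self.pa[c],
                 "commission": self.commission[c], "omission": self.omission[c]}
                for c in self.ua]
        df = pd.DataFrame(rows)
        df.attrs["OA"] = self.oa
        df.attrs["kappa"] = self.kappa
        return df


def confusion(pred_map: RasterGrid, rows: np.ndarray, cols: np.ndarray,
              ref_labels: np.ndarray, class_codes: list[int],
              class_names: list[str]) -> ConfusionMatrix:
    """Cross-tabulate mapped vs reference labels at test-pixel locations."""
    if len(rows) == 0:
        raise ValueError("empty test set")
    mapped = pred_map.values[rows, cols]
    valid = mapped != (pred_map.nodata if pred_map.nodata is not None else np.iinfo(np.int32).min)
    mapped, ref = mapped[valid], ref_labels[valid]
    k = len(class_codes)
    code_to_idx = {c: i for i, c in enumerate(class_codes)}
    counts = np.zeros((k, k), dtype=np.int64)
    for m, r in zip(mapped, ref):
        counts[code_to_idx[int(m)], code_to_idx[int(r)]] += 1
    return ConfusionMatrix(counts, list(class_names))


def metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """OA, kappa, per-class UA/PA from a confusion matrix."""
    c = cm.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    oa = diag.sum() / total
    pe = float((row * col).sum()) / total ** 2
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(row > 0, diag / row, 0.0)
        pa = np.where(col > 0, diag / col, 0.0)
    return AccuracyReport(
        oa=float(oa), kappa=float(kappa),
        ua={n: float(v) for n, v in zip(cm.class_names, ua)},
        pa={n: float(v) for n, v in zip(cm.class_names, pa)},
    )


def area_summary(class_map: RasterGrid, target_code: int = 1,
                 region_polygons: list | None = None) -> pd.DataFrame:
    """Mapped hectares of the target class, per region and total.

    Pixels are assigned to the polygon containing their center; with no
    polygons the whole grid is one region.  At 10 m resolution each pixel
    is 0.01 ha, so area is exactly linear in the pixel count.
    """
    px_ha = class_map.pixel_area_ha()
    hit = class_map.valid_mask() & (class_map.values == target_code)
    if not region_polygons:
        return pd.DataFrame([{"region": "all", "pixels": int(hit.sum()),
                              "area_ha": float(hit.sum()) * px_ha}])
    rr, cc = np.nonzero(hit)
    x, y = class_map.transform.pixel_center(rr, cc)
    rows = []
    for i, poly in enumerate(region_polygons):
        inside = shapely.contains_xy(poly, x, y)
        n = int(inside.sum())
        rows.append({"region": f"region_{i}", "pixels": n, "area_ha": n * px_ha})
    return pd.DataFrame(rows)


def compare_to_reference(mapped: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """OLS of mapped areas on reference areas across regions -> (R^2, slope)."""
    from scipy import stats
    res = stats.linregress(reference, mapped)
    return float(res.rvalue ** 2), float(res.slope)


def relative_difference(mapped_total: float, reference_total: float) -> float:
    """Percent difference of mapped vs reference total: 100*(m - r)/r."""
    return 100.0 * (mapped_total - reference_total) / reference_total


def elevation_distribution(class_map: RasterGrid, dem: RasterGrid,
                           bin_edges: np.ndarray,
                           target_code: int = 1) -> pd.DataFrame:
    """Histogram of target-class pixels across elevation bins."""
    hit = class_map.valid_mask() & (class_map.values == target_code)
    elev = dem.masked()[hit]
    elev = elev[np.isfinite(elev)]
    counts, edges = np.histogram(elev, bins=bin_edges)
    total = counts.sum()
    props = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": counts, "proportion": props})
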