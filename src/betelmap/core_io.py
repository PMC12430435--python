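"""Core data model and I/O: rasters, ROI vectors, sample tables.

Rasters are single 2-D bands with an affine georeference, stored as TIFF
with a JSON metadata block (transform, CRS id, nodata) embedded in the
ImageDescription tag so that round-trips are bit-exact and self-contained.
ROI polygons travel as GeoJSON ``FeatureCollection`` objects whose features
carry a ``class_name`` (or ``class_code``) property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as _geom_from_geojson


# --------------------------------------------------------------------------
# Affine georeference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Affine:
    """Row-major affine map from (col, row) pixel indices to world x/y.

    ``x = a*col + b*row + c``; ``y = d*col + e*row + f``.  The convention is
    origin at the top-left pixel corner, north-up grids have ``e < 0``.
    """

    a: float = 10.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = -10.0
    f: float = 0.0

    @property
    def pixel_width(self) -> float:
        return abs(self.a)

    @property
    def pixel_height(self) -> float:
        return abs(self.e)

    def pixel_center(self, row, col):
        """World coordinates of pixel centers (vectorised)."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def to_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d, self.e, self.f]

    @classmethod
    def from_list(cls, vals: Sequence[float]) -> "Affine":
        return cls(*[float(v) for v in vals])


# --------------------------------------------------------------------------
# RasterGrid
# --------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """One georeferenced 2-D band.

    ``nodata`` is a sentinel value; :meth:`valid_mask` exposes the cells
    that hold real observations.  NaN is always treated as missing in
    addition to the sentinel.
    """

    values: np.ndarray
    transform: Affine = field(default_factory=Affine)
    crs: str = "EPSG:32649"
    nodata: float | None = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"RasterGrid expects a 2-D array, got ndim={self.values.ndim}")
        if self.transform.pixel_width <= 0 or self.transform.pixel_height <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.values.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            m &= ~np.isnan(self.values)
        if self.nodata is not None and not (isinstance(self.nodata, float) and np.isnan(self.nodata)):
            m &= self.values != self.nodata
        return m

    def masked(self) -> np.ndarray:
        """Values as float with missing cells set to NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, nodata=None) -> "RasterGrid":
        g = replace(self, values=np.asarray(values))
        if nodata is not None:
            g.nodata = nodata
        return g

    def pixel_area_ha(self) -> float:
        return self.transform.pixel_width * self.transform.pixel_height / 10_000.0

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform == other.transform


def ensure_aligned(grids: Iterable[RasterGrid]) -> None:
    grids = list(grids)
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape:
            raise ValueError(f"grid shape mismatch: {g.shape} vs {first.shape}")
        if g.transform != first.transform:
            raise ValueError("grid transform mismatch")
        if g.crs != first.crs:
            raise ValueError(f"CRS mismatch: {g.crs} vs {first.crs}")


# --------------------------------------------------------------------------
# Raster I/O (TIFF + embedded JSON georeference)
# --------------------------------------------------------------------------

_META_KEY = "betelmap_meta"


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid to TIFF; transform/CRS/nodata ride in ImageDescription."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nodata = grid.nodata
    if isinstance(nodata, float) and np.isnan(nodata):
        nodata = "nan"
    meta = {
        _META_KEY: 1,
        "transform": grid.transform.to_list(),
        "crs": grid.crs,
        "nodata": nodata,
    }
    tifffile.imwrite(path, grid.values, description=json.dumps(meta))


def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                parsed = json.loads(desc.value)
                if isinstance(parsed, dict) and _META_KEY in parsed:
                    meta = parsed
            except (TypeError, ValueError):
                pass
    transform = Affine.from_list(meta.get("transform", Affine().to_list()))
    nodata = meta.get("nodata", None)
    if nodata == "nan":
        nodata = float("nan")
    return RasterGrid(values=values, transform=transform, crs=meta.get("crs", "EPSG:32649"), nodata=nodata)


# --------------------------------------------------------------------------
# Class legend
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassLegend:
    """Six reference land-cover classes plus the binary betel map codes."""

    names: tuple[str, ...] = (
        "betel_palm", "forest", "rubber", "cropland", "built_up", "water",
    )
    codes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    # binary map codes for the final product
    BETEL: int = 1
    NON_BETEL: int = 0

    def __post_init__(self):
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("class codes must be unique")
        if any(c < 0 for c in self.codes):
            raise ValueError("class codes must be non-negative")
        if len(self.names) != len(self.codes):
            raise ValueError("names/codes length mismatch")

    def code_of(self, name: str) -> int:
        return self.codes[self.names.index(name)]

    def name_of(self, code: int) -> str:
        return self.names[self.codes.index(code)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.codes))

    # super-classes used by the knowledge-based forest stage: every class
    # with tree cover counts as forest there.
    @property
    def forest_tier(self) -> tuple[int, ...]:
        return tuple(self.code_of(n) for n in ("betel_palm", "forest", "rubber"))


DEFAULT_LEGEND = ClassLegend()


# --------------------------------------------------------------------------
# FeatureStack
# --------------------------------------------------------------------------

class FeatureStack:
    """Named, ordered collection of co-registered single-band grids."""

    def __init__(self, bands: Mapping[str, RasterGrid] | None = None,
                 registry: Sequence[str] | None = None):
        self._bands: dict[str, RasterGrid] = {}
        self.registry = list(registry) if registry is not None else None
        if bands:
            for name, grid in bands.items():
                self.add(name, grid)

    def add(self, name: str, grid: RasterGrid) -> None:
        if name in self._bands:
            raise ValueError(f"duplicate band name {name!r}")
        if self._bands:
            ensure_aligned([next(iter(self._bands.values())), grid])
        self._bands[name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        if name not in self._bands:
            raise KeyError(f"missing feature {name!r}")
        return self._bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __len__(self) -> int:
        return len(self._bands)

    @property
    def names(self) -> list[str]:
        return list(self._bands)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._bands.values())).shape

    @property
    def template(self) -> RasterGrid:
        return next(iter(self._bands.values()))

    def validate_registry(self) -> None:
        if self.registry is None:
            return
        missing = [n for n in self.registry if n not in self._bands]
        if missing:
            raise ValueError(f"feature stack incomplete; missing {missing}")

    def to_matrix(self, rows: np.ndarray, cols: np.ndarray,
                  names: Sequence[str] | None = None) -> np.ndarray:
        """Extract an (n, p) matrix of feature values at pixel locations."""
        names = list(names) if names is not None else self.names
        cube = np.stack([self[n].masked()[rows, cols] for n in names], axis=1)
        return cube

    def subset(self, names: Sequence[str]) -> "FeatureStack":
        return FeatureStack({n: self[n] for n in names})


# --------------------------------------------------------------------------
# SampleSet
# --------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Per-pixel feature vectors with integer class labels and split tags."""

    features: np.ndarray            # (n, p) float
    labels: np.ndarray              # (n,) int
    feature_names: list[str]
    class_legend: ClassLegend = field(default_factory=ClassLegend)
    split: np.ndarray | None = None  # (n,) "train"/"test"
    rows: np.ndarray | None = None
    cols: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if len(self.labels) != len(self.features):
            raise ValueError("labels/features length mismatch")
        if np.isnan(self.features).any():
            raise ValueError("sample features contain missing values")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset_split(self, tag: str) -> "SampleSet":
        if self.split is None:
            raise ValueError("samples carry no split tags; call split_samples first")
        m = self.split == tag
        return SampleSet(self.features[m], self.labels[m], list(self.feature_names),
                         self.class_legend, self.split[m],
                         None if self.rows is None else self.rows[m],
                         None if self.cols is None else self.cols[m])

    def select_features(self, names: Sequence[str]) -> "SampleSet":
        idx = [self.feature_names.index(n) for n in names]
        return SampleSet(self.features[:, idx], self.labels, list(names),
                         self.class_legend, self.split, self.rows, self.cols)


def split_samples(samples: SampleSet, test_fraction: float = 0.3,
                  seed: int | None = 0) -> SampleSet:
    """Stratified train/test split; per-class test count = round(n_c * f)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    split = np.full(samples.n, "train", dtype=object)
    for cls in np.unique(samples.labels):
        idx = np.flatnonzero(samples.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot split")
        n_test = int(round(len(idx) * test_fraction))
        test_idx = rng.choice(idx, size=n_test, replace=False)
        split[test_idx] = "test"
    out = SampleSet(samples.features, samples.labels, list(samples.feature_names),
                    samples.class_legend, split.astype("U5"), samples.rows, samples.cols)
    return out


# --------------------------------------------------------------------------
# ROI vectors
# --------------------------------------------------------------------------

def read_rois(path: str | Path) -> list[tuple[object, int | str]]:
    """Read (geometry, class) pairs from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        cls = props.get("class_code", props.get("class_name"))
        if cls is None:
            raise ValueError("ROI feature lacks class_code/class_name property")
        out.append((_geom_from_geojson(feat["geometry"]), cls))
    return out


def write_rois(rois: Iterable[tuple[object, int]], path: str | Path,
               legend: ClassLegend = DEFAULT_LEGEND) -> None:
    feats = []
    for geom, code in rois:
        feats.append({
            "type": "Feature",
            "geometry": json.loads(shapely.to_geojson(geom)),
            "properties": {"class_code": int(code), "class_name": legend.name_of(int(code))},
        })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def rasterize_rois(rois: Sequence[tuple[object, int | str]], template: RasterGrid,
                   legend: ClassLegend = DEFAULT_LEGEND, nodata: int = -1) -> RasterGrid:
    """Burn ROI polygons onto the template grid by pixel-center containment.

    Overlapping polygons of *different* classes raise (ambiguous reference);
    same-class overlap is harmless.
    """
    nrow, ncol = template.shape
    labels = np.full((nrow, ncol), nodata, dtype=np.int32)
    t = template.transform
    for geom, cls in rois:
        code = legend.code_of(cls) if isinstance(cls, str) else int(cls)
        minx, miny, maxx, maxy = geom.bounds
        # candidate pixel index window from geometry bounds (north-up grids)
        cols = np.arange(ncol)
        rows = np.arange(nrow)
        xs, _ = t.pixel_center(np.zeros_like(cols), cols)
        _, ys = t.pixel_center(rows, np.zeros_like(rows))
        csel = np.flatnonzero((xs >= minx) & (xs <= maxx))
        rsel = np.flatnonzero((ys >= miny) & (ys <= maxy))
        if len(csel) == 0 or len(rsel) == 0:
            continue
        rr, cc = np.meshgrid(rsel, csel, indexing="ij")
        px, py = t.pixel_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(geom, px, py)
        rr, cc = rr.ravel()[inside], cc.ravel()[inside]
        clash = (labels[rr, cc] != nodata) & (labels[rr, cc] != code)
        if clash.any():
            raise ValueError("overlapping ROI polygons with different classes")
        labels[rr, cc] = code
    return RasterGrid(labels, template.transform, template.crs, nodata=nodata)


def sample_pixels(stack: FeatureStack, label_grid: RasterGrid,
                  max_per_class: int | None = None, seed: int | None = 0,
                  legend: ClassLegend = DEFAULT_LEGEND,
                  feature_names: Sequence[str] | None = None) -> SampleSet:
    """Build a SampleSet from labeled pixels.

    ``max_per_class=None`` takes every labeled pixel (the "all pixels"
    reading); otherwise a seeded per-class subsample (the "sampled" reading).
    Pixels with any missing feature are dropped.
    """
    names = list(feature_names) if feature_names is not None else stack.names
    lab = label_grid.values
    valid = label_grid.valid_mask()
    for n in names:
        valid &= stack[n].valid_mask()
    rng = np.random.default_rng(seed)
    rows_all, cols_all, labs_all = [], [], []
    for code in np.unique(lab[valid]):
        rr, cc = np.nonzero(valid & (lab == code))
        if max_per_class is not None and len(rr) > max_per_class:
            pick = rng.choice(len(rr), size=max_per_class, replace=False)
            rr, cc = rr[pick], cc[pick]
        rows_all.append(rr)
        cols_all.append(cc)
        labs_all.append(np.full(len(rr), code, dtype=np.int32))
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    labels = np.concatenate(labs_all)
    X = stack.to_matrix(rows, cols, names)
    return SampleSet(X, labels, names, legend, None, rows, cols)
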