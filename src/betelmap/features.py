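"""The 58-feature bank: 24 SAR features and 34 optical features.

SAR side: VV, VH backscatter (dB), six dual-pol indices, and eight GLCM
texture statistics per polarization computed over moving windows and
averaged across the four standard orientations (0, 45, 90, 135 degrees) at
offset distance 1.  Optical side: the ten surface-reflectance bands plus 24
vegetation/soil/water indices computed on reflectance scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core_io import FeatureStack, RasterGrid, ensure_aligned
from .synthetic_scene import OPTICAL_BANDS

_EPS = 1e-12

GLCM_STATS = ("Home", "Cont", "Corr", "Mean", "Vari", "Diss", "Entr", "Asm")

SAR_FEATURES: tuple[str, ...] = (
    "VV", "VH", "AVE", "DIF", "RAT1", "RAT2", "NDI", "NL",
    *[f"VV_{s}" for s in GLCM_STATS],
    *[f"VH_{s}" for s in GLCM_STATS],
)

VEGETATION_INDICES: tuple[str, ...] = (
    "EVI", "NDVI", "SATVI", "RSEI", "NDTI", "NDMI", "NDRE", "GNDVI", "GCVI",
    "MODCRC", "STI", "MNDWI", "NDNS1", "NDNS2", "GI", "VIgreen", "SRI", "MSR",
    "MCARI", "TVI", "TCARI", "MTCI", "CIRE", "CIG",
)

OPTICAL_FEATURES: tuple[str, ...] = OPTICAL_BANDS + VEGETATION_INDICES

FEATURE_REGISTRY: tuple[str, ...] = SAR_FEATURES + OPTICAL_FEATURES

# spelling variants that appear in the wild for the same features
FEATURE_ALIASES = {
    "GCTV": "GCVI",
    "MNDW": "MNDWI",
    "RT1": "RAT1",
    "RT2": "RAT2",
    "VV-Home": "VV_Home",
    "VH-Home": "VH_Home",
}

assert len(SAR_FEATURES) == 24
assert len(OPTICAL_FEATURES) == 34
assert len(FEATURE_REGISTRY) == 58


def canonical_name(name: str) -> str:
    return FEATURE_ALIASES.get(name, name)


# --------------------------------------------------------------------------
# SAR dual-pol indices
# --------------------------------------------------------------------------

def _guard_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.abs(den) > _EPS
    out[ok] = num[ok] / den[ok]
    return out


def sar_indices(vv: RasterGrid, vh: RasterGrid) -> dict[str, RasterGrid]:
    """AVE, DIF, RAT1, RAT2, NDI, NL from dB-scaled VV/VH."""
    ensure_aligned([vv, vh])
    a = vv.masked()
    b = vh.masked()
    out = {
        "AVE": (a + b) / 2.0,
        "DIF": a - b,
        "RAT1": _guard_div(a, b),
        "RAT2": _guard_div(b, a),
        "NDI": _guard_div(a - b, a + b),
        "NL": _guard_div(a * b, a + b),
    }
    return {k: vv.with_values(v, nodata=np.nan) for k, v in out.items()}


# --------------------------------------------------------------------------
# GLCM textures
# --------------------------------------------------------------------------

@dataclass
class GlcmConfig:
    window: int = 5
    levels: int = 32
    distance: int = 1
    range_percentiles: tuple[float, float] = (2.0, 98.0)
    # explicit quantization range overrides the percentile rule
    range_values: tuple[float, float] | None = None

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("GLCM window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("GLCM needs at least 2 gray levels")


# directed offsets (drow, dcol) for 0, 45, 90, 135 degrees at distance 1
_OFFSETS = np.array([(0, 1), (-1, 1), (-1, 0), (-1, -1)], dtype=np.int64)


def quantize(values: np.ndarray, cfg: GlcmConfig) -> np.ndarray:
    """Clip to the robust range and quantize to cfg.levels integer levels."""
    finite = values[np.isfinite(values)]
    if cfg.range_values is not None:
        lo, hi = cfg.range_values
    elif finite.size:
        lo, hi = np.percentile(finite, cfg.range_percentiles)
    else:
        lo, hi = 0.0, 1.0
    v = np.nan_to_num(values, nan=lo)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    q = np.floor((np.clip(v, lo, hi) - lo) / (hi - lo) * cfg.levels).astype(np.int32)
    return np.clip(q, 0, cfg.levels - 1)


def glcm_from_pairs(window_levels: np.ndarray, levels: int,
                    offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of one quantized window."""
    dr, dc = offset
    h, w = window_levels.shape
    P = np.zeros((levels, levels), dtype=float)
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w:
                a, b = window_levels[i, j], window_levels[ii, jj]
                P[a, b] += 1.0
                P[b, a] += 1.0
    s = P.sum()
    if s > 0:
        P /= s
    return P


def glcm_stats_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The eight texture statistics of one symmetric normalized GLCM."""
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    pi = P.sum(axis=1)
    mu = float((i[:, 0] * pi).sum())
    var = float(((i[:, 0] - mu) ** 2 * pi).sum())
    home = float((P / (1.0 + (i - j) ** 2)).sum())
    cont = float((P * (i - j) ** 2).sum())
    diss = float((P * np.abs(i - j)).sum())
    if var > 0:
        corr = float((P * (i - mu) * (j - mu)).sum()) / var
    else:
        corr = 0.0
    nz = P[P > 0]
    entr = float(-(nz * np.log(nz)).sum())
    asm = float((P ** 2).sum())
    return {"Home": home, "Cont": cont, "Corr": corr, "Mean": mu,
            "Vari": var, "Diss": diss, "Entr": entr, "Asm": asm}


def glcm_stats(window_levels: np.ndarray, levels: int,
               offsets: np.ndarray = _OFFSETS) -> dict[str, float]:
    """Orientation-averaged texture statistics of one quantized window."""
    acc = {k: 0.0 for k in GLCM_STATS}
    for off in offsets:
        st = glcm_stats_from_matrix(glcm_from_pairs(window_levels, levels, tuple(off)))
        for k in GLCM_STATS:
            acc[k] += st[k]
    return {k: v / len(offsets) for k, v in acc.items()}


@njit(cache=True)
def _glcm_core(q, window, offsets):  # pragma: no cover - numba
    nrow, ncol = q.shape
    half = window // 2
    n_off = offsets.shape[0]
    out = np.zeros((8, nrow, ncol))
    max_pairs = 2 * window * window
    av = np.empty(max_pairs, dtype=np.int64)
    bv = np.empty(max_pairs, dtype=np.int64)
    for i in range(nrow):
        for j in range(ncol):
            for o in range(n_off):
                dr = offsets[o, 0]
                dc = offsets[o, 1]
                n = 0
                for wi in range(-half, half + 1):
                    for wj in range(-half, half + 1):
                        wi2 = wi + dr
                        wj2 = wj + dc
                        if wi2 < -half or wi2 > half or wj2 < -half or wj2 > half:
                            continue
                        # edge replication of the underlying image
                        r1 = min(max(i + wi, 0), nrow - 1)
                        c1 = min(max(j + wj, 0), ncol - 1)
                        r2 = min(max(i + wi2, 0), nrow - 1)
                        c2 = min(max(j + wj2, 0), ncol - 1)
                        a = q[r1, c1]
                        b = q[r2, c2]
                        # symmetric: store both directions
                        av[n] = a
                        bv[n] = b
                        n += 1
                        av[n] = b
                        bv[n] = a
                        n += 1
                if n == 0:
                    continue
                # moment statistics over the symmetric pair list
                sa = 0.0
                saa = 0.0
                sab = 0.0
                s_home = 0.0
                s_cont = 0.0
                s_diss = 0.0
                for u in range(n):
                    fa = float(av[u])
                    fb = float(bv[u])
                    d = fa - fb
                    sa += fa
                    saa += fa * fa
                    sab += fa * fb
                    s_home += 1.0 / (1.0 + d * d)
                    s_cont += d * d
                    s_diss += abs(d)
                mu = sa / n
                var = saa / n - mu * mu
                cov = sab / n - mu * mu
                corr = cov / var if var > 0 else 0.0
                # entropy / ASM via pairwise equality counting
                s_entr = 0.0
                s_asm = 0.0
                for u in range(n):
                    c_u = 0
                    for v in range(n):
                        if av[u] == av[v] and bv[u] == bv[v]:
                            c_u += 1
                    s_asm += c_u
                    s_entr += np.log(c_u / n)
                out[0, i, j] += s_home / n
                out[1, i, j] += s_cont / n
                out[2, i, j] += corr
                out[3, i, j] += mu
                out[4, i, j] += var
                out[5, i, j] += s_diss / n
                out[6, i, j] += -s_entr / n
                out[7, i, j] += s_asm / (n * n)
    out /= n_off
    return out


def glcm_features(band: RasterGrid, cfg: GlcmConfig | None = None,
                  prefix: str = "") -> dict[str, RasterGrid]:
    """Windowed, orientation-averaged GLCM texture grids for one band."""
    cfg = cfg or GlcmConfig()
    if cfg.window > min(band.shape):
        raise ValueError("GLCM window larger than image")
    q = quantize(band.masked(), cfg)
    cube = _glcm_core(q.astype(np.int64), cfg.window, _OFFSETS * cfg.distance)
    names = [f"{prefix}{s}" for s in GLCM_STATS]
    return {name: band.with_values(cube[k], nodata=np.nan)
            for k, name in enumerate(names)}


# --------------------------------------------------------------------------
# optical vegetation indices
# --------------------------------------------------------------------------

def vegetation_indices(bands: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """The 24 index formulas, on reflectance scaled to [0, 1].

    All ratio denominators are guarded: |denominator| below epsilon yields
    NaN.  NDMI and NDNS1 share a formula and are both emitted.
    """
    missing = [b for b in OPTICAL_BANDS if b not in bands]
    if missing:
        raise ValueError(f"missing optical bands {missing}")
    B2, B3, B4, B5, B6, B7, B8 = (bands[b] for b in ("B2", "B3", "B4", "B5", "B6", "B7", "B8"))
    B11, B12 = bands["B11"], bands["B12"]
    d = _guard_div
    sri = d(B8, B4)
    out = {
        "EVI": 2.5 * d(B8 - B4, B8 + 6.0 * B4 - 7.5 * B2 + 1.0),
        "NDVI": d(B8 - B4, B8 + B4),
        "SATVI": d(B11 - B4, B12 + B4 + 0.1) * 1.1 - B12 / 2.0,
        "RSEI": d(B7 + B6 - B5, B5 + B6 + B7),
        "NDTI": d(B11 - B12, B11 + B12),
        "NDMI": d(B8 - B11, B8 + B11),
        "NDRE": d(B6 - B5, B6 + B5),
        "GNDVI": d(B8 - B3, B8 + B3),
        "GCVI": d(B8, B3) - 1.0,
        "MODCRC": d(B11 - B3, B11 + B3),
        "STI": d(B11, B12),
        "MNDWI": d(B3 - B11, B3 + B11),
        "NDNS1": d(B8 - B11, B8 + B11),
        "NDNS2": d(B8 - B12, B8 + B12),
        "GI": d(B3, B4),
        "VIgreen": d(B3 - B4, B3 + B4),
        "SRI": sri,
        "MSR": d(sri - 1.0, np.sqrt(np.abs(sri)) + 1.0),
        "MCARI": ((B8 - B4) - 0.2 * (B8 - B3)) * sri,
        "TVI": 0.5 * (120.0 * (B8 - B3) - 200.0 * (B4 - B3)),
        "TCARI": 3.0 * ((B8 - B4) - 0.2 * (B8 - B3) * sri),
        "MTCI": d(B6 - B5, B5 - B4),
        "CIRE": d(B7, B5) - 1.0,
        "CIG": d(B7, B3) - 1.0,
    }
    return out


# --------------------------------------------------------------------------
# full stack assembly
# --------------------------------------------------------------------------

def resample_nearest(grid: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Nearest-neighbour resample onto the template grid (integer factors)."""
    if grid.shape == template.shape:
        return grid
    fr = template.shape[0] / grid.shape[0]
    fc = template.shape[1] / grid.shape[1]
    if fr != int(fr) or fc != int(fc):
        raise ValueError("non-integer resampling factor")
    vals = np.repeat(np.repeat(grid.values, int(fr), axis=0), int(fc), axis=1)
    return RasterGrid(vals, template.transform, template.crs, grid.nodata)


def build_stack(vv: RasterGrid, vh: RasterGrid,
                optical: dict[str, RasterGrid],
                glcm_cfg: GlcmConfig | None = None,
                reflectance_scale: float = 10000.0) -> FeatureStack:
    """Assemble the registry-complete 58-band feature stack.

    ``optical`` holds the 10 composited bands in scaled-reflectance units
    (0-10000); 20 m bands are resampled to the 10 m grid by nearest
    neighbour.  Indices are computed on values divided by
    ``reflectance_scale``; the band grids themselves are stacked unscaled.
    """
    missing = [b for b in OPTICAL_BANDS if b not in optical]
    if missing:
        raise ValueError(f"feature stack incomplete; missing bands {missing}")
    optical = {b: resample_nearest(optical[b], vv) for b in OPTICAL_BANDS}
    ensure_aligned([vv, vh] + [optical[b] for b in OPTICAL_BANDS])
    glcm_cfg = glcm_cfg or GlcmConfig()

    stack = FeatureStack(registry=list(FEATURE_REGISTRY))
    stack.add("VV", vv)
    stack.add("VH", vh)
    for name, grid in sar_indices(vv, vh).items():
        stack.add(name, grid)
    for pol, grid in (("VV", vv), ("VH", vh)):
        for name, tex in glcm_features(grid, glcm_cfg, prefix=f"{pol}_").items():
            stack.add(name, tex)
    scaled = {b: optical[b].masked() / reflectance_scale for b in OPTICAL_BANDS}
    for b in OPTICAL_BANDS:
        stack.add(b, optical[b])
    template = optical["B2"]
    for name, vals in vegetation_indices(scaled).items():
        stack.add(name, template.with_values(vals, nodata=np.nan))
    stack.validate_registry()
    return stack
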