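"""Optical cloud masking, median compositing, and SAR speckle filtering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core_io import RasterGrid, ensure_aligned
from .synthetic_scene import OPTICAL_BANDS, QA_CIRRUS_BIT, QA_OPAQUE_BIT


@dataclass
class DatedStack:
    """One acquisition date: 10 optical bands plus a QA bitmask grid."""

    date_id: str
    bands: dict[str, RasterGrid]
    qa: RasterGrid

    def __post_init__(self):
        if not np.issubdtype(self.qa.values.dtype, np.integer):
            raise ValueError("QA band must be integer-valued")
        ensure_aligned(list(self.bands.values()) + [self.qa])


def mask_clouds(stack: DatedStack, opaque_bit: int = QA_OPAQUE_BIT,
                cirrus_bit: int = QA_CIRRUS_BIT) -> DatedStack:
    """Set pixels with either cloud bit to nodata in every band."""
    qa = stack.qa.values
    cloudy = ((qa >> opaque_bit) & 1).astype(bool) | ((qa >> cirrus_bit) & 1).astype(bool)
    out = {}
    for name, grid in stack.bands.items():
        vals = grid.masked()
        vals[cloudy] = np.nan
        out[name] = grid.with_values(vals, nodata=np.nan)
    return DatedStack(stack.date_id, out, stack.qa)


def median_composite(stacks: list[DatedStack],
                     band_names: tuple[str, ...] = OPTICAL_BANDS) -> dict[str, RasterGrid]:
    """Per-pixel, per-band median over valid observations.

    Pixels with zero valid observations become nodata.  Even observation
    counts take the mean of the two central order statistics (numpy's
    median convention).
    """
    if not stacks:
        raise ValueError("need at least one dated stack to composite")
    ensure_aligned([s.qa for s in stacks])
    template = stacks[0].bands[band_names[0]]
    out = {}
    for b in band_names:
        cube = np.stack([s.bands[b].masked() for s in stacks], axis=0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(cube, axis=0)
        out[b] = template.with_values(med, nodata=np.nan)
    return out


# --------------------------------------------------------------------------
# Refined Lee speckle filter
# --------------------------------------------------------------------------

# 8 edge-aligned directional sub-window masks for a 7x7 window, indexed by
# gradient direction (E, NE, N, NW, W, SW, S, SE).  Each keeps the half of
# the window on the low-gradient side of the detected edge plus the center
# column/row, the classical refined Lee geometry.
def _directional_masks(w: int) -> np.ndarray:
    c = w // 2
    masks = np.zeros((8, w, w), dtype=np.bool_)
    rr, cc = np.meshgrid(np.arange(w), np.arange(w), indexing="ij")
    masks[0] = cc >= c           # edge runs N-S, keep east half
    masks[4] = cc <= c           # west half
    masks[2] = rr <= c           # north half
    masks[6] = rr >= c           # south half
    masks[1] = cc - rr >= 0      # NE diagonal half
    masks[5] = cc - rr <= 0      # SW
    masks[3] = (rr + cc) <= 2 * c  # NW
    masks[7] = (rr + cc) >= 2 * c  # SE
    return masks


@njit(cache=True)
def _refined_lee_core(img, w, sigma_v2, masks):  # pragma: no cover - numba
    nrow, ncol = img.shape
    half = w // 2
    out = np.empty((nrow, ncol))
    sub = np.empty((3, 3))
    for i in range(nrow):
        for j in range(ncol):
            # gather window with edge replication
            win = np.empty((w, w))
            for di in range(-half, half + 1):
                ii = min(max(i + di, 0), nrow - 1)
                for dj in range(-half, half + 1):
                    jj = min(max(j + dj, 0), ncol - 1)
                    win[di + half, dj + half] = img[ii, jj]
            # 3x3 grid of sub-window means (thirds of the window)
            step = max(w // 3, 1)
            for a in range(3):
                r0 = a * step
                r1 = w if a == 2 else (a + 1) * step
                for b in range(3):
                    c0 = b * step
                    c1 = w if b == 2 else (b + 1) * step
                    s = 0.0
                    n = 0
                    for r in range(r0, r1):
                        for c in range(c0, c1):
                            s += win[r, c]
                            n += 1
                    sub[a, b] = s / n
            # gradient direction from the 4 axes of the 3x3 mean grid
            gh = abs(sub[1, 0] - sub[1, 2])   # horizontal contrast -> N-S edge
            gv = abs(sub[0, 1] - sub[2, 1])
            gd1 = abs(sub[0, 0] - sub[2, 2])  # NW-SE
            gd2 = abs(sub[0, 2] - sub[2, 0])  # NE-SW
            gmax = gh
            axis = 0
            if gv > gmax:
                gmax = gv
                axis = 1
            if gd1 > gmax:
                gmax = gd1
                axis = 2
            if gd2 > gmax:
                gmax = gd2
                axis = 3
            # pick the half-window on the lower-mean-gradient side
            if axis == 0:
                k = 0 if abs(win[half, half] - sub[1, 2]) < abs(win[half, half] - sub[1, 0]) else 4
            elif axis == 1:
                k = 2 if abs(win[half, half] - sub[0, 1]) < abs(win[half, half] - sub[2, 1]) else 6
            elif axis == 2:
                k = 3 if abs(win[half, half] - sub[0, 0]) < abs(win[half, half] - sub[2, 2]) else 7
            else:
                k = 1 if abs(win[half, half] - sub[0, 2]) < abs(win[half, half] - sub[2, 0]) else 5
            # local statistics over the selected directional sub-window
            s = 0.0
            s2 = 0.0
            n = 0
            for r in range(w):
                for c in range(w):
                    if masks[k, r, c]:
                        v = win[r, c]
                        s += v
                        s2 += v * v
                        n += 1
            mean = s / n
            var = s2 / n - mean * mean
            if var <= 0.0:
                out[i, j] = mean
            else:
                noise = sigma_v2 * mean * mean
                bcoef = var - noise
                if bcoef < 0.0:
                    bcoef = 0.0
                bcoef = bcoef / var
                out[i, j] = mean + bcoef * (win[half, half] - mean)
    return out


def estimate_noise_cv(values: np.ndarray, window: int = 7) -> float:
    """Multiplicative-noise coefficient of variation, from local statistics.

    The median of the local coefficient of variation over the image is
    robust to edges: homogeneous regions dominate, where local CV estimates
    the speckle CV directly.
    """
    from scipy.ndimage import uniform_filter
    v = np.nan_to_num(values, nan=float(np.nanmean(values)))
    mean = uniform_filter(v, window, mode="nearest")
    mean2 = uniform_filter(v * v, window, mode="nearest")
    var = np.maximum(mean2 - mean ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / np.abs(mean)
    cv = cv[np.isfinite(cv)]
    return float(np.median(cv)) if cv.size else 0.0


def refined_lee(band: RasterGrid, window: int = 7,
                noise_cv: float | None = None) -> RasterGrid:
    """Edge-adaptive Lee MMSE speckle filter.

    Per pixel: detect the dominant gradient direction from the 3x3 grid of
    sub-window means, restrict statistics to the edge-aligned directional
    sub-window, then apply the MMSE weighting
    ``out = mean + b * (x - mean)`` with ``b = max(0, var - sigma_v^2 *
    mean^2) / var``.  ``noise_cv`` is the multiplicative speckle coefficient
    of variation; if None it is estimated from the median local CV.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(band.shape):
        raise ValueError("window larger than image")
    vals = band.masked()
    fill = float(np.nanmean(vals)) if np.isnan(vals).any() else 0.0
    invalid = ~np.isfinite(vals)
    work = np.where(invalid, fill, vals)
    if noise_cv is None:
        noise_cv = estimate_noise_cv(work, window)
    masks = _directional_masks(window)
    out = _refined_lee_core(work.astype(np.float64), window, float(noise_cv) ** 2, masks)
    out[invalid] = np.nan
    return band.with_values(out, nodata=np.nan)
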