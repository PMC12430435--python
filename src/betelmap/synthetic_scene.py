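"""Synthetic Sentinel-1/2-like scene generator.

Renders labeled six-class landscapes (betel palm, natural forest, rubber,
cropland, built-up, water) with the statistical structure the mapping
pipeline assumes:

* patchy smallholder field geometry (seeded region growing),
* class-conditional 10-band reflectance with per-date multiplicative drift
  and cloud gaps flagged in a QA bitmask,
* class-conditional dual-pol backscatter with L-look Gamma multiplicative
  speckle, delivered in dB,
* smoothed random relief (DEM) with betel patches preferring low ground.

Backscatter class ordering encodes the field knowledge the rule stage
exploits: water is darkest, built-up brightest, tree cover in between;
forest GNDVI sits well above cropland GNDVI.  All generation is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import Affine, ClassLegend, DEFAULT_LEGEND, RasterGrid

OPTICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

QA_OPAQUE_BIT = 10
QA_CIRRUS_BIT = 11


@dataclass
class ClassRadiometry:
    """Class-conditional radiometric model for one land-cover class.

    Reflectance is in scaled-reflectance units (0-10000); backscatter means
    are dB.  ``reflectance_cov`` is the per-pixel covariance of the 10
    bands; ``texture_looks_scale`` multiplies the scene's speckle looks for
    this class (values > 1 render a smoother canopy, which is what makes
    palm plantations stand out in GLCM homogeneity).
    """

    reflectance_mean: np.ndarray          # (10,)
    reflectance_cov: np.ndarray           # (10, 10)
    vv_db: float
    vh_db: float
    texture_looks_scale: float = 1.0

    def __post_init__(self):
        self.reflectance_mean = np.asarray(self.reflectance_mean, dtype=float)
        self.reflectance_cov = np.asarray(self.reflectance_cov, dtype=float)
        if self.reflectance_mean.shape != (10,):
            raise ValueError("reflectance mean must have 10 bands")
        if not ((self.reflectance_mean > 0) & (self.reflectance_mean < 10000)).all():
            raise ValueError("reflectance means must lie in (0, 10000)")
        # positive semi-definiteness
        eig = np.linalg.eigvalsh(self.reflectance_cov)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("reflectance covariance not positive semi-definite")

    def gndvi_mean(self) -> float:
        b3 = self.reflectance_mean[OPTICAL_BANDS.index("B3")]
        b8 = self.reflectance_mean[OPTICAL_BANDS.index("B8")]
        return (b8 - b3) / (b8 + b3)


@dataclass
class SceneConfig:
    shape: tuple[int, int] = (256, 256)
    class_proportions: dict[int, float] = field(default_factory=lambda: {
        1: 0.18,   # betel palm
        2: 0.30,   # natural forest
        3: 0.17,   # rubber
        4: 0.20,   # cropland
        5: 0.08,   # built-up
        6: 0.07,   # water
    })
    mean_patch_px: float = 220.0     # expected patch size (pixels) -> smallholder scale
    n_dates: int = 6
    cloud_fraction: float = 0.10
    looks: float = 4.0
    date_drift_sd: float = 0.03      # multiplicative, per date
    relief_scale_m: float = 250.0
    relief_smooth_px: float = 24.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.looks < 1:
            raise ValueError("looks must be >= 1")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud fraction must lie in [0, 1)")


def _grid(shape) -> Affine:
    return Affine(10.0, 0.0, 0.0, 0.0, -10.0, 10.0 * shape[0])


# --------------------------------------------------------------------------
# label geometry
# --------------------------------------------------------------------------

def generate_dem(config: SceneConfig, seed: int | None = None) -> RasterGrid:
    """Smoothed random relief, rescaled to [0, relief_scale_m]."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    noise = rng.standard_normal(config.shape)
    relief = ndimage.gaussian_filter(noise, config.relief_smooth_px, mode="reflect")
    relief -= relief.min()
    if relief.max() > 0:
        relief = relief / relief.max() * config.relief_scale_m
    return RasterGrid(relief, _grid(config.shape), nodata=np.nan)


def generate_labels(config: SceneConfig, seed: int | None = None,
                    dem: RasterGrid | None = None) -> RasterGrid:
    """Region-growing tessellation into connected class patches.

    Poisson-scattered seeds claim the grid by watershed-like nearest-seed
    growth with jittered distances; each seed carries a class drawn to match
    the requested proportions.  When a DEM is supplied, betel-class seeds
    are preferentially dropped on low ground.
    """
    nrow, ncol = config.shape
    if nrow < 8 or ncol < 8:
        raise ValueError("grid too small; need at least 8x8")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_seeds = max(len(config.class_proportions), int(round(nrow * ncol / config.mean_patch_px)))
    sr = rng.integers(0, nrow, size=n_seeds)
    sc = rng.integers(0, ncol, size=n_seeds)

    codes = np.array(sorted(config.class_proportions))
    props = np.array([config.class_proportions[c] for c in codes])
    # deterministic proportional allocation of seeds to classes
    counts = np.floor(props * n_seeds).astype(int)
    remainder = n_seeds - counts.sum()
    order = np.argsort(-(props * n_seeds - counts))
    counts[order[:remainder]] += 1
    seed_classes = np.repeat(codes, counts)
    rng.shuffle(seed_classes)

    legend = DEFAULT_LEGEND
    betel = legend.code_of("betel_palm")
    if dem is not None and betel in codes:
        # swap betel seeds onto the lowest-relief seed positions
        elev = dem.values[sr, sc]
        is_betel = seed_classes == betel
        n_b = int(is_betel.sum())
        low = np.argsort(elev)[:n_b]
        new_classes = seed_classes[~is_betel]
        out_classes = np.empty_like(seed_classes)
        out_classes[low] = betel
        rest = np.setdiff1d(np.arange(n_seeds), low, assume_unique=False)
        out_classes[rest] = new_classes
        seed_classes = out_classes

    # nearest-seed tessellation with per-seed radius jitter -> irregular patches
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    best = np.full((nrow, ncol), np.inf)
    label = np.zeros((nrow, ncol), dtype=np.int32)
    jitter = rng.uniform(0.75, 1.35, size=n_seeds)
    for k in range(n_seeds):
        d = ((rr - sr[k]) ** 2 + (cc - sc[k]) ** 2) * jitter[k]
        closer = d < best
        best[closer] = d[closer]
        label[closer] = seed_classes[k]
    return RasterGrid(label, _grid(config.shape), nodata=-1)


# --------------------------------------------------------------------------
# radiometry rendering
# --------------------------------------------------------------------------

def render_optical(labels: RasterGrid, radiometry: dict[int, ClassRadiometry],
                   dates: int, cloud_fraction: float, seed: int,
                   drift_sd: float = 0.03,
                   ) -> list[tuple[dict[str, RasterGrid], RasterGrid]]:
    """Render per-date 10-band stacks plus QA cloud masks.

    Each date draws per-pixel reflectance from the class-conditional
    Gaussian, applies a date-level multiplicative drift, and flags a
    spatially coherent ``cloud_fraction`` of pixels in the QA band
    (opaque-cloud bit; a random half of those also get the cirrus bit).
    """
    rng = np.random.default_rng(seed)
    lab = labels.values
    present = np.unique(lab[lab != labels.nodata])
    missing = [int(c) for c in present if int(c) not in radiometry]
    if missing:
        raise ValueError(f"missing class radiometry for codes {missing}")
    nrow, ncol = lab.shape
    out = []
    for _ in range(dates):
        drift = 1.0 + rng.normal(0.0, drift_sd)
        bands = {b: np.empty((nrow, ncol)) for b in OPTICAL_BANDS}
        for code in present:
            cr = radiometry[int(code)]
            m = lab == code
            n = int(m.sum())
            draw = rng.multivariate_normal(cr.reflectance_mean, cr.reflectance_cov,
                                           size=n, method="eigh") * drift
            draw = np.clip(draw, 1.0, 10000.0)
            for j, b in enumerate(OPTICAL_BANDS):
                bands[b][m] = draw[:, j]
        qa = np.zeros((nrow, ncol), dtype=np.uint16)
        if cloud_fraction > 0:
            blob = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), 8.0)
            thr = np.quantile(blob, 1.0 - cloud_fraction)
            cloudy = blob > thr
            qa[cloudy] |= 1 << QA_OPAQUE_BIT
            cirrus = cloudy & (rng.random((nrow, ncol)) < 0.5)
            qa[cirrus] |= 1 << QA_CIRRUS_BIT
        grids = {b: RasterGrid(v, labels.transform, labels.crs, nodata=np.nan)
                 for b, v in bands.items()}
        out.append((grids, RasterGrid(qa, labels.transform, labels.crs, nodata=None)))
    return out


def render_sar(labels: RasterGrid, radiometry: dict[int, ClassRadiometry],
               looks: float, seed: int) -> tuple[RasterGrid, RasterGrid]:
    """Render VV/VH backscatter with L-look Gamma multiplicative speckle.

    Linear-power intensity = class mean power x Gamma(L, 1/L), converted to
    dB.  Per-class ``texture_looks_scale`` multiplies L, so smoother
    canopies (palms) carry visibly less texture.
    """
    if looks < 1:
        raise ValueError("looks must be >= 1")
    rng = np.random.default_rng(seed)
    lab = labels.values
    present = np.unique(lab[lab != labels.nodata])
    nrow, ncol = lab.shape
    out = []
    for pol in ("vv_db", "vh_db"):
        img = np.empty((nrow, ncol))
        for code in present:
            cr = radiometry[int(code)]
            mean_db = getattr(cr, pol)
            mean_pow = 10.0 ** (mean_db / 10.0)
            if mean_pow <= 0:
                raise ValueError("class mean power must be positive")
            m = lab == code
            L = looks * cr.texture_looks_scale
            speckle = rng.gamma(shape=L, scale=1.0 / L, size=int(m.sum()))
            img[m] = 10.0 * np.log10(mean_pow * speckle)
        out.append(RasterGrid(img, labels.transform, labels.crs, nodata=np.nan))
    return out[0], out[1]


# --------------------------------------------------------------------------
# default parameterization
# --------------------------------------------------------------------------

def _diag_cov(mean: np.ndarray, cv: float) -> np.ndarray:
    sd = np.asarray(mean, dtype=float) * cv
    return np.diag(sd ** 2)


def default_scene() -> tuple[SceneConfig, dict[int, ClassRadiometry]]:
    """Default well-separated scene parameterization.

    Reflectance means encode the qualitative class contrasts the pipeline
    exploits: dense forest with the highest GNDVI, cropland clearly below
    the forest tier, water with negative GNDVI; betel palms differ from the
    other tree classes mainly in the green/SWIR balance (GCVI, STI, CIG)
    and, on the SAR side, in speckle texture (higher effective looks ->
    higher GLCM homogeneity).  Backscatter means follow the standard
    ordering water << cropland < tree cover < built-up.
    """
    legend = DEFAULT_LEGEND
    mean = {
        #            B2    B3    B4    B5    B6    B7    B8   B8A   B11   B12
        "betel_palm": [260, 420, 300, 820, 2100, 2100, 2900, 2950, 1800, 650],
        "forest":     [250, 440, 300, 800, 2200, 2600, 2850, 2950, 1400, 600],
        "rubber":     [255, 470, 320, 830, 2250, 2700, 3050, 3100, 1300, 650],
        "cropland":   [600, 800, 900, 1200, 1800, 2000, 2200, 2250, 2400, 1600],
        "built_up":   [1800, 2000, 2100, 2150, 2200, 2250, 2300, 2350, 2600, 2400],
        "water":      [600, 500, 300, 220, 160, 120, 100, 90, 50, 30],
    }
    sar = {  # (VV dB, VH dB, texture_looks_scale); sub-dB contrasts within
        # the tree tier, as typical of C-band over closed tropical canopies
        "betel_palm": (-8.5, -13.4, 2.0),
        "forest":     (-9.0, -14.0, 1.0),
        "rubber":     (-8.8, -13.7, 1.3),
        "cropland":   (-14.0, -20.0, 1.0),
        "built_up":   (-4.0, -9.0, 1.0),
        "water":      (-22.0, -28.0, 1.0),
    }
    radiometry = {}
    for name in legend.names:
        mu = np.array(mean[name], dtype=float)
        vv, vh, tls = sar[name]
        radiometry[legend.code_of(name)] = ClassRadiometry(
            reflectance_mean=mu,
            reflectance_cov=_diag_cov(mu, 0.07),
            vv_db=vv, vh_db=vh, texture_looks_scale=tls,
        )
    config = SceneConfig()
    _check_orderings(radiometry, legend)
    return config, radiometry


def _check_orderings(radiometry: dict[int, ClassRadiometry], legend: ClassLegend) -> None:
    water = radiometry[legend.code_of("water")]
    forest = radiometry[legend.code_of("forest")]
    built = radiometry[legend.code_of("built_up")]
    crop = radiometry[legend.code_of("cropland")]
    if not (water.vv_db < forest.vv_db < built.vv_db):
        raise ValueError("backscatter ordering water < forest < built-up violated")
    if not (water.vh_db < forest.vh_db < built.vh_db):
        raise ValueError("backscatter ordering water < forest < built-up violated")
    if not forest.gndvi_mean() > crop.gndvi_mean():
        raise ValueError("GNDVI ordering forest > cropland violated")


# --------------------------------------------------------------------------
# whole-scene convenience
# --------------------------------------------------------------------------

@dataclass
class Scene:
    labels: RasterGrid
    dem: RasterGrid
    vv: RasterGrid
    vh: RasterGrid
    optical_dates: list[tuple[dict[str, RasterGrid], RasterGrid]]
    config: SceneConfig
    radiometry: dict[int, ClassRadiometry]


def simulate_scene(config: SceneConfig | None = None,
                   radiometry: dict[int, ClassRadiometry] | None = None,
                   seed: int | None = None) -> Scene:
    """Generate a full pixel-aligned scene from one seed."""
    if config is None or radiometry is None:
        dcfg, drad = default_scene()
        config = config or dcfg
        radiometry = radiometry or drad
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    dem = generate_dem(config, seed=sub[0])
    labels = generate_labels(config, seed=sub[1], dem=dem)
    vv, vh = render_sar(labels, radiometry, config.looks, seed=sub[2])
    optical = render_optical(labels, radiometry, config.n_dates,
                             config.cloud_fraction, seed=sub[3],
                             drift_sd=config.date_drift_sd)
    return Scene(labels, dem, vv, vh, optical, config, radiometry)
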