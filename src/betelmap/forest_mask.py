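"""Knowledge-based forest delineation.

The stage analyses dual-pol backscatter signatures of four super-classes
(forest tier, cropland, built-up, water) over training ROIs, derives
interval rules from the percentile envelopes, applies them by voting,
refines the resulting mask with a GNDVI percentile threshold, and cleans it
spatially (modal filter + minimum mapping unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import FeatureStack, RasterGrid

SIGNATURE_FEATURES = ("VV", "VH", "RAT1", "RAT2", "DIF", "NDI", "NL", "AVE")
INCLUDE_FEATURES = ("VV", "VH", "AVE", "NL", "NDI", "RAT1")

SUPER_FOREST = "forest"
SUPER_CLASSES = (SUPER_FOREST, "cropland", "built_up", "water")


@dataclass
class ClassSignature:
    """Per-feature frequency distribution of one super-class."""

    class_name: str
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # feature -> (edges, counts)
    percentiles: dict[str, np.ndarray]                    # feature -> p1..p99

    def pct(self, feature: str, p: float) -> float:
        return float(self.percentiles[feature][int(p) - 1])


@dataclass
class Rule:
    feature: str
    target: str
    lo: float
    hi: float
    role: str  # include-forest | exclude-water | exclude-built-up

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("rule interval lo > hi")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


@dataclass
class RuleSet:
    rules: list[Rule]
    vote_threshold: int = 2

    def __post_init__(self):
        n_inc = sum(r.role == "include-forest" for r in self.rules)
        if not 1 <= self.vote_threshold <= max(n_inc, 1):
            raise ValueError("vote threshold out of range")

    @property
    def include_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.role == "include-forest"]

    @property
    def exclude_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.role.startswith("exclude")]

    def to_text(self) -> str:
        lines = [f"vote_threshold: {self.vote_threshold} of {len(self.include_rules)}"]
        for r in self.rules:
            lines.append(f"{r.role:18s} {r.feature:6s} [{r.lo:+.4f}, {r.hi:+.4f}]  ({r.target})")
        return "\n".join(lines)


def _percentile_table(values: np.ndarray) -> np.ndarray:
    # linear interpolation between closest order statistics
    return np.percentile(values, np.arange(1, 100), method="linear")


def compute_signatures(stack: FeatureStack, roi_labels: RasterGrid,
                       class_groups: dict[str, list[int]],
                       features: tuple[str, ...] = SIGNATURE_FEATURES,
                       bins: int = 64) -> dict[str, ClassSignature]:
    """Per-super-class histograms and percentile tables of the SAR features.

    ``class_groups`` maps super-class name -> list of label codes (the
    forest super-class merges every tree-covered class).
    """
    lab = roi_labels.values
    valid = roi_labels.valid_mask()
    sigs = {}
    for name in SUPER_CLASSES:
        if name not in class_groups or not class_groups[name]:
            raise ValueError(f"super-class {name!r} absent from class groups")
        m = valid & np.isin(lab, class_groups[name])
        if not m.any():
            raise ValueError(f"no ROI pixels for super-class {name!r}")
        hists, pcts = {}, {}
        for f in features:
            v = stack[f].masked()[m]
            v = v[np.isfinite(v)]
            counts, edges = np.histogram(v, bins=bins)
            hists[f] = (edges, counts)
            pcts[f] = _percentile_table(v)
        sigs[name] = ClassSignature(name, hists, pcts)
    return sigs


@dataclass
class RuleConfig:
    """Parameters of the rule-derivation stage.

    The include envelopes intentionally carry the *sensitivity* of the
    stage while specificity comes from the exclusion bounds and the GNDVI
    refinement: each [p5, p95] envelope by construction drops 10% of the
    forest population and the six dual-pol features are strongly
    correlated, so a high vote demand compounds those tail cuts.  A low
    vote threshold (default 2 of 6) keeps forest recall high; water is
    caught by the exclusion bounds and cropland by the GNDVI cut.
    """

    include_lo_pct: float = 5.0
    include_hi_pct: float = 95.0
    vote_threshold: int = 2


def derive_rules(signatures: dict[str, ClassSignature],
                 config: RuleConfig | None = None) -> RuleSet:
    """Interval rules from percentile envelopes.

    Include rules: the forest [p5, p95] envelope on the six dual-pol
    features.  Water exclusion: everything below the midpoint between the
    water upper tail and the forest lower tail on AVE/NL.  Built-up is
    handled implicitly by the forest p95 caps on AVE/NL (high backscatter
    falls outside the include envelope).  Non-separable signatures produce
    a warning but rules are still emitted.
    """
    config = config or RuleConfig()
    forest = signatures[SUPER_FOREST]
    rules = []
    for f in INCLUDE_FEATURES:
        lo = forest.pct(f, config.include_lo_pct)
        hi = forest.pct(f, config.include_hi_pct)
        rules.append(Rule(f, SUPER_FOREST, lo, hi, "include-forest"))
    water = signatures.get("water")
    if water is not None:
        for f in ("AVE", "NL"):
            w_hi = water.pct(f, 95)
            f_lo = forest.pct(f, 5)
            if w_hi >= f_lo:
                warnings.warn(f"water and forest signatures overlap on {f}; "
                              "exclusion bound placed at midpoint anyway")
            mid = 0.5 * (w_hi + f_lo)
            rules.append(Rule(f, "water", -np.inf, mid, "exclude-water"))
    return RuleSet(rules, vote_threshold=config.vote_threshold)


def apply_rules(stack: FeatureStack, ruleset: RuleSet) -> RasterGrid:
    """Binary forest mask: include-votes >= m and no exclusion hit."""
    template = stack.template
    votes = np.zeros(template.shape, dtype=np.int32)
    valid = np.ones(template.shape, dtype=bool)
    for r in ruleset.include_rules:
        v = stack[r.feature].masked()
        valid &= np.isfinite(v)
        votes += np.where(np.isfinite(v) & r.contains(v), 1, 0)
    excluded = np.zeros(template.shape, dtype=bool)
    for r in ruleset.exclude_rules:
        v = stack[r.feature].masked()
        excluded |= np.isfinite(v) & r.contains(v)
    mask = (votes >= ruleset.vote_threshold) & ~excluded
    out = mask.astype(np.int16)
    out[~valid] = -1
    return RasterGrid(out, template.transform, template.crs, nodata=-1)


def gndvi_threshold(gndvi: RasterGrid, forest_pixels: np.ndarray,
                    percentile: float = 5.0) -> float:
    """Percentile threshold of GNDVI over forest training pixels."""
    v = gndvi.masked()[forest_pixels]
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ValueError("need at least 20 forest training pixels")
    return float(np.percentile(v, percentile, method="linear"))


def refine_with_gndvi(mask: RasterGrid, gndvi: RasterGrid, threshold: float) -> RasterGrid:
    """Drop forest pixels whose GNDVI falls below the threshold."""
    out = mask.values.copy()
    g = gndvi.masked()
    drop = (out == 1) & (~np.isfinite(g) | (g < threshold))
    out[drop] = 0
    return mask.with_values(out)


def majority_filter(label_grid: RasterGrid, window: int = 5) -> RasterGrid:
    """Modal (majority) filter on a categorical map.

    Each pixel takes the modal label of its window; ties keep the center
    pixel's label; nodata cells are ignored in the counts (and stay
    nodata).  On binary maps this equals a median filter.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    lab = label_grid.values
    valid = label_grid.valid_mask()
    codes = np.unique(lab[valid])
    counts = np.stack([
        ndimage.uniform_filter((valid & (lab == c)).astype(np.float64),
                               size=window, mode="constant", cval=0.0)
        for c in codes
    ], axis=0)
    best = counts.max(axis=0)
    # modal label = first code attaining the max (deterministic)
    arg = counts.argmax(axis=0)
    out = codes[arg].astype(lab.dtype)
    # ties (center's own count equals the max) keep the center label
    tol = 1e-9
    center_idx = np.searchsorted(codes, lab)
    center_idx = np.clip(center_idx, 0, len(codes) - 1)
    center_count = np.take_along_axis(counts, center_idx[None], axis=0)[0]
    keep_center = valid & (center_count >= best - tol) & (codes[center_idx] == lab)
    out[keep_center] = lab[keep_center]
    out[~valid] = label_grid.nodata if label_grid.nodata is not None else 0
    return label_grid.with_values(out)


def mmu_filter(mask: RasterGrid, min_area_ha: float = 0.5) -> RasterGrid:
    """Remove 8-connected forest components below the minimum mapping unit."""
    min_pixels = int(np.ceil(min_area_ha / mask.pixel_area_ha()))
    structure = np.ones((3, 3), dtype=bool)
    comp, n = ndimage.label(mask.values == 1, structure=structure)
    if n == 0:
        return mask.with_values(mask.values.copy())
    sizes = np.bincount(comp.ravel())
    small = np.flatnonzero(sizes < min_pixels)
    out = mask.values.copy()
    out[np.isin(comp, small[small > 0])] = 0
    return mask.with_values(out)


@dataclass
class ForestMaskResult:
    mask: RasterGrid
    ruleset: RuleSet
    gndvi_cut: float
    signatures: dict[str, ClassSignature] = field(repr=False, default=None)


def build_forest_mask(stack: FeatureStack, roi_labels: RasterGrid,
                      class_groups: dict[str, list[int]],
                      rule_config: RuleConfig | None = None,
                      gndvi_percentile: float = 5.0,
                      majority_window: int = 5,
                      min_area_ha: float = 0.5) -> ForestMaskResult:
    """Full knowledge-based chain: signatures -> rules -> vote -> GNDVI ->
    modal filter -> minimum mapping unit."""
    sigs = compute_signatures(stack, roi_labels, class_groups)
    ruleset = derive_rules(sigs, rule_config)
    mask = apply_rules(stack, ruleset)
    forest_train = roi_labels.valid_mask() & np.isin(roi_labels.values,
                                                     class_groups[SUPER_FOREST])
    cut = gndvi_threshold(stack["GNDVI"], forest_train, gndvi_percentile)
    mask = refine_with_gndvi(mask, stack["GNDVI"], cut)
    mask = majority_filter(mask, majority_window)
    mask = mmu_filter(mask, min_area_ha)
    return ForestMaskResult(mask, ruleset, cut, sigs)
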