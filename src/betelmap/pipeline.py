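"""End-to-end orchestration: scene -> preprocess -> features -> forest mask
-> feature selection -> random forest -> assessment.

This is the chain the CLI drives stage by stage; ``run_pipeline`` executes
it in one call on a synthetic scene and is the package's reference
benchmark entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assess, classify, feature_select, forest_mask, preprocess
from .core_io import DEFAULT_LEGEND, FeatureStack, RasterGrid, SampleSet, sample_pixels, split_samples
from .features import GlcmConfig, build_stack
from .synthetic_scene import Scene, simulate_scene


@dataclass
class PipelineResult:
    stack: FeatureStack
    samples: SampleSet
    forest: forest_mask.ForestMaskResult
    ranking: feature_select.FeatureRanking
    selected: list[str]
    model: classify.RfModel
    pred_map: RasterGrid          # pre-post-filter map (used for metrics)
    final_map: RasterGrid         # after 5x5 modal post-filter
    cm: assess.ConfusionMatrix
    report: assess.AccuracyReport
    scene: Scene = field(repr=False, default=None)

    @property
    def forest_precision(self) -> float:
        return self._forest_pr()[0]

    @property
    def forest_recall(self) -> float:
        return self._forest_pr()[1]

    def _forest_pr(self) -> tuple[float, float]:
        truth = np.isin(self.scene.labels.values, DEFAULT_LEGEND.forest_tier)
        pred = self.forest.mask.values == 1
        tp = float((pred & truth).sum())
        prec = tp / pred.sum() if pred.sum() else 0.0
        rec = tp / truth.sum() if truth.sum() else 0.0
        return prec, rec


def class_groups(legend=DEFAULT_LEGEND) -> dict[str, list[int]]:
    """Map the four signature super-classes to six-class label codes."""
    return {
        forest_mask.SUPER_FOREST: list(legend.forest_tier),
        "cropland": [legend.code_of("cropland")],
        "built_up": [legend.code_of("built_up")],
        "water": [legend.code_of("water")],
    }


def preprocess_scene(scene: Scene) -> tuple[dict[str, RasterGrid], RasterGrid, RasterGrid]:
    """Cloud-mask + median-composite the optical dates; despeckle the SAR."""
    stacks = [
        preprocess.mask_clouds(preprocess.DatedStack(f"d{i}", bands, qa))
        for i, (bands, qa) in enumerate(scene.optical_dates)
    ]
    composite = preprocess.median_composite(stacks)
    vv = preprocess.refined_lee(scene.vv)
    vh = preprocess.refined_lee(scene.vh)
    return composite, vv, vh


def run_pipeline(seed: int = 0, scene: Scene | None = None,
                 max_per_class: int = 1500, top_k: int = 20,
                 glcm_cfg: GlcmConfig | None = None,
                 rf_cfg: classify.RfConfig | None = None) -> PipelineResult:
    """Run the full mapping chain on a (possibly simulated) scene."""
    legend = DEFAULT_LEGEND
    if scene is None:
        scene = simulate_scene(seed=seed)
    composite, vv, vh = preprocess_scene(scene)
    stack = build_stack(vv, vh, composite, glcm_cfg)

    # reference sampling from the truth map, stratified 3:7 test:train
    samples = sample_pixels(stack, scene.labels, max_per_class=max_per_class,
                            seed=seed, legend=legend)
    samples = split_samples(samples, test_fraction=0.3, seed=seed)
    train = samples.subset_split("train")

    # knowledge-based forest mask from training pixels only
    roi_grid = _roi_grid_from_samples(scene.labels, train)
    forest = forest_mask.build_forest_mask(stack, roi_grid, class_groups(legend))

    # betel-vs-rest feature ranking within the forest tier
    betel = legend.code_of("betel_palm")
    tier_mask = np.isin(train.labels, legend.forest_tier)
    tier_train = SampleSet(train.features[tier_mask], train.labels[tier_mask],
                           list(train.feature_names), legend)
    fit = feature_select.fit_logistic(tier_train, target_class=betel)
    ranking = feature_select.importance_scores(fit)
    selected = feature_select.select_top_k(ranking, top_k)

    rf_cfg = rf_cfg or classify.RfConfig(seed=seed)
    model = classify.train_rf(tier_train.select_features(selected), rf_cfg,
                              target_class=betel)
    pred_map = classify.predict_map(model, stack, forest.mask, legend)
    final_map = forest_mask.majority_filter(pred_map, window=5)

    # Table-1-style binary assessment on the held-out split, pre-post-filter
    test = samples.subset_split("test")
    ref_binary = (test.labels == betel).astype(int)
    cm = assess.confusion(pred_map, test.rows, test.cols, ref_binary,
                          class_codes=[legend.BETEL, legend.NON_BETEL],
                          class_names=["betel", "non_betel"])
    report = assess.metrics(cm)
    return PipelineResult(stack, samples, forest, ranking, selected, model,
                          pred_map, final_map, cm, report, scene)


def _roi_grid_from_samples(labels: RasterGrid, train: SampleSet) -> RasterGrid:
    """Label grid holding class codes at training-pixel locations only."""
    out = np.full(labels.shape, -1, dtype=np.int32)
    out[train.rows, train.cols] = train.labels
    return RasterGrid(out, labels.transform, labels.crs, nodata=-1)
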