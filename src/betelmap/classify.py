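"""Random-forest betel/non-betel classification within the forest mask.

Hyperparameters follow the common cloud-platform defaults for this task:
100 trees, sqrt(p) candidate features per split, each tree grown on a 50%
row subsample (without replacement by default, with replacement via
config), minimum leaf population 1, unbounded depth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .core_io import DEFAULT_LEGEND, FeatureStack, RasterGrid, SampleSet


@dataclass
class RfConfig:
    n_trees: int = 100
    bag_fraction: float = 0.5
    with_replacement: bool = False
    min_leaf: int = 1
    max_nodes: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag fraction must lie in (0, 1]")


def make_classifier(cfg: RfConfig) -> BaggingClassifier:
    """Bagged decision trees with per-split random feature subsets.

    Feature subsampling happens at each split inside the tree
    (``max_features='sqrt'``), row subsampling at the bag level, which
    matches the random-forest construction with a configurable bagging
    fraction.
    """
    tree = DecisionTreeClassifier(
        max_features="sqrt",
        min_samples_leaf=cfg.min_leaf,
        max_leaf_nodes=cfg.max_nodes,
    )
    return BaggingClassifier(
        estimator=tree,
        n_estimators=cfg.n_trees,
        max_samples=cfg.bag_fraction,
        bootstrap=cfg.with_replacement,
        random_state=cfg.seed,
        n_jobs=1,
    )


@dataclass
class RfModel:
    classifier: BaggingClassifier
    feature_names: list[str]
    config: RfConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(X)

    def oob_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        """Out-of-bag accuracy computed from the stored per-tree samples."""
        n = len(y)
        votes = np.zeros((n, len(self.classifier.classes_)))
        seen = np.zeros(n, dtype=bool)
        for est, samp in zip(self.classifier.estimators_,
                             self.classifier.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), samp, assume_unique=False)
            if len(oob) == 0:
                continue
            pred = est.predict(X[oob])
            for ci, c in enumerate(self.classifier.classes_):
                votes[oob[pred == c], ci] += 1
            seen[oob] = True
        pred = self.classifier.classes_[votes.argmax(axis=1)]
        return float((pred[seen] == y[seen]).mean())


def train_rf(train: SampleSet, cfg: RfConfig | None = None,
             target_class: int | None = None) -> RfModel:
    """Fit the ensemble on the training split.

    With ``target_class`` given, labels are binarized to betel (1) vs rest
    (0); otherwise labels are used as-is.
    """
    cfg = cfg or RfConfig()
    y = train.labels
    if target_class is not None:
        y = (y == target_class).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(cfg)
    clf.fit(train.features, y)
    return RfModel(clf, list(train.feature_names), cfg)


def predict_map(model: RfModel, stack: FeatureStack, forest_mask: RasterGrid,
                legend=DEFAULT_LEGEND) -> RasterGrid:
    """Per-pixel betel/non-betel map, restricted to the forest mask.

    Non-forest pixels get the non-betel code; pixels that are nodata in the
    mask or in any model feature propagate nodata.
    """
    nrow, ncol = forest_mask.shape
    if stack.shape != (nrow, ncol):
        raise ValueError("stack/mask shape mismatch")
    out = np.full((nrow, ncol), legend.NON_BETEL, dtype=np.int16)
    mask_valid = forest_mask.valid_mask()
    forest = mask_valid & (forest_mask.values == 1)
    rr, cc = np.nonzero(forest)
    if len(rr):
        X = stack.to_matrix(rr, cc, model.feature_names)
        ok = ~np.isnan(X).any(axis=1)
        pred = np.full(len(rr), legend.NON_BETEL, dtype=np.int16)
        if ok.any():
            pred[ok] = model.predict(X[ok]).astype(np.int16)
        pred[~ok] = -9
        out[rr, cc] = pred
    out[~mask_valid] = -9
    return RasterGrid(out, forest_mask.transform, forest_mask.crs, nodata=-9)


def save_model(model: RfModel, path: str | Path) -> None:
    """Persist the fitted ensemble plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.classifier, path)
    meta = {"feature_names": model.feature_names, "config": asdict(model.config),
            "format_version": 1}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> RfModel:
    clf = joblib.load(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return RfModel(clf, meta["feature_names"], RfConfig(**meta["config"]))
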