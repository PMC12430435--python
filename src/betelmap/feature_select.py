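"""Logistic-regression feature importance and top-k selection.

A binomial logistic model P(y=1|x) = 1/(1 + exp(-(b0 + b'x))) is fit by
iteratively reweighted least squares on z-standardized features with a mild
L2 ridge for numerical stability.  Feature importance is the absolute Wald
statistic |beta_hat / SE| on the standardized scale, which is scale-free;
|standardized beta| is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SampleSet
from .features import FEATURE_REGISTRY, canonical_name

#: top-20 feature preset reported for betel palm mapping (canonical spellings)
PAPER_TOP20: tuple[str, ...] = tuple(canonical_name(n) for n in (
    "GCVI", "STI", "CIG", "CIRE", "GI", "VV-Home", "SRI", "NDNS2", "VH_Home",
    "GNDVI", "VV_Vari", "VH_Entr", "RT1", "MNDW", "MODCRC", "NDMI", "NDNS1",
    "VV_Cont", "VV_Asm", "VH",
))


def preset_composition(names=PAPER_TOP20) -> tuple[int, int]:
    """(optical count, SAR count) of a feature-name list."""
    from .features import SAR_FEATURES
    sar = sum(n in SAR_FEATURES for n in names)
    return len(names) - sar, sar


@dataclass
class LogisticFit:
    intercept: float
    coef: np.ndarray           # on standardized features
    se: np.ndarray
    feature_names: list[str]
    converged: bool
    n_iter: int
    n: int
    scale_mean: np.ndarray = field(repr=False, default=None)
    scale_sd: np.ndarray = field(repr=False, default=None)


@dataclass
class FeatureRanking:
    names: list[str]
    scores: np.ndarray
    n: int
    p: int

    def __post_init__(self):
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing in rank order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": np.arange(1, len(self.names) + 1),
                             "feature": self.names, "score": self.scores})


def fit_logistic(samples: SampleSet, target_class: int,
                 ridge: float = 1e-4, tol: float = 1e-8,
                 max_iter: int = 200) -> LogisticFit:
    """Ridge-stabilized maximum-likelihood logistic fit of class-vs-rest.

    Features are z-standardized internally; zero-variance columns get unit
    scale (their coefficient is then exactly shrunk to ~0 by the ridge).
    Standard errors come from the inverse penalized Fisher information.
    Non-convergence (e.g. complete separation) sets ``converged=False``
    while the ridge keeps all coefficients finite.
    """
    X = samples.features
    y = (samples.labels == target_class).astype(float)
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = np.column_stack([np.ones(n), (X - mu) / sd])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(prob * (1.0 - prob), 1e-10, None)
        grad = Z.T @ (y - prob) - pen * beta
        H = (Z * w[:, None]).T @ Z + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Z @ beta
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    H = (Z * w[:, None]).T @ Z + np.diag(pen)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogisticFit(intercept=float(beta[0]), coef=beta[1:], se=se[1:],
                       feature_names=list(samples.feature_names),
                       converged=converged, n_iter=it, n=n,
                       scale_mean=mu, scale_sd=sd)


def importance_scores(fit: LogisticFit, method: str = "wald") -> FeatureRanking:
    """Rank features by |beta/SE| (``wald``) or |beta| (``beta``)."""
    if method == "wald":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.abs(fit.coef) / fit.se
        score = np.nan_to_num(score, nan=0.0, posinf=0.0)
    elif method == "beta":
        score = np.abs(fit.coef)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    # stable sort; ties broken by registry order via the secondary key
    reg_order = {n: i for i, n in enumerate(FEATURE_REGISTRY)}
    keys = [(-score[i], reg_order.get(n, len(reg_order)), i)
            for i, n in enumerate(fit.feature_names)]
    order = [k[2] for k in sorted(keys)]
    return FeatureRanking([fit.feature_names[i] for i in order], score[order],
                          n=fit.n, p=len(fit.feature_names))


def select_top_k(ranking: FeatureRanking, k: int = 20) -> list[str]:
    if not 1 <= k <= len(ranking.names):
        raise ValueError(f"k must lie in [1, {len(ranking.names)}]")
    return ranking.names[:k]


def accuracy_vs_k(samples: SampleSet, ranking: FeatureRanking,
                  target_class: int, ks: list[int],
                  classifier_cfg=None, cv: int = 3,
                  seed: int = 0) -> pd.DataFrame:
    """Cross-validated accuracy of the classifier on top-k features.

    Returns a (k, accuracy) curve plus the plateau point: the smallest k
    whose accuracy is within 0.5 percentage points of the curve maximum
    (stored in ``df.attrs['plateau_k']``).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    from .classify import RfConfig, make_classifier

    if any(k < 1 or k > samples.p for k in ks):
        raise ValueError("ks must lie within [1, p]")
    cfg = classifier_cfg or RfConfig(seed=seed)
    y = (samples.labels == target_class).astype(int)
    rows = []
    for k in ks:
        names = select_top_k(ranking, k)
        X = samples.select_features(names).features
        clf = make_classifier(cfg)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        acc = cross_val_score(clf, X, y, cv=skf, scoring="accuracy").mean()
        rows.append((k, float(acc)))
    df = pd.DataFrame(rows, columns=["k", "accuracy"])
    best = df["accuracy"].max()
    plateau = df.loc[df["accuracy"] >= best - 0.005, "k"].min()
    df.attrs["plateau_k"] = int(plateau)
    return df
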