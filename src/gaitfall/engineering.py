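"""Two-step feature engineering: discrepancy filtering and PCA, train-only.

Step 1 — unsupervised discrepancy screening: the training rows are split
randomly in half many times; a two-sample (Welch) t-test per feature
compares the halves, and each feature's p-values are averaged over repeats.
Features whose averaged p is lowest behave inhomogeneously across random
subsets of the same source (a proxy for train/test source discrepancy) and
are removed — the count removed, not a p threshold, is the knob.

Step 2 — PCA on the z-scored surviving features, keeping the smallest
number of components that explains the target fraction (99%) of training
variance. Centering, scaling and loadings are fitted on training rows only
and applied unchanged to held-out rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "DiscrepancyReport",
    "PcaProjection",
    "discrepancy_filter",
    "pca_fit",
    "pca_apply",
]


@dataclass
class DiscrepancyReport:
    averaged_p: pd.Series          # per feature, in [0, 1]
    n_repeats: int
    removed: list
    kept: list
    n_degenerate: int = 0          # (repeat, feature) cells with zero variance


def discrepancy_filter(
    train_features: pd.DataFrame,
    n_repeats: int = 1000,
    k_remove: int = 4,
    seed: int = 0,
    equal_var: bool = False,
) -> DiscrepancyReport:
    """Average half-split t-test p-values and flag the k lowest features.

    Unsupervised: labels never enter. A feature that is constant within a
    split contributes p = 1 for that repeat (and is counted as degenerate).
    """
    X = train_features.to_numpy(float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 rows for half-splitting")
    if not (0 <= k_remove <= p):
        raise ValueError("k_remove out of range")
    rng = np.random.default_rng(seed)
    half = n // 2
    psum = np.zeros(p)
    n_degenerate = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            a, b = X[perm[:half]], X[perm[half:]]
            pvals = stats.ttest_ind(a, b, axis=0, equal_var=equal_var).pvalue
            bad = ~np.isfinite(pvals)
            n_degenerate += int(bad.sum())
            pvals = np.where(bad, 1.0, pvals)
            psum += pvals
    avg = pd.Series(psum / n_repeats, index=train_features.columns)
    order = avg.sort_values().index
    removed = list(order[:k_remove])
    kept = [c for c in train_features.columns if c not in removed]
    return DiscrepancyReport(
        averaged_p=avg, n_repeats=n_repeats, removed=removed, kept=kept,
        n_degenerate=n_degenerate,
    )


@dataclass
class PcaProjection:
    feature_names: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray           # features × components, orthonormal columns
    n_components: int
    explained_fraction: float
    explained_ratio: np.ndarray = field(repr=False, default=None)

    def to_json(self, path) -> None:
        obj = {
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "n_components": self.n_components,
            "explained_fraction": self.explained_fraction,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PcaProjection":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            feature_names=obj["feature_names"],
            center=np.array(obj["center"]),
            scale=np.array(obj["scale"]),
            loadings=np.array(obj["loadings"]),
            n_components=obj["n_components"],
            explained_fraction=obj["explained_fraction"],
        )


def pca_fit(train_features: pd.DataFrame, variance_target: float = 0.99) -> PcaProjection:
    """Correlation-mode PCA keeping the smallest PC count reaching the target.

    Features are z-scored with the training mean and (n−1) SD — the
    descriptor list mixes seconds, cm/s and unitless quantities. Components
    get a deterministic sign (largest-magnitude loading positive).
    """
    X = train_features.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    degenerate = scale == 0
    if degenerate.any():
        warnings.warn("constant feature(s) given unit scale in PCA", stacklevel=2)
        scale = np.where(degenerate, 1.0, scale)
    Z = (X - center) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, len(ratio))
    rank = int(np.linalg.matrix_rank(Z))
    if k > rank:
        warnings.warn("rank-deficient input: components limited to rank", stacklevel=2)
        k = rank
    load = pca.components_[:k].T.copy()  # features × k
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    load *= flip
    return PcaProjection(
        feature_names=list(train_features.columns),
        center=center,
        scale=scale,
        loadings=load,
        n_components=k,
        explained_fraction=float(cum[k - 1]),
        explained_ratio=ratio[:k],
    )


def pca_apply(proj: PcaProjection, features: pd.DataFrame) -> pd.DataFrame:
    """Project rows with the fitted (train-only) center/scale/loadings."""
    if list(features.columns) != list(proj.feature_names):
        raise ValueError("feature set does not match the fitted projection")
    Z = (features.to_numpy(float) - proj.center) / proj.scale
    scores = Z @ proj.loadings
    cols = [f"PC{i + 1}" for i in range(proj.n_components)]
    return pd.DataFrame(scores, index=features.index, columns=cols)
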