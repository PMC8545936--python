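"""Random-forest classification with an explicit out-of-bag (OOB) estimate.

The forest draws one bootstrap sample (with replacement) per tree, grows an
unpruned CART tree (Gini impurity) considering ``mtry`` random features per
split, and classifies by majority vote. Because roughly 1/3 of rows are
out-of-bag per tree, every row can be scored by the trees that never saw
it; the OOB error is

    ER_OOB = n⁻¹ Σ_i 1{ Ŷ_OOB(x_i) ≠ y_i }

over rows with at least one OOB vote — an internal cross-validation that
keeps the blind test untouched. The bootstrap is handled here (not by
scikit-learn) so OOB membership, in-bag coverage and vote fractions are
explicit and reproducible.

Model selection for the combined-feature experiment adds linear principal
components one at a time to the nonlinear-PC model and picks the elbow of
the OOB-error curve (ties broken by OOB-vote AUC, then by fewer PCs).

Positive class = faller throughout; a vote fraction exactly at the
threshold predicts faller (the clinically conservative choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestSpec",
    "OobEstimate",
    "MetricSet",
    "ElbowCurve",
    "RandomForest",
    "train_forest",
    "evaluate",
    "repeat_over_seeds",
    "aggregate_metrics",
    "incremental_pc_selection",
]


@dataclass
class ForestSpec:
    n_trees: int = 365
    mtry: int = 1
    seed: int = 0
    class_threshold: float = 0.5

    def validate(self, n_features: int | None = None) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if n_features is not None and self.mtry > n_features:
            raise ValueError(f"mtry={self.mtry} exceeds n_features={n_features}")


@dataclass
class OobEstimate:
    oob_error: float
    oob_prediction: np.ndarray     # per-sample label (-1 where no OOB vote)
    oob_vote_fraction: np.ndarray  # fraction of OOB trees voting faller
    n_oob_votes: np.ndarray


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    auc: float
    confusion: tuple = None        # (tp, fp, fn, tn)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
            "mcc": self.mcc, "auc": self.auc,
        }


class RandomForest:
    """Bagged CART ensemble with explicit bootstrap bookkeeping."""

    def __init__(self, spec: ForestSpec):
        self.spec = spec
        self.trees_: list = []
        self.inbag_: np.ndarray | None = None   # n_trees × n bootstrap counts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        n, p = X.shape
        self.spec.validate(n_features=p)
        ss = np.random.SeedSequence(self.spec.seed)
        boot_rng = np.random.default_rng(ss.spawn(1)[0])
        tree_seeds = np.random.default_rng(ss.spawn(2)[1]).integers(
            0, 2**31 - 1, self.spec.n_trees
        )
        self.trees_ = []
        inbag = np.zeros((self.spec.n_trees, n), dtype=np.int32)
        for t in range(self.spec.n_trees):
            idx = boot_rng.integers(0, n, n)
            np.add.at(inbag[t], idx, 1)
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=self.spec.mtry,
                random_state=int(tree_seeds[t]),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        self.inbag_ = inbag
        self._X_train, self._y_train = X, y
        return self

    # -- prediction -------------------------------------------------------
    def _tree_votes(self, tree, X: np.ndarray) -> np.ndarray:
        """Per-row vote for the faller class (handles single-class trees)."""
        pred = tree.predict(X)
        return (pred == 1).astype(float)

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            votes += self._tree_votes(tree, X)
        return votes / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        frac = self.vote_fraction(X)
        return (frac >= self.spec.class_threshold).astype(int)

    # -- out-of-bag -------------------------------------------------------
    def oob(self) -> OobEstimate:
        X, y = self._X_train, self._y_train
        n = len(y)
        pos = np.zeros(n)
        tot = np.zeros(n, dtype=int)
        for t, tree in enumerate(self.trees_):
            mask = self.inbag_[t] == 0
            if not mask.any():
                continue
            v = self._tree_votes(tree, X[mask])
            pos[mask] += v
            tot[mask] += 1
        has = tot > 0
        if not has.all():
            warnings.warn(
                f"{int((~has).sum())} sample(s) had no OOB vote; excluded",
                stacklevel=2,
            )
        frac = np.where(has, pos / np.maximum(tot, 1), np.nan)
        pred = np.where(has, (frac >= self.spec.class_threshold).astype(int), -1)
        err = float(np.mean(pred[has] != y[has])) if has.any() else np.nan
        return OobEstimate(err, pred, frac, tot)

    @property
    def inbag_fraction(self) -> float:
        """Mean unique fraction of training rows in-bag per tree (≈ 0.632)."""
        return float((self.inbag_ > 0).mean(axis=1).mean())

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        s = imp.sum()
        return imp / s if s > 0 else imp


def train_forest(X, y, spec: ForestSpec) -> tuple[RandomForest, OobEstimate]:
    model = RandomForest(spec).fit(X, y)
    return model, model.oob()


def oob_error(model: RandomForest) -> float:
    return model.oob().oob_error


def _metrics_from_scores(y, frac, threshold) -> MetricSet:
    y = np.asarray(y, int)
    pred = (frac >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else np.nan
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec_ = tn / (tn + fp) if (tn + fp) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else 0.0
    )
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, frac))
    else:
        warnings.warn("single-class evaluation set: AUC undefined", stacklevel=2)
        auc = np.nan
    return MetricSet(acc, sens, spec_, f1, float(mcc), auc, confusion=(tp, fp, fn, tn))


def evaluate(model: RandomForest, X_test, y_test, threshold: float | None = None) -> MetricSet:
    """Six-metric evaluation of one trained forest on held-out data."""
    thr = model.spec.class_threshold if threshold is None else threshold
    frac = model.vote_fraction(np.asarray(X_test, float))
    return _metrics_from_scores(y_test, frac, thr)


def repeat_over_seeds(run, n_seeds: int = 10, base_seed: int = 0) -> list:
    """Call ``run(seed)`` for ``n_seeds`` derived seeds; returns the results."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31 - 1)
    return [run(int(s)) for s in seeds]


def aggregate_metrics(metric_sets: list) -> dict:
    """mean ± SE (SD/√n) per metric over repeated seeded runs."""
    out = {}
    names = ["accuracy", "sensitivity", "specificity", "f1", "mcc", "auc"]
    for name in names:
        vals = np.array([getattr(m, name) for m in metric_sets], float)
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean()) if len(vals) else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[name] = {"mean": mean, "se": se}
    return out


@dataclass
class ElbowCurve:
    k: np.ndarray                  # number of linear PCs added
    oob_error: np.ndarray
    auc: np.ndarray                # from OOB vote fractions (no test leakage)
    k_star: int


def incremental_pc_selection(
    nl_scores: np.ndarray,
    lin_scores_ordered: np.ndarray,
    y: np.ndarray,
    spec: ForestSpec,
    k_max: int | None = None,
    n_seeds: int = 5,
) -> ElbowCurve:
    """Add variance-ordered linear PCs to the nonlinear-PC forest.

    For each k, forests are trained on [nonlinear PCs ∥ first k linear PCs]
    and the OOB error and OOB-vote AUC, averaged over ``n_seeds`` seeded
    runs (single-run OOB curves are too noisy to place an elbow), are
    recorded. The selected k* minimizes mean OOB error; ties prefer higher
    AUC, then smaller k. ``mtry`` is capped at the current feature count
    when k is small.
    """
    nl = np.atleast_2d(np.asarray(nl_scores, float))
    lin = np.atleast_2d(np.asarray(lin_scores_ordered, float))
    K = lin.shape[1] if k_max is None else min(k_max, lin.shape[1])
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_seeds) % (2**31 - 1)
    ks, errs, aucs = [], [], []
    for k in range(K + 1):
        X = np.hstack([nl, lin[:, :k]]) if k else nl.copy()
        err_k, auc_k = [], []
        for s in seeds:
            sp = ForestSpec(
                n_trees=spec.n_trees,
                mtry=min(spec.mtry, X.shape[1]),
                seed=int(s),
                class_threshold=spec.class_threshold,
            )
            model, oob = train_forest(X, y, sp)
            has = oob.n_oob_votes > 0
            err_k.append(oob.oob_error)
            auc_k.append(
                float(roc_auc_score(np.asarray(y)[has], oob.oob_vote_fraction[has]))
                if len(np.unique(np.asarray(y)[has])) == 2
                else np.nan
            )
        ks.append(k)
        errs.append(float(np.mean(err_k)))
        aucs.append(float(np.mean(auc_k)))
    errs_a = np.array(errs)
    aucs_a = np.array(aucs)
    best = np.flatnonzero(errs_a == errs_a.min())
    if len(best) > 1:
        best_auc = np.nanmax(aucs_a[best])
        best = best[np.flatnonzero(aucs_a[best] == best_auc)]
    k_star = int(np.array(ks)[best[0]])
    return ElbowCurve(np.array(ks), errs_a, aucs_a, k_star)
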