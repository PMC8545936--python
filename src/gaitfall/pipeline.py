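"""End-to-end orchestration of the three fall-risk experiments.

Experiment I  — random forest on the raw 58 descriptors (no engineering).
Experiment II — discrepancy filter + PCA (99% variance) on one descriptor
                family (linear or nonlinear), forest on the PC scores.
Experiment III— engineering on both families; linear PCs are added
                incrementally to the nonlinear-PC forest and the OOB elbow
                picks how many to keep.

All fitting (discrepancy screening, PCA, forests, elbow selection) consumes
training rows only; held-out rows meet nothing but the fitted projection
and the final evaluation. Every matrix a fit touches is hashed row-wise so
the blind-test isolation can be audited after the fact.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import row_hashes
from .engineering import DiscrepancyReport, PcaProjection, discrepancy_filter, pca_apply, pca_fit
from .features import FEATURE_NAMES, LINEAR_FEATURES, NONLINEAR_FEATURES, extract_cohort_features
from .forest import (
    ElbowCurve,
    ForestSpec,
    RandomForest,
    aggregate_metrics,
    evaluate,
    incremental_pc_selection,
    repeat_over_seeds,
    train_forest,
)

__all__ = ["ExperimentConfig", "RunReport", "run_experiment", "run_cohort", "error_surface"]

# (n_trees, mtry) per experiment/feature-set, as tabulated for the study.
DEFAULT_FOREST = {
    ("I", "linear"): (365, 1),
    ("I", "nonlinear"): (311, 3),
    ("I", "both"): (365, 1),
    ("II", "linear"): (230, 1),
    ("II", "nonlinear"): (490, 18),
    ("III", "both"): (490, 20),
}


@dataclass
class ExperimentConfig:
    experiment: str = "I"              # 'I' | 'II' | 'III'
    feature_set: str = "both"          # 'linear' | 'nonlinear' | 'both'
    forest: ForestSpec | None = None
    n_repeats: int = 1000              # discrepancy half-splits
    k_remove: int = 4
    variance_target: float = 0.99
    n_seeds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("I", "II", "III"):
            raise ValueError("experiment must be 'I', 'II' or 'III'")
        if self.experiment == "II" and self.feature_set == "both":
            raise ValueError("Experiment II uses a single feature family")
        if self.experiment == "III":
            self.feature_set = "both"
        if self.forest is None:
            nt, mt = DEFAULT_FOREST[(self.experiment, self.feature_set)]
            self.forest = ForestSpec(n_trees=nt, mtry=mt, seed=self.seed)

    @property
    def engineering(self) -> bool:
        return self.experiment in ("II", "III")


@dataclass
class RunReport:
    config: ExperimentConfig
    n_train: int
    n_test: int
    feature_names: list
    discrepancy: DiscrepancyReport | None
    projections: dict                     # family -> PcaProjection
    elbow: ElbowCurve | None
    per_seed_metrics: list
    metrics: dict                         # mean ± SE per metric
    oob_errors: list
    oob_error_mean: float
    importances: pd.Series
    test_scores: pd.Series | None = None   # mean faller-vote fraction per test row
    fit_row_hashes: set = field(repr=False, default_factory=set)
    test_row_hashes: set = field(repr=False, default_factory=set)

    def metrics_json(self) -> str:
        obj = {
            "experiment": self.config.experiment,
            "feature_set": self.config.feature_set,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "oob_error_mean": self.oob_error_mean,
            "metrics": self.metrics,
            "per_seed": [m.as_dict() for m in self.per_seed_metrics],
        }
        if self.elbow is not None:
            obj["elbow"] = {
                "k": self.elbow.k.tolist(),
                "oob_error": self.elbow.oob_error.tolist(),
                "auc": self.elbow.auc.tolist(),
                "k_star": self.elbow.k_star,
            }
        return json.dumps(obj, indent=2, sort_keys=True)


def _split_features(features: pd.DataFrame):
    if "label" not in features or "split" not in features:
        raise ValueError("feature table must carry 'label' and 'split' columns")
    train = features[features["split"] == "train"]
    test = features[features["split"] == "test"]
    if len(train) == 0:
        raise ValueError("empty training split")
    return train, test


def _family_columns(feature_set: str) -> list:
    return {
        "linear": LINEAR_FEATURES,
        "nonlinear": NONLINEAR_FEATURES,
        "both": FEATURE_NAMES,
    }[feature_set]


def run_experiment(config: ExperimentConfig, features: pd.DataFrame) -> RunReport:
    """Execute one experiment on an extracted per-participant feature table.

    ``features``: rows = participants, columns = the 58 descriptors plus
    ``label`` (1 = faller) and ``split`` ('train'/'test').
    """
    train, test = _split_features(features)
    y_train = train["label"].to_numpy(int)
    y_test = test["label"].to_numpy(int)
    fit_hashes: set = set()
    projections: dict = {}
    discrepancy = None
    elbow = None

    if not config.engineering:
        cols = _family_columns(config.feature_set)
        X_train = train[cols].to_numpy(float)
        X_test = test[cols].to_numpy(float)
        feat_names = list(cols)
    else:
        # Step 1: unsupervised discrepancy screening on all 58 (train only)
        discrepancy = discrepancy_filter(
            train[FEATURE_NAMES],
            n_repeats=config.n_repeats,
            k_remove=config.k_remove,
            seed=config.seed,
        )
        fit_hashes |= row_hashes(train[FEATURE_NAMES].to_numpy(float))
        kept = discrepancy.kept

        def engineered(family: str):
            cols = [c for c in _family_columns(family) if c in kept]
            proj = pca_fit(train[cols], variance_target=config.variance_target)
            projections[family] = proj
            fit_hashes.update(row_hashes(train[cols].to_numpy(float)))
            return (
                pca_apply(proj, train[cols]).to_numpy(),
                pca_apply(proj, test[cols]).to_numpy() if len(test) else np.empty((0, proj.n_components)),
                [f"{family}_PC{i+1}" for i in range(proj.n_components)],
            )

        if config.experiment == "II":
            X_train, X_test, feat_names = engineered(config.feature_set)
        else:  # Experiment III
            nl_train, nl_test, nl_names = engineered("nonlinear")
            lin_train, lin_test, lin_names = engineered("linear")
            elbow = incremental_pc_selection(
                nl_train, lin_train, y_train, config.forest
            )
            fit_hashes |= row_hashes(np.hstack([nl_train, lin_train]))
            k = elbow.k_star
            X_train = np.hstack([nl_train, lin_train[:, :k]])
            X_test = np.hstack([nl_test, lin_test[:, :k]])
            feat_names = nl_names + lin_names[:k]

    fit_hashes |= row_hashes(X_train)
    test_hashes = row_hashes(X_test) if len(X_test) else set()

    mtry = min(config.forest.mtry, X_train.shape[1])
    if mtry != config.forest.mtry:
        warnings.warn(
            f"mtry reduced to {mtry} (feature count {X_train.shape[1]})", stacklevel=2
        )

    oob_errors: list = []
    importances = np.zeros(X_train.shape[1])
    metric_sets: list = []
    score_sum = np.zeros(len(X_test))

    def one_seed(seed: int):
        sp = ForestSpec(
            n_trees=config.forest.n_trees, mtry=mtry, seed=seed,
            class_threshold=config.forest.class_threshold,
        )
        model, oob = train_forest(X_train, y_train, sp)
        oob_errors.append(oob.oob_error)
        nonlocal importances, score_sum
        importances = importances + model.feature_importances_
        if len(y_test):
            score_sum = score_sum + model.vote_fraction(X_test)
            metric_sets.append(evaluate(model, X_test, y_test))
        return model

    repeat_over_seeds(one_seed, n_seeds=config.n_seeds, base_seed=config.seed)
    metrics = aggregate_metrics(metric_sets) if metric_sets else {}
    return RunReport(
        config=config,
        n_train=len(train),
        n_test=len(test),
        feature_names=feat_names,
        discrepancy=discrepancy,
        projections=projections,
        elbow=elbow,
        per_seed_metrics=metric_sets,
        metrics=metrics,
        oob_errors=oob_errors,
        oob_error_mean=float(np.mean(oob_errors)),
        importances=pd.Series(importances / config.n_seeds, index=feat_names).sort_values(
            ascending=False
        ),
        test_scores=(
            pd.Series(score_sum / config.n_seeds, index=test.index)
            if len(y_test) else None
        ),
        fit_row_hashes=fit_hashes,
        test_row_hashes=test_hashes,
    )


def run_cohort(cohort, configs: list | None = None, max_drop_fraction: float = 0.2) -> dict:
    """Extract features from an in-memory cohort and run the experiments.

    Aborts when more than ``max_drop_fraction`` of participants lose all
    their trials upstream (event detection failures).
    """
    features = extract_cohort_features(cohort.participants)
    n_expected = len(cohort.participants)
    if len(features) < (1 - max_drop_fraction) * n_expected:
        raise RuntimeError(
            f"{n_expected - len(features)} of {n_expected} participants dropped; aborting run"
        )
    if configs is None:
        configs = [
            ExperimentConfig(experiment="I", feature_set="linear"),
            ExperimentConfig(experiment="I", feature_set="nonlinear"),
            ExperimentConfig(experiment="II", feature_set="linear"),
            ExperimentConfig(experiment="II", feature_set="nonlinear"),
            ExperimentConfig(experiment="III"),
        ]
    reports = {}
    for cfg in configs:
        key = f"{cfg.experiment}_{cfg.feature_set}"
        reports[key] = run_experiment(cfg, features)
    return {"features": features, "reports": reports}


def error_surface(
    X: np.ndarray,
    y: np.ndarray,
    tree_grid: list,
    feature_grid: list,
    seed: int = 0,
) -> pd.DataFrame:
    """OOB error over an (n_trees × mtry) grid, for heatmap inspection.

    Cells with mtry exceeding the feature count are NaN (skipped).
    """
    if not len(tree_grid) or not len(feature_grid):
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, float)
    out = np.full((len(tree_grid), len(feature_grid)), np.nan)
    for i, nt in enumerate(tree_grid):
        for j, mt in enumerate(feature_grid):
            if mt > X.shape[1]:
                continue
            _, oob = train_forest(X, y, ForestSpec(n_trees=int(nt), mtry=int(mt), seed=seed))
            out[i, j] = oob.oob_error
    return pd.DataFrame(out, index=list(tree_grid), columns=list(feature_grid))
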