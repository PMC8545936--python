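"""Random-forest contracts: bootstrap/OOB mechanics, metrics, seed
repetition, and the incremental-PC elbow rule."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gaitfall.forest import (
    ForestSpec,
    MetricSet,
    RandomForest,
    _metrics_from_scores,
    aggregate_metrics,
    evaluate,
    incremental_pc_selection,
    repeat_over_seeds,
    train_forest,
)


def gaussian_clouds(rng, n=200, d=5.0, p=4, minority=0.5):
    n1 = int(n * minority)
    X = rng.standard_normal((n, p))
    X[:n1, 0] += d
    y = np.zeros(n, int)
    y[:n1] = 1
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestTraining:
    def test_study_configuration_is_representable(self):
        spec = ForestSpec(n_trees=365, mtry=1)
        spec.validate(n_features=58)

    def test_separable_clouds_have_tiny_oob_error(self, rng):
        X, y = gaussian_clouds(rng, n=200, d=5.0)
        _, oob = train_forest(X, y, ForestSpec(n_trees=120, mtry=2, seed=0))
        assert oob.oob_error <= 0.02

    def test_permuted_labels_hit_majority_baseline(self, rng):
        errs = []
        for seed in range(5):
            X = rng.standard_normal((500, 6))
            y = np.zeros(500, int)
            y[rng.permutation(500)[:100]] = 1  # 20% minority, no signal
            _, oob = train_forest(X, y, ForestSpec(n_trees=150, mtry=2, seed=seed))
            errs.append(oob.oob_error)
        assert np.mean(errs) == pytest.approx(0.20, abs=0.05)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_forest(rng.standard_normal((20, 3)), np.zeros(20, int), ForestSpec())

    def test_mtry_above_feature_count_rejected(self, rng):
        X, y = gaussian_clouds(rng, n=40, p=3)
        with pytest.raises(ValueError, match="mtry"):
            train_forest(X, y, ForestSpec(n_trees=10, mtry=5))

    def test_missing_values_rejected(self, rng):
        X, y = gaussian_clouds(rng, n=40)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_forest(X, y, ForestSpec(n_trees=5))

    def test_deterministic_given_seed(self, rng):
        X, y = gaussian_clouds(rng, n=100, d=1.0)
        _, oob1 = train_forest(X, y, ForestSpec(n_trees=50, mtry=2, seed=5))
        _, oob2 = train_forest(X, y, ForestSpec(n_trees=50, mtry=2, seed=5))
        assert oob1.oob_error == oob2.oob_error
        np.testing.assert_array_equal(oob1.oob_vote_fraction, oob2.oob_vote_fraction)

    def test_inbag_fraction_near_632(self, rng):
        X, y = gaussian_clouds(rng, n=150, d=1.0)
        model, _ = train_forest(X, y, ForestSpec(n_trees=500, mtry=2, seed=1))
        assert model.inbag_fraction == pytest.approx(1 - 1 / np.e, abs=0.02)


class TestOob:
    def test_oob_matches_independent_aggregation(self, rng):
        # re-derive the OOB majority vote from the stored trees and in-bag
        # counts, one sample at a time
        X, y = gaussian_clouds(rng, n=60, d=1.5)
        model, oob = train_forest(X, y, ForestSpec(n_trees=25, mtry=2, seed=3))
        errors = 0
        n_votes = 0
        for i in range(len(y)):
            votes = []
            for t, tree in enumerate(model.trees_):
                if model.inbag_[t, i] == 0:
                    votes.append(int(tree.predict(X[i : i + 1])[0]))
            if not votes:
                continue
            n_votes += 1
            pred = 1 if np.mean(votes) >= 0.5 else 0
            errors += pred != y[i]
        assert oob.oob_error == pytest.approx(errors / n_votes, abs=1e-12)

    def test_all_correct_gives_zero(self, rng):
        X, y = gaussian_clouds(rng, n=100, d=12.0)
        _, oob = train_forest(X, y, ForestSpec(n_trees=200, mtry=2, seed=0))
        assert oob.oob_error == 0.0


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        m = _metrics_from_scores(y, y.astype(float), 0.5)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
        assert (m.f1, m.mcc, m.auc) == (1.0, 1.0, 1.0)

    def test_all_negative_on_study_test_split(self):
        # 9 fallers / 35 non-fallers, predictor always says non-faller
        y = np.array([1] * 9 + [0] * 35)
        m = _metrics_from_scores(y, np.zeros(44), 0.5)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == pytest.approx(35 / 44)

    def test_hand_confusion_matrix(self):
        # TP=2 FP=1 FN=1 TN=2
        y = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([1, 1, 0, 1, 0, 0], float)
        m = _metrics_from_scores(y, scores, 0.5)
        assert m.confusion == (2, 1, 1, 2)
        assert m.mcc == pytest.approx(1 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_identities_recomputed_from_confusion(self, rng):
        y = (rng.random(80) < 0.3).astype(int)
        scores = rng.random(80)
        m = _metrics_from_scores(y, scores, 0.5)
        tp, fp, fn, tn = m.confusion
        assert m.accuracy == pytest.approx((tp + tn) / 80)
        prec = tp / (tp + fp)
        assert m.f1 == pytest.approx(2 * prec * m.sensitivity / (prec + m.sensitivity))

    def test_tie_votes_predict_faller(self):
        y = np.array([1, 0])
        m = _metrics_from_scores(y, np.array([0.5, 0.5]), 0.5)
        assert m.confusion == (1, 1, 0, 0)


class TestSeedRepetition:
    def test_deterministic_closure_has_zero_se(self):
        runs = repeat_over_seeds(lambda s: MetricSet(0.8, 0.7, 0.9, 0.6, 0.5, 0.85), 10)
        agg = aggregate_metrics(runs)
        assert agg["accuracy"]["mean"] == pytest.approx(0.8)
        assert all(v["se"] == pytest.approx(0.0, abs=1e-12) for v in agg.values())

    def test_se_shrinks_with_seed_count(self, rng):
        X, y = gaussian_clouds(rng, n=120, d=1.0)
        Xt, yt = gaussian_clouds(rng, n=120, d=1.0)

        def run(seed):
            model, _ = train_forest(X, y, ForestSpec(n_trees=30, mtry=2, seed=seed))
            return evaluate(model, Xt, yt)

        se10 = aggregate_metrics(repeat_over_seeds(run, 10, base_seed=1))["auc"]["se"]
        se40 = aggregate_metrics(repeat_over_seeds(run, 40, base_seed=2))["auc"]["se"]
        assert se40 == pytest.approx(se10 / 2, rel=0.6)


class TestElbow:
    def test_signal_in_first_linear_pc_selects_one(self, rng):
        n = 120
        y = np.array([0, 1] * (n // 2))
        nl = rng.standard_normal((n, 3))               # pure noise
        lin = rng.standard_normal((n, 5)) * 0.1
        lin[:, 0] = y * 4 + rng.standard_normal(n) * 0.1  # perfect separator
        curve = incremental_pc_selection(nl, lin, y, ForestSpec(n_trees=60, mtry=2, seed=0))
        assert curve.k_star == 1
        assert curve.oob_error[1] < curve.oob_error[0]

    def test_no_linear_signal_keeps_nonlinear_only(self, rng):
        n = 120
        y = np.array([0, 1] * (n // 2))
        nl = rng.standard_normal((n, 3))
        nl[:, 0] = y * 5 + rng.standard_normal(n) * 0.1  # nl already perfect
        lin = rng.standard_normal((n, 4))
        curve = incremental_pc_selection(nl, lin, y, ForestSpec(n_trees=60, mtry=2, seed=0))
        assert curve.oob_error[0] == 0.0
        assert curve.k_star == 0  # ties broken toward fewer PCs

    def test_both_criteria_curves_emitted(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        curve = incremental_pc_selection(
            rng.standard_normal((n, 2)), rng.standard_normal((n, 3)), y,
            ForestSpec(n_trees=20, mtry=1, seed=0),
        )
        assert len(curve.k) == len(curve.oob_error) == len(curve.auc) == 4
        assert 0 <= curve.k_star <= 3

    def test_zero_linear_pcs_degenerates_to_single_point(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        curve = incremental_pc_selection(
            rng.standard_normal((n, 2)), np.empty((n, 0)), y,
            ForestSpec(n_trees=15, mtry=1, seed=0),
        )
        assert list(curve.k) == [0] and curve.k_star == 0


class TestImportances:
    def test_ranking_reproducible_across_seeds(self, rng):
        n, p = 300, 8
        X = rng.standard_normal((n, p))
        y = (X[:, 0] + 0.8 * X[:, 1] + 0.3 * rng.standard_normal(n) > 0).astype(int)

        def imps(seed):
            model, _ = train_forest(X, y, ForestSpec(n_trees=150, mtry=2, seed=seed))
            return model.feature_importances_

        rho = spearmanr(imps(1), imps(2)).statistic
        assert rho >= 0.8
        assert np.argmax(imps(1)) in (0, 1)
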