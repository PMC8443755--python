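"""Feature selection, CV tuning, metrics and importances."""

import warnings

import numpy as np
import pytest

from uaatol.learning import (
    ALGORITHMS,
    EvalReport,
    ModelSpec,
    build_pipeline,
    choose_k,
    dummy_stratified,
    evaluate,
    f1_from_precision_recall,
    grid_search_cv,
    kbest_select,
    logistic_importance,
    predict_krr_class,
    reconstruct_confusion,
)


def _spec(alg="LOG", grid=None):
    return ModelSpec(alg, grid or dict(ALGORITHMS[alg]["grid"]))


class TestKBestSelect:
    def test_informative_feature_found(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 10))
            y = rng.integers(0, 2, 40)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 2, 40)
            X[:, 4] += 10.0 * y  # class means 0 vs 10, sd 1
            hits += kbest_select(X, y, 1)[0] == 4
        assert hits >= 95

    def test_k_equals_n_features_returns_all_ordered_by_F(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = rng.integers(0, 2, 30)
        idx = kbest_select(X, y, 5)
        assert sorted(idx) == list(range(5))

    def test_duplicated_column_tie_prefers_earlier(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        y = (base > 0).astype(int)
        X = np.column_stack([rng.standard_normal(30), base, base])
        idx = kbest_select(X, y, 2)
        assert list(idx) == [1, 2]

    def test_constant_feature_warns_zero_F(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            idx = kbest_select(X, y, 2)
        assert idx[-1] == 0  # constant column ranked last


class TestChooseK:
    def test_singleton_k_range(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 8))
        y = np.array([0, 1] * 20)
        out = choose_k(X, y, [_spec()], k_range=[5], seed=0)
        assert out["LOG"]["k"] == 5

    def test_planted_three_feature_signal_concentrates(self):
        chosen = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 15))
            latent = X[:, 0] + X[:, 1] + X[:, 2]
            y = (latent > np.median(latent)).astype(int)
            out = choose_k(X, y, [_spec()], k_range=range(1, 11), seed=seed)
            chosen.append(out["LOG"]["k"])
        # most runs should land at or near the planted count
        assert np.median(chosen) <= 6
        assert sum(2 <= k <= 6 for k in chosen) >= 12

    def test_pure_noise_no_k_beats_chance_substantially(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 12))
        y = np.array([0, 1] * 30)
        out = choose_k(X, y, [_spec()], k_range=range(1, 11), seed=0)
        assert out["LOG"]["cv_accuracy"] < 0.75


class TestGridSearch:
    def test_grid_of_size_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4))
        y = np.array([0, 1] * 20)
        params, _ = grid_search_cv(_spec(grid={"C": [3.14]}), X, y, k=2, seed=0)
        assert params == {"C": 3.14}

    def test_separable_data_high_cv_accuracy(self):
        rng = np.random.default_rng(6)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = np.column_stack([y * 6.0 + rng.normal(0, 0.5, n),
                             rng.standard_normal(n)])
        _, report = grid_search_cv(_spec(), X, y, k=2, seed=0)
        assert report.accuracy >= 0.95

    def test_too_small_class_raises(self):
        X = np.random.default_rng(7).standard_normal((10, 3))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError, match="folds"):
            grid_search_cv(_spec(), X, y, k=2, folds=5)

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 10))
        y = rng.permutation([0, 1] * 30)
        _, report = grid_search_cv(
            _spec(grid={"C": [1.0]}), X, y, k=5, seed=0
        )
        # pooled CV accuracy within binomial noise of the 0.5 prior
        assert abs(report.accuracy - 0.5) <= 3 * np.sqrt(0.25 / 60)


class TestKrrAsClassifier:
    @pytest.mark.parametrize("value,expect", [(0.2, True), (-0.2, False), (0.0, False)])
    def test_threshold_rule(self, value, expect):
        assert predict_krr_class([value])[0] == expect

    def test_pipeline_fits_and_predicts(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 25 + [1] * 25)
        X = np.column_stack([y + rng.normal(0, 0.3, 50), rng.standard_normal(50)])
        pipe = build_pipeline(_spec("KRR"), k=2, params={"alpha": 0.1, "kernel": "linear"})
        pipe.fit(X, y.astype(bool))
        assert np.mean(pipe.predict(X) == y.astype(bool)) > 0.9


class TestEvaluate:
    def test_all_correct(self):
        rep = evaluate([True, False, True], [True, False, True])
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_published_holdout_metrics_reproduced(self):
        """A 10-sample holdout with counts (6,0,1,3) yields the printed
        0.900/1.000/0.857/0.923 metric quadruple."""
        rep = EvalReport(tp=6, fp=0, fn=1, tn=3)
        assert rep.as_dict() == {
            "tp": 6, "fp": 0, "fn": 1, "tn": 3,
            "accuracy": 0.9, "precision": 1.0,
            "recall": 0.857, "f1": 0.923,
        }

    def test_undefined_precision_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            rep = evaluate([False, False], [True, False])
        assert np.isnan(rep.precision)

    def test_counts_always_satisfy_formulas(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pred = rng.integers(0, 2, 15).astype(bool)
            truth = rng.integers(0, 2, 15).astype(bool)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = evaluate(pred, truth)
            assert rep.n == 15
            assert rep.accuracy == (rep.tp + rep.tn) / 15


PUBLISHED_PR_F1 = [
    # (precision, recall, printed F1): CV5 and holdout columns for the
    # energy-based and empirical score-function classifiers
    (0.875, 0.700, 0.778),
    (0.777, 0.777, 0.777),
    (0.810, 0.895, 0.850),
    (1.000, 0.857, 0.923),
    (1.000, 0.875, 0.933),
    (0.833, 1.000, 0.909),
    (0.750, 0.600, 0.667),
    (0.600, 0.667, 0.632),
    (0.778, 0.368, 0.500),
    (1.000, 0.714, 0.833),
    (0.857, 0.750, 0.800),
    (1.000, 0.400, 0.571),
]


class TestF1:
    @pytest.mark.parametrize("p,r,expect", PUBLISHED_PR_F1)
    def test_published_f1_identities(self, p, r, expect):
        from uaatol.dataset import round_half_away

        assert round_half_away(f1_from_precision_recall(p, r), 3) == expect

    def test_idempotent_on_equal_inputs(self):
        for x in (0.1, 0.5, 0.923, 1.0):
            assert f1_from_precision_recall(x, x) == pytest.approx(x)

    def test_undefined_at_zero(self):
        with pytest.raises(ValueError):
            f1_from_precision_recall(0.0, 0.0)


class TestDummy:
    def test_degenerate_prior_always_active(self):
        pred = dummy_stratified([True] * 10, 50, seed=0)
        assert pred.all()

    def test_closed_form_expected_accuracy(self):
        """Simulated accuracy matches p^2 + (1-p)^2 for prior p."""
        p = 0.53
        rng = np.random.default_rng(11)
        y_train = rng.random(1000) < p
        accs = []
        for seed in range(200):
            truth = rng.random(50) < p
            pred = dummy_stratified(y_train, 50, seed=seed)
            accs.append(np.mean(pred == truth))
        expect = p**2 + (1 - p) ** 2
        assert np.mean(accs) == pytest.approx(expect, abs=0.02)


class TestReconstructConfusion:
    def test_unique_published_holdout_solution(self):
        assert reconstruct_confusion(10, 0.900, 1.000, 0.857) == (6, 0, 1, 3)

    def test_other_published_holdout_solution(self):
        assert reconstruct_confusion(10, 0.900, 0.833, 1.000) == (5, 1, 0, 4)

    def test_degenerate_multiple_solutions(self):
        sols = reconstruct_confusion(2, 1.0, 1.0, 1.0)
        assert isinstance(sols, list)
        assert (1, 0, 0, 1) in sols and (2, 0, 0, 0) in sols

    def test_infeasible_metrics_return_none(self):
        assert reconstruct_confusion(10, 0.95, 1.0, 1.0) is None


class TestLogisticImportance:
    def test_two_coefficients(self):
        rep = logistic_importance([2.0, -1.0], ["a", "b"])
        assert rep.scores == {"a": 100.0, "b": 50.0}

    def test_single_feature_is_100(self):
        assert logistic_importance([0.3]).scores == {"feature_0": 100.0}

    def test_scale_invariance(self):
        a = logistic_importance([2.0, -1.0, 0.5]).scores
        b = logistic_importance([14.0, -7.0, 3.5]).scores
        assert a == b

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            rep = logistic_importance([0.0, 0.0])
        assert set(rep.scores.values()) == {0.0}


class TestLeakageHygiene:
    def test_in_fold_selection_does_not_overfit_noise(self):
        """With selection inside the CV pipeline, many-noise-feature data
        under permuted labels scores near chance; selecting on the full
        data first (leaky) scores notably higher."""
        from sklearn.model_selection import StratifiedKFold, cross_val_predict

        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 100))
        y = rng.permutation([0, 1] * 30).astype(bool)
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        pipe = build_pipeline(_spec(), k=5, params={"C": 1.0})
        clean = np.mean(cross_val_predict(pipe, X, y, cv=cv) == y)

        leaky_idx = kbest_select(X, y, 5)  # selection sees all rows
        leaky = np.mean(
            cross_val_predict(pipe, X[:, leaky_idx], y, cv=cv) == y
        )
        assert abs(clean - 0.5) <= 3 * np.sqrt(0.25 / 60)
        assert leaky > clean + 0.1  # the probe detects leakage when present
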