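import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropvote.features import (
    FeatureConfig,
    FeatureError,
    FeatureReport,
    binarize_features,
    feature_engineering,
    feature_importance,
    ngd,
    ngd_matrix,
    prune_redundant,
    rank_features,
    rising_star_scores,
    select_top_m,
    svm_objective,
    train_linear_svm,
)


class TestLinearSVM:
    def test_separating_coordinate_dominates(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 0, 1, 1])  # only coordinate 1 separates
        model = train_linear_svm(X, y)
        imp = feature_importance(model)
        assert imp[0] > 10 * imp[1]
        assert select_top_m(imp, 1) == [0]

    def test_duplicated_rows_same_direction(self, rng):
        X = rng.standard_normal((30, 3))
        y = (X[:, 0] > 0).astype(int)
        m1 = train_linear_svm(X, y, seed=0)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), seed=0)
        cos = m1.W @ m2.W / (np.linalg.norm(m1.W) * np.linalg.norm(m2.W))
        assert cos > 0.99

    def test_objective_matches_grid_oracle(self):
        """6-point instance: brute-force grid over (W1, W2, b) in [-3,3]^3,
        step 0.01. The continuous optimum can undercut the grid slightly;
        our solution must not exceed the grid optimum by more than 1e-3."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0],
                      [1.0, 1.0], [0.2, 0.5], [0.9, 0.4]])
        y = np.array([0, 0, 1, 1, 0, 1])
        ys = np.where(y > 0, 1.0, -1.0)
        vals = np.arange(-3, 3.0001, 0.01)
        W1, W2 = np.meshgrid(vals, vals, indexing="ij")
        Wgrid = np.stack([W1.ravel(), W2.ravel()], axis=1)
        best = np.inf
        base = 0.5 * (Wgrid**2).sum(1)
        for b in vals:
            margins = ys[None, :] * (Wgrid @ X.T + b)
            best = min(best, (base + np.maximum(0, 1 - margins).sum(1)).min())
        model = train_linear_svm(X, y)
        assert model.objective_value <= best + 1e-3
        assert model.objective_value >= best - 0.05  # grid resolution slack

    def test_objective_trace_non_increasing(self, rng):
        X = rng.standard_normal((60, 4))
        y = (X[:, 1] + 0.3 * rng.standard_normal(60) > 0).astype(int)
        model = train_linear_svm(X, y)
        trace = np.array(model.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_agrees_with_independent_solver(self, rng):
        from sklearn.svm import LinearSVC

        X = rng.standard_normal((150, 6))
        y = (X[:, 0] - X[:, 2] + 0.5 * rng.standard_normal(150) > 0).astype(int)
        ours = train_linear_svm(X, y)
        sk = LinearSVC(C=1.0, loss="hinge", max_iter=200000, tol=1e-10).fit(X, y)
        obj_sk = svm_objective(sk.coef_[0], sk.intercept_[0], X,
                               np.where(y > 0, 1.0, -1.0), 1.0)
        assert ours.objective_value <= obj_sk * 1.01

    def test_nonfinite_input_rejected(self):
        with pytest.raises(FeatureError):
            train_linear_svm(np.array([[np.inf, 0.0], [0.0, 1.0]]), np.array([0, 1]))


class TestImportanceSelection:
    def test_importance_is_absolute_weight(self):
        from cropvote.features import LinearSVMModel

        model = LinearSVMModel(W=np.array([-2.0, 0.5]), b=0.0, C=1.0, objective_value=0.0)
        np.testing.assert_array_equal(feature_importance(model), [2.0, 0.5])

    def test_top_m_order_and_ties(self):
        assert select_top_m(np.array([0.1, 0.9, 0.5]), 2) == [1, 2]
        assert select_top_m(np.array([0.5, 0.5, 0.1]), 2) == [0, 1]

    def test_m_equals_feature_count_keeps_all(self):
        assert select_top_m(np.array([3.0, 1.0, 2.0]), 3) == [0, 2, 1]

    def test_m_out_of_range(self):
        with pytest.raises(FeatureError):
            select_top_m(np.array([1.0]), 2)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 1.0]), min_size=2, max_size=12))
    def test_matches_sort_then_slice_oracle(self, values):
        imp = np.array(values)
        m = max(1, len(values) // 2)
        oracle = sorted(range(len(values)), key=lambda i: (-imp[i], i))[:m]
        assert select_top_m(imp, m) == oracle


class TestNGD:
    def test_binarize_median_rule(self):
        occ = binarize_features(np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert occ.indicators[:, 0].tolist() == [0, 0, 1, 1]
        assert occ.counts[0] == 2

    def test_identical_columns_identical_indicators(self, rng):
        x = rng.standard_normal(30)
        occ = binarize_features(np.stack([x, x], axis=1))
        assert (occ.indicators[:, 0] == occ.indicators[:, 1]).all()
        assert occ.joint[0, 1] == occ.counts[0]

    def test_joint_counts_match_and_oracle(self, rng):
        B = (rng.random((40, 6)) > 0.5).astype(float)
        occ = binarize_features(B, thresholds=np.full(6, 0.5))
        for i in range(6):
            for j in range(6):
                assert occ.joint[i, j] == int(np.sum(B[:, i] * B[:, j]))

    def test_hand_case(self):
        # (log4 - log2) / (log8 - log2) = log2 / log4 = 0.5, any base
        assert ngd(4, 2, 2, 8) == pytest.approx(0.5, abs=1e-15)

    def test_identical_features_zero(self):
        assert ngd(5, 5, 5, 10) == 0.0

    def test_sentinels(self):
        assert ngd(4, 2, 0, 8) == 1.0  # never co-occur
        assert ngd(0, 2, 0, 8) == 1.0  # dead feature
        assert ngd(8, 8, 8, 8) == 0.0  # both everywhere, identical
        assert ngd(8, 8, 7, 8) == 1.0  # denominator zero, not identical

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(FeatureError):
            ngd(2, 2, 3, 8)

    def test_matrix_matches_scalar_loop_oracle(self, rng):
        X = rng.standard_normal((50, 12))
        occ = binarize_features(X)
        C = ngd_matrix(occ)
        np.testing.assert_allclose(C, C.T, atol=0)
        for i in range(12):
            for j in range(12):
                expected = ngd(int(occ.counts[i]), int(occ.counts[j]),
                               int(occ.joint[i, j]), occ.N)
                assert C[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(np.diag(C), 0.0)

    def test_large_matrix_oracle_and_symmetry(self, rng):
        """50 features x 1000 samples: counting-oracle equality to 1e-12."""
        B = (rng.random((1000, 50)) > 0.6).astype(float)
        occ = binarize_features(B, thresholds=np.full(50, 0.5))
        C = ngd_matrix(occ)
        logN = np.log(occ.N)
        f = occ.counts.astype(float)
        for i in range(0, 50, 7):
            for j in range(50):
                fij = occ.joint[i, j]
                if fij == 0 or f[i] == 0 or f[j] == 0:
                    expected = 1.0
                else:
                    expected = (max(np.log(f[i]), np.log(f[j])) - np.log(fij)) / (
                        logN - min(np.log(f[i]), np.log(f[j]))
                    )
                assert abs(C[i, j] - expected) <= 1e-12


class TestPruning:
    def test_tau_zero_keeps_everything(self, rng):
        C = rng.random((5, 5))
        kept, log = prune_redundant(C, rng.random(5), tau=0.0)
        assert kept == list(range(5)) and log == []

    def test_duplicate_pair_drops_weaker(self):
        C = np.array([[0.0, 0.0], [0.0, 0.0]])
        kept, log = prune_redundant(C, np.array([0.9, 0.4]), tau=0.2)
        assert kept == [0] and log[0]["dropped"] == 1

    def test_no_kept_pair_below_tau(self, rng):
        X = rng.standard_normal((60, 8))
        X[:, 3] = X[:, 1]  # plant a duplicate
        occ = binarize_features(X)
        C = ngd_matrix(occ)
        kept, _ = prune_redundant(C, rng.random(8), tau=0.3)
        for a in kept:
            for b in kept:
                if a != b:
                    assert C[a, b] >= 0.3

    def test_duplicated_feature_pruned_exactly_once(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = X[:, 0]
        occ = binarize_features(X)
        C = ngd_matrix(occ)
        kept, log = prune_redundant(C, np.array([0.9, 0.5, 0.3, 0.4]), tau=0.1)
        assert 0 in kept and 2 not in kept
        assert len([e for e in log if e["dropped"] == 2]) == 1


class TestRisingStar:
    def test_alpha_one_is_historical_mean(self, rng):
        H = rng.standard_normal((4, 6))
        np.testing.assert_allclose(rising_star_scores(H, 1.0, 0.0),
                                   np.abs(H).mean(axis=0))

    def test_beta_one_is_latest(self, rng):
        H = rng.standard_normal((4, 6))
        np.testing.assert_allclose(rising_star_scores(H, 0.0, 1.0), np.abs(H[-1]))

    def test_linear_combination(self):
        H = np.array([[0.4], [0.8]])  # P=0.6, R=0.8
        assert rising_star_scores(H, 0.5, 0.5)[0] == pytest.approx(0.7)

    def test_single_model_history(self):
        H = np.array([[0.3, 0.9]])
        np.testing.assert_allclose(rising_star_scores(H, 0.5, 0.5),
                                   np.abs(H[0]))  # P = R, S = (a+b)*R

    def test_empty_history_errors(self):
        with pytest.raises(FeatureError):
            rising_star_scores(np.empty((0, 3)))

    def test_rank_descending_with_index_ties(self):
        assert rank_features(np.array([0.2, 0.9, 0.5])) == [1, 2, 0]
        assert rank_features(np.array([0.5, 0.5, 0.5])) == [0, 1, 2]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.1, 0.5, 0.9]), min_size=1, max_size=10))
    def test_rank_matches_sort_oracle(self, scores):
        s = np.array(scores)
        oracle = sorted(range(len(s)), key=lambda i: (-s[i], i))
        assert rank_features(s) == oracle


class TestFeatureEngineering:
    def test_informative_feature_recovered(self):
        """1 informative + 9 noise features: informative ranked first in at
        least 4 of 5 seeds."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 10))
            y = (X[:, 0] * 2 + rng.standard_normal(300) > 0).astype(int)
            report = feature_engineering(X, y, config=FeatureConfig(seed=seed))
            hits += report.ranked[0] == "f0"
        assert hits >= 4

    def test_keep_everything_configuration(self, rng):
        X = rng.standard_normal((100, 5))
        y = (X[:, 0] > 0).astype(int)
        report = feature_engineering(X, y, config=FeatureConfig(m=5, tau=0.0))
        assert set(report.kept) == {f"f{i}" for i in range(5)}
        assert sorted(report.ranked) == sorted(report.kept)

    def test_report_json_round_trip(self, rng):
        X = rng.standard_normal((80, 4))
        y = (X[:, 1] > 0).astype(int)
        report = feature_engineering(X, y)
        back = FeatureReport.from_json(report.to_json())
        assert back.to_json() == report.to_json()
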