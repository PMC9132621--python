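import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from sonotex.selection import (SelectorConfig, chi2_nca_select, chi2_scores,
                               fold_internal_cv_error, iterative_nca_select,
                               knn_cv_error, minmax_scale, nca_weights,
                               select_top_k)


def _labels(n0, n1):
    return np.array(["a"] * n0 + ["b"] * n1)


class TestChi2:
    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(20), np.random.default_rng(0).uniform(0, 1, 20)])
        r = chi2_scores(X, _labels(10, 10))
        assert r.scores[0] == 0.0

    def test_perfect_binary_feature_equals_hand_computed_statistic(self):
        # 2x2 table with 20/20 split and perfect association: sum (O-E)^2/E = n
        y = _labels(20, 20)
        X = (y == "b").astype(float)[:, None]
        r = chi2_scores(X, y)
        assert r.scores[0] == pytest.approx(40.0, abs=1e-12)

    def test_matches_scipy_contingency_on_discrete_features(self):
        # exhaustive cross-check against scipy's Pearson statistic on
        # small discrete instances (bins land exactly on the values)
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(10, 51))
            levels = int(rng.integers(2, 6))
            x = rng.integers(0, levels, n).astype(float)
            y = np.where(rng.random(n) < 0.5, "a", "b")
            if np.unique(y).size < 2 or min((y == "a").sum(), (y == "b").sum()) < 2:
                continue
            if np.unique(x).size < 2:
                continue
            r = chi2_scores(x[:, None], y, n_bins=levels)
            table = np.zeros((levels, 2))
            for xi, yi in zip(x.astype(int), y):
                table[xi, 0 if yi == "a" else 1] += 1
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            expected = chi2_contingency(table, correction=False).statistic
            assert r.scores[0] == pytest.approx(expected, rel=1e-10)

    def test_null_features_follow_chi2_distribution(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (200, 1000))
        y = np.where(rng.random(200) < 0.5, "a", "b")
        sc = chi2_scores(X, y).scores
        df = 9  # (10 bins - 1) * (2 classes - 1)
        assert (sc > chi2_dist.ppf(0.5, df)).mean() == pytest.approx(0.5, abs=0.05)
        assert (sc > chi2_dist.ppf(0.9, df)).mean() == pytest.approx(0.1, abs=0.025)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            chi2_scores(np.zeros((10, 2)), np.array(["a"] * 10))


class TestTopK:
    def test_all_features_when_k_equals_width(self):
        X = np.random.default_rng(2).uniform(0, 1, (30, 7))
        r = chi2_scores(X, _labels(15, 15))
        assert sorted(select_top_k(r, 7).tolist()) == list(range(7))

    def test_ties_break_by_ascending_index(self):
        y = _labels(10, 10)
        col = (y == "b").astype(float)
        X = np.column_stack([col, col, col])  # identical scores
        r = chi2_scores(X, y)
        assert select_top_k(r, 2).tolist() == [0, 1]

    def test_k_beyond_width_rejected(self):
        X = np.random.default_rng(3).uniform(0, 1, (20, 5))
        with pytest.raises(ValueError):
            select_top_k(chi2_scores(X, _labels(10, 10)), 6)


class TestNCA:
    def test_informative_feature_gets_largest_weight(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = _labels(30, 30)
            informative = (y == "b").astype(float)
            noise = rng.uniform(0, 1, (60, 5))
            X = minmax_scale(np.column_stack([noise[:, :2], informative, noise[:, 2:]]))
            w = nca_weights(X, y, seed=seed).w
            assert int(np.argmax(w)) == 2, f"seed {seed}"

    def test_duplicated_columns_get_near_equal_weights(self):
        rng = np.random.default_rng(5)
        y = _labels(25, 25)
        base = (y == "b") * 0.8 + rng.normal(0, 0.1, 50)
        X = minmax_scale(np.column_stack([base, base, rng.uniform(0, 1, 50)]))
        w = nca_weights(X, y).w
        assert abs(w[0] - w[1]) <= 0.05 * max(w[0], w[1], 1e-12)

    def test_huge_regularization_shrinks_weights(self):
        rng = np.random.default_rng(6)
        X = minmax_scale(rng.uniform(0, 1, (40, 4)))
        w = nca_weights(X, _labels(20, 20), lam=1e6).w
        assert np.all(w <= 1e-2)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            nca_weights(np.zeros((3, 2)), np.array(["a", "a", "b"]))


class TestKnnCvError:
    def test_identical_twin_dataset_has_zero_error(self):
        from sklearn.model_selection import StratifiedKFold
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 1, (4, 3))
        X = np.tile(base, (6, 1))  # six exact copies of every point
        y = np.tile(_labels(2, 2), 6)
        # precondition of the example: every held-out point keeps an
        # identical same-class twin in the training fold
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        for tr, te in skf.split(X, y):
            for i in te:
                assert any((X[j] == X[i]).all() and y[j] == y[i] for j in tr)
        assert knn_cv_error(X, y, k=1, folds=2, seed=0) == 0.0

    def test_null_labels_give_chance_error(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (200, 5))
            y = np.array(["a", "b"] * 100)
            errs.append(knn_cv_error(X, y, k=1, folds=10, seed=seed))
        assert np.mean(errs) == pytest.approx(0.5, abs=0.08)

    def test_xor_arrangement_is_always_misclassified(self):
        # nearest neighbour of every XOR corner is the opposite class
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array(["a", "a", "b", "b"])
        assert knn_cv_error(X, y, k=1, folds=2, seed=0) == 1.0

    def test_k_exceeding_training_fold_rejected(self):
        X = np.random.default_rng(8).uniform(0, 1, (8, 2))
        with pytest.raises(ValueError):
            knn_cv_error(X, _labels(4, 4), k=10, folds=2, seed=0)


class TestIterativeSelect:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(9)
        y = _labels(25, 25)
        informative = (y == "b")[:, None] * 0.9 + rng.normal(0, 0.15, (50, 3))
        X = np.column_stack([informative, rng.uniform(0, 1, (50, 27))])
        w = np.concatenate([[3.0, 2.5, 2.0], rng.uniform(0, 0.5, 27)])
        return X, y, w

    def test_degenerate_range_returns_that_size(self, toy):
        X, y, w = toy
        res = iterative_nca_select(X, y, w, range_lo=5, range_hi=5, folds=5)
        assert res.l_star == 5
        assert res.error_curve.shape == (1,)

    def test_min_error_is_curve_minimum_and_prefix_selected(self, toy):
        X, y, w = toy
        res = iterative_nca_select(X, y, w, range_lo=2, range_hi=30, folds=5)
        assert res.min_error == res.error_curve.min()
        assert np.array_equal(res.selected, res.weight_order[:res.l_star])
        # argmin tie rule: no smaller prefix attains the minimum
        first = np.flatnonzero(res.error_curve == res.min_error)[0]
        assert res.candidate_sizes[first] == res.l_star

    def test_fast_path_matches_generic_knn_cv(self, toy):
        X, y, w = toy
        res = iterative_nca_select(X, y, w, range_lo=2, range_hi=20, folds=5, seed=3)
        Xs = minmax_scale(X)
        order = res.weight_order
        for i, l in enumerate(res.candidate_sizes):
            generic = knn_cv_error(Xs[:, order[:l]], y, k=1, folds=5, seed=3)
            assert res.error_curve[i] == pytest.approx(generic, abs=1e-12)

    def test_range_clamped_with_warning(self, toy):
        X, y, w = toy
        with pytest.warns(RuntimeWarning, match="clamped"):
            res = iterative_nca_select(X, y, w, range_lo=10, range_hi=500, folds=5)
        assert res.candidate_sizes[-1] == X.shape[1]

    def test_invalid_range_rejected(self, toy):
        X, y, w = toy
        with pytest.raises(ValueError):
            iterative_nca_select(X, y, w, range_lo=20, range_hi=10)


class TestTwoStageSelector:
    def test_selected_indices_come_from_chi2_prefilter(self):
        rng = np.random.default_rng(10)
        y = _labels(20, 20)
        X = rng.uniform(0, 1, (40, 1200))
        cfg = SelectorConfig(top_k=1000, range_lo=10, range_hi=50, folds=4,
                             sweep_step=10, nca_max_iter=20)
        res = chi2_nca_select(X, y, cfg, seed=0)
        kept = set(select_top_k(chi2_scores(X, y), 1000).tolist())
        assert set(res.selected.tolist()) <= kept
        assert res.l_star <= 50

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(11)
        y = _labels(15, 15)
        X = rng.uniform(0, 1, (30, 200))
        cfg = SelectorConfig(top_k=100, range_lo=5, range_hi=30, folds=3,
                             sweep_step=5, nca_max_iter=20)
        r1 = chi2_nca_select(X, y, cfg, seed=4)
        r2 = chi2_nca_select(X, y, cfg, seed=4)
        assert r1.to_dict() == r2.to_dict()


class TestLeakageModes:
    def test_whole_data_selection_is_optimistic_on_noise_but_fold_internal_is_not(self):
        cfg = SelectorConfig(top_k=100, range_lo=10, range_hi=100, folds=5,
                             sweep_step=10, nca_max_iter=30)
        whole, honest = [], []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            y = _labels(30, 30)
            X = rng.uniform(0, 1, (60, 400))  # label-independent features
            whole.append(chi2_nca_select(X, y, cfg, seed=seed).min_error)
            honest.append(fold_internal_cv_error(X, y, cfg, folds=5, seed=seed))
        assert np.mean(honest) == pytest.approx(0.5, abs=0.1)
        assert np.mean(whole) <= np.mean(honest) - 0.1
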