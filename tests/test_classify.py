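import numpy as np
import pytest
from scipy.stats import norm

from sonotex.classify import (ClassifierSpec, Dim, bayes_tune, cross_validate,
                              default_specs, enumerate_space, train_predict)


def _blobs(n_per, sep, seed, d=2):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(sep, 1, (n_per, d))
    return np.vstack([a, b]), np.array(["a"] * n_per + ["b"] * n_per)


class TestSpecs:
    def test_reference_hyperparameters(self):
        specs = default_specs()
        assert specs["knn"].params == {"k": 70, "metric": "correlation",
                                       "weights": "squared_inverse"}
        assert specs["ld"].params["gamma"] == 0.0
        assert specs["svm"].params == {"box_constraint": 3.0, "kernel_scale": 5.6}
        assert specs["dt"].params["max_splits"] == 51

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("mlp", {})


class TestTrainPredict:
    def test_one_nn_memorizes_training_points(self):
        X, y = _blobs(20, 1.0, 0)
        spec = ClassifierSpec("knn", {"k": 1, "metric": "euclidean",
                                      "weights": "none"})
        pred, scores = train_predict(spec, X, y, X)
        assert (pred == y).all()
        assert scores.shape == (40,)

    def test_svm_separates_wide_margin_blobs(self):
        X, y = _blobs(30, 30.0, 1)  # margin far beyond the kernel scale
        cv = cross_validate(default_specs()["svm"], X, y, folds=5, seed=0)
        assert cv.pooled_error == 0.0

    def test_nb_approaches_analytic_bayes_error(self):
        # two univariate normals N(0,1) vs N(2,1): Bayes error = Phi(-1)
        rng = np.random.default_rng(2)
        n = 1000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])[:, None]
        y = np.array(["a"] * n + ["b"] * n)
        cv = cross_validate(default_specs()["nb"], X, y, folds=10, seed=0)
        assert cv.pooled_error == pytest.approx(norm.cdf(-1), abs=0.03)

    def test_correlation_knn_matches_scipy_correlation_distance(self):
        # the row-standardized euclidean implementation must rank
        # neighbours exactly like scipy's correlation distance
        from scipy.spatial.distance import cdist
        rng = np.random.default_rng(7)
        Xtr, ytr = _blobs(20, 1.0, 7, d=6)
        Xte = rng.normal(0.5, 1, (15, 6))
        spec = ClassifierSpec("knn", {"k": 3, "metric": "correlation",
                                      "weights": "none"})
        pred, _ = train_predict(spec, Xtr, ytr, Xte)
        d = cdist(Xte, Xtr, metric="correlation")
        oracle = []
        for row in d:
            nn = np.argsort(row, kind="stable")[:3]
            votes = ytr[nn]
            vals, counts = np.unique(votes, return_counts=True)
            oracle.append(vals[np.argmax(counts)])
        assert (pred == np.array(oracle)).all()

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_predict(default_specs()["nb"], np.zeros((5, 2)),
                          np.array(["a"] * 5), np.zeros((2, 2)))


class TestCrossValidate:
    def test_twin_dataset_zero_error_with_one_nn(self):
        from sklearn.model_selection import StratifiedKFold
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, (4, 3))
        X = np.tile(base, (6, 1))
        y = np.tile(np.array(["a", "a", "b", "b"]), 6)
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        for tr, te in skf.split(X, y):  # twin available in every train fold
            for i in te:
                assert any((X[j] == X[i]).all() and y[j] == y[i] for j in tr)
        spec = ClassifierSpec("knn", {"k": 1, "metric": "euclidean",
                                      "weights": "none"})
        assert cross_validate(spec, X, y, folds=2, seed=0).pooled_error == 0.0

    def test_permuted_labels_give_chance_error(self):
        spec = ClassifierSpec("knn", {"k": 1, "metric": "euclidean",
                                      "weights": "none"})
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (100, 4))
            y = np.array(["a", "b"] * 50)
            errs.append(cross_validate(spec, X, y, folds=5, seed=seed).pooled_error)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.08)

    def test_every_row_predicted_once_and_folds_balanced(self):
        X, y = _blobs(25, 1.0, 4)
        cv = cross_validate(default_specs()["dt"], X, y, folds=5, seed=0)
        assert cv.y_pred.shape == y.shape
        sizes = np.bincount(cv.fold_assignments)
        assert sizes.max() - sizes.min() <= 1
        assert cv.pooled_error == (cv.y_pred != y).mean()

    def test_class_smaller_than_folds_rejected(self):
        X, y = _blobs(3, 1.0, 5)
        with pytest.raises(ValueError):
            cross_validate(default_specs()["nb"], X, y, folds=5, seed=0)


class TestBayesTune:
    @pytest.fixture(scope="class")
    def data(self):
        return _blobs(30, 1.5, 6, d=3)

    def test_budget_covering_finite_space_finds_grid_minimum(self, data):
        X, y = data
        space = [Dim("k", "int", 1, 20)]
        trace = bayes_tune("knn", X, y, budget=20, seed=0, folds=5, space=space)
        grid = enumerate_space(space)
        errs = {p["k"]: cross_validate(
            ClassifierSpec("knn", {**default_specs()["knn"].params, **p}),
            X, y, folds=5, seed=0).pooled_error for p in grid}
        assert trace.best_error == min(errs.values())

    def test_partial_budget_lands_near_grid_minimum(self, data):
        X, y = data
        space = [Dim("k", "int", 1, 20)]
        trace = bayes_tune("knn", X, y, budget=12, seed=1, folds=5, space=space)
        grid_best = min(
            cross_validate(ClassifierSpec(
                "knn", {**default_specs()["knn"].params, "k": k}),
                X, y, folds=5, seed=1).pooled_error
            for k in range(1, 21))
        assert trace.best_error <= grid_best + 0.05

    def test_same_seed_gives_identical_trace(self, data):
        X, y = data
        t1 = bayes_tune("svm", X, y, budget=8, seed=2, folds=5)
        t2 = bayes_tune("svm", X, y, budget=8, seed=2, folds=5)
        assert t1.to_dict() == t2.to_dict()

    def test_incumbent_never_worse_than_seeded_default(self, data):
        X, y = data
        for family in ("svm", "dt", "nb"):
            trace = bayes_tune(family, X, y, budget=8, seed=3, folds=5)
            default_err = cross_validate(default_specs()[family], X, y,
                                         folds=5, seed=3).pooled_error
            assert trace.best_error <= default_err + 1e-12
            assert trace.best_error == min(e for _, e in trace.iterations)

    def test_tiny_budget_rejected(self, data):
        X, y = data
        with pytest.raises(ValueError):
            bayes_tune("svm", X, y, budget=3, seed=0)
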