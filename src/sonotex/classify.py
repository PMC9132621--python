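"""Five shallow classifier families with Bayesian hyperparameter tuning.

The families ship with a fixed reference parameterisation: kNN (k=70, correlation distance, squared-inverse
vote weights), linear discriminant (no shrinkage), Gaussian naive
Bayes, Gaussian-kernel SVM (box constraint 3, kernel scale 5.6 — i.e.
gamma = 1/5.6^2) and a decision tree (entropy split, at most 51
splits).  Evaluation is stratified seeded k-fold cross-validation with
pooled predictions; tuning is a Gaussian-process surrogate with
expected-improvement acquisition over family-specific search spaces,
with the reference spec seeded into the initial design so the incumbent
can never be worse than it on the same folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "CVResult",
    "TuningTrace",
    "default_specs",
    "build_estimator",
    "train_predict",
    "cross_validate",
    "bayes_tune",
    "default_search_space",
    "enumerate_space",
]

FAMILIES = ("knn", "ld", "nb", "svm", "dt")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


def default_specs() -> dict[str, ClassifierSpec]:
    """Reference hyperparameters for each family."""
    return {
        "knn": ClassifierSpec("knn", {"k": 70, "metric": "correlation",
                                      "weights": "squared_inverse"}),
        "ld": ClassifierSpec("ld", {"gamma": 0.0}),
        "nb": ClassifierSpec("nb", {"var_smoothing": 1e-9}),
        "svm": ClassifierSpec("svm", {"box_constraint": 3.0, "kernel_scale": 5.6}),
        "dt": ClassifierSpec("dt", {"max_splits": 51}),
    }


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / (dist ** 2 + 1e-12)


def _row_standardize(X: np.ndarray) -> np.ndarray:
    """Center and unit-normalize each row (zero-variance rows -> zero)."""
    X = np.asarray(X, dtype=np.float64)
    c = X - X.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(c, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return c / nrm


def _squared_inverse_corr(dist: np.ndarray) -> np.ndarray:
    # euclidean distance d between row-standardized vectors maps to the
    # correlation distance d^2/2; weight by the inverse square of the latter
    d_corr = dist ** 2 / 2.0
    return 1.0 / (d_corr ** 2 + 1e-12)


def build_estimator(spec: ClassifierSpec, seed: int = 0, n_train: int | None = None):
    """Instantiate the sklearn estimator behind a spec.

    ``n_train`` lets kNN clamp k to the available neighbors.
    """
    p = spec.params
    if spec.family == "knn":
        k = int(p.get("k", 70))
        if n_train is not None and k > n_train:
            warnings.warn(f"kNN k={k} clamped to training size {n_train}",
                          RuntimeWarning, stacklevel=2)
            k = n_train
        wt = p.get("weights", "squared_inverse")
        metric = p.get("metric", "correlation")
        if metric == "correlation":
            # correlation distance == ||z_u - z_v||^2 / 2 on row-standardized
            # vectors: euclidean kNN on z gives the same neighbor ranking and
            # stays defined for zero-variance rows
            from sklearn.pipeline import Pipeline
            from sklearn.preprocessing import FunctionTransformer

            if wt == "squared_inverse":
                weights = _squared_inverse_corr
            elif wt == "none":
                weights = "uniform"
            else:
                weights = wt
            return Pipeline([
                ("standardize", FunctionTransformer(_row_standardize)),
                ("knn", KNeighborsClassifier(n_neighbors=k, metric="euclidean",
                                             weights=weights, algorithm="brute")),
            ])
        if wt == "squared_inverse":
            weights = _squared_inverse
        elif wt == "none":
            weights = "uniform"
        else:
            weights = wt
        return KNeighborsClassifier(n_neighbors=k, metric=metric,
                                    weights=weights, algorithm="brute")
    if spec.family == "ld":
        gamma = float(p.get("gamma", 0.0))
        if gamma > 0:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=gamma)
        # svd solver handles singular within-class covariance via pseudoinverse
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.family == "nb":
        return GaussianNB(var_smoothing=float(p.get("var_smoothing", 1e-9)))
    if spec.family == "svm":
        scale = float(p.get("kernel_scale", 5.6))
        return SVC(C=float(p.get("box_constraint", 3.0)), kernel="rbf",
                   gamma=1.0 / scale ** 2, random_state=seed)
    if spec.family == "dt":
        return DecisionTreeClassifier(criterion="entropy",
                                      max_leaf_nodes=int(p.get("max_splits", 51)) + 1,
                                      random_state=seed)
    raise ValueError(spec.family)


def _positive_scores(est, X, classes, positive):
    """Continuous score for the positive class, usable for ROC."""
    pos_col = int(np.flatnonzero(classes == positive)[0])
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, pos_col]
    dec = est.decision_function(X)
    # sklearn's decision_function is oriented toward classes_[1]
    return dec if pos_col == 1 else -dec


def train_predict(spec: ClassifierSpec, X_train, y_train, X_test,
                  seed: int = 0, positive=None):
    """Fit one spec and predict labels + positive-class scores."""
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if positive is None:
        positive = classes[-1]
    est = build_estimator(spec, seed=seed, n_train=len(y_train))
    try:
        est.fit(X_train, y_train)
    except (np.linalg.LinAlgError, IndexError, FloatingPointError):
        if spec.family != "ld":
            raise
        warnings.warn("singular within-class covariance; refitting LD with a "
                      "ridge (lsqr + shrinkage)", RuntimeWarning, stacklevel=2)
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-3)
        est.fit(X_train, y_train)
    return est.predict(X_test), _positive_scores(est, X_test, est.classes_, positive)


@dataclass(frozen=True)
class CVResult:
    fold_assignments: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    pooled_error: float
    positive: object
    seed: int


def cross_validate(spec: ClassifierSpec, X, y, folds: int = 10, seed: int = 0,
                   positive=None) -> CVResult:
    """Stratified seeded k-fold CV; every observation predicted once."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < folds:
        raise ValueError(f"smallest class ({counts.min()}) smaller than folds={folds}")
    if positive is None:
        positive = classes[-1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=np.int64)
    pred = np.empty(len(y), dtype=y.dtype)
    scores = np.empty(len(y))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        assign[te] = f
        pred[te], scores[te] = train_predict(spec, X[tr], y[tr], X[te],
                                             seed=seed, positive=positive)
    return CVResult(fold_assignments=assign, y_true=y.copy(), y_pred=pred,
                    scores=scores, pooled_error=float((pred != y).mean()),
                    positive=positive, seed=seed)


# ---------------------------------------------------------------------------
# Bayesian tuning


@dataclass(frozen=True)
class Dim:
    name: str
    kind: str                      # "int" | "float" | "cat"
    lo: float = 0.0
    hi: float = 1.0
    log: bool = False
    choices: tuple = ()


def default_search_space(family: str) -> list[Dim]:
    if family == "knn":
        return [Dim("k", "int", 1, 100),
                Dim("metric", "cat", choices=("euclidean", "correlation", "cosine"))]
    if family == "svm":
        return [Dim("box_constraint", "float", 1e-2, 1e3, log=True),
                Dim("kernel_scale", "float", 1e-2, 1e2, log=True)]
    if family == "dt":
        return [Dim("max_splits", "int", 2, 200)]
    if family == "ld":
        return [Dim("gamma", "float", 0.0, 1.0)]
    if family == "nb":
        return [Dim("var_smoothing", "float", 1e-12, 1e-6, log=True)]
    raise ValueError(family)


def _encode(params: dict, space: list[Dim]) -> np.ndarray:
    vec = []
    for dim in space:
        v = params[dim.name]
        if dim.kind == "cat":
            one_hot = [1.0 if c == v else 0.0 for c in dim.choices]
            vec.extend(one_hot)
        else:
            x, lo, hi = float(v), dim.lo, dim.hi
            if dim.log:
                x, lo, hi = np.log(x), np.log(lo), np.log(hi)
            vec.append((x - lo) / (hi - lo))
    return np.array(vec)


def _sample(space: list[Dim], rng: np.random.Generator) -> dict:
    out = {}
    for dim in space:
        if dim.kind == "cat":
            out[dim.name] = dim.choices[rng.integers(len(dim.choices))]
        elif dim.kind == "int":
            out[dim.name] = int(rng.integers(int(dim.lo), int(dim.hi) + 1))
        else:
            if dim.log:
                out[dim.name] = float(np.exp(rng.uniform(np.log(dim.lo),
                                                         np.log(dim.hi))))
            else:
                out[dim.name] = float(rng.uniform(dim.lo, dim.hi))
    return out


def enumerate_space(space: list[Dim]) -> list[dict] | None:
    """Full enumeration for finite (int/cat-only) spaces, else None."""
    grids = []
    for dim in space:
        if dim.kind == "cat":
            grids.append([(dim.name, c) for c in dim.choices])
        elif dim.kind == "int":
            grids.append([(dim.name, int(v))
                          for v in range(int(dim.lo), int(dim.hi) + 1)])
        else:
            return None
    out = [{}]
    for grid in grids:
        out = [{**d, k: v} for d in out for (k, v) in grid]
    return out


def _key(params: dict, space: list[Dim]):
    return tuple(params[d.name] for d in space)


@dataclass(frozen=True)
class TuningTrace:
    family: str
    iterations: list = dc_field(repr=False)   # [(params, cv_error), ...]
    best: ClassifierSpec = None
    best_error: float = np.nan
    budget: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"family": self.family, "budget": self.budget, "seed": self.seed,
                "best": self.best.params, "best_error": float(self.best_error),
                "iterations": [{"params": p, "error": float(e)}
                               for p, e in self.iterations]}


def bayes_tune(family: str, X, y, budget: int = 100, seed: int = 0,
               folds: int = 10, space: list[Dim] | None = None,
               include_default: bool = True) -> TuningTrace:
    """Gaussian-process Bayesian optimization of the CV error.

    A Matern-5/2 GP with a white-noise term models the pooled k-fold CV
    misclassification over the encoded search space; each iteration
    evaluates the not-yet-tried candidate maximizing expected
    improvement.  All CV evaluations reuse one seeded fold partition so
    errors are comparable; the run is fully deterministic given the seed.
    """
    if budget < 5:
        raise ValueError("budget must be >= 5")
    space = space if space is not None else default_search_space(family)
    rng = np.random.default_rng(seed)
    defaults = default_specs()[family].params

    def in_space(params: dict) -> bool:
        for dim in space:
            if dim.name not in params:
                return False
            v = params[dim.name]
            if dim.kind == "cat":
                if v not in dim.choices:
                    return False
            elif not (dim.lo <= float(v) <= dim.hi):
                return False
        return True

    def evaluate(params: dict) -> float:
        full = {**defaults, **params}
        # clamp kNN k to what the training folds can provide
        if family == "knn":
            min_train = len(y) - int(np.ceil(len(y) / folds))
            full["k"] = min(int(full["k"]), max(1, min_train))
        return cross_validate(ClassifierSpec(family, full), X, y,
                              folds=folds, seed=seed).pooled_error

    all_candidates = enumerate_space(space)
    evaluated: dict[tuple, float] = {}
    trace: list[tuple[dict, float]] = []

    def run(params: dict) -> None:
        key = _key(params, space)
        if key in evaluated:
            return
        err = evaluate(params)
        evaluated[key] = err
        trace.append((params, err))

    if include_default and in_space(defaults):
        run({d.name: defaults[d.name] for d in space})
    n_init = min(max(4, len(space) + 1), budget)
    attempts = 0
    while len(trace) < n_init and attempts < 200:
        run(_sample(space, rng))
        attempts += 1

    kernel = (ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
              + WhiteKernel(noise_level=1e-4))
    while len(trace) < budget:
        if all_candidates is not None:
            cands = [c for c in all_candidates if _key(c, space) not in evaluated]
            if not cands:
                break
        else:
            cands = [_sample(space, rng) for _ in range(256)]
            cands = [c for c in cands if _key(c, space) not in evaluated]
            if not cands:
                continue
        Xgp = np.array([_encode(p, space) for p, _ in trace])
        ygp = np.array([e for _, e in trace])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          random_state=seed, alpha=1e-8)
            gp.fit(Xgp, ygp)
        Xc = np.array([_encode(c, space) for c in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best_f = ygp.min()
        sd = np.maximum(sd, 1e-12)
        z = (best_f - mu) / sd
        ei = (best_f - mu) * norm.cdf(z) + sd * norm.pdf(z)
        run(cands[int(np.argmax(ei))])

    errs = np.array([e for _, e in trace])
    best_i = int(np.argmin(errs))
    best_params = {**defaults, **trace[best_i][0]}
    return TuningTrace(family=family, iterations=trace,
                       best=ClassifierSpec(family, best_params),
                       best_error=float(errs[best_i]), budget=budget, seed=seed)
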