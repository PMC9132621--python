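"""Two-stage feature selection: chi-square filter then iterative NCA.

Stage one ranks every feature by the Pearson chi-square statistic of a
binned feature-vs-class contingency table and keeps the top ``k``
(default 1000) — a fast univariate filter that makes the second stage
tractable on the 99,572-column image feature matrix.

Stage two learns per-feature relevance weights with neighborhood
component analysis (NCA: maximize a soft leave-one-out nearest-neighbor
objective), sorts features by weight, and sweeps prefix sizes ``l`` in a
configured range, scoring each prefix by stratified k-fold 1-NN
cross-validated misclassification; the smallest ``l`` attaining the
minimum error wins.

The default whole-data mode fits the selector on all data once (which leaks
label information into any subsequent cross-validated estimate); a
fold-internal mode that refits selection inside each outer fold is
provided for honest error estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "ChiRanking",
    "SelectionResult",
    "SelectorConfig",
    "minmax_scale",
    "chi2_scores",
    "select_top_k",
    "nca_weights",
    "knn_cv_error",
    "iterative_nca_select",
    "chi2_nca_select",
    "fold_internal_cv_error",
    "plot_error_curve",
]


def _check_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x features)")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 observations")
    return X, y, classes


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Per-column min-max rescaling to [0, 1]; constant columns map to 0."""
    X = np.asarray(X, dtype=np.float64)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


@dataclass(frozen=True)
class ChiRanking:
    """Chi-square score per feature and the descending-score order
    (ties broken by ascending feature index)."""

    scores: np.ndarray
    order: np.ndarray


def chi2_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> ChiRanking:
    """Chi-square association of each feature with the class label.

    Continuous features are discretized into ``n_bins`` equal-width bins
    over their observed range; the statistic is the Pearson
    ``sum((O-E)^2 / E)`` of the bin-by-class contingency table.  Constant
    features score 0.
    """
    X, y, classes = _check_xy(X, y)
    n, d = X.shape
    y_idx = np.searchsorted(classes, y)
    n_classes = classes.size

    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    const = span == 0
    span_safe = np.where(const, 1.0, span)
    bins = np.floor((X - lo) / span_safe * n_bins).astype(np.int64)
    np.clip(bins, 0, n_bins - 1, out=bins)

    # one flat bincount over (feature, bin, class) for speed
    flat = (np.arange(d)[None, :] * n_bins + bins) * n_classes + y_idx[:, None]
    table = np.bincount(flat.ravel(), minlength=d * n_bins * n_classes)
    table = table.reshape(d, n_bins, n_classes).astype(np.float64)

    row = table.sum(axis=2, keepdims=True)        # (d, bins, 1)
    col = table.sum(axis=1, keepdims=True)        # (d, 1, classes)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    scores = contrib.sum(axis=(1, 2))
    scores[const] = 0.0
    order = np.lexsort((np.arange(d), -scores))
    return ChiRanking(scores=scores, order=order)


def select_top_k(ranking: ChiRanking, k: int = 1000) -> np.ndarray:
    """First ``k`` feature indices of the ranking, order preserved."""
    if k < 1 or k > ranking.order.size:
        raise ValueError(f"k={k} outside [1, {ranking.order.size}]")
    return ranking.order[:k].copy()


@dataclass(frozen=True)
class NCAWeights:
    w: np.ndarray
    lam: float
    seed: int
    objective: float
    n_iter: int
    converged: bool


def _nca_objective_grad(A, w, p_mask_same, need_grad=True):
    """Soft LOO objective sum_i p_i - lam*|w|^2 and its gradient.

    ``A`` is the (n, n, d) tensor of absolute coordinate differences;
    distances are d_ij = sum_r w_r^2 |x_ir - x_jr| (the weighted-L1 NCA
    form).  lam term added by the caller.
    """
    n = A.shape[0]
    w2 = w ** 2
    dist = A @ w2                     # (n, n)
    np.fill_diagonal(dist, np.inf)
    shift = dist.min(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    ker = np.exp(-(dist - shift))
    ker[~np.isfinite(ker)] = 0.0
    denom = ker.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    p = ker / denom                   # p_ij, p_ii = 0
    p_i = (p * p_mask_same).sum(axis=1)
    obj = p_i.sum()
    if not need_grad:
        return obj, None, p_i
    m = p * (p_i[:, None] - p_mask_same)   # (n, n)
    grad = 2.0 * w * np.einsum("ij,ijr->r", m, A)
    return obj, grad, p_i


def nca_weights(X: np.ndarray, y: np.ndarray, lam: float | None = None,
                seed: int = 0, max_iter: int = 200, tol: float = 1e-6,
                step: float = 1.0) -> NCAWeights:
    """Neighborhood-component-analysis relevance weights.

    Maximizes ``sum_i p_i - lam * sum_r w_r^2`` with
    ``p_ij proportional to exp(-sum_r w_r^2 |x_ir - x_jr|)`` by projected
    gradient ascent from an all-ones start, halving the step whenever the
    objective would decrease.  Input features should be min-max scaled.
    ``lam`` defaults to ``1/n``.  The procedure is deterministic; the
    seed is recorded for provenance.
    """
    X, y, _ = _check_xy(X, y)
    n, d = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    lam = 1.0 / n if lam is None else float(lam)

    # |x_ir - x_jr| tensor; n and d are desk-scale here (post chi-square)
    A = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    w = np.ones(d)
    obj, grad, _ = _nca_objective_grad(A, w, same)
    obj -= lam * (w ** 2).sum()
    grad -= 2.0 * lam * w
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        accepted = False
        for _ in range(30):
            w_new = np.maximum(w + step * grad, 0.0)
            obj_new, _, _ = _nca_objective_grad(A, w_new, same, need_grad=False)
            obj_new -= lam * (w_new ** 2).sum()
            if obj_new >= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        rel = abs(obj_new - obj) / max(abs(obj), 1e-12)
        w = w_new
        obj = obj_new
        _, grad, _ = _nca_objective_grad(A, w, same)
        grad -= 2.0 * lam * w
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("NCA gradient ascent did not converge; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    return NCAWeights(w=w, lam=lam, seed=seed, objective=obj,
                      n_iter=n_iter, converged=converged)


def _fold_indices(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def knn_cv_error(X: np.ndarray, y: np.ndarray, k: int = 1, folds: int = 10,
                 seed: int = 0, metric: str = "euclidean",
                 weights: str = "none") -> float:
    """Pooled stratified k-fold kNN misclassification rate."""
    X, y, _ = _check_xy(X, y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    splits = _fold_indices(y, folds, seed)
    min_train = min(len(tr) for tr, _ in splits)
    if k >= min_train + 1:
        raise ValueError(f"k={k} too large for smallest training fold ({min_train})")
    wt = "uniform" if weights == "none" else weights
    errors = 0
    for tr, te in splits:
        clf = KNeighborsClassifier(n_neighbors=k, metric=metric, weights=wt)
        clf.fit(X[tr], y[tr])
        errors += int((clf.predict(X[te]) != y[te]).sum())
    return errors / len(y)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the iterative prefix sweep.

    ``selected`` are feature indices (into the matrix handed to the
    sweep, or global indices after the two-stage composition), ordered by
    descending NCA weight; ``error_curve[i]`` is the CV misclassification
    of the prefix of size ``candidate_sizes[i]``.
    """

    selected: np.ndarray
    l_star: int
    candidate_sizes: np.ndarray
    error_curve: np.ndarray
    min_error: float
    weights: np.ndarray = field(repr=False)
    weight_order: np.ndarray = field(repr=False)
    scope: str = "whole-data"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.tolist(),
            "l_star": int(self.l_star),
            "candidate_sizes": self.candidate_sizes.tolist(),
            "error_curve": self.error_curve.tolist(),
            "min_error": float(self.min_error),
            "scope": self.scope,
            "seed": int(self.seed),
        }


def _prefix_1nn_errors(Xs: np.ndarray, y: np.ndarray, order: np.ndarray,
                       sizes: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """1-NN CV error for every weight-sorted prefix size.

    Maintains the pairwise squared-Euclidean distance matrix incrementally
    as features are appended, so the whole sweep costs O(n^2 * d) rather
    than O(n^2 * sum(sizes)).
    """
    n = Xs.shape[0]
    splits = _fold_indices(y, folds, seed)
    D = np.zeros((n, n))
    errs = np.empty(sizes.size)
    next_col = 0
    for si, l in enumerate(sizes):
        for j in order[next_col:l]:
            c = Xs[:, j]
            diff = c[:, None] - c[None, :]
            D += diff * diff
        next_col = l
        wrong = 0
        for tr, te in splits:
            sub = D[np.ix_(te, tr)]
            nn = np.argmin(sub, axis=1)
            wrong += int((y[tr][nn] != y[te]).sum())
        errs[si] = wrong / n
    return errs


def iterative_nca_select(X: np.ndarray, y: np.ndarray, weights: np.ndarray,
                         range_lo: int = 100, range_hi: int = 1000,
                         folds: int = 10, seed: int = 0,
                         knn_k: int = 1, metric: str = "euclidean",
                         knn_weights: str = "none",
                         step: int = 1) -> SelectionResult:
    """Sweep prefixes of the weight-sorted feature list and keep the
    prefix with the lowest CV nearest-neighbor error.

    Ties in weight break by ascending feature index; ties in error by the
    smallest prefix.  ``range_hi`` is clamped (with a warning) to the
    number of available features.
    """
    X, y, _ = _check_xy(X, y)
    d = X.shape[1]
    if range_lo > range_hi:
        raise ValueError(f"range_lo={range_lo} > range_hi={range_hi}")
    if range_lo < 1:
        raise ValueError("range_lo must be >= 1")
    if range_hi > d:
        warnings.warn(f"range_hi clamped from {range_hi} to {d} features",
                      RuntimeWarning, stacklevel=2)
        range_hi = d
        range_lo = min(range_lo, d)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (d,):
        raise ValueError("one weight per feature required")
    order = np.lexsort((np.arange(d), -weights))
    sizes = np.arange(range_lo, range_hi + 1, step)
    if sizes[-1] != range_hi:
        sizes = np.append(sizes, range_hi)
    Xs = minmax_scale(X)
    if knn_k == 1 and metric == "euclidean" and knn_weights == "none":
        errs = _prefix_1nn_errors(Xs, y, order, sizes, folds, seed)
    else:
        errs = np.array([
            knn_cv_error(Xs[:, order[:l]], y, k=knn_k, folds=folds, seed=seed,
                         metric=metric, weights=knn_weights)
            for l in sizes
        ])
    best = int(np.argmin(errs))  # argmin takes the first (smallest) size on ties
    l_star = int(sizes[best])
    return SelectionResult(selected=order[:l_star].copy(), l_star=l_star,
                           candidate_sizes=sizes, error_curve=errs,
                           min_error=float(errs[best]), weights=weights,
                           weight_order=order, seed=seed)


@dataclass(frozen=True)
class SelectorConfig:
    """Configuration of the two-stage selector."""

    n_bins: int = 10
    top_k: int = 1000
    range_lo: int = 100
    range_hi: int = 1000
    folds: int = 10
    knn_k: int = 1
    metric: str = "euclidean"
    knn_weights: str = "none"
    sweep_step: int = 1
    nca_lambda: float | None = None
    nca_max_iter: int = 200
    scope: str = "whole-data"  # or "fold-internal" via fold_internal_cv_error


def chi2_nca_select(X: np.ndarray, y: np.ndarray,
                    config: SelectorConfig | None = None,
                    seed: int = 0) -> SelectionResult:
    """Full two-stage selection; returned indices are in the original
    feature space of ``X``."""
    config = config or SelectorConfig()
    X, y, _ = _check_xy(X, y)
    top_k = min(config.top_k, X.shape[1])
    if top_k < X.shape[1]:
        kept = select_top_k(chi2_scores(X, y, config.n_bins), top_k)
    else:
        kept = np.arange(X.shape[1])
    Xk = minmax_scale(X[:, kept])
    nca = nca_weights(Xk, y, lam=config.nca_lambda, seed=seed,
                      max_iter=config.nca_max_iter)
    res = iterative_nca_select(Xk, y, nca.w, range_lo=config.range_lo,
                               range_hi=config.range_hi, folds=config.folds,
                               seed=seed, knn_k=config.knn_k,
                               metric=config.metric,
                               knn_weights=config.knn_weights,
                               step=config.sweep_step)
    d = X.shape[1]
    full_w = np.zeros(d)
    full_w[kept] = nca.w
    return SelectionResult(selected=kept[res.selected], l_star=res.l_star,
                           candidate_sizes=res.candidate_sizes,
                           error_curve=res.error_curve,
                           min_error=res.min_error, weights=full_w,
                           weight_order=kept[res.weight_order],
                           scope=config.scope, seed=seed)


def fold_internal_cv_error(X: np.ndarray, y: np.ndarray,
                           config: SelectorConfig | None = None,
                           folds: int = 10, seed: int = 0) -> float:
    """Leakage-safe estimate: selection is refit inside each outer fold
    and a 1-NN classifier on the fold-selected features predicts the
    held-out observations.  On label-independent features this stays at
    chance, unlike the whole-data scope."""
    config = config or SelectorConfig()
    X, y, _ = _check_xy(X, y)
    wrong = 0
    for i, (tr, te) in enumerate(_fold_indices(y, folds, seed)):
        res = chi2_nca_select(X[tr], y[tr], config, seed=seed + i)
        cols = res.selected
        Xtr = X[np.ix_(tr, cols)]
        lo = Xtr.min(axis=0)
        span = Xtr.max(axis=0) - lo
        span[span == 0] = 1.0
        clf = KNeighborsClassifier(n_neighbors=config.knn_k, metric=config.metric)
        clf.fit((Xtr - lo) / span, y[tr])
        pred = clf.predict((X[np.ix_(te, cols)] - lo) / span)
        wrong += int((pred != y[te]).sum())
    return wrong / len(y)


def plot_error_curve(result: SelectionResult, path) -> None:
    """Misclassification-vs-prefix-size diagnostic plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(result.candidate_sizes, result.error_curve, lw=1)
    ax.axvline(result.l_star, color="crimson", ls="--", lw=1,
               label=f"l* = {result.l_star} (error {result.min_error:.4f})")
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("CV misclassification rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
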