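"""Estimation pipeline: collinearity filter, univariate screening, ridge.

The pipeline mirrors the scikit-learn estimator contract (``fit`` /
``transform`` / ``predict``) but the three built-in components are
implemented directly on numpy for speed: a permutation run refits the whole
pipeline tens of thousands of times, so per-fit overhead dominates.  Each
component is cross-checked against its scikit-learn counterpart in the test
suite.

Polygenic signals argue for non-sparse multivariate models, hence the final
predictor is a ridge regression (L2 penalty, well-posed for q >> n) applied
after a univariate F-score screen keeps the K most associated SNPs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .exceptions import DegenerateDataError

__all__ = [
    "CollinearityFilter",
    "UnivariateKBest",
    "RidgeEstimator",
    "REGISTRY",
    "filter_collinear",
    "score_univariate",
    "select_k_best",
    "fit_ridge",
    "PipelineSpec",
    "FittedPipeline",
    "compile_pipeline",
    "grid_search",
    "fit_pipeline",
]


# ---------------------------------------------------------------------------
# Core numeric operations
# ---------------------------------------------------------------------------

def filter_collinear(X: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Indices of a maximal prefix-greedy set of non-collinear columns.

    Scans columns left to right, keeping a column iff (a) it is not constant
    and (b) its absolute Pearson correlation with every already-kept column
    is <= 1 - tol.  Among duplicated columns the lowest index therefore wins.

    Raises
    ------
    DegenerateDataError
        If every column is constant.
    """
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    kept: list[int] = []
    basis: list[np.ndarray] = []  # unit-norm centered kept columns
    for j in range(q):
        if norms[j] <= 1e-12 * max(1.0, np.abs(X[:, j]).max()):
            continue  # constant column
        u = Xc[:, j] / norms[j]
        if basis:
            corr = np.abs(np.asarray(basis) @ u)
            if corr.max() > 1.0 - tol:
                continue
        kept.append(j)
        basis.append(u)
    if not kept:
        raise DegenerateDataError("all columns are constant; nothing to keep")
    return np.asarray(kept)


def score_univariate(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column F statistic of the simple regression of ``y`` on that column.

    F = r^2 (n - 2) / (1 - r^2) with r the Pearson correlation; a monotone
    transform of r^2, so ranking by F equals ranking by squared correlation.
    Constant columns score 0; perfect correlation scores +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    if y_norm <= 0.0:
        raise DegenerateDataError("target has zero variance; F scores undefined")
    Xc = X - X.mean(axis=0)
    x_norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (x_norms * y_norm)
        r[x_norms == 0.0] = 0.0
        r = np.clip(r, -1.0, 1.0)
        r2 = r * r
        f = r2 * (n - 2) / (1.0 - r2)
        f[1.0 - r2 <= 1e-15] = np.inf  # r2 == 1 up to rounding
    f[x_norms == 0.0] = 0.0
    return f


def select_k_best(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest scores, ties to the lowest index, sorted."""
    scores = np.asarray(scores)
    if k > scores.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {scores.shape[0]} available columns"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(-scores, kind="stable")  # stable => lowest index on ties
    return np.sort(order[:k])


def fit_ridge(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Ridge regression with unpenalized intercept.

    Minimizes ||y - X w - c||^2 + alpha ||w||^2.  Centering both X and y
    absorbs the intercept; the coefficients are obtained from the primal
    normal equations when n >= K and from the n x n dual system otherwise.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if n >= k:
        A = Xc.T @ Xc
        A[np.diag_indices_from(A)] += alpha
        w = scipy.linalg.solve(A, Xc.T @ yc, assume_a="pos")
    else:
        G = Xc @ Xc.T
        G[np.diag_indices_from(G)] += alpha
        w = Xc.T @ scipy.linalg.solve(G, yc, assume_a="pos")
    return w, float(y_mean - x_mean @ w)


# ---------------------------------------------------------------------------
# Components (fit/transform/predict contract)
# ---------------------------------------------------------------------------

class CollinearityFilter:
    """Transformer dropping constant and (near-)duplicate columns."""

    def __init__(self, tol: float = 1e-6):
        self.tol = float(tol)

    def fit(self, X, y=None):
        self.kept_: np.ndarray = filter_collinear(X, self.tol)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.kept_]

    def get_params(self) -> dict:
        return {"tol": self.tol}


class UnivariateKBest:
    """Transformer keeping the K columns with the largest univariate F score."""

    def __init__(self, k: int):
        self.k = int(k)

    def fit(self, X, y):
        self.scores_: np.ndarray = score_univariate(X, y)
        self.support_: np.ndarray = select_k_best(self.scores_, self.k)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_params(self) -> dict:
        return {"k": self.k}


class RidgeEstimator:
    """Ridge predictor with an unpenalized intercept (alpha applied unscaled)."""

    def __init__(self, alpha: float):
        self.alpha = float(alpha)

    def fit(self, X, y):
        self.coef_, self.intercept_ = fit_ridge(X, y, self.alpha)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def get_params(self) -> dict:
        return {"alpha": self.alpha}


#: Built-in components addressable from a descriptor's pipeline section.
REGISTRY: dict[str, type] = {
    "collinearity_filter": CollinearityFilter,
    "select_k_best": UnivariateKBest,
    "ridge": RidgeEstimator,
}


# ---------------------------------------------------------------------------
# Pipeline assembly and (optional) inner-CV grid search
# ---------------------------------------------------------------------------

@dataclass
class PipelineSpec:
    """Instantiable pipeline: ordered (name, class, constructor kwargs)."""

    steps: list[tuple[str, type, dict[str, Any]]]
    grid_axes: dict[str, list[Any]] | None = None
    inner_cv_folds: int = 5

    def instantiate(self, overrides: Mapping[str, Any] | None = None) -> list[tuple[str, Any]]:
        """Fresh component instances, with ``"step__param"`` overrides applied."""
        params: dict[str, dict[str, Any]] = {
            name: dict(kw) for name, _, kw in self.steps
        }
        if overrides:
            for key, value in overrides.items():
                step, _, pname = key.partition("__")
                params[step][pname] = value
        return [(name, cls(**params[name])) for name, cls, _ in self.steps]


@dataclass
class FittedPipeline:
    """A fitted pipeline plus introspection of what each built-in step kept."""

    steps: list[tuple[str, Any]]
    chosen_grid_point: dict[str, Any] | None = None
    kept_columns: np.ndarray | None = field(default=None)
    selected_columns: np.ndarray | None = field(default=None)
    ridge_coefficients: np.ndarray | None = field(default=None)
    ridge_intercept: float | None = field(default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        for _, step in self.steps[:-1]:
            X = step.transform(X)
        return self.steps[-1][1].predict(X)


def compile_pipeline(
    pipeline_steps: Sequence[Any],
    grid_axes: Mapping[str, Sequence[Any]] | None = None,
    registry: Mapping[str, type] | None = None,
) -> PipelineSpec:
    """Resolve descriptor pipeline steps into a :class:`PipelineSpec`.

    ``pipeline_steps`` are objects with ``name`` / ``component_ref`` /
    ``parameters`` attributes (the config module's ``EstimatorStep``).
    Plugin references (``DYNAMIC_IMPORT::``) are resolved here, i.e. lazily
    at worker start.
    """
    from .config import resolve_component  # local import: config -> estimator too

    steps = [
        (s.name, resolve_component(s.component_ref, registry), dict(s.parameters))
        for s in pipeline_steps
    ]
    axes = {k: list(v) for k, v in grid_axes.items()} if grid_axes else None
    return PipelineSpec(steps=steps, grid_axes=axes)


def _fit_steps(steps: list[tuple[str, Any]], X: np.ndarray, y: np.ndarray) -> None:
    for _, step in steps[:-1]:
        step.fit(X, y)
        X = step.transform(X)
    steps[-1][1].fit(X, y)


def make_inner_folds(n: int, n_folds: int, seed_parts: tuple[int, ...]) -> list[np.ndarray]:
    """``n_folds`` near-equal disjoint folds from a deterministic shuffle."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_parts))
    return [np.sort(f) for f in np.array_split(rng.permutation(n), n_folds)]


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: PipelineSpec,
    seed_parts: tuple[int, ...] = (0,),
) -> tuple[dict[str, Any], dict[tuple, float]]:
    """Pick grid-point maximizing mean R^2 over a deterministic inner K-fold CV.

    Candidates are enumerated in axis order (itertools product of the axes in
    their declared order); ties keep the first candidate.  A fold whose test
    target has zero variance is skipped with a warning; if every fold is
    degenerate the search fails.

    Returns the winning parameter map and the per-candidate mean scores
    (keyed by the candidate value tuple).
    """
    if not spec.grid_axes:
        raise ValueError("grid_search called without grid axes")
    n = y.shape[0]
    if n < 2 * spec.inner_cv_folds:
        raise DegenerateDataError(
            f"n_train={n} too small for {spec.inner_cv_folds}-fold inner CV"
        )
    folds = make_inner_folds(n, spec.inner_cv_folds, seed_parts)
    all_idx = np.arange(n)
    keys = list(spec.grid_axes.keys())
    best: tuple[dict[str, Any], float] | None = None
    scores: dict[tuple, float] = {}
    for values in itertools.product(*(spec.grid_axes[k] for k in keys)):
        point = dict(zip(keys, values))
        fold_scores = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
            y_test = y[test_idx]
            denom = float(y_test @ y_test)
            if denom == 0.0:
                warnings.warn("inner-CV fold with zero-variance target skipped")
                continue
            steps = spec.instantiate(point)
            _fit_steps(steps, X[train_idx], y[train_idx])
            pred = FittedPipeline(steps=steps).predict(X[test_idx])
            err = y_test - pred
            fold_scores.append(1.0 - float(err @ err) / denom)
        if not fold_scores:
            raise DegenerateDataError("all inner-CV folds degenerate")
        mean_score = float(np.mean(fold_scores))
        scores[values] = mean_score
        if best is None or mean_score > best[1]:  # strict: ties keep first
            best = (point, mean_score)
    assert best is not None
    return best[0], scores


def fit_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    spec: PipelineSpec,
    seed_parts: tuple[int, ...] = (0,),
) -> FittedPipeline:
    """Fit the full pipeline on a training set, grid-searching if configured."""
    chosen: dict[str, Any] | None = None
    if spec.grid_axes:
        chosen, _ = grid_search(X, y, spec, seed_parts)
    steps = spec.instantiate(chosen)
    _fit_steps(steps, X, y)
    fitted = FittedPipeline(steps=steps, chosen_grid_point=chosen)
    # introspection for the built-in components
    cursor: np.ndarray | None = None
    for _, step in steps:
        if isinstance(step, CollinearityFilter):
            fitted.kept_columns = step.kept_
            cursor = step.kept_
        elif isinstance(step, UnivariateKBest):
            sel = step.support_ if cursor is None else cursor[step.support_]
            fitted.selected_columns = sel
            cursor = sel
        elif isinstance(step, RidgeEstimator):
            fitted.ridge_coefficients = step.coef_
            fitted.ridge_intercept = step.intercept_
    if fitted.selected_columns is None and fitted.kept_columns is not None:
        fitted.selected_columns = fitted.kept_columns
    return fitted
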