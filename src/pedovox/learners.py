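"""Regression engines behind one contract: random forest, RBF support vector
regression and an adaptive piecewise-linear (MARS-style) learner, tuned by
shared-fold 10-fold cross-validation with lowest-RMSE selection.

All learners see the same fold partition so their cross-validation scores are
comparable. Grid points are enumerated from simplest to most complex and the
first strict RMSE minimum wins, so ties break toward the simpler model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .grids import CovariateStack

KINDS = ("rf", "svm_rbf", "mars_like")


# ---------------------------------------------------------------------------
# fold assignment

@dataclass(frozen=True)
class FoldAssignment:
    """Partition of sample indices into k folds; fold sizes differ by <= 1."""

    labels: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return self.labels.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)

    def subset(self, keep: np.ndarray) -> "FoldAssignment":
        """Restrict to a boolean/index subset of samples (e.g. after excluding
        plots whose profile fit failed)."""
        return FoldAssignment(labels=self.labels[keep], k=self.k)


def assign_folds(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random balanced k-fold partition, deterministic given the seed."""
    if not 2 <= k <= n:
        raise ValueError(f"require 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = fold
    return FoldAssignment(labels=labels, k=k)


# ---------------------------------------------------------------------------
# RBF bandwidth heuristic

def estimate_rbf_sigma(X: np.ndarray, quantiles=(0.1, 0.5, 0.9), max_rows: int = 100,
                       seed: int = 0) -> np.ndarray:
    """Bandwidth candidates for the RBF kernel exp(-sigma*||x-y||^2).

    Candidates are quantiles of the inverse squared pairwise distances over
    (a deterministic subsample of) the rows — the quantile-of-distances
    heuristic commonly used to bracket plausible kernel scales.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_rows, replace=False)]
    d2 = pdist(X, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise ValueError("all rows identical: RBF bandwidth undefined")
    return np.quantile(1.0 / d2, quantiles)


# ---------------------------------------------------------------------------
# MARS-style adaptive piecewise-linear regression

class MarsRegressor:
    """Forward/backward hinge-basis regression (adaptive piecewise-linear).

    The forward pass greedily adds reflected hinge pairs max(x-t, 0) /
    max(t-x, 0), optionally multiplied into an existing basis function up to
    ``degree`` interactions; the backward pass prunes terms by generalised
    cross-validation GCV = MSE / (1 - C(M)/n)^2 with C(M) = terms +
    penalty*(terms - 1).
    """

    def __init__(self, max_terms: int = 15, degree: int = 1, penalty: float = 3.0,
                 n_knots: int = 10):
        self.max_terms = max_terms
        self.degree = degree
        self.penalty = penalty
        self.n_knots = n_knots

    # each basis term is a tuple of (var, knot, sign) hinge factors; () = intercept
    @staticmethod
    def _basis_column(X, term):
        col = np.ones(X.shape[0])
        for var, knot, sign in term:
            col = col * np.maximum(sign * (X[:, var] - knot), 0.0)
        return col

    def _design(self, X, terms):
        return np.column_stack([self._basis_column(X, t) for t in terms])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        terms = [()]
        B = np.ones((n, 1))
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        sse = float(np.sum((y - B @ coef) ** 2))
        knots = {v: np.unique(np.quantile(X[:, v],
                                          np.linspace(0.05, 0.95, self.n_knots)))
                 for v in range(p)}
        while len(terms) < self.max_terms:
            best = None
            for parent in terms:
                if len(parent) >= self.degree:
                    continue
                used = {f[0] for f in parent}
                pcol = self._basis_column(X, parent)
                for v in range(p):
                    if v in used:
                        continue
                    for t in knots[v]:
                        c1 = pcol * np.maximum(X[:, v] - t, 0.0)
                        c2 = pcol * np.maximum(t - X[:, v], 0.0)
                        cand = np.column_stack([B, c1, c2])
                        beta, *_ = np.linalg.lstsq(cand, y, rcond=None)
                        s = float(np.sum((y - cand @ beta) ** 2))
                        if best is None or s < best[0] - 1e-12:
                            best = (s, parent, v, t)
            if best is None or best[0] >= sse * (1 - 1e-9):
                break
            s, parent, v, t = best
            terms.append(parent + ((v, t, 1),))
            terms.append(parent + ((v, t, -1),))
            B = self._design(X, terms)
            sse = s
            if len(terms) >= self.max_terms:
                break

        # backward pruning by GCV
        def gcv(terms_subset):
            Bs = self._design(X, terms_subset)
            beta, *_ = np.linalg.lstsq(Bs, y, rcond=None)
            mse = float(np.mean((y - Bs @ beta) ** 2))
            m = len(terms_subset)
            c = m + self.penalty * (m - 1)
            denom = (1 - c / n) ** 2 if c < n else np.inf
            return (mse / denom if np.isfinite(denom) and denom > 0 else np.inf), beta

        current = list(terms)
        best_terms, (best_gcv, best_beta) = current, gcv(current)
        while len(current) > 1:
            scores = []
            for i in range(1, len(current)):  # never drop the intercept
                subset = current[:i] + current[i + 1:]
                g, b = gcv(subset)
                scores.append((g, i, subset, b))
            g, i, subset, b = min(scores, key=lambda s: s[0])
            current = subset
            if g < best_gcv:
                best_gcv, best_terms, best_beta = g, subset, b
        self.terms_, self.coef_ = best_terms, best_beta
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self._design(X, self.terms_) @ self.coef_

    @property
    def n_terms_(self) -> int:
        return len(self.terms_)


# ---------------------------------------------------------------------------
# learner specification and tuning

@dataclass
class LearnerSpec:
    """One learner kind plus its hyperparameter grid.

    rf: {"mtry": [...]} with n_estimators fixed at 500 (the package default).
    svm_rbf: {"cost": [...], "sigma": [...]}; epsilon fixed at 0.1.
    mars_like: {"degree": [...], "max_terms": [...]}.
    """

    kind: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        """Grid points ordered simplest-first (ascending in every parameter)."""
        keys = sorted(self.grid)
        combos = itertools.product(*(sorted(self.grid[k]) for k in keys))
        return [dict(zip(keys, c)) for c in combos]

    def build(self, params: dict):
        if self.kind == "rf":
            return RandomForestRegressor(n_estimators=500, max_features=int(params["mtry"]),
                                         random_state=self.seed, n_jobs=1)
        if self.kind == "svm_rbf":
            return SVR(kernel="rbf", C=float(params["cost"]), gamma=float(params["sigma"]),
                       epsilon=0.1)
        return MarsRegressor(max_terms=int(params["max_terms"]), degree=int(params["degree"]))


def default_learner_spec(kind: str, X: np.ndarray, seed: int = 0) -> LearnerSpec:
    """Reference grids: rf mtry {p/10, sqrt(p), p/3} clipped to [1, p]; svm cost
    {0.25, 0.5, 1, 2, 4} with sigma from the distance-quantile heuristic;
    mars degree {1, 2} x max_terms {7, 15, 21}."""
    p = X.shape[1]
    if kind == "rf":
        mtry = sorted({int(np.clip(v, 1, p)) for v in (p // 10, int(np.sqrt(p)), p // 3)})
        return LearnerSpec("rf", {"mtry": mtry}, seed=seed)
    if kind == "svm_rbf":
        sig = estimate_rbf_sigma(X, seed=seed)
        return LearnerSpec("svm_rbf", {"cost": [0.25, 0.5, 1.0, 2.0, 4.0],
                                       "sigma": [float(s) for s in np.unique(sig)]}, seed=seed)
    if kind == "mars_like":
        return LearnerSpec("mars_like", {"degree": [1], "max_terms": [7, 15, 21]}, seed=seed)
    raise ValueError(f"unknown learner kind {kind!r}")


@dataclass
class CVResult:
    """Cross-validation summary for one response variable."""

    kind: str
    records: list[dict]           # one per grid point: params, rmse, r2
    selected: dict                # the lowest-RMSE grid point
    oof_predictions: np.ndarray   # out-of-fold predictions at the selected point
    folds: FoldAssignment
    rmse: float
    r2: float
    nrmse: float | None = None


@dataclass
class FittedLearner:
    model: object
    kind: str
    params: dict
    feature_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def _oof_predict(spec: LearnerSpec, params: dict, X, y, folds: FoldAssignment) -> np.ndarray:
    pred = np.empty_like(y, dtype=float)
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        model = spec.build(params)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return pred


def tune_and_fit(spec: LearnerSpec, X: np.ndarray, y: np.ndarray, folds: FoldAssignment,
                 feature_names: list[str] | None = None) -> tuple[FittedLearner, CVResult]:
    """Grid-tune with shared folds, select the lowest pooled out-of-fold RMSE
    (ties to the simplest model), refit on all data."""
    from .metrics import compute_metrics

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if y.size != X.shape[0]:
        raise ValueError("X and y size mismatch")
    if folds.n != y.size:
        raise ValueError("fold assignment does not cover all samples")

    records, best = [], None
    for params in spec.grid_points():
        pred = _oof_predict(spec, params, X, y, folds)
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        try:
            r2 = compute_metrics(y, pred).r2
        except ValueError:
            r2 = np.nan
        records.append({"params": params, "rmse": rmse, "r2": r2})
        if best is None or rmse < best["rmse"]:   # strict <: first (simplest) wins ties
            best = {"params": params, "rmse": rmse, "r2": r2, "pred": pred}

    model = spec.build(best["params"])
    model.fit(X, y)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    fitted = FittedLearner(model=model, kind=spec.kind, params=best["params"],
                           feature_names=names)
    cv = CVResult(kind=spec.kind, records=records, selected=best["params"],
                  oof_predictions=best["pred"], folds=folds,
                  rmse=best["rmse"], r2=best["r2"])
    return fitted, cv


def predict_surface(fitted: FittedLearner, stack: CovariateStack) -> np.ndarray:
    """Predict over every valid cell of a (standardized) covariate stack;
    nodata cells propagate as NaN."""
    if fitted.feature_names != stack.names:
        raise ValueError("covariate names do not match the training features")
    X, idx = stack.full_matrix()
    out = np.full(stack.shape, np.nan)
    out.ravel()[idx] = fitted.predict(X)
    return out


class Oracle:
    """A stand-in regressor that returns known truth grids, used to verify the
    pipeline plumbing independently of any statistical learner."""

    def __init__(self, grids: dict[object, np.ndarray]):
        self.grids = grids

    def surface(self, key) -> np.ndarray:
        return self.grids[key]
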