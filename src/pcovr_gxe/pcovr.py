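"""Principal covariates regression (PCovR).

PCovR jointly reduces a predictor matrix X (here: standardized SNP
dosages) to R orthonormal component scores T = XW and regresses an
outcome y on those components, minimizing

    L(T) = alpha * ||X - T Px'||^2 / ||X||^2
         + (1 - alpha) * ||y - T py||^2 / ||y||^2

over T with T'T = I in the column space of X.  alpha = 1 recovers
principal component analysis of X; alpha = 0 tilts the components wholly
toward predicting y (at R = 1 the single component is the least-squares
fitted-value direction).  The optimum is closed-form: T collects the
top-R eigenvectors of

    G = alpha * X X' / ||X||^2 + (1 - alpha) * yhat yhat' / ||y||^2

with yhat the projection of y onto the column space of X.  We compute
this via a thin SVD of X and an eigendecomposition of the projected
r x r operator, which covers both the n x n (J > n) and J x J regimes
in one numerically stable path.

Model selection follows a two-stage alpha grid (coarse 0-1 by 0.10,
fine 0.70-1.00 by 0.01) and an explicit balance rule that formalizes
picking the "knee" of the explained-variance trade-off by eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, MultiOutputMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PCovR",
    "PcovrSolution",
    "AlphaSweepResult",
    "fit_pcovr",
    "alpha_sweep",
    "select_alpha",
    "choose_n_components",
    "coarse_alpha_grid",
    "fine_alpha_grid",
]

_RANK_RTOL = 1e-10  # relative to the largest singular value


def coarse_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.10), 10)


def fine_alpha_grid(lo: float = 0.70, hi: float = 1.00, step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(lo, hi + 1e-9, step), 10)


@dataclass
class PcovrSolution:
    """One (alpha, R) fit: weights, scores, loadings, explained variance."""

    weights: np.ndarray  # W, J x R: T = X W
    scores: np.ndarray  # T, n x R, orthonormal columns
    x_loadings: np.ndarray  # P_X, J x R
    y_loadings: np.ndarray  # p_y, length R
    r2_x: float
    r2_y: float
    alpha: float
    n_components: int
    loss: float


class PCovR(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """Principal covariates regression estimator.

    Parameters
    ----------
    n_components : int, number of components R.
    alpha : float in [0, 1], reduction-vs-prediction weight.
    center : bool, default True — center X columns and y before fitting
        (a warning is raised if inputs arrive uncentered); the means are
        stored and reapplied in transform/predict.

    Attributes (after fit)
    ----------------------
    weights_ : (J, R) SNP-to-component weights, T = Xc @ weights_.
    scores_ : (n, R) orthonormal component scores of the training data.
    x_loadings_ : (J, R); y_loadings_ : (R,).
    r2_x_, r2_y_ : explained-variance fractions in X and y.
    loss_ : value of the PCovR objective at the optimum.
    """

    def __init__(self, n_components: int = 5, alpha: float = 0.8, center: bool = True):
        self.n_components = n_components
        self.alpha = alpha
        self.center = center

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, j = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        if self.center:
            Xc, yc = X - x_mean, y - y_mean
        else:
            Xc, yc = X, y
            if abs(x_mean).max() > 1e-8 or abs(y_mean) > 1e-8:
                warnings.warn(
                    "inputs are not centered; fitting on raw values as requested",
                    UserWarning,
                )
        self.x_mean_ = x_mean if self.center else np.zeros(j)
        self.y_mean_ = y_mean if self.center else 0.0

        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int((s > _RANK_RTOL * s[0]).sum()) if s.size else 0
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank(X)={rank}")
        U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]

        ssx = float((s**2).sum())
        ssy = float(yc @ yc)
        if ssx == 0 or ssy == 0:
            raise ValueError("X or y has zero variance")

        # projected operator M = U' G U (r x r):
        #   alpha * diag(s^2)/||X||^2 + (1-alpha) * (U'y)(U'y)'/||y||^2
        uy = U.T @ yc
        M = np.diag(self.alpha * s**2 / ssx) + (1 - self.alpha) * np.outer(uy, uy) / ssy
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1][: self.n_components]
        V = evecs[:, order]
        T = U @ V
        T = _fix_signs(T)

        Px = Xc.T @ T
        py = T.T @ yc
        W = (Vt.T / s) @ (U.T @ T)  # pinv(Xc) @ T

        r2_x = float((Px**2).sum() / ssx)
        r2_y = float((py**2).sum() / ssy)
        self.weights_ = W
        self.scores_ = T
        self.x_loadings_ = Px
        self.y_loadings_ = py
        self.r2_x_ = r2_x
        self.r2_y_ = r2_y
        self.rank_ = rank
        self.loss_ = self.alpha * (1 - r2_x) + (1 - self.alpha) * (1 - r2_y)
        self.n_features_in_ = j
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.weights_

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).scores_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self.transform(X) @ self.y_loadings_ + self.y_mean_

    def solution_(self) -> PcovrSolution:
        check_is_fitted(self, "weights_")
        return PcovrSolution(
            weights=self.weights_,
            scores=self.scores_,
            x_loadings=self.x_loadings_,
            y_loadings=self.y_loadings_,
            r2_x=self.r2_x_,
            r2_y=self.r2_y_,
            alpha=self.alpha,
            n_components=self.n_components,
            loss=self.loss_,
        )


def _fix_signs(T: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    T = T.copy()
    for r in range(T.shape[1]):
        k = np.argmax(np.abs(T[:, r]))
        if T[k, r] < 0:
            T[:, r] = -T[:, r]
    return T


def fit_pcovr(X, y, n_components: int, alpha: float, center: bool = True) -> PcovrSolution:
    """Functional wrapper over :class:`PCovR`."""
    return PCovR(n_components=n_components, alpha=alpha, center=center).fit(X, y).solution_()


# ---------------------------------------------------------------------------
# alpha sweep and selection


@dataclass
class AlphaSweepResult:
    alphas: np.ndarray
    r2_x: np.ndarray
    r2_y: np.ndarray
    n_components: int
    selected_alpha: float | None = None
    trace: list[str] = field(default_factory=list)

    def as_records(self) -> list[dict]:
        return [
            {"alpha": float(a), "r2_x": float(rx), "r2_y": float(ry)}
            for a, rx, ry in zip(self.alphas, self.r2_x, self.r2_y)
        ]


def alpha_sweep(X, y, n_components: int, grid=None) -> AlphaSweepResult:
    """Fit PCovR at every alpha on the grid; returns the r2 curves only."""
    grid = coarse_alpha_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    if (np.diff(grid) <= 0).any() or grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must be sorted, unique and within [0, 1]")
    r2_x = np.empty(grid.size)
    r2_y = np.empty(grid.size)
    for i, a in enumerate(grid):
        sol = fit_pcovr(X, y, n_components=n_components, alpha=float(a))
        r2_x[i], r2_y[i] = sol.r2_x, sol.r2_y
    return AlphaSweepResult(alphas=grid, r2_x=r2_x, r2_y=r2_y, n_components=n_components)


def select_alpha(
    sweep: AlphaSweepResult, tau: float = 0.10, manual: float | None = None
) -> tuple[float, list[str]]:
    """Balance rule: among alphas retaining at least (1 - tau) of the
    reduction quality at the grid maximum, pick the alpha with the best
    prediction; ties break toward larger alpha.  A manual override is
    accepted and logged in the trace."""
    trace: list[str] = []
    if manual is not None:
        if not np.isclose(sweep.alphas, manual).any():
            raise ValueError(f"manual alpha {manual} not on the sweep grid")
        trace.append(f"manual override: alpha={manual}")
        sweep.selected_alpha = float(manual)
        sweep.trace = trace
        return float(manual), trace
    rx_top = sweep.r2_x[np.argmax(sweep.alphas)]
    ok = sweep.r2_x >= (1 - tau) * rx_top
    trace.append(
        f"constraint r2_x >= {(1 - tau) * rx_top:.6f} "
        f"((1-tau) * r2_x at alpha={sweep.alphas.max():.2f}) keeps {int(ok.sum())} grid points"
    )
    if not ok.any():
        trace.append("constraint set empty; falling back to max-r2_y point")
        warnings.warn("alpha balance constraint empty; using max r2_y", UserWarning)
        ok = np.ones_like(ok, dtype=bool)
    best = sweep.r2_y[ok].max()
    # ties toward larger alpha
    cand = sweep.alphas[ok][np.isclose(sweep.r2_y[ok], best)]
    selected = float(cand.max())
    trace.append(f"selected alpha={selected} with r2_y={best:.6f}")
    sweep.selected_alpha = selected
    sweep.trace = trace
    return selected, trace


def choose_n_components(
    X,
    y,
    alpha: float,
    strategy: str = "fixed",
    n_components: int = 5,
    max_components: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick R: "fixed" returns the requested value; "scree" takes the elbow
    (maximum second difference) of the eigenvalues of the PCovR operator;
    "cross_validated" minimizes out-of-fold squared prediction error."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if strategy == "fixed":
        if n_components > rank:
            raise ValueError(f"requested R={n_components} exceeds rank {rank}")
        return int(n_components)
    if strategy == "scree":
        kmax = min(max_components, rank)
        evals = _operator_eigenvalues(X, y, alpha)[: kmax + 1]
        if evals.size < 3:
            return 1
        second_diff = evals[:-2] - 2 * evals[1:-1] + evals[2:]
        return int(np.argmax(second_diff) + 1)
    if strategy == "cross_validated":
        from sklearn.model_selection import KFold

        kmax = min(max_components, rank - 1)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        errs = np.zeros(kmax)
        for train, test in kf.split(X):
            r_train = np.linalg.matrix_rank(X[train] - X[train].mean(axis=0))
            for ridx in range(kmax):
                r = ridx + 1
                if r > r_train:
                    errs[ridx] += np.inf
                    continue
                model = PCovR(n_components=r, alpha=alpha).fit(X[train], y[train])
                resid = y[test] - model.predict(X[test])
                errs[ridx] += float(resid @ resid)
        return int(np.argmin(errs) + 1)
    raise ValueError(f"unknown strategy {strategy!r}")


def _operator_eigenvalues(X, y, alpha: float) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > _RANK_RTOL * s[0]
    U, s = U[:, keep], s[keep]
    uy = U.T @ yc
    M = np.diag(alpha * s**2 / (s**2).sum()) + (1 - alpha) * np.outer(uy, uy) / (yc @ yc)
    return np.sort(np.linalg.eigvalsh(M))[::-1]
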