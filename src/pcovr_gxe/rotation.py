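"""Oblique quartimin rotation by gradient projection.

The quartimin criterion Q(L) = sum_j sum_{r != s} L_jr^2 L_js^2 rewards
simple structure: each variable should load on as few components as
possible.  Minimization runs over oblique transformations T with
unit-length columns via the gradient-projection algorithm (update T along
the projected negative gradient, renormalize columns, halve the step
until the criterion decreases).  The criterion is non-increasing across
accepted iterations; convergence when the change drops below 1e-8 or
after 1000 iterations, with up to 10 seeded random orthonormal restarts
if the running transformation becomes singular.

Rotated component scores are rescaled to unit variance (and loadings
inversely), so the model-implied reconstruction T P' is preserved exactly
while downstream analyses receive standardized scores; the component
correlation matrix Phi then has unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcovr import PcovrSolution

__all__ = ["RotatedSolution", "rotate_quartimin", "quartimin_criterion", "tucker_congruence"]


@dataclass
class RotatedSolution:
    loadings: np.ndarray  # J x R, oblique-rotated (score-standardized scale)
    transform: np.ndarray  # R x R oblique transformation applied to scores
    phi: np.ndarray  # R x R component correlation matrix
    scores: np.ndarray  # n x R standardized (mean 0, SD 1 per column)
    y_loadings: np.ndarray  # outcome loadings on the rotated, standardized scores
    criterion: float
    n_iter: int
    converged: bool
    criterion_path: np.ndarray | None = None  # accepted-iterate criterion values


def quartimin_criterion(L: np.ndarray) -> float:
    """Q(L) = sum_j sum_{r != s} L_jr^2 L_js^2 (both orders counted)."""
    L2 = L**2
    R = L.shape[1]
    N = np.ones((R, R)) - np.eye(R)
    return float((L2 * (L2 @ N)).sum())


def _quartimin_vgQ(L: np.ndarray) -> tuple[float, np.ndarray]:
    # value/gradient pair on the GPA scale (criterion / 4)
    L2 = L**2
    R = L.shape[1]
    N = np.ones((R, R)) - np.eye(R)
    X = L2 @ N
    return float((L2 * X).sum()) / 4.0, L * X


def _gpa_oblique(
    A: np.ndarray,
    T0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Gradient-projection minimization of the quartimin criterion over
    oblique transformations with unit-length columns (Jennrich-style)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_vgQ(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    n_iter = 0
    converged = False
    history = [f * 4.0]
    for n_iter in range(1, max_iter + 1):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        f_new, T_new, L_new = f, T, L
        for _ in range(20):
            Xc = T - al * Gp
            Xc = Xc / np.sqrt((Xc**2).sum(axis=0, keepdims=True))
            if np.linalg.cond(Xc) > 1e12:
                al /= 2.0
                continue
            Ti_c = np.linalg.inv(Xc)
            L_c = A @ Ti_c.T
            f_c, Gq = _quartimin_vgQ(L_c)
            if f_c < f - 0.5 * s**2 * al:
                f_new, T_new, L_new = f_c, Xc, L_c
                break
            al /= 2.0
        if f_new >= f and n_iter > 1:
            converged = True
            break
        T, f, L = T_new, f_new, L_new
        history.append(f * 4.0)
        Ti = np.linalg.inv(T)
        _, Gq = _quartimin_vgQ(L)
        G = -(L.T @ Gq @ Ti).T
    return L, T, f * 4.0, n_iter, converged, np.asarray(history)


def rotate_quartimin(
    solution: PcovrSolution,
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_restarts: int = 10,
    seed: int = 0,
) -> RotatedSolution:
    """Quartimin-rotate a PCovR solution; R = 1 passes through unchanged."""
    P = solution.x_loadings
    T_scores = solution.scores
    R = P.shape[1]
    if R == 1:
        sd = T_scores[:, 0].std()
        scores = (T_scores - T_scores.mean(axis=0)) / sd
        return RotatedSolution(
            loadings=P * sd,
            transform=np.eye(1),
            phi=np.eye(1),
            scores=scores,
            y_loadings=solution.y_loadings * sd,
            criterion=quartimin_criterion(P),
            n_iter=0,
            converged=True,
        )

    rng = np.random.default_rng(seed)
    best = None
    start = np.eye(R)
    for attempt in range(max_restarts + 1):
        try:
            L, T, crit, n_iter, converged, history = _gpa_oblique(
                P, start, tol=tol, max_iter=max_iter
            )
        except np.linalg.LinAlgError:
            converged = False
            L = None
        if L is not None and (best is None or crit < best[2]):
            best = (L, T, crit, n_iter, converged, history)
        if L is not None and converged:
            break
        # random orthonormal restart
        q, _ = np.linalg.qr(rng.standard_normal((R, R)))
        start = q
    if best is None:
        raise np.linalg.LinAlgError("quartimin rotation failed from all restarts")
    L, T, crit, n_iter, converged, history = best

    # rotated (pattern-scale) scores: S = T_scores @ T ; reconstruction
    # S @ L' == T_scores @ P' exactly.  Rescale so scores have unit SD.
    S = T_scores @ T
    mu = S.mean(axis=0)
    sd = S.std(axis=0)
    S_std = (S - mu) / sd
    L_std = L * sd  # absorbs the scale: S_std @ L_std' == (S - mu) @ L'
    phi = np.corrcoef(S_std, rowvar=False)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    # outcome loadings on the rotated standardized scores (least squares)
    y_fit = solution.scores @ solution.y_loadings
    py_rot, *_ = np.linalg.lstsq(S_std, y_fit, rcond=None)
    return RotatedSolution(
        loadings=L_std,
        transform=T,
        phi=phi,
        scores=S_std,
        y_loadings=py_rot,
        criterion=crit,
        n_iter=n_iter,
        converged=converged,
        criterion_path=history,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading vectors."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def congruence_match(
    reference: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy-match candidate loading columns to reference columns by
    maximal |Tucker congruence|, with sign alignment.

    Returns (permutation, signs, congruences): candidate[:, permutation] *
    signs best matches the reference column-by-column.
    """
    R = reference.shape[1]
    C = np.zeros((R, R))
    for i in range(R):
        for k in range(candidate.shape[1]):
            C[i, k] = tucker_congruence(reference[:, i], candidate[:, k])
    perm = np.full(R, -1)
    signs = np.ones(R)
    cong = np.zeros(R)
    absC = np.abs(C).copy()
    for _ in range(R):
        i, k = np.unravel_index(np.argmax(absC), absC.shape)
        perm[i] = k
        signs[i] = np.sign(C[i, k]) or 1.0
        cong[i] = absC[i, k]
        absC[i, :] = -np.inf
        absC[:, k] = -np.inf
    return perm, signs, cong
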