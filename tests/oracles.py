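"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: the
PCovR oracle minimizes the objective numerically over unconstrained
parametrizations of the component subspace, and the Hardy-Weinberg
oracle enumerates the conditional distribution in exact rational
arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
from scipy import optimize


def pcovr_loss(X: np.ndarray, y: np.ndarray, T: np.ndarray, alpha: float) -> float:
    """PCovR objective for orthonormal scores T (loadings profiled out)."""
    ssx = (X**2).sum()
    ssy = y @ y
    Px = X.T @ T
    py = T.T @ y
    loss_x = ((X - T @ Px.T) ** 2).sum() / ssx
    loss_y = ((y - T @ py) ** 2).sum() / ssy
    return alpha * loss_x + (1 - alpha) * loss_y


def brute_force_pcovr_loss(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    alpha: float,
    n_restarts: int = 50,
    seed: int = 0,
) -> float:
    """Best loss over random-restart quasi-Newton minimizations.

    The scores are parametrized as T = Q(X A) (thin QR of X A for a free
    J x R coefficient matrix A), which ranges over all orthonormal bases
    of R-dimensional subspaces of the column space of X.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    J = Xc.shape[1]
    rng = np.random.default_rng(seed)

    def loss_of(a_flat: np.ndarray) -> float:
        A = a_flat.reshape(J, n_components)
        Q, R = np.linalg.qr(Xc @ A)
        if np.abs(np.diag(R)).min() < 1e-12:
            return 2.0  # rank-deficient start; worst-case loss is bounded by 1
        return pcovr_loss(Xc, yc, Q, alpha)

    best = np.inf
    for _ in range(n_restarts):
        a0 = rng.standard_normal(J * n_components)
        res = optimize.minimize(loss_of, a0, method="L-BFGS-B", options={"maxiter": 200})
        best = min(best, float(res.fun))
    return best


def hwe_enumeration_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> Fraction:
    """Exact conditional Hardy-Weinberg p-value by full enumeration with
    rational arithmetic.

    P(h | n, n_minor) = 2^h * n! / (a! h! b!) / sum over attainable h' of
    the same expression, with a = (n_minor - h)/2, b = (n_major - h)/2.
    The p-value sums P(h') over all h' with P(h') <= P(h_obs).
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("empty genotype table")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return Fraction(1)
    weights: dict[int, Fraction] = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        a = (n_minor - h) // 2
        b = (n_major - h) // 2
        weights[h] = Fraction(2**h * factorial(n), factorial(a) * factorial(h) * factorial(b))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def enumerate_genotype_triples(max_total: int):
    """All (n_hom_minor, n_het, n_hom_major) with 0 < total <= max_total."""
    for total in range(1, max_total + 1):
        for n2 in range(total + 1):
            for n1 in range(total - n2 + 1):
                yield n2, n1, total - n2 - n1
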