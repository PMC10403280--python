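"""Independent reference implementations used only by the test suite."""

from __future__ import annotations

import numpy as np
from scipy import optimize


def frankwolfe_glasso(
    s: np.ndarray,
    alpha: float,
    max_iter: int = 20000,
    gap_tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Frank-Wolfe reference solver for the L1-ball-constrained problem
    maximize log det(theta) - <S, theta>, ||theta||_1 <= alpha, theta PD.

    An entirely different algorithm from the ADMM implementation under
    test: iterates stay feasible, each step moves toward the best L1-ball
    vertex for the current gradient, and the Frank-Wolfe duality gap
    certifies suboptimality. Returns (theta, certified_gap).
    """
    d = s.shape[0]
    theta = (alpha / d) * np.eye(d)

    def objective(t: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0:
            return -np.inf
        return logdet - float(np.sum(s * t))

    gap = np.inf
    for _ in range(max_iter):
        grad = np.linalg.inv(theta) - s  # gradient of the concave objective
        flat = np.abs(grad)
        p, q = np.unravel_index(np.argmax(flat), flat.shape)
        vertex = np.zeros_like(theta)
        if p == q:
            vertex[p, p] = alpha * np.sign(grad[p, p])
        else:
            vertex[p, q] = vertex[q, p] = alpha / 2 * np.sign(grad[p, q])
        gap = float(np.sum(grad * (vertex - theta)))
        if gap < gap_tol:
            break

        direction = vertex - theta

        # exact line search: phi(gamma) = objective(theta + gamma*D) is
        # concave on the PD segment; bisect its derivative
        # phi'(gamma) = tr((theta + gamma D)^-1 D) - <S, D>
        chol = np.linalg.cholesky(theta)
        inv_chol = np.linalg.inv(chol)
        mid = inv_chol @ direction @ inv_chol.T
        lam_min = np.linalg.eigvalsh(mid).min()
        gamma_max = 1.0 if lam_min >= 0 else min(1.0, -0.999 / lam_min)
        sd = float(np.sum(s * direction))

        def dphi(gamma: float) -> float:
            return float(
                np.trace(np.linalg.solve(theta + gamma * direction, direction))
            ) - sd

        if dphi(gamma_max * (1 - 1e-9)) > 0:
            gamma = gamma_max * (1 - 1e-9)
        else:
            lo, hi = 0.0, gamma_max * (1 - 1e-9)
            for _ in range(80):
                midpoint = 0.5 * (lo + hi)
                if dphi(midpoint) > 0:
                    lo = midpoint
                else:
                    hi = midpoint
            gamma = 0.5 * (lo + hi)
        if gamma <= 0:
            break
        theta = theta + gamma * direction
    return theta, gap


def suboptimality_certificate(theta: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """Convex-duality bound on how far theta is from the constrained optimum.

    For the concave objective F(theta) = logdet(theta) - <S, theta> over
    the L1 ball, F(opt) - F(theta) <= max_{v in ball} <grad F(theta), v - theta>
    = alpha * max|grad|_inf - <grad, theta>. Independent of any solver.
    """
    grad = np.linalg.inv(theta) - s
    return float(alpha * np.abs(grad).max() - np.sum(grad * theta))


def diagonal_glasso_closed_form(s_diag: np.ndarray, alpha: float) -> np.ndarray:
    """Closed form for diagonal S: theta_i = 1/(s_i + lam) with lam >= 0
    chosen so the budget holds (water-filling via scalar root-find)."""
    s_diag = np.asarray(s_diag, dtype=float)
    unconstrained = 1.0 / s_diag
    if unconstrained.sum() <= alpha:
        return unconstrained

    def excess(lam: float) -> float:
        return np.sum(1.0 / (s_diag + lam)) - alpha

    hi = max(len(s_diag) / alpha - s_diag.min(), 1e-12) + 1.0
    lam = optimize.brentq(excess, 0.0, hi, xtol=1e-14)
    return 1.0 / (s_diag + lam)
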