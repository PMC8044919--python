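"""Solver for the box- and equality-constrained projection QP

    minimize    0.5 * ||x - r||^2
    subject to  S x = 0,   lb <= x <= ub.

This is the MOMA work-horse.  The solution is the Euclidean projection of
the reference point r onto the flux polytope, computed by an ADMM
splitting (the operator-splitting scheme of OSQP specialized to an
identity Hessian, so the x-update is one pre-factorized linear solve,
with the customary heavier penalty on equality rows).  Periodically the
iterate is "polished": its active bounds are fixed as equalities and the
reduced projection is solved exactly by least squares; if the polished
point is feasible and its KKT bound multipliers are nonnegative, that is
a certificate of global optimality (the problem is strictly convex) and
the polished point is returned at machine precision.  ADMM is immune to
the active-set cycling that degenerate polytopes (e.g. lethal knockouts
forcing most fluxes to zero) provoke.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


class QPError(RuntimeError):
    pass


def _vi_gap(r, S, lb, ub, x):
    """Variational-inequality gap of x for the projection of r: x is the
    exact projection iff max_y {(r-x)^T (y-x) : Sy=0, lb<=y<=ub} is 0."""
    from scipy.optimize import linprog

    g = r - x
    res = linprog(-g, A_eq=S if S.shape[0] else None,
                  b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return np.inf
    return float(g @ res.x - g @ x)


def _polish_with_certificate(r, S, lb, ub, x, active_tol, feas_tol):
    """Fix bounds active at x, re-project exactly, and certify optimality
    through the variational inequality (robust to dual degeneracy).
    Returns the polished point when it is certifiably optimal, else None."""
    n = r.size
    at_lo = x <= lb + active_tol
    at_hi = (x >= ub - active_tol) & ~at_lo
    fixed = at_lo | at_hi
    free = ~fixed
    xp = np.empty(n)
    xp[at_lo] = lb[at_lo]
    xp[at_hi] = ub[at_hi]
    A = S[:, free]
    d = -S[:, fixed] @ xp[fixed] if fixed.any() else np.zeros(S.shape[0])
    rhs = A @ r[free] - d
    lam, *_ = np.linalg.lstsq(A @ A.T, rhs, rcond=None)
    xp[free] = r[free] - A.T @ lam

    feasible = (
        (np.max(np.abs(S @ xp)) <= feas_tol if S.shape[0] else True)
        and np.all(xp >= lb - feas_tol)
        and np.all(xp <= ub + feas_tol)
    )
    if not feasible:
        return None
    xp = np.clip(xp, lb, ub)
    if _vi_gap(r, S, lb, ub, xp) > 1e-7 * (1.0 + np.linalg.norm(r - xp)):
        return None
    return xp


def solve_box_eq_qp(
    r: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    rho_box: float = 1.0,
    rho_eq: float = 1000.0,
    alpha: float = 1.6,
    eps: float = 1e-10,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Return the minimizer of 0.5||x - r||^2 on {Sx = 0, lb <= x <= ub}."""
    r = np.asarray(r, dtype=float)
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = r.size
    m = S.shape[0]
    if np.any(lb > ub + 1e-12):
        raise QPError("crossed bounds")

    lo = np.concatenate([np.zeros(m), lb])
    hi = np.concatenate([np.zeros(m), ub])
    rho = np.concatenate([np.full(m, rho_eq), np.full(n, rho_box)])

    # x-update: (I + S^T R_eq S + R_box) x = r + A^T R (z - w)
    M = (1.0 + rho_box) * np.eye(n) + rho_eq * (S.T @ S)
    cho = linalg.cho_factor(M, lower=True)

    def Ax(x):
        return np.concatenate([S @ x, x])

    def ATRy(y):
        ry = rho * y
        return S.T @ ry[:m] + ry[m:]

    x = np.clip(r, lb, ub)
    z = np.clip(Ax(x), lo, hi)
    w = np.zeros(m + n)
    converged = False
    for it in range(max_iter):
        x = linalg.cho_solve(cho, r + ATRy(z - w))
        ax = Ax(x)
        ax_relaxed = alpha * ax + (1.0 - alpha) * z
        z_prev = z
        z = np.clip(ax_relaxed + w, lo, hi)
        w = w + ax_relaxed - z
        if it % 50 == 49:
            scale = 1.0 + max(np.max(np.abs(ax)), np.max(np.abs(z)))
            prim = np.max(np.abs(ax - z))
            if prim < 1e-5 * scale:
                xc = np.clip(x, lb, ub)
                for atol in (1e-7 * scale, 1e-5 * scale):
                    xp = _polish_with_certificate(
                        r, S, lb, ub, xc, atol, 1e-8 * scale
                    )
                    if xp is not None:
                        return xp
            dual = np.max(np.abs(ATRy(z - z_prev)))
            if prim < eps * scale and dual < eps * scale:
                converged = True
                break

    # no certificate found: fall back to the (tightly) converged iterate
    x_admm = np.clip(x, lb, ub)
    scale = 1.0 + np.max(np.abs(x_admm))
    if converged and (m == 0 or np.max(np.abs(S @ x_admm)) <= 1e-7 * scale):
        return x_admm
    raise QPError("QP did not converge to tolerance")
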