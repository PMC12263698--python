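"""Simplex-constrained least squares used by deconvolution and signatures.

Solves  min ||W (A x - b)||^2  subject to  x >= 0  and either
sum(x) <= 1  or  sum(x) == 1.  SLSQP provides the constrained solve; an
active-set polish step then re-solves the reduced unconstrained/equality
KKT system exactly, which removes solver jitter for well-posed problems
(noiseless inputs recover exact solutions to machine precision).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

_ZERO_TOL = 1e-9


def simplex_lsq(
    A: np.ndarray,
    b: np.ndarray,
    *,
    sum_to_one: bool = False,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize ``||W (A x - b)||^2`` over the (sub-)simplex.

    Parameters
    ----------
    A : (m, n) design matrix.
    b : (m,) target vector.
    sum_to_one : if True constrain ``sum(x) == 1``, else ``sum(x) <= 1``.
    weights : optional (m,) non-negative row weights (applied as sqrt in
        the residual, i.e. weighted *squared* residuals).

    For rank-deficient ``A`` the polish step uses ``lstsq`` on the active
    support, giving the smallest-norm solution among minimizers.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = A.shape
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Aw = A * w[:, None]
        bw = b * w
    else:
        Aw, bw = A, b

    if n == 0:
        return np.zeros(0)

    AtA = Aw.T @ Aw
    Atb = Aw.T @ bw

    def objective(x):
        r = Aw @ x - bw
        return 0.5 * float(r @ r)

    def gradient(x):
        return AtA @ x - Atb

    x0 = np.full(n, (1.0 / n) if sum_to_one else (0.5 / n))
    if sum_to_one:
        constraints = [{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                        "jac": lambda x: np.ones(n)}]
    else:
        constraints = [{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                        "jac": lambda x: -np.ones(n)}]
    res = optimize.minimize(
        objective, x0, jac=gradient, method="SLSQP",
        bounds=[(0.0, 1.0)] * n, constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, None)
    x = _polish(Aw, bw, x, sum_to_one)
    x[x < _ZERO_TOL] = 0.0
    if sum_to_one and x.sum() > 0:
        x /= x.sum()
    elif x.sum() > 1.0:
        x /= x.sum()
    return x


def _polish(Aw, bw, x, sum_to_one):
    """Exact re-solve on the active support identified by SLSQP."""
    support = np.flatnonzero(x > 1e-7)
    if support.size == 0:
        if not sum_to_one:
            return x
        support = np.arange(x.size)
    As = Aw[:, support]
    xs, *_ = np.linalg.lstsq(As, bw, rcond=None)
    total = xs.sum()
    needs_eq = sum_to_one or total > 1.0 + 1e-12
    if needs_eq:
        # KKT system for min ||As y - bw||^2 s.t. sum(y) == 1
        k = support.size
        AtA = As.T @ As
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = AtA
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([As.T @ bw, [1.0]])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        xs = sol[:k]
    if np.any(xs < -1e-9):
        return x  # polish left the feasible set; keep the SLSQP solution
    candidate = np.zeros_like(x)
    candidate[support] = np.clip(xs, 0.0, None)
    old = Aw @ x - bw
    new = Aw @ candidate - bw
    if new @ new <= old @ old + 1e-12:
        return candidate
    return x
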