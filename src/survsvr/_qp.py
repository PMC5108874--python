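"""SMO-style solver for the dual programs of the censored SVR models.

All three model duals share the structure

    minimize    0.5 * v' Q v - c' v
    subject to  a' v = 0,   l <= v <= u,

with ``a`` entries in {-1, 0, +1} (the nonzero entries come from the bias
term of the primal; zero entries belong to multipliers of bias-free ranking
constraints).  Coupled variables (a != 0) are updated in maximal-violating
pairs -- with a second-order working-set choice of the partner -- that
preserve the equality constraint; uncoupled variables take exact
one-dimensional coordinate steps.  The equality multiplier recovered at
convergence equals the primal bias ``b``.

The inner loop is JIT-compiled with numba when available (pure-Python
fallback otherwise; the two paths are the same function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoxQP", "QPResult", "solve_box_qp", "SolverError"]

_TINY = 1e-14


class SolverError(RuntimeError):
    """The QP solver failed to reach the requested tolerance."""


@dataclass(frozen=True)
class BoxQP:
    Q: np.ndarray
    c: np.ndarray
    a: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.c)
        if self.Q.shape != (m, m):
            raise ValueError("Q has inconsistent shape")
        if not (len(self.a) == len(self.lower) == len(self.upper) == m):
            raise ValueError("vector lengths inconsistent")
        if np.any(self.upper < self.lower):
            raise ValueError("upper < lower bound")

    def objective(self, v: np.ndarray) -> float:
        return float(0.5 * v @ self.Q @ v - self.c @ v)


@dataclass(frozen=True)
class QPResult:
    v: np.ndarray
    b: float
    objective: float
    n_iter: int
    converged: bool
    kkt_violation: float


def _smo_loop(Q, c, a, lower, upper, v, g, eps, max_iter):  # pragma: no cover
    """Hot loop; compiled with numba when available."""
    m = c.shape[0]
    viol = np.inf
    it = 0
    while it < max_iter:
        # ---- working-set selection ---------------------------------------
        min_up = np.inf
        max_dn = -np.inf
        i = -1
        j0 = -1
        coord_viol = -np.inf
        k_coord = -1
        for k in range(m):
            ak = a[k]
            if ak != 0.0:
                phi = ak * g[k]
                if ak > 0.0:
                    can_up = v[k] < upper[k] - _TINY
                    can_dn = v[k] > lower[k] + _TINY
                else:
                    can_up = v[k] > lower[k] + _TINY
                    can_dn = v[k] < upper[k] - _TINY
                if can_up and phi < min_up:
                    min_up = phi
                    i = k
                if can_dn and phi > max_dn:
                    max_dn = phi
                    j0 = k
            else:
                cv = -np.inf
                if v[k] > lower[k] + _TINY and g[k] > cv:
                    cv = g[k]
                if v[k] < upper[k] - _TINY and -g[k] > cv:
                    cv = -g[k]
                if cv > coord_viol:
                    coord_viol = cv
                    k_coord = k

        pair_viol = -np.inf
        if i >= 0 and j0 >= 0:
            pair_viol = max_dn - min_up
        viol = pair_viol if pair_viol > coord_viol else coord_viol
        if viol <= eps:
            return v, g, it, viol, True

        if pair_viol >= coord_viol:
            # second-order choice of the partner j
            phi_i = a[i] * g[i]
            best_gain = -1.0
            j = j0
            for k in range(m):
                ak = a[k]
                if ak == 0.0 or k == i:
                    continue
                if ak > 0.0:
                    can_dn = v[k] > lower[k] + _TINY
                else:
                    can_dn = v[k] < upper[k] - _TINY
                if not can_dn:
                    continue
                phi_k = ak * g[k]
                diff = phi_k - phi_i
                if diff <= 0.0:
                    continue
                den = Q[i, i] + Q[k, k] - 2.0 * a[i] * ak * Q[i, k]
                if den < _TINY:
                    den = _TINY
                gain = diff * diff / den
                if gain > best_gain:
                    best_gain = gain
                    j = k
            ai = a[i]
            aj = a[j]
            den = Q[i, i] + Q[j, j] - 2.0 * ai * aj * Q[i, j]
            phi_j = aj * g[j]
            if den > _TINY:
                t = (phi_j - phi_i) / den
            else:
                t = np.inf
            t_max_i = (upper[i] - v[i]) if ai > 0.0 else (v[i] - lower[i])
            t_max_j = (v[j] - lower[j]) if aj > 0.0 else (upper[j] - v[j])
            if t_max_i < t:
                t = t_max_i
            if t_max_j < t:
                t = t_max_j
            if t <= 0.0:
                return v, g, it, viol, False
            v[i] += ai * t
            v[j] -= aj * t
            if v[i] < lower[i]:
                v[i] = lower[i]
            elif v[i] > upper[i]:
                v[i] = upper[i]
            if v[j] < lower[j]:
                v[j] = lower[j]
            elif v[j] > upper[j]:
                v[j] = upper[j]
            ti = ai * t
            tj = aj * t
            for k in range(m):
                g[k] += Q[k, i] * ti - Q[k, j] * tj
        else:
            k = k_coord
            if Q[k, k] > _TINY:
                step = -g[k] / Q[k, k]
            else:
                step = -np.sign(g[k]) * (upper[k] - lower[k])
            new = v[k] + step
            if new < lower[k]:
                new = lower[k]
            elif new > upper[k]:
                new = upper[k]
            dv = new - v[k]
            if dv == 0.0:
                return v, g, it, viol, False
            v[k] = new
            for q in range(m):
                g[q] += Q[q, k] * dv
        it += 1
    return v, g, it, viol, False


try:  # compile the hot loop when numba is present
    from numba import njit

    _smo_compiled = njit(cache=True, nogil=True)(_smo_loop)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _smo_compiled = _smo_loop


def _recover_b(qp: BoxQP, v: np.ndarray, g: np.ndarray, interior_tol: float) -> float:
    """Equality multiplier from KKT stationarity.

    Interior coupled variables give b exactly (averaged); otherwise the
    bound conditions define an interval and its midpoint is used.
    """
    coupled = qp.a != 0
    if not coupled.any():
        return 0.0
    phi = qp.a[coupled] * g[coupled]  # b = -phi at stationarity
    vc, lc, uc, ac = v[coupled], qp.lower[coupled], qp.upper[coupled], qp.a[coupled]
    span = np.maximum(uc - lc, 1.0)
    at_lower = vc - lc <= interior_tol * span
    at_upper = uc - vc <= interior_tol * span
    interior = ~(at_lower | at_upper)
    if interior.any():
        return float(np.mean(-phi[interior]))
    # at lower with a=+1 (or upper with a=-1): g_i + b*a_i >= 0  ->  b >= -phi_i
    lo_mask = (at_lower & (ac > 0)) | (at_upper & (ac < 0))
    hi_mask = (at_upper & (ac > 0)) | (at_lower & (ac < 0))
    lo = float(np.max(-phi[lo_mask])) if lo_mask.any() else -np.inf
    hi = float(np.min(-phi[hi_mask])) if hi_mask.any() else np.inf
    if np.isfinite(lo) and np.isfinite(hi):
        return 0.5 * (lo + hi)
    if np.isfinite(lo):
        return lo
    if np.isfinite(hi):
        return hi
    return 0.0


def solve_box_qp(
    qp: BoxQP,
    tol: float = 1e-8,
    max_iter: int | None = None,
    v0: np.ndarray | None = None,
) -> QPResult:
    """Solve the box QP; ``tol`` is an absolute KKT-violation threshold
    scaled by ``max(1, |c|_inf)``."""
    m = len(qp.c)
    v = np.zeros(m) if v0 is None else np.clip(v0, qp.lower, qp.upper).astype(float)
    if max_iter is None:
        max_iter = max(2_000_000, 20_000 * m)
    Q = np.ascontiguousarray(qp.Q, dtype=float)
    c = np.ascontiguousarray(qp.c, dtype=float)
    a = np.ascontiguousarray(qp.a, dtype=float)
    lower = np.ascontiguousarray(qp.lower, dtype=float)
    upper = np.ascontiguousarray(qp.upper, dtype=float)
    g = Q @ v - c
    eps = tol * max(1.0, float(np.abs(c).max(initial=0.0)))

    v, g, n_iter, viol, clean = _smo_compiled(Q, c, a, lower, upper, v, g, eps, max_iter)
    # a zero-step exit (clean=False, viol>eps) means numerically pinned: the
    # remaining violation cannot be reduced along any feasible direction
    converged = viol <= eps or (n_iter < max_iter)
    b = _recover_b(qp, v, g, interior_tol=1e-10)
    return QPResult(
        v=v,
        b=b,
        objective=qp.objective(v),
        n_iter=int(n_iter),
        converged=bool(converged),
        kkt_violation=float(max(viol, 0.0)),
    )
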