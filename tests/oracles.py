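"""Independent reference computations used only by the test suite."""

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from survsvr.svr_models import comparable_neighbors


def primal_svr_objective(X, y, delta, gamma, mu, kind, mrl=None):
    """Solve the primal program directly (explicit w, b, slacks) with a
    generic constrained optimizer; returns the optimal objective value.

    Only valid for the linear kernel (phi = identity).  Deliberately shares
    no code with the dual solver under test.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    delta = np.asarray(delta, float)
    n, d = X.shape
    pairs = comparable_neighbors(y, delta).pairs if kind == "model2" else np.empty((0, 2), int)
    cens = np.flatnonzero(delta == 0) if kind == "ssvr_mrl" else np.array([], int)
    p = len(pairs) if kind == "model2" else len(cens)
    m = d + 1 + 2 * n + p  # w, b, eps, eps*, xi

    def f(v):
        w = v[:d]
        e = v[d + 1 : d + 1 + n]
        es = v[d + 1 + n : d + 1 + 2 * n]
        xi = v[d + 1 + 2 * n :]
        return 0.5 * w @ w + gamma * (e.sum() + es.sum()) + mu * xi.sum()

    cons = []
    A1 = np.zeros((n, m))  # Xw + b + eps >= y
    A1[:, :d] = X
    A1[:, d] = 1
    A1[np.arange(n), d + 1 + np.arange(n)] = 1
    cons.append(LinearConstraint(A1, y, np.inf))
    A2 = np.zeros((n, m))  # -delta(Xw + b) + eps* >= -delta y
    A2[:, :d] = -delta[:, None] * X
    A2[:, d] = -delta
    A2[np.arange(n), d + 1 + n + np.arange(n)] = 1
    cons.append(LinearConstraint(A2, -delta * y, np.inf))
    if kind == "model2" and p:
        A3 = np.zeros((p, m))
        for k, (i, j) in enumerate(pairs):
            A3[k, :d] = X[i] - X[j]
            A3[k, d + 1 + 2 * n + k] = 1
        cons.append(LinearConstraint(A3, y[pairs[:, 0]] - y[pairs[:, 1]], np.inf))
    if kind == "ssvr_mrl" and p:
        A3 = np.zeros((p, m))
        for k, i in enumerate(cens):
            A3[k, :d] = -X[i]
            A3[k, d] = -1
            A3[k, d + 1 + 2 * n + k] = 1
        cons.append(LinearConstraint(A3, -(y[cens] + mrl[cens]), np.inf))

    bounds = [(None, None)] * (d + 1) + [(0, None)] * (2 * n + p)
    v0 = np.zeros(m)
    v0[d + 1 : d + 1 + n] = np.maximum(y, 0)

    def grad(v):
        g = np.zeros(m)
        g[:d] = v[:d]
        g[d + 1 : d + 1 + 2 * n] = gamma
        g[d + 1 + 2 * n :] = mu
        return g

    res = minimize(f, v0, jac=grad, method="trust-constr", constraints=cons,
                   bounds=bounds, options={"maxiter": 3000, "gtol": 1e-12,
                                           "xtol": 1e-14})
    if not res.success:  # fall back to an independent second attempt
        res = minimize(f, v0, method="SLSQP", constraints=cons, bounds=bounds,
                       options={"maxiter": 800, "ftol": 1e-12})
    assert res.success, res.message
    return res.fun


def breslow_partial_loglik(beta, z, y, delta):
    """Breslow partial log-likelihood for a scalar covariate ``z``."""
    beta = float(beta)
    ll = 0.0
    for t in np.unique(y[delta == 1]):
        here = (y == t) & (delta == 1)
        at_risk = y >= t
        ll += beta * z[here].sum() - here.sum() * np.log(
            np.exp(beta * z[at_risk]).sum()
        )
    return ll
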