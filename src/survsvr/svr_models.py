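"""Censored support vector regression models and the Cox baseline.

Three quadratic programs are supported, all sharing the regression
constraints

    u_i >= y_i - eps_i            (penalized underprediction, every subject)
    -delta_i * u_i >= -delta_i * y_i - eps*_i   (overprediction, events only)

with ``u_i = w' phi(x_i) + b``:

* ``model1`` -- the constraints above only.
* ``model2`` -- adds ranking constraints ``w'(phi(x_i) - phi(x_j(i))) >=
  y_i - y_j(i) - xi_i`` over comparable neighbor pairs.
* ``ssvr_mrl`` -- adds, for censored subjects, the upper constraint
  ``u_i <= y_i + MRL_i + xi_i`` built from the Kaplan-Meier mean residual
  lifetime, giving a two-sided loss for censored data.

Each program is solved through its Wolfe dual (so any PSD kernel works);
predictions use the kernel expansion ``u(x) = sum_i beta_i k(x_i, x) + b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._qp import BoxQP, solve_box_qp
from .kernels import KernelSpec, ensure_psd, gram
from .km_mrl import MRLTable
from .survdata import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "ComparablePairs",
    "TrainedSVR",
    "CoxBaseline",
    "comparable_neighbors",
    "fit_model1",
    "fit_model2",
    "fit_ssvr_mrl",
    "fit_svr",
    "predict",
    "fit_cox_baseline",
    "FitError",
]

MODEL_KINDS = ("model1", "model2", "ssvr_mrl")


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class HyperParams:
    """Regularization constants: gamma weighs the regression slacks,
    mu the ranking / MRL slacks."""

    gamma: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass(frozen=True)
class ComparablePairs:
    """``neighbor[i]`` is the index of i's comparable neighbor with the
    largest survival time strictly smaller than y_i, or -1 if none."""

    neighbor: np.ndarray

    @property
    def pairs(self) -> np.ndarray:
        """(i, j) rows for subjects that have a neighbor."""
        idx = np.flatnonzero(self.neighbor >= 0)
        return np.column_stack([idx, self.neighbor[idx]])


@dataclass
class TrainedSVR:
    model_kind: str
    beta: np.ndarray  # kernel-expansion coefficients over training points
    b: float
    kernel: KernelSpec
    X_train: np.ndarray
    hp: HyperParams
    w_linear: np.ndarray | None = None  # primal weights, linear kernel only
    degenerate: bool = False
    objective: float = np.nan
    dual: np.ndarray | None = field(default=None, repr=False)


def comparable_neighbors(y: np.ndarray, delta: np.ndarray) -> ComparablePairs:
    """For each subject, the comparable observation with the largest time
    strictly below its own.

    A pair's event-time order is known only when the earlier observation is
    an event, so candidate neighbors are events with ``y_j < y_i``.  Ties
    among candidates are broken toward the smallest index.
    """
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    n = len(y)
    neighbor = np.full(n, -1, dtype=int)
    event_idx = np.flatnonzero(delta == 1)
    if event_idx.size:
        # sort events by (time, index) so the scan picks largest time,
        # smallest index on ties
        order = np.lexsort((event_idx, y[event_idx]))
        ev_sorted = event_idx[order]
        ev_times = y[ev_sorted]
        for i in range(n):
            k = np.searchsorted(ev_times, y[i], side="left")
            if k > 0:
                t = ev_times[k - 1]
                first = np.searchsorted(ev_times, t, side="left")
                neighbor[i] = int(ev_sorted[first])
    return ComparablePairs(neighbor=neighbor)


def _degenerate_model(ds, kernel, hp, kind) -> TrainedSVR:
    logger.warning("all observations censored: returning degenerate %s fit", kind)
    w = np.zeros(ds.d) if kernel.kind == "linear" else None
    return TrainedSVR(
        model_kind=kind,
        beta=np.zeros(ds.n),
        b=float(ds.y.max()),
        kernel=kernel,
        X_train=ds.X.copy(),
        hp=hp,
        w_linear=w,
        degenerate=True,
        objective=0.0,
    )


def _solve_dual(
    ds: SurvivalDataset,
    kernel: KernelSpec,
    hp: HyperParams,
    kind: str,
    G_extra: np.ndarray | None,
    a_extra: np.ndarray | None,
    c_extra: np.ndarray | None,
    mu_cap: float,
    tol: float,
) -> TrainedSVR:
    n = ds.n
    K = ensure_psd(gram(ds.X, ds.X, kernel))

    # regression block: beta_i = alpha_i - delta_i alpha*_i in [-gamma*delta_i, gamma]
    lower = np.where(ds.delta == 1, -hp.gamma, 0.0)
    upper = np.full(n, hp.gamma)
    a = np.ones(n)
    c = ds.y.astype(float).copy()
    G = np.eye(n)

    if G_extra is not None and G_extra.shape[1] > 0:
        p = G_extra.shape[1]
        G = np.hstack([G, G_extra])
        a = np.concatenate([a, a_extra])
        c = np.concatenate([c, c_extra])
        lower = np.concatenate([lower, np.zeros(p)])
        upper = np.concatenate([upper, np.full(p, mu_cap)])

    Q = G.T @ K @ G
    Q = 0.5 * (Q + Q.T)
    res = solve_box_qp(BoxQP(Q=Q, c=c, a=a, lower=lower, upper=upper), tol=tol)
    if not res.converged:
        raise FitError(
            f"{kind} dual solver did not converge "
            f"(KKT violation {res.kkt_violation:.3e})"
        )
    v = np.where(np.abs(res.v) < 1e-10, 0.0, res.v)  # reproducible support set
    beta = G @ v
    w = ds.X.T @ beta if kernel.kind == "linear" else None
    return TrainedSVR(
        model_kind=kind,
        beta=beta,
        b=res.b,
        kernel=kernel,
        X_train=ds.X.copy(),
        hp=hp,
        w_linear=w,
        objective=res.objective,
        dual=v,
    )


def fit_model1(
    ds: SurvivalDataset, kernel: KernelSpec, hp: HyperParams, tol: float = 1e-8
) -> TrainedSVR:
    """Standard censored SVR: one-sided loss for censored subjects."""
    if ds.n < 2:
        raise FitError("need at least 2 observations")
    if ds.n_events == 0:
        return _degenerate_model(ds, kernel, hp, "model1")
    return _solve_dual(ds, kernel, hp, "model1", None, None, None, 0.0, tol)


def fit_model2(
    ds: SurvivalDataset, kernel: KernelSpec, hp: HyperParams, tol: float = 1e-8
) -> TrainedSVR:
    """Censored SVR with additional comparable-pair ranking constraints."""
    if ds.n < 2:
        raise FitError("need at least 2 observations")
    if ds.n_events == 0:
        return _degenerate_model(ds, kernel, hp, "model2")
    pairs = comparable_neighbors(ds.y, ds.delta).pairs
    if pairs.shape[0] == 0 or hp.mu == 0.0:
        m = _solve_dual(ds, kernel, hp, "model2", None, None, None, 0.0, tol)
        return m
    p = pairs.shape[0]
    G_extra = np.zeros((ds.n, p))
    G_extra[pairs[:, 0], np.arange(p)] = 1.0
    G_extra[pairs[:, 1], np.arange(p)] -= 1.0  # handles i's neighbor j
    a_extra = np.zeros(p)  # ranking constraints carry no bias term
    c_extra = ds.y[pairs[:, 0]] - ds.y[pairs[:, 1]]
    return _solve_dual(ds, kernel, hp, "model2", G_extra, a_extra, c_extra, hp.mu, tol)


def fit_ssvr_mrl(
    ds: SurvivalDataset,
    kernel: KernelSpec,
    hp: HyperParams,
    mrl: MRLTable,
    tol: float = 1e-8,
) -> TrainedSVR:
    """Two-sided loss for censored subjects: predictions above
    ``y_i + MRL_i`` are penalized with weight mu."""
    if ds.n < 2:
        raise FitError("need at least 2 observations")
    if len(mrl.mrl) != ds.n:
        raise FitError("MRL table is not aligned with the dataset")
    if ds.n_events == 0:
        return _degenerate_model(ds, kernel, hp, "ssvr_mrl")
    cens = np.flatnonzero(ds.delta == 0)
    if cens.size == 0 or hp.mu == 0.0:
        return _solve_dual(ds, kernel, hp, "ssvr_mrl", None, None, None, 0.0, tol)
    p = cens.size
    G_extra = np.zeros((ds.n, p))
    G_extra[cens, np.arange(p)] = -1.0  # upper constraint enters with -phi(x_i)
    a_extra = -np.ones(p)
    c_extra = -(ds.y[cens] + mrl.mrl[cens])
    return _solve_dual(ds, kernel, hp, "ssvr_mrl", G_extra, a_extra, c_extra, hp.mu, tol)


def fit_svr(
    ds: SurvivalDataset,
    kernel: KernelSpec,
    hp: HyperParams,
    model_kind: str = "model1",
    tol: float = 1e-8,
) -> TrainedSVR:
    """Dispatch on ``model_kind`` (computing the MRL table when needed)."""
    if model_kind == "model1":
        return fit_model1(ds, kernel, hp, tol)
    if model_kind == "model2":
        return fit_model2(ds, kernel, hp, tol)
    if model_kind == "ssvr_mrl":
        from .km_mrl import mrl_augment

        if ds.n_events == 0:
            return _degenerate_model(ds, kernel, hp, "ssvr_mrl")
        return fit_ssvr_mrl(ds, kernel, hp, mrl_augment(ds), tol)
    raise ValueError(f"unknown model kind {model_kind!r}")


def predict(m: TrainedSVR, X: np.ndarray) -> np.ndarray:
    """Prognostic index for new points; higher predicts longer survival."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.X_train.shape[1]:
        raise ValueError(
            f"expected {m.X_train.shape[1]} features, got {X.shape[1]}"
        )
    return gram(X, m.X_train, m.kernel) @ m.beta + m.b


@dataclass
class CoxBaseline:
    """Cox proportional-hazards baseline.

    ``predict`` returns the negated linear predictor so that, like the SVR
    models, higher values mean longer predicted survival.
    """

    coef: np.ndarray
    feature_names: list[str]
    alpha: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return -(np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef)


def fit_cox_baseline(
    ds: SurvivalDataset, alphas: tuple[float, ...] = (0.0, 1e-6, 1e-3, 1e-1, 10.0)
) -> CoxBaseline:
    """Breslow-tie partial-likelihood fit, escalating ridge penalties as a
    fallback for singular or non-convergent designs (each escalation is
    logged)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    if ds.n_events == 0:
        raise FitError("Cox model requires at least one event")
    yy = Surv.from_arrays(ds.delta.astype(bool), ds.y)
    last_err: Exception | None = None
    for alpha in alphas:
        try:
            est = CoxPHSurvivalAnalysis(alpha=alpha, ties="breslow", n_iter=200)
            with np.errstate(all="ignore"):
                est.fit(ds.X, yy)
            if not np.isfinite(est.coef_).all():
                raise FitError("non-finite Cox coefficients")
            if alpha > 0:
                logger.info("Cox baseline used ridge fallback alpha=%g", alpha)
            return CoxBaseline(
                coef=np.asarray(est.coef_, dtype=float),
                feature_names=ds.feature_names,
                alpha=alpha,
            )
        except Exception as err:  # noqa: BLE001 - escalate the ridge ladder
            last_err = err
    raise FitError(f"Cox baseline failed to converge: {last_err}")
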