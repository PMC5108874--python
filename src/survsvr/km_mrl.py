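"""Kaplan-Meier estimation and mean residual lifetime (MRL).

The MRL at time ``t`` is ``integral_t^inf S(u) du / S(t)``.  The integral is
truncated at the largest observed time (restricted-mean convention), so the
quantity stays finite when the Kaplan-Meier curve does not reach zero because
the last observation is censored.  At tied times events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepSurvival", "MRLTable", "km_estimate", "mrl_at", "mrl_augment", "EstimationError"]


class EstimationError(ValueError):
    """Kaplan-Meier estimate is undefined (no events)."""


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous Kaplan-Meier step function.

    ``surv[k]`` is the survival probability just after ``times[k]``;
    implicitly S(t) = 1 for t < times[0].
    """

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray
    t_max: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.surv):
            raise ValueError("times and surv must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.surv) > 1e-15):
            raise ValueError("survival curve must be non-increasing")

    def evaluate(self, t: float) -> float:
        """S(t), right-continuous."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.surv[k - 1])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "surv": self.surv, "n_at_risk": self.n_at_risk}
        )


@dataclass(frozen=True)
class MRLTable:
    """Per-subject mean residual lifetime; 0 by convention for events."""

    mrl: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mrl < 0) or not np.isfinite(self.mrl).all():
            raise ValueError("MRL entries must be finite and non-negative")


def km_estimate(y: np.ndarray, delta: np.ndarray) -> StepSurvival:
    """Product-limit estimate of the survival function."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    if np.any(y <= 0):
        raise ValueError("times must be positive")
    if delta.sum() == 0:
        raise EstimationError("no events: Kaplan-Meier estimate undefined")

    event_times = np.unique(y[delta == 1])
    n_at_risk = np.empty(event_times.size, dtype=int)
    d_events = np.empty(event_times.size, dtype=int)
    for k, t in enumerate(event_times):
        n_at_risk[k] = int((y >= t).sum())  # censored at t still at risk
        d_events[k] = int(((y == t) & (delta == 1)).sum())
    surv = np.cumprod(1.0 - d_events / n_at_risk)
    return StepSurvival(
        times=event_times,
        surv=surv,
        n_at_risk=n_at_risk,
        t_max=float(y.max()),
    )


def mrl_at(s: StepSurvival, t: float) -> float:
    """Mean residual lifetime at ``t``; 0 when S(t) = 0 or t >= t_max."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t >= s.t_max:
        return 0.0
    st = s.evaluate(t)
    if st <= 0.0:
        return 0.0
    # area under the step curve on [t, t_max]
    knots = np.concatenate(([t], s.times[(s.times > t) & (s.times < s.t_max)], [s.t_max]))
    heights = np.array([s.evaluate(u) for u in knots[:-1]])
    area = float(np.sum(np.diff(knots) * heights))
    return area / st


def mrl_augment(ds) -> MRLTable:
    """MRL evaluated at each censored subject's time; events get 0."""
    s = km_estimate(ds.y, ds.delta)
    mrl = np.zeros(ds.n)
    for i in np.flatnonzero(ds.delta == 0):
        mrl[i] = mrl_at(s, float(ds.y[i]))
    return MRLTable(mrl=mrl)
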