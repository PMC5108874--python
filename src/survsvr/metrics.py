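"""Survival performance measures for a prognostic index.

A prognostic index ``u`` is oriented so that higher values predict longer
survival.  Three measures are provided: Harrell's concordance index, the
two-group log-rank chi-square after a median split of ``u``, and the hazard
ratio of the below-median (high-risk) group from a univariate Cox fit.  A
Wilcoxon rank-sum helper compares per-replicate measure streams between
models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceTriple",
    "c_index",
    "logrank_chi2",
    "hazard_ratio",
    "wilcoxon_rank_sum",
    "score_triple",
    "UndefinedMetricError",
]

HR_CAP = 100.0


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class PerformanceTriple:
    c_index: float
    logrank_chi2: float
    hazard_ratio: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c_index, self.logrank_chi2, self.hazard_ratio)


def _check(u, y, delta):
    u = np.asarray(u, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    delta = np.asarray(delta).ravel()
    if not (len(u) == len(y) == len(delta)):
        raise ValueError("u, y, delta must have equal length")
    return u, y, delta


def c_index(u, y, delta) -> float:
    """Harrell's concordance estimator.

    Usable pairs are those whose event-time order is known: the shorter time
    is an event (strictly shorter, or tied with the other subject censored).
    Pairs tied on both time and event status are skipped; prediction ties
    count 1/2.
    """
    u, y, delta = _check(u, y, delta)
    dy = y[:, None] - y[None, :]
    # usable with i the known-shorter subject
    usable = ((dy < 0) | ((dy == 0) & (delta[None, :] == 0))) & (delta[:, None] == 1)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise UndefinedMetricError("no usable pairs for the concordance index")
    du = u[:, None] - u[None, :]
    concordant = np.where(du < 0, 1.0, np.where(du == 0, 0.5, 0.0))
    return float((concordant * usable).sum() / n_pairs)


def _median_groups(u) -> np.ndarray:
    """True for the low (below-or-at-median ``u``) high-risk group."""
    u = np.asarray(u, dtype=float)
    return u <= np.median(u)


def logrank_chi2(u, y, delta) -> float:
    """Two-sample log-rank chi-square (1 df) between median-split groups of
    the prognostic index (ties go to the low group)."""
    u, y, delta = _check(u, y, delta)
    low = _median_groups(u)
    if low.all() or not low.any():
        raise UndefinedMetricError("median split left a group empty")
    if delta.sum() == 0:
        raise UndefinedMetricError("no events for the log-rank test")
    d, d1, n1, n0 = _breslow_tables(low.astype(int), y, delta)
    n = n1 + n0
    o_minus_e = float((d1 - d * n1 / n).sum())
    ok = n > 1
    var = float(
        (d[ok] * (n1[ok] / n[ok]) * (1 - n1[ok] / n[ok]) * (n[ok] - d[ok]) / (n[ok] - 1)).sum()
    )
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


def _breslow_tables(z, y, delta):
    """Per-unique-event-time Breslow risk tables for a binary covariate:
    (d, s1, n1, n0) with d events, s1 events in group 1, n1/n0 at-risk."""
    times = np.unique(y[delta == 1])
    at_risk = y[None, :] >= times[:, None]
    d_here = (y[None, :] == times[:, None]) & (delta[None, :] == 1)
    z1 = z == 1
    d = d_here.sum(axis=1)
    s1 = (d_here & z1[None, :]).sum(axis=1)
    n1 = (at_risk & z1[None, :]).sum(axis=1)
    n0 = at_risk.sum(axis=1) - n1
    return d, s1, n1, n0


def _newton_binary_cox(z, y, delta, cap: float) -> float:
    """Maximize the Breslow partial likelihood in the binary-covariate
    coefficient by Newton iteration with step halving."""
    d, s1, n1, n0 = _breslow_tables(z, y, delta)
    s1_tot = float(s1.sum())

    def loglik(beta):
        return float(beta * s1_tot - (d * np.log(n0 + n1 * np.exp(beta))).sum())

    beta = 0.0
    bcap = np.log(cap)
    for _ in range(100):
        e = n1 * np.exp(beta)
        pi = e / (n0 + e)
        grad = s1_tot - float((d * pi).sum())
        hess = float((d * pi * (1 - pi)).sum())
        if hess <= 1e-12:
            break
        step = grad / hess
        ll0 = loglik(beta)
        t_step = 1.0
        for _ in range(30):
            cand = float(np.clip(beta + t_step * step, -bcap, bcap))
            if loglik(cand) >= ll0 - 1e-12:
                break
            t_step *= 0.5
        new = float(np.clip(beta + t_step * step, -bcap, bcap))
        if abs(new - beta) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def hazard_ratio(u, y, delta, cap: float = HR_CAP) -> float:
    """Hazard ratio of the below-median-``u`` (high-risk) group.

    ``exp(beta)`` from a univariate Cox fit on the group indicator,
    orientation-forced >= 1 and capped at ``cap`` under monotone likelihood
    (e.g. all events in one group).
    """
    u, y, delta = _check(u, y, delta)
    low = _median_groups(u)
    if low.all() or not low.any():
        raise UndefinedMetricError("median split left a group empty")
    if delta.sum() == 0:
        raise UndefinedMetricError("no events for the hazard ratio")
    if delta[low].sum() == 0 or delta[~low].sum() == 0:
        warnings.warn(
            "monotone likelihood: a risk group has no events; capping the "
            "hazard ratio",
            RuntimeWarning,
            stacklevel=2,
        )
        return cap
    z = low.astype(int)
    beta = _newton_binary_cox(z, y, delta, cap)
    hr = float(np.exp(abs(beta)))
    if hr >= cap:
        warnings.warn("hazard ratio at cap (monotone likelihood)", RuntimeWarning, stacklevel=2)
        return cap
    return hr


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value: exact null distribution for combined
    n <= 20 without ties, normal approximation with tie correction
    otherwise."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def score_triple(u, y, delta) -> PerformanceTriple:
    """All three measures of a prognostic index on one test set."""
    return PerformanceTriple(
        c_index=c_index(u, y, delta),
        logrank_chi2=logrank_chi2(u, y, delta),
        hazard_ratio=hazard_ratio(u, y, delta),
    )
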