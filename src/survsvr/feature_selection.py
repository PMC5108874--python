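"""SVR-based feature selection.

Three methods:

1. ``association_tests`` -- statistical tests between a fitted model's
   prognostic index and each feature (correlation t-test, two-sample t-test
   or one-way ANOVA, depending on the feature type).
2. ``univariate_rank`` / ``select_top_p`` -- rank features by the test
   c-index of a single-feature linear SVR over repeated splits, then
   evaluate nested top-``p`` subsets.
3. ``rfe`` -- recursive feature elimination: repeatedly fit a linear SVR and
   drop the feature with the smallest squared weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import UndefinedMetricError
from .survdata import UNKNOWN, SurvivalDataset, standardize
from .svr_models import FitError, fit_svr
from .tuning_eval import (
    ModelSpec,
    PerformanceSummary,
    TuningError,
    evaluate_repeated,
    tune,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRanking",
    "SubsetEvaluation",
    "association_tests",
    "univariate_rank",
    "select_top_p",
    "rfe",
]

SIGNIFICANCE_LEVEL = 0.05
_RFE_GRID = {"gamma": (2.0**-4, 1.0, 2.0**4)}
_UNIVARIATE_SPEC = ModelSpec("model1", "linear", grid={"gamma": (2.0**-4, 1.0, 2.0**4)})


@dataclass(frozen=True)
class FeatureRanking:
    """Features in descending criterion order."""

    features: tuple[str, ...]
    criterion: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if len(self.features) != len(self.criterion):
            raise ValueError("features and criterion lengths differ")
        if np.any(np.diff(self.criterion) > 1e-12):
            raise ValueError("criterion must be sorted in descending order")

    def top(self, p: int) -> list[str]:
        return list(self.features[:p])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "criterion": self.criterion, "method": self.method}
        )


@dataclass
class SubsetEvaluation:
    p: int
    members: list[str]
    svr_summary: PerformanceSummary
    cox_summary: PerformanceSummary | None = None
    best: bool = False


def association_tests(ds: SurvivalDataset, u: np.ndarray) -> pd.DataFrame:
    """Per-feature tests of association with the prognostic index ``u``.

    Continuous: Pearson correlation with its t-test; binary categorical:
    two-sample t-test on ``u``; 3+ levels: one-way ANOVA.  Rows in an
    ``Unknown`` category are excluded from that feature's test.  Constant
    features (or constant ``u``) are skipped with a flag.
    """
    u = np.asarray(u, dtype=float).ravel()
    if len(u) != ds.n:
        raise ValueError("u must align with the dataset rows")
    rows = []
    u_const = np.ptp(u) == 0
    for j, s in enumerate(ds.schema):
        col = ds.X[:, j]
        row: dict[str, object] = {"feature": s.name, "kind": s.kind}
        if u_const or np.ptp(col) == 0:
            row.update(test="skipped", statistic=np.nan, p_value=np.nan, skipped=True)
            rows.append(row)
            continue
        if s.is_continuous:
            r, p = stats.pearsonr(col, u)
            row.update(test="pearson", statistic=float(r), p_value=float(p), skipped=False)
        else:
            codes = col.astype(int)
            levels = [
                k for k, lab in enumerate(s.categories) if lab != UNKNOWN
            ]
            groups = [u[codes == k] for k in levels]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                row.update(test="skipped", statistic=np.nan, p_value=np.nan, skipped=True)
            elif len(groups) == 2:
                t, p = stats.ttest_ind(groups[0], groups[1])
                row.update(test="t-test", statistic=float(t), p_value=float(p), skipped=False)
            else:
                f, p = stats.f_oneway(*groups)
                row.update(test="anova", statistic=float(f), p_value=float(p), skipped=False)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < SIGNIFICANCE_LEVEL
    return out


def univariate_rank(
    ds: SurvivalDataset, n_reps: int = 50, seed: int = 0
) -> FeatureRanking:
    """Rank features by median test c-index of a single-feature linear SVR.

    All features share the same replicate split seeds so their criterion
    values are comparable.
    """
    if ds.d < 2:
        raise ValueError("need at least 2 features to rank")
    crit = np.empty(ds.d)
    for j, s in enumerate(ds.schema):
        sub = ds.subset_features([s.name])
        summary = evaluate_repeated(sub, _UNIVARIATE_SPEC, n_reps=n_reps, seed=seed)
        comp = summary.completed
        crit[j] = float(np.median(comp[:, 0])) if len(comp) else -np.inf
    order = np.argsort(-crit, kind="stable")
    return FeatureRanking(
        features=tuple(ds.feature_names[j] for j in order),
        criterion=crit[order],
        method="univariate",
    )


def _evaluate_subset(
    ds: SurvivalDataset,
    members: list[str],
    n_reps: int,
    seed: int,
    with_cox: bool,
) -> SubsetEvaluation:
    sub = ds.subset_features(members)
    svr = evaluate_repeated(
        sub, ModelSpec("model1", "linear", grid=_RFE_GRID), n_reps=n_reps, seed=seed
    )
    cox = (
        evaluate_repeated(sub, ModelSpec("cox"), n_reps=n_reps, seed=seed)
        if with_cox
        else None
    )
    return SubsetEvaluation(p=len(members), members=list(members), svr_summary=svr,
                            cox_summary=cox)


def _flag_best(evals: list[SubsetEvaluation]) -> None:
    scores = [
        float(np.median(e.svr_summary.completed[:, 0]))
        if len(e.svr_summary.completed)
        else -np.inf
        for e in evals
    ]
    evals[int(np.argmax(scores))].best = True


def select_top_p(
    ranking: FeatureRanking,
    ds: SurvivalDataset,
    p_values: list[int],
    n_reps: int = 50,
    seed: int = 0,
    with_cox: bool = True,
) -> list[SubsetEvaluation]:
    """Evaluate linear SVR (and Cox) on each top-``p`` subset; the subset
    with the highest SVR median c-index is flagged best."""
    if max(p_values) > ds.d:
        raise ValueError("p exceeds the number of features")
    evals = [
        _evaluate_subset(ds, ranking.top(p), n_reps, seed, with_cox) for p in p_values
    ]
    _flag_best(evals)
    return evals


def rfe(
    ds: SurvivalDataset,
    n_reps: int = 50,
    seed: int = 0,
    with_cox: bool = True,
    tune_folds: int = 3,
) -> list[SubsetEvaluation]:
    """Recursive feature elimination on squared linear-SVR weights.

    Fits a tuned linear SVR on the (standardized) current subset, records a
    subset evaluation, then removes the feature with the smallest squared
    weight (ties: the later-indexed feature) until one feature remains.
    Returns the nested path, sizes d..1, with the best subset flagged.
    """
    members = list(ds.feature_names)
    evals: list[SubsetEvaluation] = []
    prev_order: list[str] = []
    while members:
        evals.append(_evaluate_subset(ds, members, n_reps, seed, with_cox))
        if len(members) == 1:
            break
        sub = ds.subset_features(members)
        strain, _ = standardize(sub)
        try:
            hp, kspec = tune(strain, "model1", "linear", _RFE_GRID,
                             folds=tune_folds, seed=seed)
            model = fit_svr(strain, kspec, hp, "model1")
            if model.degenerate:
                raise FitError("degenerate elimination fit")
            w2 = model.w_linear**2
            # smallest w^2 leaves; ties drop the later-indexed feature
            worst = len(w2) - 1 - int(np.argmin(w2[::-1]))
            prev_order = [m for _, m in sorted(zip(w2, members), key=lambda t: t[0])]
        except (FitError, TuningError):
            if not prev_order:
                worst = len(members) - 1
            else:
                logger.warning("degenerate fit during elimination; falling back to "
                               "previous iteration's ranking")
                cand = [m for m in prev_order if m in members]
                worst = members.index(cand[0])
        del members[worst]
    _flag_best(evals)
    return evals


def subset_table(evals: list[SubsetEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evals:
        row: dict[str, object] = {"p": e.p, "members": "+".join(e.members), "best": e.best}
        for prefix, summ in (("svr", e.svr_summary), ("cox", e.cox_summary)):
            if summ is None:
                continue
            med, sd = summ.median(), summ.sd()
            for m, v in med.items():
                row[f"{prefix}_{m}_median"] = v
            for m, v in sd.items():
                row[f"{prefix}_{m}_sd"] = v
        rows.append(row)
    return pd.DataFrame(rows)
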