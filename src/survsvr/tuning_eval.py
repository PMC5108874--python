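"""Hyperparameter tuning (3-fold CV) and the repeated random-split
evaluation harness.

``evaluate_repeated`` mirrors the benchmark protocol: per replicate the data
are split 2/3 train : 1/3 test, standardized on the training part, tuned by
k-fold cross-validation maximizing the mean validation concordance index,
fitted, and scored on the test part with all three performance measures.
Replicate split seeds derive from one master seed, so models evaluated with
the same seed see identical replicate streams and can be compared with the
rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec, gram
from .metrics import PerformanceTriple, UndefinedMetricError, c_index, score_triple, wilcoxon_rank_sum
from .survdata import SurvivalDataset, split_train_test, standardize
from .svr_models import FitError, HyperParams, fit_cox_baseline, fit_svr, predict

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PerformanceSummary",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "tune",
    "evaluate_repeated",
    "compare_models",
    "fit_and_score",
    "TuningError",
]

MEASURES = ("c_index", "logrank_chi2", "hazard_ratio")

#: gamma/mu ladders 2^-8, 2^-6, ..., 2^8; RBF bandwidths from inverse
#: quantiles of the pairwise squared distances; polynomial degree 2 or 3.
DEFAULT_GRID: dict[str, tuple] = {
    "gamma": tuple(2.0**k for k in range(-8, 9, 2)),
    "mu": tuple(2.0**k for k in range(-8, 9, 2)),
    "rbf_quantile": (0.1, 0.5, 0.9),
    "degree": (2, 3),
}

#: coarse ladder for simulation-scale runs
REDUCED_GRID: dict[str, tuple] = {
    "gamma": (2.0**-4, 1.0, 2.0**4),
    "mu": (2.0**-4, 1.0, 2.0**4),
    "rbf_quantile": (0.5,),
    "degree": (2, 3),
}


class TuningError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Descriptor of one model entry in a benchmark.

    ``model_kind`` is one of ``model1``, ``model2``, ``ssvr_mrl`` or
    ``cox``.  If ``grid`` is given, hyperparameters are tuned per replicate;
    otherwise ``hp`` is used as-is.
    """

    model_kind: str
    kernel_kind: str = "linear"
    hp: HyperParams = field(default_factory=lambda: HyperParams(gamma=1.0))
    grid: Mapping[str, Sequence] | None = None
    standardize: bool = True
    tune_folds: int = 3
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(
                self,
                "label",
                self.model_kind
                if self.model_kind == "cox"
                else f"{self.model_kind}-{self.kernel_kind}",
            )

    @property
    def uses_mu(self) -> bool:
        return self.model_kind in ("model2", "ssvr_mrl")


@dataclass
class PerformanceSummary:
    label: str
    triples: list[PerformanceTriple | None]
    n_reps: int

    @property
    def completed(self) -> np.ndarray:
        """(k, 3) array of completed replicate triples."""
        rows = [t.as_tuple() for t in self.triples if t is not None]
        return np.array(rows) if rows else np.empty((0, 3))

    @property
    def n_degenerate(self) -> int:
        return sum(t is None for t in self.triples)

    def measure(self, name: str) -> np.ndarray:
        return self.completed[:, MEASURES.index(name)]

    def median(self) -> dict[str, float]:
        comp = self.completed
        if not len(comp):
            return {m: float("nan") for m in MEASURES}
        return {m: float(np.median(comp[:, k])) for k, m in enumerate(MEASURES)}

    def sd(self) -> dict[str, float]:
        comp = self.completed
        return {m: float(np.std(comp[:, k], ddof=1)) if len(comp) > 1 else 0.0
                for k, m in enumerate(MEASURES)}

    def mean(self) -> dict[str, float]:
        comp = self.completed
        if not len(comp):
            return {m: float("nan") for m in MEASURES}
        return {m: float(np.mean(comp[:, k])) for k, m in enumerate(MEASURES)}

    def row(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {"model": self.label, "n_reps": self.n_reps,
                                       "n_degenerate": self.n_degenerate}
        med, sd = self.median(), self.sd()
        for m in MEASURES:
            out[f"{m}_median"] = med[m]
            out[f"{m}_sd"] = sd[m]
        return out


def _rbf_gamma(X: np.ndarray, quantile: float) -> float:
    n = X.shape[0]
    idx = np.triu_indices(n, k=1)
    sq = (
        (X**2).sum(axis=1)[:, None] - 2 * X @ X.T + (X**2).sum(axis=1)[None, :]
    )[idx]
    q = float(np.quantile(sq, quantile))
    return 1.0 / q if q > 0 else 1.0


def _kernel_spec(kernel_kind: str, train: SurvivalDataset, params: dict) -> KernelSpec:
    if kernel_kind == "linear":
        return KernelSpec("linear")
    if kernel_kind == "polynomial":
        return KernelSpec("polynomial", degree=int(params.get("degree", 3)))
    if kernel_kind == "rbf":
        g = params.get("gamma_rbf")
        if g is None:
            g = _rbf_gamma(train.X, params.get("rbf_quantile", 0.5))
        return KernelSpec("rbf", gamma_rbf=float(g))
    if kernel_kind == "clinical":
        return KernelSpec("clinical", schema=tuple(train.with_ranges().schema))
    raise ValueError(f"unknown kernel kind {kernel_kind!r}")


def _kernel_sort_key(params: dict) -> float:
    return float(
        params.get("degree", params.get("rbf_quantile", params.get("gamma_rbf", 0.0)))
    )


def _cv_folds(n: int, folds: int, delta: np.ndarray, rng: np.random.Generator):
    for _ in range(100):
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        ok = all(delta[np.concatenate([p for q, p in enumerate(parts) if q != k])].sum() >= 1
                 for k in range(folds))
        if ok:
            return parts
    raise TuningError("could not form folds with events in every training part")


def tune(
    ds: SurvivalDataset,
    model_kind: str,
    kernel_kind: str,
    grid: Mapping[str, Sequence],
    folds: int = 3,
    seed: int = 0,
) -> tuple[HyperParams, KernelSpec]:
    """Exhaustive grid search maximizing mean validation c-index.

    Ties break toward smaller gamma, then smaller mu, then the smaller
    kernel parameter; fold assignment is deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    gammas = sorted(grid.get("gamma", (1.0,)))
    uses_mu = model_kind in ("model2", "ssvr_mrl")
    mus = sorted(grid.get("mu", (1.0,))) if uses_mu else (0.0,)
    if kernel_kind == "polynomial":
        kparams = [{"degree": v} for v in sorted(grid.get("degree", (3,)))]
    elif kernel_kind == "rbf":
        if "gamma_rbf" in grid:
            kparams = [{"gamma_rbf": v} for v in sorted(grid["gamma_rbf"])]
        else:
            kparams = [{"rbf_quantile": v} for v in sorted(grid.get("rbf_quantile", (0.5,)))]
    else:
        kparams = [{}]

    rng = np.random.default_rng(seed)
    parts = _cv_folds(ds.n, folds, ds.delta, rng)
    splits = []
    for k in range(folds):
        va = parts[k]
        tr = np.concatenate([p for q, p in enumerate(parts) if q != k])
        splits.append((ds.subset_rows(tr), ds.subset_rows(va)))

    best = None
    best_score = -np.inf
    for g, mu, kp in itertools.product(gammas, mus, kparams):
        hp = HyperParams(gamma=float(g), mu=float(mu))
        scores = []
        for tr, va in splits:
            try:
                spec = _kernel_spec(kernel_kind, tr, kp)
                model = fit_svr(tr, spec, hp, model_kind)
                if model.degenerate:
                    continue
                scores.append(c_index(predict(model, va.X), va.y, va.delta))
            except (FitError, UndefinedMetricError):
                continue
        if not scores:
            continue
        score = float(np.mean(scores))
        if score > best_score + 1e-12:  # strict: earlier (smaller) combos win ties
            best_score = score
            best = (hp, kp)
    if best is None:
        raise TuningError("every grid point was degenerate")
    hp, kp = best
    return hp, _kernel_spec(kernel_kind, ds, kp)


def fit_and_score(
    train: SurvivalDataset,
    test: SurvivalDataset,
    spec: ModelSpec,
    seed: int = 0,
) -> PerformanceTriple | None:
    """Standardize, (optionally) tune, fit and score one replicate.

    Returns ``None`` for degenerate replicates (degenerate fit or undefined
    metric).
    """
    if spec.standardize:
        train, (test,) = standardize(train, [test])
    try:
        if spec.model_kind == "cox":
            model = fit_cox_baseline(train)
            u = model.predict(test.X)
        else:
            if spec.grid is not None:
                hp, kspec = tune(
                    train, spec.model_kind, spec.kernel_kind, spec.grid,
                    folds=spec.tune_folds, seed=seed,
                )
            else:
                hp = spec.hp
                kspec = _kernel_spec(spec.kernel_kind, train, {})
            m = fit_svr(train, kspec, hp, spec.model_kind)
            if m.degenerate:
                return None
            u = predict(m, test.X)
        return score_triple(u, test.y, test.delta)
    except (FitError, UndefinedMetricError, TuningError):
        return None


def replicate_seeds(seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate split seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n_reps)]


def evaluate_repeated(
    ds: SurvivalDataset,
    model_spec: ModelSpec,
    n_reps: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> PerformanceSummary:
    """Benchmark protocol: ``n_reps`` random 2/3 - 1/3 splits."""
    triples: list[PerformanceTriple | None] = []
    for rep_seed in replicate_seeds(seed, n_reps):
        train, test = split_train_test(ds, train_fraction, rep_seed)
        triples.append(fit_and_score(train, test, model_spec, seed=rep_seed))
    summary = PerformanceSummary(label=model_spec.label, triples=triples, n_reps=n_reps)
    if summary.n_degenerate > 0.2 * n_reps:
        logger.warning(
            "%s: %d/%d replicates degenerate", model_spec.label,
            summary.n_degenerate, n_reps,
        )
    return summary


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_models(
    summaries: Sequence[PerformanceSummary], reference: str
) -> pd.DataFrame:
    """Rank-sum p-values of every model against the reference, per measure."""
    by_label = {s.label: s for s in summaries}
    if reference not in by_label:
        raise ValueError(f"reference {reference!r} not among summaries")
    ref = by_label[reference]
    if any(s.n_reps != ref.n_reps for s in summaries):
        raise ValueError("summaries have mismatched replicate counts")
    rows = []
    for s in summaries:
        if s.label == reference:
            continue
        row: dict[str, object] = {"model": s.label, "reference": reference}
        for m in MEASURES:
            if len(s.completed) and len(ref.completed):
                p = wilcoxon_rank_sum(s.measure(m), ref.measure(m))
            else:
                p = float("nan")
            row[f"{m}_p"] = p
            row[f"{m}_sig"] = _stars(p) if np.isfinite(p) else ""
        rows.append(row)
    return pd.DataFrame(rows)
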