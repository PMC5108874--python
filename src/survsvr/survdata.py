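"""Data model and I/O for right-censored survival tables.

A dataset couples an ``n x d`` numeric feature matrix with survival times
``y > 0``, event indicators ``delta`` (1 = event, 0 = right-censored) and a
per-feature schema.  Categorical features are integer-coded against the
ordered category list recorded in the schema; missing categorical values
become an explicit ``"Unknown"`` category, while rows with missing
continuous values are dropped (with a logged count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"

__all__ = [
    "FeatureSchema",
    "SurvivalDataset",
    "Standardizer",
    "load_dataset",
    "write_dataset",
    "split_train_test",
    "standardize",
    "SchemaError",
    "ValidationError",
    "UnsplittableError",
]


class SchemaError(ValueError):
    """A required column is absent or the schema is inconsistent."""


class ValidationError(ValueError):
    """A cell value violates the dataset invariants."""


class UnsplittableError(ValueError):
    """The dataset cannot be partitioned as requested."""


@dataclass(frozen=True)
class FeatureSchema:
    """Type metadata for one feature column."""

    name: str
    kind: str  # "continuous" | "categorical"
    categories: tuple[str, ...] = ()
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.categories) < 1:
            raise SchemaError(f"categorical feature {self.name!r} needs >=1 category")
        if self.kind == "continuous" and self.range is not None:
            lo, hi = self.range
            if hi < lo:
                raise SchemaError(f"feature {self.name!r} has max < min")

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"


@dataclass
class SurvivalDataset:
    """Feature matrix plus survival outcome.

    ``X`` is float with categorical columns holding integer category codes.
    """

    X: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    schema: list[FeatureSchema] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.delta) != n:
            raise ValidationError("X, y and delta must have equal length")
        bad = np.flatnonzero(~(self.y > 0))
        if bad.size:
            raise ValidationError(f"non-positive survival time at row {bad[0]}")
        if not np.isin(self.delta, (0, 1)).all():
            raise ValidationError("delta entries must be 0 or 1")
        self.delta = self.delta.astype(np.int8)
        if not np.isfinite(self.X).all():
            raise ValidationError("feature matrix contains non-finite entries")
        if not self.schema:
            self.schema = [
                FeatureSchema(f"x{j}", "continuous") for j in range(self.X.shape[1])
            ]
        if len(self.schema) != self.X.shape[1]:
            raise SchemaError("schema length does not match number of columns")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def subset_rows(self, idx: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(self.X[idx], self.y[idx], self.delta[idx], list(self.schema))

    def subset_features(self, names: Sequence[str]) -> "SurvivalDataset":
        pos = {s.name: j for j, s in enumerate(self.schema)}
        cols = [pos[nm] for nm in names]
        return SurvivalDataset(
            self.X[:, cols], self.y, self.delta, [self.schema[j] for j in cols]
        )

    def with_ranges(self) -> "SurvivalDataset":
        """Return a copy whose continuous schemas carry observed (min, max)."""
        schema = []
        for j, s in enumerate(self.schema):
            if s.is_continuous:
                col = self.X[:, j]
                schema.append(replace(s, range=(float(col.min()), float(col.max()))))
            else:
                schema.append(s)
        return SurvivalDataset(self.X.copy(), self.y.copy(), self.delta.copy(), schema)

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        cols: dict[str, object] = {time_col: self.y, event_col: self.delta.astype(int)}
        for j, s in enumerate(self.schema):
            if s.is_continuous:
                cols[s.name] = self.X[:, j]
            else:
                codes = self.X[:, j].astype(int)
                cols[s.name] = [s.categories[k] for k in codes]
        return pd.DataFrame(cols)


def _infer_kind(series: pd.Series) -> str:
    return "continuous" if pd.api.types.is_numeric_dtype(series) else "categorical"


def load_dataset(
    path,
    time_col: str,
    event_col: str,
    schema_hints: Mapping[str, object] | None = None,
    delimiter: str | None = None,
) -> SurvivalDataset:
    """Read a delimited text file into a :class:`SurvivalDataset`.

    ``schema_hints`` maps a feature column to ``"continuous"`` or
    ``"categorical"``, or the event column to a ``{label: 0/1}`` mapping for
    non-numeric event coding.  Feature kinds are otherwise inferred from the
    column dtype (numeric -> continuous, anything else -> categorical).
    """
    hints = dict(schema_hints or {})
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")

    ev = df[event_col]
    if event_col in hints:
        mapping = hints.pop(event_col)
        if not isinstance(mapping, Mapping):
            raise SchemaError(f"hint for event column {event_col!r} must be a mapping")
        ev = ev.map(mapping)
    ev_arr = pd.to_numeric(ev, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isin(ev_arr, (0.0, 1.0)))
    if bad.size:
        raise ValidationError(
            f"event value {df[event_col].iloc[bad[0]]!r} at row {bad[0]} is not in {{0, 1}}"
        )

    t_arr = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~(t_arr > 0))
    if bad.size:
        raise ValidationError(
            f"non-positive or missing survival time at row {bad[0]}"
        )

    feat_cols = [c for c in df.columns if c not in (time_col, event_col)]
    kinds = {}
    for c in feat_cols:
        k = hints.get(c, _infer_kind(df[c]))
        if k not in ("continuous", "categorical"):
            raise SchemaError(f"hint for {c!r} must be 'continuous' or 'categorical'")
        kinds[c] = k

    # drop rows with missing continuous values
    cont = [c for c in feat_cols if kinds[c] == "continuous"]
    keep = np.ones(len(df), dtype=bool)
    for c in cont:
        keep &= pd.to_numeric(df[c], errors="coerce").notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d row(s) with missing continuous values", n_drop)

    schema: list[FeatureSchema] = []
    columns: list[np.ndarray] = []
    for c in feat_cols:
        if kinds[c] == "continuous":
            vals = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)[keep]
            schema.append(FeatureSchema(c, "continuous"))
            columns.append(vals)
        else:
            raw = df[c].astype("object").where(df[c].notna(), UNKNOWN).astype(str)[keep]
            cats = tuple(sorted(raw.unique()))
            code = {lab: k for k, lab in enumerate(cats)}
            logger.info("categorical %r coded as %s", c, code)
            schema.append(FeatureSchema(c, "categorical", categories=cats))
            columns.append(raw.map(code).to_numpy(dtype=float))

    X = np.column_stack(columns) if columns else np.empty((int(keep.sum()), 0))
    return SurvivalDataset(X, t_arr[keep], ev_arr[keep].astype(int), schema)


def write_dataset(
    ds: SurvivalDataset, path, time_col: str = "time", event_col: str = "event",
    delimiter: str = ","
) -> None:
    ds.to_frame(time_col, event_col).to_csv(path, sep=delimiter, index=False)


def split_train_test(
    ds: SurvivalDataset, train_fraction: float, seed: int, max_retries: int = 100
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Random disjoint row partition with ``ceil(n * f)`` training rows.

    Resamples (bounded) until the training part contains at least one event.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if ds.n < 3:
        raise UnsplittableError("need at least 3 rows to split")
    if ds.n_events == 0:
        raise UnsplittableError("dataset has no events; cannot form a training set")
    n_train = int(np.ceil(ds.n * train_fraction))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(ds.n)
        tr, te = perm[:n_train], perm[n_train:]
        if ds.delta[tr].sum() >= 1:
            return ds.subset_rows(tr), ds.subset_rows(te)
    raise UnsplittableError("could not place an event in the training set")


@dataclass(frozen=True)
class Standardizer:
    """Per-feature affine transform fitted on training data.

    Continuous features are centred and scaled by the training mean and
    population standard deviation (``ddof=0``); a constant feature is scaled
    by 1.  Categorical codes pass through untouched.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, ds: SurvivalDataset) -> "Standardizer":
        mean = np.zeros(ds.d)
        scale = np.ones(ds.d)
        for j, s in enumerate(ds.schema):
            if s.is_continuous:
                col = ds.X[:, j]
                mean[j] = col.mean()
                sd = col.std(ddof=0)
                scale[j] = sd if sd > 0 else 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, ds: SurvivalDataset) -> SurvivalDataset:
        X = (ds.X - self.mean) / self.scale
        out = SurvivalDataset(X, ds.y.copy(), ds.delta.copy(), list(ds.schema))
        return out.with_ranges()


def standardize(
    train: SurvivalDataset, others: Sequence[SurvivalDataset] = ()
) -> tuple[SurvivalDataset, list[SurvivalDataset]]:
    """Standardize ``train`` and apply the same parameters to ``others``."""
    for o in others:
        if [s.name for s in o.schema] != train.feature_names or [
            s.kind for s in o.schema
        ] != [s.kind for s in train.schema]:
            raise SchemaError("schemas do not match across datasets")
    tf = Standardizer.fit(train)
    return tf.transform(train), [tf.transform(o) for o in others]
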