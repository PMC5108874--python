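"""Kernel functions and Gram-matrix construction.

Supported kinds: ``linear`` (A @ B.T), ``polynomial`` ((A @ B.T + 1)^degree),
``rbf`` (exp(-gamma * ||a - b||^2)) and the additive ``clinical`` kernel for
mixed continuous/categorical tables.  The clinical kernel averages per-feature
components so values stay in [0, 1]: a continuous feature with training range
``r`` contributes ``clip((r - |x - z|) / r, 0, 1)``, a categorical feature
contributes an equality indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survdata import FeatureSchema

__all__ = ["KernelSpec", "gram", "ensure_psd", "ConditioningError"]

KINDS = ("linear", "polynomial", "rbf", "clinical")


class ConditioningError(RuntimeError):
    """Jitter budget exhausted while repairing a non-PSD matrix."""


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "linear"
    degree: int = 3
    gamma_rbf: float | None = None
    schema: tuple[FeatureSchema, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be a positive integer")
        if self.kind == "rbf" and (self.gamma_rbf is None or self.gamma_rbf <= 0):
            raise ValueError("rbf kernel requires gamma_rbf > 0")
        if self.kind == "clinical":
            if not self.schema:
                raise ValueError("clinical kernel requires a feature schema")
            for s in self.schema:
                if s.is_continuous and s.range is None:
                    raise ValueError(
                        f"clinical kernel needs a training range for {s.name!r}"
                    )

    def to_config(self) -> dict:
        cfg: dict = {"kind": self.kind}
        if self.kind == "polynomial":
            cfg["degree"] = self.degree
        if self.kind == "rbf":
            cfg["gamma_rbf"] = self.gamma_rbf
        return cfg


def _clinical_gram(A: np.ndarray, B: np.ndarray, schema) -> np.ndarray:
    K = np.zeros((A.shape[0], B.shape[0]))
    for j, s in enumerate(schema):
        a = A[:, j][:, None]
        b = B[:, j][None, :]
        if s.is_continuous:
            lo, hi = s.range
            r = hi - lo
            if r <= 0:
                comp = (a == b).astype(float)
            else:
                comp = np.clip((r - np.abs(a - b)) / r, 0.0, 1.0)
        else:
            comp = (a == b).astype(float)
        K += comp
    return K / len(schema)


def gram(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix ``K[i, j] = k(A[i], B[j])``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B have different numbers of features")
    if spec.kind == "clinical" and len(spec.schema) != A.shape[1]:
        raise ValueError("clinical schema does not match matrix dimensionality")

    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "polynomial":
        return (A @ B.T + 1.0) ** spec.degree
    if spec.kind == "rbf":
        sq = (
            (A**2).sum(axis=1)[:, None]
            - 2.0 * (A @ B.T)
            + (B**2).sum(axis=1)[None, :]
        )
        return np.exp(-spec.gamma_rbf * np.maximum(sq, 0.0))
    return _clinical_gram(A, B, spec.schema)


def ensure_psd(K: np.ndarray, jitter_max: float = 1e-6) -> np.ndarray:
    """Add the smallest diagonal jitter from a geometric ladder making
    ``min eig(K) >= -1e-10``; returns ``K`` unchanged if already PSD."""
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    min_eig = float(np.linalg.eigvalsh(K).min())
    if min_eig >= -1e-10:
        return K
    jitter = 1e-12
    while jitter <= jitter_max:
        if min_eig + jitter >= -1e-10:
            return K + jitter * np.eye(K.shape[0])
        jitter *= 10.0
    raise ConditioningError(
        f"could not reach PSD within jitter_max={jitter_max} (min eig {min_eig:.3e})"
    )
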