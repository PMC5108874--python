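"""Structured-text (JSON) persistence for trained SVR models.

The artifact stores the kernel spec, expansion coefficients, bias, training
features, feature schema and the standardization parameters, so a saved
model can score new delimited-text inputs byte-for-byte reproducibly.
"""

from __future__ import annotations

import json

import numpy as np

from .kernels import KernelSpec
from .survdata import FeatureSchema, Standardizer
from .svr_models import HyperParams, TrainedSVR

__all__ = ["save_model", "load_model"]


def _schema_to_obj(schema) -> list[dict]:
    out = []
    for s in schema:
        out.append(
            {
                "name": s.name,
                "kind": s.kind,
                "categories": list(s.categories),
                "range": list(s.range) if s.range is not None else None,
            }
        )
    return out


def _schema_from_obj(obj) -> tuple[FeatureSchema, ...]:
    return tuple(
        FeatureSchema(
            name=o["name"],
            kind=o["kind"],
            categories=tuple(o["categories"]),
            range=tuple(o["range"]) if o["range"] is not None else None,
        )
        for o in obj
    )


def save_model(
    model: TrainedSVR,
    path,
    schema=None,
    standardizer: Standardizer | None = None,
) -> None:
    obj = {
        "format": "survsvr-model/1",
        "model_kind": model.model_kind,
        "kernel": {
            "kind": model.kernel.kind,
            "degree": model.kernel.degree,
            "gamma_rbf": model.kernel.gamma_rbf,
            "schema": _schema_to_obj(model.kernel.schema) if model.kernel.schema else None,
        },
        "beta": model.beta.tolist(),
        "b": model.b,
        "X_train": model.X_train.tolist(),
        "hp": {"gamma": model.hp.gamma, "mu": model.hp.mu},
        "w_linear": model.w_linear.tolist() if model.w_linear is not None else None,
        "degenerate": model.degenerate,
        "objective": None if np.isnan(model.objective) else model.objective,
        "schema": _schema_to_obj(schema) if schema is not None else None,
        "standardizer": None
        if standardizer is None
        else {"mean": standardizer.mean.tolist(), "scale": standardizer.scale.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_model(path):
    """Returns ``(model, schema, standardizer)``; the latter two may be None."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format") != "survsvr-model/1":
        raise ValueError(f"{path} is not a survsvr model artifact")
    k = obj["kernel"]
    kernel = KernelSpec(
        kind=k["kind"],
        degree=k["degree"],
        gamma_rbf=k["gamma_rbf"],
        schema=_schema_from_obj(k["schema"]) if k["schema"] else None,
    )
    model = TrainedSVR(
        model_kind=obj["model_kind"],
        beta=np.asarray(obj["beta"], dtype=float),
        b=float(obj["b"]),
        kernel=kernel,
        X_train=np.asarray(obj["X_train"], dtype=float),
        hp=HyperParams(**obj["hp"]),
        w_linear=None if obj["w_linear"] is None else np.asarray(obj["w_linear"]),
        degenerate=bool(obj["degenerate"]),
        objective=np.nan if obj["objective"] is None else float(obj["objective"]),
    )
    schema = _schema_from_obj(obj["schema"]) if obj["schema"] else None
    std = (
        None
        if obj["standardizer"] is None
        else Standardizer(
            mean=np.asarray(obj["standardizer"]["mean"]),
            scale=np.asarray(obj["standardizer"]["scale"]),
        )
    )
    return model, schema, std
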