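"""The eight fitted TEAC equations shipped as fixed predictors.

The one- to eight-variable linear TEAC models are packaged with their
printed coefficients and uncertainties, alongside metadata for every
descriptor they use.  Inputs must already be normalized to the original
training min/max (which is not public), so these predictors serve for
equation evaluation and interpretation, not for scoring raw descriptor
values.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, NamedTuple

__all__ = [
    "PublishedModel",
    "DescriptorInfo",
    "TeacPrediction",
    "get_model",
    "predict_teac",
    "describe_descriptor",
    "coefficient_sign_summary",
    "list_descriptors",
]


@dataclass(frozen=True)
class PublishedModel:
    """One fixed TEAC equation: ordered (name, coefficient, uncertainty)
    terms plus intercept, all in mM per normalized-descriptor unit."""

    model_id: int
    terms: tuple[tuple[str, float, float], ...]
    intercept: float
    intercept_uncertainty: float

    @property
    def descriptor_names(self) -> list[str]:
        return [t[0] for t in self.terms]


@dataclass(frozen=True)
class DescriptorInfo:
    """Name, printed definition and family of a model descriptor."""

    name: str
    definition: str
    family: str
    models: tuple[int, ...]
    note: str | None = None


class TeacPrediction(NamedTuple):
    """Predicted TEAC (mM) with evaluation warnings."""

    teac: float
    out_of_range_inputs: list[str]
    negative_prediction: bool


@lru_cache(maxsize=1)
def _models() -> dict[int, PublishedModel]:
    ref = importlib.resources.files("teacqsar.fixtures") / "published_models.json"
    payload = json.loads(ref.read_text())
    out = {}
    for key, entry in payload.items():
        model_id = int(key)
        terms = tuple((name, float(c), float(u)) for name, c, u in entry["terms"])
        if len(terms) != model_id:
            raise RuntimeError(f"model {model_id} has {len(terms)} terms")
        out[model_id] = PublishedModel(
            model_id=model_id,
            terms=terms,
            intercept=float(entry["intercept"][0]),
            intercept_uncertainty=float(entry["intercept"][1]),
        )
    return out


@lru_cache(maxsize=1)
def _descriptor_info() -> dict[str, DescriptorInfo]:
    ref = importlib.resources.files("teacqsar.fixtures") / "descriptor_info.json"
    payload = json.loads(ref.read_text())
    return {
        name: DescriptorInfo(
            name=name,
            definition=entry["definition"],
            family=entry["family"],
            models=tuple(entry["models"]),
            note=entry.get("note"),
        )
        for name, entry in payload.items()
    }


def get_model(model_id: int) -> PublishedModel:
    """Fetch one of the eight fixed TEAC equations by its size."""
    models = _models()
    if model_id not in models:
        raise KeyError(f"unknown model id {model_id}; valid ids are 1-8")
    return models[model_id]


def predict_teac(model_id: int, values: Mapping[str, float]) -> TeacPrediction:
    """Evaluate a fixed equation on normalized descriptor values.

    Inputs outside [0, 1] are accepted but reported; negative predictions
    are returned as-is (the equation is linear) with a warning flag.
    """
    model = get_model(model_id)
    missing = [name for name in model.descriptor_names if name not in values]
    if missing:
        raise KeyError(f"missing descriptor values: {missing}")
    teac = model.intercept
    out_of_range = []
    for name, coef, _ in model.terms:
        v = float(values[name])
        if not 0.0 <= v <= 1.0:
            out_of_range.append(name)
        teac += coef * v
    return TeacPrediction(teac=float(teac), out_of_range_inputs=out_of_range,
                          negative_prediction=teac < 0)


def describe_descriptor(name: str) -> DescriptorInfo:
    """Metadata (definition, family) of a descriptor used by any model."""
    info = _descriptor_info()
    if name not in info:
        raise KeyError(f"unknown descriptor name: {name}")
    return info[name]


def list_descriptors() -> list[str]:
    return sorted(_descriptor_info())


def coefficient_sign_summary(model_id: int) -> list[dict]:
    """Per-term sign of a fixed equation, tagged by its interpretation."""
    model = get_model(model_id)
    summary = []
    for name, coef, _ in model.terms:
        sign = "positive" if coef > 0 else "negative"
        summary.append({
            "descriptor": name,
            "coefficient": coef,
            "sign": sign,
            "interpretation": ("raises predicted TEAC" if coef > 0
                               else "lowers predicted TEAC"),
        })
    return summary
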