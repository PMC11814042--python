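"""YAML/JSON config loaders for thresholds, ecological risk, uncertainty,
exposure and toxicity tables.

All site-specific numbers (background values, base thresholds, sigma/MDL,
exposure factors, toxicity values) live in config files keyed by element
symbol or population name so the computational engine stays data-free.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .hra import ExposureParams, ToxicityValues
from .indices import EcoRiskConfig, ThresholdConstants
from .receptors import UncertaintySpec

__all__ = [
    "load_mapping",
    "dump_mapping",
    "load_thresholds",
    "load_ecorisk",
    "load_uncertainty",
    "load_exposure",
    "load_toxicity",
]


def load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_mapping(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_thresholds(path: str | Path) -> dict[str, ThresholdConstants]:
    """Per-element SW/IW/A/B/C table."""
    raw = load_mapping(path)
    return {
        el: ThresholdConstants(
            sw=float(v["sw"]), iw=float(v["iw"]),
            a=float(v["a"]), b=float(v["b"]), c=float(v["c"]),
        )
        for el, v in raw.items()
    }


def load_ecorisk(path: str | Path) -> dict[str, EcoRiskConfig]:
    """Per-element Tr/GB table."""
    raw = load_mapping(path)
    return {
        el: EcoRiskConfig(tr=float(v["tr"]), gb=float(v["gb"]))
        for el, v in raw.items()
    }


def load_uncertainty(path: str | Path) -> UncertaintySpec:
    """Per-element sigma and MDL for the PMF uncertainty matrix."""
    raw = load_mapping(path)
    return UncertaintySpec(
        sigma={el: float(v["sigma"]) for el, v in raw.items()},
        mdl={el: float(v["mdl"]) for el, v in raw.items()},
    )


def load_exposure(path: str | Path) -> dict[str, ExposureParams]:
    """Per-population exposure parameter sets."""
    raw = load_mapping(path)
    out = {}
    for pop, v in raw.items():
        fields = {f.name for f in dataclasses.fields(ExposureParams)}
        kwargs = {k: (None if val is None else float(val)) for k, val in v.items() if k in fields}
        kwargs["population"] = v.get("population", pop)
        out[pop] = ExposureParams(**kwargs)
    return out


def load_toxicity(path: str | Path) -> dict[str, ToxicityValues]:
    """Per-element toxicity values; absent endpoints stay None."""
    raw = load_mapping(path)
    out = {}
    for el, v in raw.items():
        kwargs = {
            k: (None if val is None else float(val))
            for k, val in v.items()
            if k in {"RfDo", "RfC", "GIABS", "ABSd", "RBA", "CSFo", "IUR"}
        }
        for frac in ("GIABS", "ABSd", "RBA"):
            if kwargs.get(frac) is None:
                kwargs.pop(frac, None)
        out[el] = ToxicityValues(element=el, **kwargs)
    return out
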