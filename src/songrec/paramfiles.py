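"""YAML parameter files for all model families.

Field names mirror the published parameter tables (delays, gains, lobe
durations per model; one section per neuron for the network).  Units are
encoded in the field names where ambiguity is possible: all times are ms,
frequencies Hz, potentials mV.  Files round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass

import yaml

from .lifac import LIFACParams
from .minimal import AutocorrParams, FFIParams, ReboundParams
from .network import (
    AdaptationSpec,
    Filter,
    FilterLobe,
    NetworkParams,
    NeuronSpec,
    Relu,
    Sigmoid,
    SynapseSpec,
)
from .resonate_fire import RFParams

__all__ = ["save_params", "load_params", "save_network_params", "load_network_params"]

_SIMPLE_CLASSES = {
    cls.__name__: cls for cls in (AutocorrParams, ReboundParams, FFIParams, RFParams, LIFACParams)
}

_STAGE_CLASSES = {
    cls.__name__: cls for cls in (Filter, Sigmoid, Relu, AdaptationSpec)
}


def _plain(obj):
    """Dataclass -> dict with nested dataclasses expanded and a type tag."""
    d = {"type": type(obj).__name__}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if is_dataclass(v):
            d[f.name] = _plain(v)
        elif isinstance(v, frozenset):
            d[f.name] = sorted(v)
        else:
            d[f.name] = v
    return d


def save_params(params, path) -> None:
    """Write a simple model's parameter dataclass as YAML."""
    if type(params).__name__ not in _SIMPLE_CLASSES:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(params), fh, sort_keys=False)


def load_params(path):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return _build_simple(d)


def _build_simple(d: dict):
    cls = _SIMPLE_CLASSES[d.pop("type")]
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, dict) and "type" in v:
            kwargs[k] = _build_simple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def _stage_to_dict(stage):
    if isinstance(stage, Filter):
        return {"type": "Filter", "lobes": [_lobe_to_dict(lb) for lb in stage.lobes]}
    d = {"type": type(stage).__name__}
    for f in fields(stage):
        v = getattr(stage, f.name)
        d[f.name] = sorted(v) if isinstance(v, frozenset) else v
    return d


def _lobe_to_dict(lobe: FilterLobe):
    d = {"shape": lobe.shape, "width_or_tau": lobe.width_or_tau, "duration": lobe.duration,
         "gain": lobe.gain, "center": lobe.center, "fixed": sorted(lobe.fixed)}
    return d


def _stage_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    if kind == "Filter":
        return Filter(lobes=tuple(
            FilterLobe(
                shape=lb["shape"],
                width_or_tau=lb["width_or_tau"],
                duration=lb["duration"],
                gain=lb["gain"],
                center=lb.get("center"),
                fixed=frozenset(lb.get("fixed", ())),
            )
            for lb in d["lobes"]
        ))
    if "fixed" in d:
        d["fixed"] = frozenset(d["fixed"])
    return _STAGE_CLASSES[kind](**d)


def save_network_params(net: NetworkParams, path) -> None:
    """One section per neuron: inputs (delay/gain per source) then stages."""
    doc = {
        "output": net.output,
        "sample_rate": net.sample_rate,
        "n_tied": net.n_tied,
        "neurons": {},
    }
    for name, spec in net.neurons.items():
        doc["neurons"][name] = {
            "inputs": [
                {"source": s.source, "delay": s.delay, "gain": s.gain, "fixed": sorted(s.fixed)}
                for s in spec.inputs
            ],
            "stages": [_stage_to_dict(st) for st in spec.stages],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_network_params(path) -> NetworkParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    neurons = {}
    for name, nd in doc["neurons"].items():
        neurons[name] = NeuronSpec(
            name=name,
            inputs=tuple(
                SynapseSpec(
                    source=s["source"], delay=s["delay"], gain=s["gain"],
                    fixed=frozenset(s.get("fixed", ())),
                )
                for s in nd["inputs"]
            ),
            stages=tuple(_stage_from_dict(st) for st in nd["stages"]),
        )
    return NetworkParams(
        neurons=neurons,
        output=doc["output"],
        sample_rate=doc["sample_rate"],
        n_tied=doc.get("n_tied", 0),
    )
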