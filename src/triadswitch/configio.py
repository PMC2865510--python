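"""Structured-text serialization: enhancer models, triad parameters, configs.

Models round-trip through plain dictionaries so they can be stored as YAML
or JSON; reporter tables use the CSV schema of :mod:`triadswitch.fitting`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .enhancers import (
    CONFIG_TEMPLATES,
    EnhancerModel,
    fli1p12_model,
    gata2m3_model,
    scl19_model,
)
from .triad import DEFAULT_HALF_LIVES, TriadParameters

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "PipelineConfig",
]

_BUILDERS = {
    "Scl+19": scl19_model,
    "Gata2-3": gata2m3_model,
    "Fli1+12": fli1p12_model,
}


def model_to_dict(model: EnhancerModel) -> dict:
    return {
        "name": model.name,
        "K": model.K,
        "weights": model.weights(),
        "energies": model.energies() if all(c.weight > 0 for c in model.configurations) else None,
        "omega": dict(model.omega),
        "configurations": [c.id for c in model.configurations],
    }


def model_from_dict(d: dict) -> EnhancerModel:
    name = d["name"]
    if name not in _BUILDERS:
        raise ValueError(f"unknown enhancer {name!r}")
    template_ids = [cid for cid, _s, _t in CONFIG_TEMPLATES[name]]
    weights = d["weights"]
    model = _BUILDERS[name](*(weights[cid] for cid in template_ids), d["K"])
    omega = d.get("omega")
    if omega:
        model = _with_omega(model, omega)
    # Deleted-site models serialize fewer configuration ids.
    kept = set(d.get("configurations", template_ids))
    if kept != set(template_ids):
        from dataclasses import replace

        model = replace(
            model,
            configurations=tuple(
                c for c in model.configurations if c.id in kept
            ),
        )
    return model


def _with_omega(model: EnhancerModel, omega: dict) -> EnhancerModel:
    from dataclasses import replace

    return replace(model, omega=dict(omega))


def params_to_dict(params: TriadParameters) -> dict:
    return {
        "models": {g: model_to_dict(m) for g, m in params.models.items()},
        "gamma": list(params.gamma),
        "wt_rates": list(params.wt_rates),
        "production_scale": list(params.production_scale),
        "clamp_xs": params.clamp_xs,
        "hours_per_tau": params.hours_per_tau,
    }


def params_from_dict(d: dict) -> TriadParameters:
    return TriadParameters(
        models={g: model_from_dict(m) for g, m in d["models"].items()},
        gamma=tuple(d["gamma"]),
        wt_rates=tuple(d["wt_rates"]),
        production_scale=tuple(d.get("production_scale", (1.0, 1.0, 1.0))),
        clamp_xs=d.get("clamp_xs"),
        hours_per_tau=d.get("hours_per_tau", TriadParameters.hours_per_tau),
    )


def save_params(params: TriadParameters, path) -> None:
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_params(path) -> TriadParameters:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_dict(data)


@dataclass
class PipelineConfig:
    """Fully serializable run configuration for the CLI pipeline."""

    library_csv: Optional[str] = None  # None -> packaged reference library
    K: dict = field(default_factory=lambda: {
        "Scl+19": "auto", "Gata2-3": "auto", "Fli1+12": "auto",
    })
    half_lives: tuple = DEFAULT_HALF_LIVES
    time_convention: str = "mean_lifetime"
    fold_notch: float = 3.5
    fold_bmp4: float = 4.0
    seed: int = 0
    sigma: float = 0.0
    output_dir: str = "triadswitch_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "half_lives" in data:
            data["half_lives"] = tuple(data["half_lives"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["half_lives"] = list(self.half_lives)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
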