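"""Pipeline configuration loaded from YAML.

Strict by construction: unknown keys anywhere in the document are
rejected by name, seeds are mandatory for stochastic stages, and the
structurally non-identifiable parameters (kA, kex) cannot be unfixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


def _from_mapping(cls, doc: dict, context: str):
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"{context}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in doc:
            continue
        sub = _SECTION_TYPES.get((cls, f.name))
        value = doc[f.name]
        kwargs[f.name] = (_from_mapping(sub, value, f"{context}.{f.name}")
                          if sub else value)
    return cls(**kwargs)


@dataclass(frozen=True)
class FitConfig:
    variants: tuple[str, ...] = ("all", "none")
    n_starts: int = 200
    method: str = "trf"


@dataclass(frozen=True)
class GridSearchConfig:
    kmax: float = 20.0
    step: float = 0.1


@dataclass(frozen=True)
class MCMCConfig:
    n_steps: int = 5000
    n_aux_chains: int = 20
    posterior_draws: int = 20


@dataclass(frozen=True)
class SynthConfig:
    truth: str = "all"          #: reference parameter set, or path to a JSON file
    noise: str = "default"      #: "default" or "none"


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "ctldyn_run"
    seed: int | None = None
    v0: float = 100.0
    synth: SynthConfig = field(default_factory=SynthConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    gridsearch: GridSearchConfig = field(default_factory=GridSearchConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")
        if self.synth.noise not in ("default", "none"):
            raise ValueError(f"unknown noise preset {self.synth.noise!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        forbidden = {"kA", "kex"} & set(doc or ())
        if forbidden:
            raise ValueError(
                f"parameters {sorted(forbidden)} are fixed to 1 and cannot "
                "be configured")
        return _from_mapping(cls, doc, "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc or {})


_SECTION_TYPES = {
    (PipelineConfig, "synth"): SynthConfig,
    (PipelineConfig, "fit"): FitConfig,
    (PipelineConfig, "gridsearch"): GridSearchConfig,
    (PipelineConfig, "mcmc"): MCMCConfig,
}
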