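"""Validated run configuration for the command-line pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "NetworkFlags", "EnsembleConfig", "GsaConfig", "load_config"]

#: model inputs flagged for the sensitivity runs: the four sensitive
#: receptor/kinase/phosphatase amounts plus the transcription, transport,
#: heterodimerization and s80-branch rate constants
DEFAULT_GSA_INPUTS = [
    "HER4", "ERBB", "JAK", "SHP",
    "n_transc", "V_transc", "K_transc",
    "kR15", "kR45", "kfR36", "kR37", "kfR41",
]

OUTPUTS = ["integrated_casein", "switch_ratio", "delay"]


class NetworkFlags(BaseModel):
    heterodimerization_on: bool = True
    jak_independent_on: bool = True


class EnsembleConfig(BaseModel):
    n_members: int = Field(50, ge=2)
    seed: int = 0
    rate_fold: float = Field(2.0, gt=1.0)
    init_fold: float = Field(1.5, gt=1.0)
    inputs: list[str] | None = None  # defaults to DEFAULT_GSA_INPUTS


class GsaConfig(BaseModel):
    N: int = Field(128, ge=2)
    skip: int | None = None
    outputs: list[str] = Field(default_factory=lambda: list(OUTPUTS))
    dose: float = Field(20.0, ge=0.0)
    inputs: list[str] = Field(default_factory=lambda: list(DEFAULT_GSA_INPUTS))
    rate_fold: float = Field(10.0, gt=1.0)
    init_fold: float = Field(2.0, gt=1.0)
    #: the peak-to-peak delay readout is only defined where both profiles
    #: peak inside the simulated window, so its box is narrower
    delay_rate_fold: float = Field(2.0, gt=1.0)

    @field_validator("outputs")
    @classmethod
    def _known_outputs(cls, v: list[str]) -> list[str]:
        bad = set(v) - set(OUTPUTS)
        if bad:
            raise ValueError(f"unknown outputs: {sorted(bad)}")
        return v


class RunConfig(BaseModel):
    flags: NetworkFlags = Field(default_factory=NetworkFlags)
    doses: list[float] = Field(default_factory=lambda: [0.0, 10.0, 20.0, 50.0])
    t_end: float = Field(48.0, gt=0)
    output_step: float = Field(0.01, gt=0)
    ensemble: EnsembleConfig = Field(default_factory=EnsembleConfig)
    gsa: GsaConfig = Field(default_factory=GsaConfig)
    sbml_path: str | None = None
    out_dir: str = "out"
    log_level: str = "INFO"

    @field_validator("doses")
    @classmethod
    def _doses_ok(cls, v: list[float]) -> list[float]:
        if any(d < 0 for d in v):
            raise ValueError("doses must be non-negative")
        return sorted(v)

    @field_validator("sbml_path")
    @classmethod
    def _file_exists(cls, v: str | None) -> str | None:
        if v is not None and not Path(v).exists():
            raise ValueError(f"file not found: {v}")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if ``path`` is None)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
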