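"""Run configuration: schema-validated YAML with packaged defaults.

Unknown keys are rejected so typos surface immediately; an empty file (or
no file) yields the packaged defaults — Table-style scale factors, the
default segment fixtures, the standard factorial levels, a 30 MPa disc
failure stress and a +50 % ligament strain increase.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScaleFactorConfig(_Strict):
    g_s: float = 0.723
    lambda_x: float = 0.723
    lambda_z: float = 0.793
    alpha_bone: float = 0.805
    alpha_disc: float = 0.782
    alpha_ligament: float = 0.893


class FailureConfig(_Strict):
    disc_failure_stress_mpa: float = 30.0
    strain_increase_pct: float = 50.0

    @field_validator("disc_failure_stress_mpa")
    @classmethod
    def _positive_stress(cls, v: float) -> float:
        if v <= 0.0:
            raise ValueError("disc_failure_stress_mpa must be > 0")
        return v

    @field_validator("strain_increase_pct")
    @classmethod
    def _nonneg_strain(cls, v: float) -> float:
        if v < 0.0:
            raise ValueError("strain_increase_pct must be >= 0")
        return v


class SolverConfig(_Strict):
    step_mm: float = 0.01
    step_deg: float = 0.05

    @field_validator("step_mm", "step_deg")
    @classmethod
    def _positive_step(cls, v: float) -> float:
        if v <= 0.0:
            raise ValueError("solver steps must be > 0")
        return v


class DoceConfig(_Strict):
    strain_levels: list[float] = Field(default_factory=lambda: [0.0, 25.0, 50.0, 75.0])
    stress_levels: list[float] = Field(
        default_factory=lambda: [15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0]
    )
    segments: list[str] = Field(default_factory=lambda: ["C0-C2", "C4-C5", "C6-C7"])
    targets: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "C0-C2": [14.4, 2.185],
            "C4-C5": [5.0, 1.277],
            "C6-C7": [6.4, 1.623],
        }
    )


class RunConfig(_Strict):
    scale_factors: ScaleFactorConfig = Field(default_factory=ScaleFactorConfig)
    geometry_overrides: dict[str, Any] = Field(default_factory=dict)
    failure: FailureConfig = Field(default_factory=FailureConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    doce: DoceConfig = Field(default_factory=DoceConfig)
    output_dir: str = "results"
    seed: int = 0


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields all defaults.  Schema violations raise
    :class:`ConfigurationError` naming the offending key.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text(encoding="utf-8"))
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"config root must be a mapping, got {type(loaded)}")
            raw = loaded
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(part) for part in first["loc"]) or "<root>"
        raise ConfigurationError(f"invalid configuration at {loc!r}: {first['msg']}") from exc


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True), encoding="utf-8"
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the fully-resolved configuration."""
    blob = yaml.safe_dump(cfg.model_dump(), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]
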