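"""Access to the packaged material and ligament data tables.

Loads the YAML files shipped under ``cspine10/data`` and exposes typed
views: the default scale-factor set, bone power-law parameters, the annulus
Hill-foam constants, the adult disc failure table and the ligament failure
library keyed by (spinal level, ligament type).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

from .constitutive import (
    HillFoamParams,
    LigamentControlPoints,
    LigamentSpec,
    PowerLawParams,
)
from .errors import ConfigurationError
from .scaling import DiscFailureSpec, ScaleFactorSet

__all__ = [
    "load_data_file",
    "default_scale_factors",
    "bone_power_law",
    "annulus_hill_foam",
    "disc_failure_specs",
    "control_points",
    "ligament_library",
    "make_ligament_spec",
]


@lru_cache(maxsize=None)
def load_data_file(name: str) -> dict[str, Any]:
    """Parse a packaged YAML data file by name (e.g. ``material_laws.yaml``)."""
    ref = resources.files("cspine10.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_scale_factors() -> ScaleFactorSet:
    """The packaged child scale factors."""
    return ScaleFactorSet(**load_data_file("material_laws.yaml")["scale_factors"])


def bone_power_law(tissue: str) -> PowerLawParams:
    """Power-law plasticity constants for ``cortical_bone``, ``cancellous_bone``
    or ``endplate``."""
    table = load_data_file("material_laws.yaml")["power_law_plasticity"]
    try:
        return PowerLawParams(**table[tissue])
    except KeyError as exc:
        raise ConfigurationError(f"unknown power-law tissue {tissue!r}") from exc


def annulus_hill_foam() -> HillFoamParams:
    """Hill-foam constants of the annulus ground substance."""
    raw = load_data_file("material_laws.yaml")["hill_foam"]["annulus_ground_substance"]
    return HillFoamParams(n=raw["n"], c=tuple(raw["c"]), b=tuple(raw["b"]))


def disc_failure_specs(level: str) -> list[DiscFailureSpec]:
    """Adult disc failure forces paired with the child AF area for a level."""
    table = load_data_file("material_laws.yaml")["disc_failure"]
    try:
        entry = table[level]
    except KeyError as exc:
        raise ConfigurationError(f"no disc failure data for level {level!r}") from exc
    return [
        DiscFailureSpec(
            adult_failure_force=row["force"],
            af_cross_section_child=entry["af_cross_section_child"],
            source_label=row["source"],
        )
        for row in entry["adult_forces"]
    ]


@lru_cache(maxsize=None)
def control_points(family: str) -> LigamentControlPoints:
    """Normalized control points for a ligament family (ALL/PLL/CL/LF/ISL)."""
    table = load_data_file("ligaments.yaml")["control_points"]
    try:
        return LigamentControlPoints(**table[family])
    except KeyError as exc:
        raise ConfigurationError(f"no control points for ligament family {family!r}") from exc


@lru_cache(maxsize=None)
def ligament_library() -> dict[tuple[str, str], dict[str, Any]]:
    """Failure library keyed by ``(level, ligament_type)``.

    Subaxial entries carry ``eps_max``/``f_max``/``adult_length`` and use
    their own family's control points; upper-cervical entries carry
    ``f_max``/``d_max``/``eps_max`` with a surrogate ``law`` family.
    """
    data = load_data_file("ligaments.yaml")
    lib: dict[tuple[str, str], dict[str, Any]] = {}
    for level, entries in data["subaxial"].items():
        for lig_type, row in entries.items():
            lib[(level, lig_type)] = {
                "f_max": row["f_max"],
                "eps_max": row["eps_max"],
                "adult_length": row["adult_length"],
                "law": lig_type,
            }
    for row in data["upper_cervical"]:
        lib[(row["level"], row["type"])] = {
            "f_max": row["f_max"],
            "eps_max": row["eps_max"],
            "d_max": row["d_max"],
            "adult_length": row["d_max"] / row["eps_max"],
            "law": row["law"],
        }
    return lib


def make_ligament_spec(
    level: str, lig_type: str, length: float, n_elements: int = 1
) -> LigamentSpec:
    """Build a :class:`LigamentSpec` from the library for a child model length."""
    try:
        row = ligament_library()[(level, lig_type)]
    except KeyError as exc:
        raise ConfigurationError(
            f"ligament library has no entry for level {level!r}, type {lig_type!r}"
        ) from exc
    return LigamentSpec(
        ligament_type=lig_type,
        spinal_level=level,
        f_max=row["f_max"],
        length=length,
        control_points=control_points(row["law"]),
        eps_max=row["eps_max"],
        adult_length=row.get("adult_length"),
        n_elements=n_elements,
    )
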