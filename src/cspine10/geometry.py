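"""Parametric sagittal-plane segment geometry and assembly construction.

Generates the synthetic two-vertebra (or occiput-to-C2) fixtures the solver
operates on: ligament attachment points and model lengths, disc layer areas
and heights, facet gap placement.  The coordinate convention is x anterior,
z superior.  Geometry is deterministic; an optional seeded jitter perturbs
attachment x-coordinates for robustness studies.  Ligament model lengths
are always the Euclidean attachment distance, which is the same length the
constitutive curve construction uses — a single source of truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import library
from .constitutive import (
    DiscElementLaw,
    FiberLaw,
    build_child_ligament_curve,
    scale_failure_strain,
)
from .errors import ConfigurationError, DomainError
from .scaling import ScaleFactorSet
from .solver import Element, SegmentAssembly

__all__ = [
    "DiscLayer",
    "DiscGeometry",
    "FacetGeometry",
    "LigamentPlacement",
    "SegmentGeometry",
    "KNOWN_LEVELS",
    "build_segment_geometry",
    "assemble_segment",
]

KNOWN_LEVELS = ("C0-C2", "C4-C5", "C6-C7")


@dataclass(frozen=True)
class DiscLayer:
    """One radial annulus layer: area share, sagittal offset, fiber law."""

    area: float
    x: float
    fiber_law: FiberLaw


@dataclass(frozen=True)
class DiscGeometry:
    area: float
    height: float
    fiber_fraction: float
    layers: tuple[DiscLayer, ...]

    def __post_init__(self) -> None:
        if self.area <= 0.0 or self.height <= 0.0:
            raise DomainError("disc area and height must be > 0")
        total = sum(layer.area for layer in self.layers)
        if not np.isclose(total, self.area, rtol=1e-6):
            raise DomainError(
                f"disc layer areas sum to {total:.4f} mm^2, expected {self.area:.4f}"
            )


@dataclass(frozen=True)
class FacetGeometry:
    x: float
    gap: float
    stiffness: float


@dataclass(frozen=True)
class LigamentPlacement:
    ligament_type: str
    library_level: str
    superior: tuple[float, float]
    inferior: tuple[float, float]
    n_elements: int

    @property
    def length(self) -> float:
        dx = self.superior[0] - self.inferior[0]
        dz = self.superior[1] - self.inferior[1]
        return float(np.hypot(dx, dz))


@dataclass(frozen=True)
class SegmentGeometry:
    """Sagittal-plane fixture for one segment."""

    level: str
    ligaments: tuple[LigamentPlacement, ...]
    disc: DiscGeometry | None
    facet: FacetGeometry
    driven_boundary: str
    rotation_center: tuple[float, float]
    max_displacement: float
    max_angle: float

    def ligament_types(self) -> set[str]:
        return {lig.ligament_type for lig in self.ligaments}


def _x_of(geom_ligs: dict[str, float], name: str) -> float:
    try:
        return geom_ligs[name]
    except KeyError as exc:
        raise ConfigurationError(f"segment is missing ligament {name!r}") from exc


def _validate_sagittal_ordering(level: str, geom: SegmentGeometry) -> None:
    # subaxial anteroposterior ordering: ALL anterior of the disc centroid,
    # PLL posterior, CL at the facet, LF/ISL posterior of PLL
    if geom.disc is None:
        return
    xs = {lig.ligament_type: lig.superior[0] for lig in geom.ligaments}
    disc_x = 0.0
    if not _x_of(xs, "ALL") > disc_x:
        raise DomainError(f"{level}: ALL must attach anterior of the disc centroid")
    if not _x_of(xs, "PLL") < disc_x:
        raise DomainError(f"{level}: PLL must attach posterior of the disc centroid")
    for name in ("LF", "ISL"):
        if not _x_of(xs, name) < xs["PLL"]:
            raise DomainError(f"{level}: {name} must attach posterior of PLL")
    if not np.isclose(xs["CL"], geom.facet.x):
        raise DomainError(f"{level}: CL must attach at the facet location")


def _geometry_from_mapping(level: str, raw: dict[str, Any]) -> SegmentGeometry:
    ligaments = []
    for entry in raw["ligaments"]:
        x = float(entry["x"])
        length = float(entry["length_mm"])
        if level == "C0-C2":
            mid = float(raw["rotation_center"][1])
        else:
            mid = float(raw["disc"]["height_mm"]) / 2.0
        ligaments.append(
            LigamentPlacement(
                ligament_type=entry["type"],
                library_level=entry["library_level"],
                inferior=(x, mid - length / 2.0),
                superior=(x, mid + length / 2.0),
                n_elements=int(entry.get("n_elements", 1)),
            )
        )
    disc = None
    if raw.get("disc"):
        d = raw["disc"]
        layers = tuple(
            DiscLayer(
                area=float(layer["area_mm2"]),
                x=float(layer["x"]),
                fiber_law=FiberLaw(**layer["fiber_law"]),
            )
            for layer in d["layers"]
        )
        disc = DiscGeometry(
            area=float(d["area_mm2"]),
            height=float(d["height_mm"]),
            fiber_fraction=float(d["fiber_fraction"]),
            layers=layers,
        )
    f = raw["facet"]
    geom = SegmentGeometry(
        level=level,
        ligaments=tuple(ligaments),
        disc=disc,
        facet=FacetGeometry(
            x=float(f["x"]), gap=float(f["gap_mm"]), stiffness=float(f["stiffness_n_per_mm"])
        ),
        driven_boundary=str(raw["driven_boundary"]),
        rotation_center=(float(raw["rotation_center"][0]), float(raw["rotation_center"][1])),
        max_displacement=float(raw["max_displacement_mm"]),
        max_angle=float(raw["max_angle_deg"]),
    )
    _validate_sagittal_ordering(level, geom)
    return geom


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def build_segment_geometry(
    level: str,
    params: dict[str, Any] | None = None,
    seed: int | None = None,
    jitter_mm: float = 0.0,
) -> SegmentGeometry:
    """Default fixture for a level, with optional overrides and seeded jitter.

    ``params`` deep-updates the packaged defaults (same schema as
    ``data/segments.yaml``).  When ``jitter_mm`` is positive, attachment
    x-coordinates receive uniform perturbations in ``+-jitter_mm`` drawn
    from ``numpy.random.default_rng(seed)``; the default is jitter-free and
    fully deterministic.
    """
    if level not in KNOWN_LEVELS:
        raise DomainError(f"unknown segment level {level!r}; known: {KNOWN_LEVELS}")
    raw = library.load_data_file("segments.yaml")[level]
    if params:
        raw = _deep_update(raw, params)
    else:
        raw = copy.deepcopy(raw)
    if jitter_mm > 0.0:
        rng = np.random.default_rng(seed)
        for entry in raw["ligaments"]:
            entry["x"] = float(entry["x"]) + float(rng.uniform(-jitter_mm, jitter_mm))
            if entry["type"] == "CL":
                raw["facet"]["x"] = entry["x"]  # facet tracks the capsule
    return _geometry_from_mapping(level, raw)


def assemble_segment(
    geom: SegmentGeometry,
    disc_failure_stress: float | None = 30.0,
    strain_increase_pct: float = 0.0,
    sf: ScaleFactorSet | None = None,
) -> SegmentAssembly:
    """Build a solver assembly with child curves and failure thresholds.

    Every ligament placement is expanded into ``n_elements`` parallel bars
    carrying the per-bar child curve (force split over the bars, deflection
    axis stretched by ``strain_increase_pct``).  Disc layers become axial
    sub-elements with the composite stress law and the given tensile
    failure stress; the facet becomes a compression-only gap element.
    """
    if sf is None:
        sf = library.default_scale_factors()
    elements: list[Element] = []
    for lig in geom.ligaments:
        spec = library.make_ligament_spec(
            lig.library_level, lig.ligament_type, length=lig.length, n_elements=lig.n_elements
        )
        curve = build_child_ligament_curve(spec, sf)
        curve = scale_failure_strain(curve, strain_increase_pct)
        for j in range(lig.n_elements):
            suffix = f"#{j + 1}" if lig.n_elements > 1 else ""
            elements.append(
                Element(
                    name=f"{lig.ligament_type}@{lig.library_level}{suffix}",
                    kind="ligament_bar",
                    inferior=lig.inferior,
                    superior=lig.superior,
                    curve=curve,
                )
            )
    if geom.disc is not None:
        if disc_failure_stress is None or disc_failure_stress <= 0.0:
            raise DomainError("a disc-bearing segment needs a positive disc failure stress")
        half = geom.disc.height / 2.0
        mid = geom.rotation_center[1]
        for i, layer in enumerate(geom.disc.layers, start=1):
            law = DiscElementLaw(
                area=layer.area,
                failure_stress=disc_failure_stress,
                hill=library.annulus_hill_foam(),
                fiber_fraction=geom.disc.fiber_fraction,
                fiber_law=layer.fiber_law,
            )
            elements.append(
                Element(
                    name=f"disc_layer_{i}",
                    kind="disc",
                    inferior=(layer.x, mid - half),
                    superior=(layer.x, mid + half),
                    disc_law=law,
                    disc_height=geom.disc.height,
                )
            )
    span = geom.disc.height if geom.disc is not None else 4.0
    mid = geom.rotation_center[1]
    elements.append(
        Element(
            name="facet_gap",
            kind="facet_gap",
            inferior=(geom.facet.x, mid - span / 2.0),
            superior=(geom.facet.x, mid + span / 2.0),
            gap=geom.facet.gap,
            gap_stiffness=geom.facet.stiffness,
        )
    )
    return SegmentAssembly(
        name=geom.level,
        elements=elements,
        driven_boundary=geom.driven_boundary,  # type: ignore[arg-type]
        rotation_center=geom.rotation_center,
    )
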