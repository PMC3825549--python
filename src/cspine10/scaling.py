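"""Adult-to-child scaling of failure forces, stresses and bending corridors.

The 10-year-old model inherits adult material data through dimensionless
scale factors: a geometric scale ``G_S`` (child/adult length ratio), its
square for cross-sectional areas, and material-property scales for bone,
disc and ligament tissue.  Two further ratios map adult flexion/extension
moment-angle corridors to the child: the bending-moment ratio is the cube
of the x-direction (anteroposterior) scale, and the angle ratio is the
z-direction scale divided by the x-direction scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ScaleFactorSet",
    "DiscFailureSpec",
    "scaled_disc_failure_force",
    "disc_failure_stress",
    "moment_scale_ratio",
    "angle_scale_ratio",
    "scale_corridor",
]


@dataclass(frozen=True)
class ScaleFactorSet:
    """Dimensionless scale factors for the 10-year-old child configuration.

    Defaults are the literature values used to build the child model:
    geometric scale 0.723, x/z direction scales 0.723/0.793, and material
    scales 0.805 (bone), 0.782 (disc), 0.893 (ligament).  The
    cross-sectional area scale is always ``G_S**2`` (a derived property,
    never stored), which is what makes the scaled disc failure forces and
    stresses mutually consistent.
    """

    g_s: float = 0.723
    lambda_x: float = 0.723
    lambda_z: float = 0.793
    alpha_bone: float = 0.805
    alpha_disc: float = 0.782
    alpha_ligament: float = 0.893

    def __post_init__(self) -> None:
        for name in (
            "g_s",
            "lambda_x",
            "lambda_z",
            "alpha_bone",
            "alpha_disc",
            "alpha_ligament",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise DomainError(f"scale factor {name} must be finite and > 0, got {value!r}")
            if value > 1.0:
                raise DomainError(
                    f"scale factor {name} = {value!r} exceeds 1; child factors are <= 1"
                )

    @property
    def area_scale(self) -> float:
        """Cross-sectional area scale factor, ``G_S**2``."""
        return self.g_s * self.g_s

    @classmethod
    def identity(cls) -> "ScaleFactorSet":
        """All-unity factors (adult = child); useful for sanity checks."""
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class DiscFailureSpec:
    """Adult disc failure force paired with the child annulus cross-section.

    ``adult_failure_force`` is the tensile failure force of the adult
    intervertebral disc (N); ``af_cross_section_child`` the child annulus
    fibrosus cross-sectional area (mm^2); ``source_label`` is free text
    naming the literature source of the adult force.
    """

    adult_failure_force: float
    af_cross_section_child: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.adult_failure_force) or self.adult_failure_force <= 0.0:
            raise DomainError(
                f"adult failure force must be > 0 N, got {self.adult_failure_force!r}"
            )
        if not np.isfinite(self.af_cross_section_child) or self.af_cross_section_child <= 0.0:
            raise DomainError(
                f"child AF cross-section must be > 0 mm^2, got {self.af_cross_section_child!r}"
            )


def scaled_disc_failure_force(f_adult: float, sf: ScaleFactorSet) -> float:
    """Child disc failure tensile force (N) from the adult force.

    ``F_child = F_adult * alpha_disc * G_S**2``: the material scale reduces
    the failure stress, the squared geometric scale reduces the load-bearing
    cross-section.
    """
    if not np.isfinite(f_adult) or f_adult <= 0.0:
        raise DomainError(f"adult failure force must be > 0 N, got {f_adult!r}")
    return f_adult * sf.alpha_disc * sf.area_scale


def disc_failure_stress(spec: DiscFailureSpec, sf: ScaleFactorSet) -> float:
    """Child disc failure stress (MPa): scaled failure force over child AF area."""
    return scaled_disc_failure_force(spec.adult_failure_force, sf) / spec.af_cross_section_child


def moment_scale_ratio(sf: ScaleFactorSet) -> float:
    """Adult-to-child bending moment ratio, ``lambda_x**3``."""
    return sf.lambda_x**3


def angle_scale_ratio(sf: ScaleFactorSet) -> float:
    """Adult-to-child bending angle ratio, ``lambda_z / lambda_x``."""
    return sf.lambda_z / sf.lambda_x


def scale_corridor(
    adult_curve: Sequence[tuple[float, float]] | np.ndarray,
    sf: ScaleFactorSet,
) -> np.ndarray:
    """Scale an adult moment-angle corridor to the child.

    ``adult_curve`` is a sequence of ``(angle_deg, moment_Nm)`` pairs with
    finite, ordered angles.  Each point maps to
    ``(angle * angle_ratio, moment * moment_ratio)``; ordering is preserved
    because both ratios are positive.  Returns an ``(n, 2)`` array.
    """
    curve = np.asarray(adult_curve, dtype=float)
    if curve.size == 0:
        raise DomainError("corridor curve is empty")
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise DomainError(f"corridor curve must be (n, 2) angle/moment pairs, got {curve.shape}")
    if not np.all(np.isfinite(curve)):
        raise DomainError("corridor curve contains non-finite values")
    angles = curve[:, 0]
    if not (np.all(np.diff(angles) >= 0.0) or np.all(np.diff(angles) <= 0.0)):
        raise DomainError("corridor angles must be monotonically ordered")
    out = curve.copy()
    out[:, 0] *= angle_scale_ratio(sf)
    out[:, 1] *= moment_scale_ratio(sf)
    return out
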