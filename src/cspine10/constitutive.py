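"""Constitutive laws: child ligament curves, bone plasticity, annulus foam.

Ligaments are tension-only bars with a sigmoidal force-deflection curve
defined by three control points (toe point A, end of the linear region B,
tolerance/failure point C).  The child curve is obtained from adult failure
data by scaling the force axis with the ligament material scale times the
squared geometric scale, and mapping normalized strain ratios onto the
child model length:

    d_i = eps_max * (eps_i / eps_max) * l           (deflection, mm)
    f_i = F_max * (F_i / F_max) * alpha * G_S^2 / N (force per bar, N)

with the third point's normalized ratios equal to one.  The curve shape
(the normalized ratios) is retained for the child; only the failure force
and deflection shrink.

Bone (cortical, cancellous, endplate) follows isotropic power-law
plasticity ``sigma = E*eps`` below yield and ``sigma = k*eps**N`` above,
with the yield strain fixed by continuity.  The annulus ground substance is
a compressible Hill foam; its uniaxial nominal stress is obtained by
solving the zero-lateral-stress condition for the free lateral stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "LigamentControlPoints",
    "LigamentSpec",
    "LigamentCurve",
    "PowerLawParams",
    "HillFoamParams",
    "build_child_ligament_curve",
    "failure_strain_from_deflection",
    "scale_failure_strain",
    "ligament_force",
    "power_law_stress",
    "power_law_yield_strain",
    "hill_foam_strain_energy",
    "hill_foam_lateral_stretch",
    "hill_foam_uniaxial_stress",
    "FiberLaw",
    "DiscElementLaw",
    "build_disc_element",
]

LigamentType = Literal[
    "ALL", "PLL", "CL", "LF", "ISL", "JC", "AA-OM", "PA-OM", "TM", "Apical", "Alar", "CLV"
]


@dataclass(frozen=True)
class LigamentControlPoints:
    """Normalized control-point ratios of the sigmoidal ligament curve.

    ``eps1_ratio``/``force1_ratio`` locate the toe point A and
    ``eps2_ratio``/``force2_ratio`` the end of the linear region B, both as
    fractions of the failure strain/force (point C maps to (1, 1)).
    """

    eps1_ratio: float
    force1_ratio: float
    eps2_ratio: float
    force2_ratio: float

    def __post_init__(self) -> None:
        vals = (self.eps1_ratio, self.force1_ratio, self.eps2_ratio, self.force2_ratio)
        if not all(np.isfinite(v) and 0.0 < v < 1.0 for v in vals):
            raise DomainError(f"control-point ratios must lie in (0, 1), got {vals}")
        if not self.eps1_ratio < self.eps2_ratio:
            raise DomainError("strain ratio at A must be below the ratio at B")
        if not self.force1_ratio < self.force2_ratio:
            raise DomainError("force ratio at A must be below the ratio at B")


@dataclass(frozen=True)
class LigamentSpec:
    """Adult failure data plus child model geometry for one ligament.

    Exactly one of ``eps_max`` (adult failure strain) or ``d_max`` (adult
    failure deflection, mm) must be supplied; a deflection requires
    ``adult_length`` (mm) so the strain can be derived.  ``length`` is the
    ligament length in the child model (mm) and ``n_elements`` the number of
    parallel bar elements sharing the load.
    """

    ligament_type: str
    spinal_level: str
    f_max: float
    length: float
    control_points: LigamentControlPoints
    eps_max: float | None = None
    d_max: float | None = None
    adult_length: float | None = None
    n_elements: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.f_max) or self.f_max <= 0.0:
            raise DomainError(f"adult failure force must be > 0 N, got {self.f_max!r}")
        if not np.isfinite(self.length) or self.length <= 0.0:
            raise DomainError(f"child model length must be > 0 mm, got {self.length!r}")
        if self.n_elements < 1:
            raise DomainError(f"n_elements must be >= 1, got {self.n_elements!r}")
        if (self.eps_max is None) == (self.d_max is None):
            raise DomainError("exactly one of eps_max / d_max must be given")
        if self.d_max is not None and self.adult_length is None:
            raise DomainError("d_max requires adult_length to derive the failure strain")

    @property
    def failure_strain(self) -> float:
        """Adult failure strain, given directly or derived from d_max."""
        if self.eps_max is not None:
            return self.eps_max
        return failure_strain_from_deflection(self.d_max, self.adult_length)

    @property
    def adult_failure_deflection(self) -> float | None:
        """Adult failure deflection (mm) when the adult length is known."""
        if self.d_max is not None:
            return self.d_max
        if self.adult_length is not None:
            return self.eps_max * self.adult_length
        return None


@dataclass(frozen=True)
class LigamentCurve:
    """Piecewise-linear force-deflection curve through origin, A, B and C.

    ``points`` is an ``(m, 2)`` array of (deflection mm, force N) with
    strictly increasing deflections and non-decreasing forces starting at
    (0, 0); ``failure_deflection`` is the deflection of point C, beyond
    which the bar is deleted.
    """

    points: np.ndarray
    failure_deflection: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise DomainError("curve needs at least two (deflection, force) points")
        if not np.all(np.isfinite(pts)):
            raise DomainError("curve contains non-finite values")
        if abs(pts[0, 0]) > 0.0 or abs(pts[0, 1]) > 0.0:
            raise DomainError("curve must start at the origin")
        if not np.all(np.diff(pts[:, 0]) > 0.0):
            raise DomainError("curve deflections must be strictly increasing")
        if np.any(np.diff(pts[:, 1]) < 0.0):
            raise DomainError("curve forces must be non-decreasing")
        if not np.isclose(self.failure_deflection, pts[-1, 0]):
            raise DomainError("failure deflection must equal the last curve point")
        object.__setattr__(self, "points", pts)

    @property
    def failure_force(self) -> float:
        return float(self.points[-1, 1])

    def normalized(self) -> np.ndarray:
        """Points normalized by the failure deflection and force (shape check)."""
        out = self.points.copy()
        out[:, 0] /= self.failure_deflection
        out[:, 1] /= self.failure_force
        return out


def failure_strain_from_deflection(d_max: float, length: float) -> float:
    """Failure strain implied by a failure deflection over a reference length."""
    if not np.isfinite(length) or length <= 0.0:
        raise DomainError(f"reference length must be > 0 mm, got {length!r}")
    if not np.isfinite(d_max) or d_max <= 0.0:
        raise DomainError(f"failure deflection must be > 0 mm, got {d_max!r}")
    return d_max / length


def build_child_ligament_curve(spec: LigamentSpec, sf) -> LigamentCurve:
    """Child per-element force-deflection curve from adult failure data.

    Applies the ligament material scale and squared geometric scale to the
    force axis, splits the force over ``n_elements`` parallel bars, and maps
    the normalized control strains onto ``eps_max * length``.
    """
    cp = spec.control_points
    eps_max = spec.failure_strain
    f_fail = spec.f_max * sf.alpha_ligament * sf.area_scale / spec.n_elements
    d_fail = eps_max * spec.length
    eps_ratios = (cp.eps1_ratio, cp.eps2_ratio, 1.0)
    force_ratios = (cp.force1_ratio, cp.force2_ratio, 1.0)
    pts = [(0.0, 0.0)]
    pts.extend((d_fail * er, f_fail * fr) for er, fr in zip(eps_ratios, force_ratios))
    return LigamentCurve(points=np.array(pts), failure_deflection=d_fail)


def scale_failure_strain(curve: LigamentCurve, pct_increase: float) -> LigamentCurve:
    """Stretch the deflection axis by ``1 + pct/100`` with forces unchanged.

    This is the ligament calibration move: raising the assumed failure
    strain stretches the whole curve horizontally, which retains its
    normalized shape and failure force while increasing failure deflection.
    """
    if not np.isfinite(pct_increase) or pct_increase < 0.0:
        raise DomainError(f"strain increase must be >= 0 %, got {pct_increase!r}")
    factor = 1.0 + pct_increase / 100.0
    pts = curve.points.copy()
    pts[:, 0] *= factor
    return LigamentCurve(points=pts, failure_deflection=curve.failure_deflection * factor)


def ligament_force(curve: LigamentCurve, deflection: float, failed: bool = False) -> float:
    """Tension-only bar force at a deflection; zero once the bar has failed.

    Piecewise-linear interpolation through the curve points; zero for
    non-positive deflection (slack bar).  At or beyond the failure
    deflection the un-failed bar carries the tolerance-point force — the
    caller deletes the element after sampling it, so the failure step still
    records the peak bar force.
    """
    if failed or deflection <= 0.0:
        return 0.0
    return float(np.interp(deflection, curve.points[:, 0], curve.points[:, 1]))


# --- bone: isotropic power-law plasticity -------------------------------------


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law plasticity constants: modulus E (MPa), strength coefficient
    k (MPa), hardening exponent N in (0, 1), Poisson ratio (carried for
    completeness; the uniaxial law does not use it)."""

    e_modulus: float
    k: float
    n_hard: float
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.e_modulus <= 0.0 or self.k <= 0.0:
            raise DomainError("E and k must be > 0 MPa")
        if not 0.0 < self.n_hard < 1.0:
            raise DomainError(f"hardening exponent must lie in (0, 1), got {self.n_hard!r}")


def power_law_yield_strain(p: PowerLawParams) -> float:
    """Yield strain ``(k/E)**(1/(1-N))`` where the two branches meet."""
    return (p.k / p.e_modulus) ** (1.0 / (1.0 - p.n_hard))


def power_law_stress(p: PowerLawParams, strain: float) -> float:
    """Uniaxial stress (MPa): elastic below yield, ``k*eps**N`` above.

    Continuous at the yield strain by construction; returns 0 at zero strain.
    """
    if strain < 0.0:
        raise DomainError(f"strain must be >= 0, got {strain!r}")
    if strain == 0.0:
        return 0.0
    eps_y = power_law_yield_strain(p)
    if strain < eps_y:
        return p.e_modulus * strain
    return p.k * strain**p.n_hard


# --- annulus ground substance: compressible Hill foam -------------------------


@dataclass(frozen=True)
class HillFoamParams:
    """Hill (Storakers-type) compressible foam constants.

    Strain energy per unit reference volume:

        W = sum_j C_j/b_j * [l1^b_j + l2^b_j + l3^b_j - 3
                             + (1/n) * (J^(-n*b_j) - 1)]

    with principal stretches ``l_i``, ``J = l1*l2*l3`` and compressibility
    exponent ``n``.  The stress-free reference state is ``l_i = 1``.
    """

    n: float
    c: tuple[float, float, float]
    b: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.c) != len(self.b):
            raise DomainError("c and b must have equal length")
        if self.n <= 0.0:
            raise DomainError(f"compressibility exponent n must be > 0, got {self.n!r}")

    @classmethod
    def annulus_ground_substance(cls) -> "HillFoamParams":
        """Default constants fitted to annulus ground-substance test data."""
        return cls(n=2.0, c=(0.090, 1.643, -0.699), b=(4.0, -1.0, -2.0))


def hill_foam_strain_energy(p: HillFoamParams, stretches) -> float:
    """Strain-energy density (MPa) at principal stretches ``(l1, l2, l3)``."""
    l1, l2, l3 = (float(s) for s in stretches)
    if min(l1, l2, l3) <= 0.0:
        raise DomainError("principal stretches must be > 0")
    jac = l1 * l2 * l3
    w = 0.0
    for cj, bj in zip(p.c, p.b):
        w += cj / bj * (l1**bj + l2**bj + l3**bj - 3.0 + (jac ** (-p.n * bj) - 1.0) / p.n)
    return w


def _principal_nominal_stress(p: HillFoamParams, lam: float, jac: float) -> float:
    # dW/dlam_i = sum_j C_j * (lam^(b_j-1) - J^(-n*b_j)/lam)
    return sum(cj * (lam ** (bj - 1.0) - jac ** (-p.n * bj) / lam) for cj, bj in zip(p.c, p.b))


def hill_foam_lateral_stretch(p: HillFoamParams, stretch: float) -> float:
    """Free lateral stretch under uniaxial loading (zero lateral stress).

    Solves ``dW/dl_lat = 0`` for the common lateral stretch by bracketed
    root finding; the residual tolerance on the lateral stress is ~1e-10.
    """
    if not np.isfinite(stretch) or stretch <= 0.0:
        raise DomainError(f"axial stretch must be > 0, got {stretch!r}")
    if stretch == 1.0:
        return 1.0

    def residual(mu: float) -> float:
        return _principal_nominal_stress(p, mu, stretch * mu * mu)

    lo, hi = 1e-3, 50.0
    if residual(lo) * residual(hi) > 0.0:
        raise DomainError(f"cannot bracket lateral stretch at axial stretch {stretch!r}")
    return brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)


def hill_foam_uniaxial_stress(p: HillFoamParams, stretch: float) -> float:
    """Uniaxial nominal stress (MPa) at an axial stretch, free lateral faces.

    Zero at the reference stretch 1; positive in tension.  Equals the
    derivative of the strain-energy density along the uniaxial path (the
    lateral equilibrium makes the lateral terms drop out).
    """
    if stretch == 1.0:
        return 0.0
    mu = hill_foam_lateral_stretch(p, stretch)
    return _principal_nominal_stress(p, stretch, stretch * mu * mu)


# --- disc axial element -------------------------------------------------------


@dataclass(frozen=True)
class FiberLaw:
    """Annulus fiber-lamella axial stress law (tension only).

    ``kind='linear'`` uses ``sigma = e_modulus * strain``;
    ``kind='power_law'`` uses bone-style elastic/power-law hardening, which
    saturates and emulates fiber-reorientation plateau behaviour.
    """

    kind: Literal["linear", "power_law"]
    e_modulus: float
    k: float = 0.0
    n_hard: float = 0.5

    def stress(self, strain: float) -> float:
        if strain <= 0.0:
            return 0.0
        if self.kind == "linear":
            return self.e_modulus * strain
        return power_law_stress(
            PowerLawParams(e_modulus=self.e_modulus, k=self.k, n_hard=self.n_hard), strain
        )


class DiscElementLaw:
    """Axial disc (growth plate / endplate cartilage) element law.

    Composite stress of Hill-foam ground substance and fiber lamellae,
    volume-weighted by the fiber fraction:

        sigma(eps) = (1 - phi) * t_hill(1 + eps) + phi * sigma_fiber(eps)

    Force is ``sigma * area``.  The element is deleted when the *tensile*
    stress reaches the failure stress; compression (negative strain, ground
    substance only) never triggers deletion.  The Hill response is cached on
    a dense stretch grid for speed; grid interpolation error is < 1e-4 MPa.
    """

    _GRID = np.linspace(0.05, 6.0, 4096)
    _TABLE_CACHE: dict[HillFoamParams, np.ndarray] = {}

    def __init__(
        self,
        area: float,
        failure_stress: float,
        hill: HillFoamParams,
        fiber_fraction: float,
        fiber_law: FiberLaw,
    ) -> None:
        if not np.isfinite(area) or area <= 0.0:
            raise DomainError(f"disc element area must be > 0 mm^2, got {area!r}")
        if not np.isfinite(failure_stress) or failure_stress <= 0.0:
            raise DomainError(f"failure stress must be > 0 MPa, got {failure_stress!r}")
        if not 0.0 <= fiber_fraction <= 1.0:
            raise DomainError(f"fiber fraction must lie in [0, 1], got {fiber_fraction!r}")
        self.area = float(area)
        self.failure_stress = float(failure_stress)
        self.hill = hill
        self.fiber_fraction = float(fiber_fraction)
        self.fiber_law = fiber_law
        if hill not in self._TABLE_CACHE:
            self._TABLE_CACHE[hill] = np.array(
                [hill_foam_uniaxial_stress(hill, s) for s in self._GRID]
            )
        self._hill_table = self._TABLE_CACHE[hill]

    def ground_stress(self, strain: float) -> float:
        if strain == 0.0:
            return 0.0  # exact stress-free reference, no table round-off
        stretch = 1.0 + strain
        if stretch <= self._GRID[0] or stretch >= self._GRID[-1]:
            return hill_foam_uniaxial_stress(self.hill, max(stretch, 1e-6))
        return float(np.interp(stretch, self._GRID, self._hill_table))

    def stress(self, strain: float) -> float:
        """Composite axial stress (MPa) at an engineering strain."""
        sigma = (1.0 - self.fiber_fraction) * self.ground_stress(strain)
        sigma += self.fiber_fraction * self.fiber_law.stress(strain)
        return sigma

    def force(self, strain: float) -> float:
        """Axial force (N) = stress times element area."""
        return self.stress(strain) * self.area

    def exceeds_failure(self, strain: float) -> bool:
        """True when the tensile stress has reached the deletion threshold."""
        return strain > 0.0 and self.stress(strain) >= self.failure_stress


def build_disc_element(
    area: float,
    failure_stress: float,
    hill: HillFoamParams | None = None,
    fiber_fraction: float = 0.2,
    fiber_law: FiberLaw | None = None,
) -> DiscElementLaw:
    """Construct a disc axial element law with packaged defaults.

    Defaults: annulus ground-substance Hill constants, 20 % fiber volume
    fraction, and a linear 400 MPa fiber modulus.
    """
    if hill is None:
        hill = HillFoamParams.annulus_ground_substance()
    if fiber_law is None:
        fiber_law = FiberLaw(kind="linear", e_modulus=400.0)
    return DiscElementLaw(area, failure_stress, hill, fiber_fraction, fiber_law)
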