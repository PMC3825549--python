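"""Quasi-static displacement-controlled solver with progressive element deletion.

A segment assembly is a parallel network of axial elements in the sagittal
(x-z) plane: tension-only ligament bars with piecewise-linear curves, disc
sub-elements with a composite stress law and a tensile deletion threshold,
and compression-only facet gap elements.  Loading is imposed as a rigid
translation (tension) or rotation (bending) of the driven boundary; at each
step element elongations are recomputed from geometry, element forces
sampled, elements whose failure criterion is met are deleted (all
simultaneous failures apply at once), and the boundary reaction force or
moment is recorded.  There is no inertia or damping: the loading of
interest is rate-independent.

The recorded history yields the ultimate point (global reaction maximum,
earliest step on ties) and a 10-90 % secant stiffness obtained by ordinary
least squares over the pre-ultimate samples whose force lies between 10 %
and 90 % of the ultimate force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .constitutive import DiscElementLaw, LigamentCurve, ligament_force
from .errors import DomainError, NumericalError

__all__ = [
    "Element",
    "SegmentAssembly",
    "FailureEvent",
    "SimulationResult",
    "simulate_tension",
    "simulate_bending",
    "simulate_whole_spine_tension",
    "ultimate_point",
    "stiffness_10_90",
]

ElementKind = Literal["ligament_bar", "disc", "facet_gap"]


@dataclass(frozen=True)
class Element:
    """One axial element between an inferior and a superior attachment.

    ``curve`` is set for ligament bars (per-bar child curve, deflection axis
    already stretched by any strain increase), ``disc_law`` for disc
    sub-elements (strain = elongation / ``disc_height``), and
    ``gap``/``gap_stiffness`` for facet gap elements.
    """

    name: str
    kind: ElementKind
    inferior: tuple[float, float]
    superior: tuple[float, float]
    curve: LigamentCurve | None = None
    disc_law: DiscElementLaw | None = None
    disc_height: float | None = None
    gap: float = 0.0
    gap_stiffness: float = 0.0

    @property
    def rest_length(self) -> float:
        dx = self.superior[0] - self.inferior[0]
        dz = self.superior[1] - self.inferior[1]
        return math.hypot(dx, dz)

    def axial_force(self, elongation: float) -> float:
        """Signed axial force at an elongation (positive = tension)."""
        if self.kind == "ligament_bar":
            return ligament_force(self.curve, elongation)
        if self.kind == "disc":
            return self.disc_law.force(elongation / self.disc_height)
        # facet gap: compression-only once the gap has closed
        overlap = -elongation - self.gap
        return -self.gap_stiffness * overlap if overlap > 0.0 else 0.0

    def fails_at(self, elongation: float) -> bool:
        if self.kind == "ligament_bar":
            return elongation >= self.curve.failure_deflection
        if self.kind == "disc":
            return self.disc_law.exceeds_failure(elongation / self.disc_height)
        return False


@dataclass
class SegmentAssembly:
    """A named parallel element network with a driven boundary.

    ``driven_boundary`` says which side the prescribed motion is applied to
    (inferior for the occiput-to-C2 complex, superior for subaxial
    segments); ``rotation_center`` is the sagittal point bending rotations
    pivot about (the disc centroid by default).
    """

    name: str
    elements: list[Element]
    driven_boundary: Literal["superior", "inferior"] = "superior"
    rotation_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.elements:
            raise DomainError(f"assembly {self.name!r} has no elements")


@dataclass(frozen=True)
class FailureEvent:
    step: int
    displacement: float  # mm or deg, matching the loading mode
    element: str
    kind: ElementKind
    warning: bool = False  # failures during nominally non-destructive bending


@dataclass
class SimulationResult:
    """Loading history with failure events and derived failure metrics.

    ``displacement`` is the imposed axial displacement (mm) in tension or
    rotation angle (deg) in bending, ``reaction`` the boundary reaction
    force (N) or moment (N*m).  ``ultimate_force``/``ultimate_displacement``
    give the global reaction maximum (earliest step on ties);
    ``stiffness_10_90`` is filled for tension runs with a well-defined band.
    """

    mode: Literal["tension", "flexion", "extension", "whole_spine_tension"]
    displacement: np.ndarray
    reaction: np.ndarray
    failure_events: list[FailureEvent] = field(default_factory=list)
    ultimate_force: float = float("nan")
    ultimate_displacement: float = float("nan")
    stiffness_10_90: float = float("nan")
    segment: str = ""
    failed_segment: str | None = None

    def finalize(self) -> "SimulationResult":
        self.ultimate_displacement, self.ultimate_force = ultimate_point(self)
        if self.mode in ("tension", "whole_spine_tension"):
            try:
                self.stiffness_10_90 = stiffness_10_90(self)
            except DomainError:
                self.stiffness_10_90 = float("nan")
        return self


def _check_step(step: float) -> None:
    if not np.isfinite(step) or step <= 0.0:
        raise DomainError(f"step must be > 0, got {step!r}")


def _elongation_translation(element: Element, d: float) -> float:
    """Elongation under a rigid +z translation ``d`` of the driven boundary.

    Relative motion is what stretches an element, so translating either
    boundary by ``d`` gives the same elongation magnitude.
    """
    dx = element.superior[0] - element.inferior[0]
    dz = element.superior[1] - element.inferior[1] + d
    return math.hypot(dx, dz) - element.rest_length


def simulate_tension(
    assembly: SegmentAssembly, max_displacement: float, step: float = 0.01
) -> SimulationResult:
    """Displacement-controlled axial tension with progressive deletion.

    Imposes axial displacements ``step, 2*step, ... <= max_displacement`` on
    the driven boundary.  At every step each active element's elongation is
    recomputed from geometry, its force sampled (so the failure step still
    records the failing element's peak force), failing elements are deleted
    for subsequent steps, and the reaction is the sum of the axial (z)
    force components.
    """
    _check_step(step)
    if max_displacement <= 0.0:
        raise DomainError(f"max displacement must be > 0 mm, got {max_displacement!r}")
    n_steps = int(math.floor(max_displacement / step + 1e-9))
    displacements = np.arange(0, n_steps + 1) * step
    reactions = np.zeros_like(displacements)
    events: list[FailureEvent] = []
    failed = [False] * len(assembly.elements)

    for k in range(1, n_steps + 1):
        d = displacements[k]
        reaction = 0.0
        newly_failed: list[int] = []
        for idx, el in enumerate(assembly.elements):
            if failed[idx]:
                continue
            elong = _elongation_translation(el, d)
            f = el.axial_force(elong)
            if not np.isfinite(f):
                raise NumericalError(
                    f"non-finite force in element {el.name!r} at step {k} (d = {d:.4f} mm)"
                )
            # axial reaction component: force acts along the element line
            dz = el.superior[1] - el.inferior[1] + d
            length = math.hypot(el.superior[0] - el.inferior[0], dz)
            reaction += f * (dz / length if length > 0.0 else 1.0)
            if el.fails_at(elong):
                newly_failed.append(idx)
        for idx in newly_failed:
            failed[idx] = True
            events.append(
                FailureEvent(
                    step=k,
                    displacement=float(d),
                    element=assembly.elements[idx].name,
                    kind=assembly.elements[idx].kind,
                )
            )
        reactions[k] = reaction

    return SimulationResult(
        mode="tension",
        displacement=displacements,
        reaction=reactions,
        failure_events=events,
        segment=assembly.name,
    ).finalize()


def _rotate_about(point: tuple[float, float], center: tuple[float, float], theta: float):
    """Rotate a sagittal point about a center by ``theta`` (rad, +y axis).

    A positive rotation carries +z toward +x (superior points move anterior,
    anterior points move inferior), which is the flexion sense for a driven
    superior boundary.
    """
    px, pz = point[0] - center[0], point[1] - center[1]
    c, s = math.cos(theta), math.sin(theta)
    return (center[0] + c * px + s * pz, center[1] - s * px + c * pz)


def simulate_bending(
    assembly: SegmentAssembly,
    max_angle: float,
    step: float = 0.05,
    direction: Literal["flexion", "extension"] = "flexion",
) -> SimulationResult:
    """Rotation-controlled sagittal bending about the configured center.

    The driven boundary's attachment points rotate rigidly about
    ``rotation_center``; element forces act along the rotated lines of
    action and the reaction moment is the sum of their moments about the
    center, reported positive in the commanded direction.  Bending runs are
    nominally non-destructive: any element failure is recorded as a warning
    event (and the element deleted) rather than aborting.
    """
    _check_step(step)
    if max_angle <= 0.0:
        raise DomainError(f"max angle must be > 0 deg, got {max_angle!r}")
    if direction not in ("flexion", "extension"):
        raise DomainError(f"unknown bending direction {direction!r}")
    sense = 1.0 if direction == "flexion" else -1.0
    # rotating the inferior boundary by -theta is equivalent to rotating the
    # superior boundary by +theta for the relative motion
    boundary_sign = 1.0 if assembly.driven_boundary == "superior" else -1.0

    n_steps = int(math.floor(max_angle / step + 1e-9))
    angles = np.arange(0, n_steps + 1) * step
    moments = np.zeros_like(angles)
    events: list[FailureEvent] = []
    failed = [False] * len(assembly.elements)
    center = assembly.rotation_center

    for k in range(1, n_steps + 1):
        theta = sense * boundary_sign * math.radians(angles[k])
        moment = 0.0
        newly_failed: list[int] = []
        for idx, el in enumerate(assembly.elements):
            if failed[idx]:
                continue
            if assembly.driven_boundary == "superior":
                fixed_pt, moved_pt = el.inferior, _rotate_about(el.superior, center, theta)
            else:
                fixed_pt, moved_pt = el.superior, _rotate_about(el.inferior, center, theta)
            dx, dz = moved_pt[0] - fixed_pt[0], moved_pt[1] - fixed_pt[1]
            length = math.hypot(dx, dz)
            elong = length - el.rest_length
            f = el.axial_force(elong)
            if not np.isfinite(f):
                raise NumericalError(
                    f"non-finite force in element {el.name!r} at step {k} "
                    f"(angle = {angles[k]:.3f} deg)"
                )
            if length > 0.0 and f != 0.0:
                # tension pulls the moved point toward the fixed point
                fx, fz = -f * dx / length, -f * dz / length
                rx, rz = moved_pt[0] - center[0], moved_pt[1] - center[1]
                moment += rz * fx - rx * fz  # moment about +y
            if el.fails_at(elong):
                newly_failed.append(idx)
        for idx in newly_failed:
            failed[idx] = True
            events.append(
                FailureEvent(
                    step=k,
                    displacement=float(angles[k]),
                    element=assembly.elements[idx].name,
                    kind=assembly.elements[idx].kind,
                    warning=True,
                )
            )
        # resisting moment in the commanded direction, in N*m (mm*N -> N*m)
        moments[k] = -sense * boundary_sign * moment / 1000.0

    result = SimulationResult(
        mode=direction,
        displacement=angles,
        reaction=moments,
        failure_events=events,
        segment=assembly.name,
    )
    result.ultimate_displacement, result.ultimate_force = ultimate_point(result)
    return result


def ultimate_point(result: SimulationResult) -> tuple[float, float]:
    """Global reaction maximum and its displacement (earliest step on ties)."""
    if result.reaction.size == 0:
        raise DomainError("empty simulation history")
    idx = int(np.argmax(result.reaction))
    return float(result.displacement[idx]), float(result.reaction[idx])


def stiffness_10_90(result: SimulationResult) -> float:
    """Tensile stiffness (N/mm): OLS slope over the 10-90 % force band.

    Uses only pre-ultimate samples whose reaction lies within
    ``[0.1, 0.9] * ultimate_force``; requires at least two such samples and
    a positive ultimate force.
    """
    if result.reaction.size == 0:
        raise DomainError("empty simulation history")
    peak_idx = int(np.argmax(result.reaction))
    f_ult = float(result.reaction[peak_idx])
    if f_ult <= 0.0:
        raise DomainError("ultimate force must be > 0 to define the 10-90 % band")
    d = result.displacement[: peak_idx + 1]
    f = result.reaction[: peak_idx + 1]
    mask = (f >= 0.1 * f_ult) & (f <= 0.9 * f_ult)
    if int(mask.sum()) < 2:
        raise DomainError("fewer than two samples in the 10-90 % force band")
    slope = np.polyfit(d[mask], f[mask], 1)[0]
    return float(slope)


# --- whole-spine series assembly ---------------------------------------------


def _loading_branch(result: SimulationResult) -> tuple[np.ndarray, np.ndarray]:
    """Monotone pre-ultimate loading branch (displacement, force).

    Partial failures produce small load drops before the ultimate point; in
    a force-controlled series chain those unstable sub-branches are skipped
    quasi-statically, so the branch is the running maximum envelope.
    """
    peak_idx = int(np.argmax(result.reaction))
    d = result.displacement[: peak_idx + 1]
    f = np.maximum.accumulate(result.reaction[: peak_idx + 1])
    if f[-1] <= 0.0:
        raise NumericalError(f"segment {result.segment!r} has a non-positive loading branch")
    return d, f


def simulate_whole_spine_tension(
    segment_results: Sequence[SimulationResult] | Sequence,
    max_displacement: float,
    step: float = 0.01,
) -> SimulationResult:
    """Series (head-to-T1) tension of two or more segments.

    Accepts either pre-computed segment tension results or assemblies (which
    are simulated with the same step).  The segments share a common force;
    displacements add.  Per displacement step the shared force is found by
    monotone root finding on the summed inverse loading branches; beyond the
    chain peak the weakest segment (smallest ultimate force) follows its
    softening branch while the others unload along their loading branches.
    Failure localizes in the weakest segment, whose failure events are
    reported.
    """
    _check_step(step)
    results: list[SimulationResult] = []
    for seg in segment_results:
        if isinstance(seg, SegmentAssembly):
            # simulate far enough to capture each segment's full branch
            span = max(el.rest_length for el in seg.elements) * 2.0
            results.append(simulate_tension(seg, span, step))
        else:
            results.append(seg)
    if len(results) < 2:
        raise DomainError("a whole-spine chain needs at least two segments")

    branches = [_loading_branch(r) for r in results]
    peak_forces = [float(f[-1]) for _, f in branches]
    weak_idx = int(np.argmin(peak_forces))
    f_peak = peak_forces[weak_idx]
    weak = results[weak_idx]

    def chain_disp(force: float) -> float:
        return float(sum(np.interp(force, f, d) for d, f in branches))

    # softening branch of the weakest segment: from its peak onward,
    # monotone decreasing force envelope
    wpeak = int(np.argmax(weak.reaction))
    soft_d = weak.displacement[wpeak:]
    soft_f = np.minimum.accumulate(weak.reaction[wpeak:])

    def chain_disp_softening(force: float) -> float:
        # invert decreasing branch: use reversed arrays for np.interp
        d_weak = float(np.interp(force, soft_f[::-1], soft_d[::-1]))
        others = sum(
            np.interp(force, f, d) for i, (d, f) in enumerate(branches) if i != weak_idx
        )
        return d_weak + float(others)

    d_at_peak = chain_disp(f_peak)
    n_steps = int(math.floor(max_displacement / step + 1e-9))
    displacements = np.arange(0, n_steps + 1) * step
    reactions = np.zeros_like(displacements)
    from scipy.optimize import brentq

    for k in range(1, n_steps + 1):
        d_tot = displacements[k]
        if d_tot <= d_at_peak:
            g = lambda fc: chain_disp(fc) - d_tot
            reactions[k] = brentq(g, 0.0, f_peak, xtol=1e-10)
        else:
            f_min = float(soft_f[-1])
            if chain_disp_softening(f_min) <= d_tot:
                reactions[k] = f_min  # softening branch exhausted
            else:
                g = lambda fc: chain_disp_softening(fc) - d_tot
                reactions[k] = brentq(g, f_min, f_peak, xtol=1e-10)

    # map the weakest segment's failure events onto chain steps by force level
    events = [
        FailureEvent(
            step=int(ev.step),
            displacement=ev.displacement,
            element=f"{weak.segment}:{ev.element}",
            kind=ev.kind,
            warning=ev.warning,
        )
        for ev in weak.failure_events
    ]
    return SimulationResult(
        mode="whole_spine_tension",
        displacement=displacements,
        reaction=reactions,
        failure_events=events,
        segment="+".join(r.segment for r in results),
        failed_segment=weak.segment,
    ).finalize()
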