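"""Constitutive laws: ligament curves, bone plasticity, Hill foam, disc element."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cspine10 import library
from cspine10.constitutive import (
    FiberLaw,
    HillFoamParams,
    LigamentControlPoints,
    LigamentSpec,
    PowerLawParams,
    build_child_ligament_curve,
    build_disc_element,
    failure_strain_from_deflection,
    hill_foam_lateral_stretch,
    hill_foam_strain_energy,
    hill_foam_uniaxial_stress,
    ligament_force,
    power_law_stress,
    power_law_yield_strain,
    scale_failure_strain,
)
from cspine10.errors import DomainError
from cspine10.scaling import ScaleFactorSet


def all_c2c5_spec(n_elements: int = 1) -> LigamentSpec:
    return LigamentSpec(
        ligament_type="ALL",
        spinal_level="C2-C5",
        f_max=93.0,
        length=10.0,
        control_points=library.control_points("ALL"),
        eps_max=0.31,
        n_elements=n_elements,
    )


class TestChildLigamentCurve:
    def test_tolerance_point_from_adult_failure_data(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        # hand calculation: 93 N * 0.893 * 0.723^2 at 0.31 strain over 10 mm
        assert curve.failure_deflection == pytest.approx(3.1)
        assert curve.failure_force == pytest.approx(93.0 * 0.893 * 0.723**2, rel=1e-12)
        assert curve.failure_force == pytest.approx(43.4, rel=1e-2)

    def test_toe_point_from_normalized_ratios(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        d_a, f_a = curve.points[1]
        assert d_a == pytest.approx(0.31 * 0.211 * 10.0)
        assert f_a == pytest.approx(curve.failure_force * 0.108)

    def test_parallel_elements_share_force_not_deflection(self, default_sf):
        one = build_child_ligament_curve(all_c2c5_spec(1), default_sf)
        two = build_child_ligament_curve(all_c2c5_spec(2), default_sf)
        np.testing.assert_allclose(two.points[:, 0], one.points[:, 0])
        np.testing.assert_allclose(two.points[:, 1], one.points[:, 1] / 2.0)
        # total failure force over the bars is independent of the split
        assert 2 * two.failure_force == pytest.approx(one.failure_force)

    def test_curve_shape_reconstruction_is_exact(self, default_sf):
        cp = library.control_points("PLL")
        spec = LigamentSpec(
            ligament_type="PLL",
            spinal_level="C2-C5",
            f_max=71.0,
            length=10.0,
            control_points=cp,
            eps_max=0.18,
        )
        norm = build_child_ligament_curve(spec, default_sf).normalized()
        np.testing.assert_allclose(
            norm[1:], [[cp.eps1_ratio, cp.force1_ratio], [cp.eps2_ratio, cp.force2_ratio], [1, 1]]
        )

    def test_invalid_control_points_rejected(self):
        with pytest.raises(DomainError):
            LigamentControlPoints(0.5, 0.3, 0.4, 0.8)  # A strain beyond B strain
        with pytest.raises(DomainError):
            LigamentControlPoints(0.2, 0.0, 0.7, 0.8)  # ratio outside (0, 1)

    def test_spec_requires_exactly_one_failure_measure(self):
        cp = library.control_points("ALL")
        with pytest.raises(DomainError):
            LigamentSpec("ALL", "C2-C5", 93.0, 10.0, cp)  # neither given
        with pytest.raises(DomainError):
            LigamentSpec(
                "ALL", "C2-C5", 93.0, 10.0, cp, eps_max=0.3, d_max=3.0, adult_length=10.0
            )


class TestFailureStrainFromDeflection:
    @pytest.mark.parametrize(
        ("level", "lig", "expected_length"),
        [("OC-C1", "JC", 9.9 / 2.54), ("OC-C1", "AA-OM", 18.9 / 0.68)],
    )
    def test_implied_adult_lengths_recover_printed_pairs(self, level, lig, expected_length):
        row = library.ligament_library()[(level, lig)]
        length = row["d_max"] / row["eps_max"]
        assert length == pytest.approx(expected_length)
        assert failure_strain_from_deflection(row["d_max"], length) == pytest.approx(
            row["eps_max"]
        )

    def test_unit_strain_and_domain(self):
        assert failure_strain_from_deflection(5.0, 5.0) == 1.0
        with pytest.raises(DomainError):
            failure_strain_from_deflection(5.0, 0.0)


class TestStrainScaling:
    def test_zero_increase_is_identity(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        scaled = scale_failure_strain(curve, 0.0)
        np.testing.assert_allclose(scaled.points, curve.points)

    def test_fifty_percent_stretches_deflections_only(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        scaled = scale_failure_strain(curve, 50.0)
        assert scaled.failure_deflection == pytest.approx(4.65)
        np.testing.assert_allclose(scaled.points[:, 0], curve.points[:, 0] * 1.5)
        np.testing.assert_allclose(scaled.points[:, 1], curve.points[:, 1])
        # normalized shape retained
        np.testing.assert_allclose(scaled.normalized(), curve.normalized())

    def test_negative_increase_rejected(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        with pytest.raises(DomainError):
            scale_failure_strain(curve, -10.0)


class TestLigamentForce:
    def test_slack_and_failed_bars_carry_nothing(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        assert ligament_force(curve, -1.0) == 0.0
        assert ligament_force(curve, 1.0, failed=True) == 0.0

    def test_interpolation_matches_dense_segmentwise_oracle(self, default_sf):
        curve = build_child_ligament_curve(all_c2c5_spec(), default_sf)
        pts = curve.points

        def oracle(d: float) -> float:
            # brute-force: locate the segment, interpolate linearly
            if d <= 0.0:
                return 0.0
            if d >= pts[-1, 0]:
                return pts[-1, 1]
            for (d0, f0), (d1, f1) in zip(pts[:-1], pts[1:]):
                if d0 <= d <= d1:
                    return f0 + (f1 - f0) * (d - d0) / (d1 - d0)
            raise AssertionError("unreachable")

        for d in np.linspace(-0.5, curve.failure_deflection * 1.1, 600):
            assert ligament_force(curve, float(d)) == pytest.approx(oracle(float(d)), abs=1e-12)

    @given(st.floats(0.0, 100.0))
    def test_force_is_nonnegative_and_bounded_by_failure_force(self, d):
        curve = build_child_ligament_curve(all_c2c5_spec(), ScaleFactorSet())
        f = ligament_force(curve, d)
        assert 0.0 <= f <= curve.failure_force + 1e-12


class TestPowerLawPlasticity:
    def test_zero_strain_zero_stress(self):
        p = library.bone_power_law("cortical_bone")
        assert power_law_stress(p, 0.0) == 0.0

    def test_cortical_yield_strain_solves_branch_crossing(self):
        p = library.bone_power_law("cortical_bone")
        eps_y = power_law_yield_strain(p)
        assert eps_y == pytest.approx(0.0066, rel=0.02)
        # defining equation: elastic and hardening branches meet at yield
        assert p.e_modulus * eps_y == pytest.approx(p.k * eps_y**p.n_hard, rel=1e-9)

    @pytest.mark.parametrize("tissue", ["cortical_bone", "cancellous_bone", "endplate"])
    def test_stress_is_continuous_and_nondecreasing(self, tissue):
        p = library.bone_power_law(tissue)
        strains = np.linspace(0.0, 1.0, 2001)
        stresses = np.array([power_law_stress(p, float(e)) for e in strains])
        assert np.all(np.diff(stresses) >= 0.0)
        eps_y = power_law_yield_strain(p)
        below = power_law_stress(p, eps_y * (1 - 1e-9))
        above = power_law_stress(p, eps_y * (1 + 1e-9))
        assert above - below < 1e-6 * p.e_modulus * eps_y

    def test_invalid_hardening_exponent_rejected(self):
        with pytest.raises(DomainError):
            PowerLawParams(e_modulus=100.0, k=10.0, n_hard=1.5)


class TestHillFoam:
    def test_reference_state_is_stress_free(self):
        p = HillFoamParams.annulus_ground_substance()
        assert hill_foam_uniaxial_stress(p, 1.0) == 0.0

    def test_tension_positive_compression_negative(self):
        p = HillFoamParams.annulus_ground_substance()
        assert hill_foam_uniaxial_stress(p, 1.1) > 0.0
        assert hill_foam_uniaxial_stress(p, 0.9) < 0.0

    def test_lateral_stress_residual_vanishes(self):
        p = HillFoamParams.annulus_ground_substance()
        for lam in (0.7, 1.05, 1.5, 2.5):
            mu = hill_foam_lateral_stretch(p, lam)
            # lateral nominal stress residual at the solved stretch
            h = 1e-7
            w_plus = hill_foam_strain_energy(p, (lam, mu + h, mu + h))
            w_minus = hill_foam_strain_energy(p, (lam, mu - h, mu - h))
            assert abs(w_plus - w_minus) / (2 * h) < 1e-8

    @pytest.mark.parametrize("lam", [0.8, 0.95, 1.05, 1.3, 1.8, 2.5])
    def test_stress_matches_energy_derivative_oracle(self, lam):
        # central finite difference of the relaxed strain-energy density;
        # lateral equilibrium makes the lateral terms drop out (envelope)
        p = HillFoamParams.annulus_ground_substance()
        h = 1e-6

        def relaxed_energy(l1: float) -> float:
            mu = hill_foam_lateral_stretch(p, l1)
            return hill_foam_strain_energy(p, (l1, mu, mu))

        fd = (relaxed_energy(lam + h) - relaxed_energy(lam - h)) / (2 * h)
        assert hill_foam_uniaxial_stress(p, lam) == pytest.approx(fd, rel=1e-3)

    def test_nonpositive_stretch_rejected(self):
        p = HillFoamParams.annulus_ground_substance()
        with pytest.raises(DomainError):
            hill_foam_uniaxial_stress(p, 0.0)


class TestDiscElement:
    def test_zero_strain_zero_force(self):
        el = build_disc_element(area=14.66, failure_stress=30.0)
        assert el.force(0.0) == 0.0

    def test_force_at_deletion_threshold_is_stress_times_area(self):
        el = build_disc_element(area=14.66, failure_stress=30.0)
        # 30 MPa over the 14.66 mm^2 annulus: about 440 N at deletion
        assert 30.0 * 14.66 == pytest.approx(439.8)
        # find the strain where the threshold is reached and check the force
        strains = np.linspace(0.0, 2.0, 20001)
        crossing = next(s for s in strains if el.exceeds_failure(float(s)))
        assert el.force(float(crossing)) == pytest.approx(439.8, rel=5e-3)

    def test_compression_never_triggers_deletion(self):
        el = build_disc_element(area=14.66, failure_stress=0.001)
        for strain in np.linspace(-0.9, 0.0, 50):
            assert not el.exceeds_failure(float(strain))
        assert el.force(-0.3) < 0.0  # ground substance pushes back

    def test_invalid_fiber_fraction_rejected(self):
        with pytest.raises(DomainError):
            build_disc_element(area=10.0, failure_stress=30.0, fiber_fraction=1.5)

    def test_saturating_fiber_law_uses_power_hardening(self):
        law = FiberLaw(kind="power_law", e_modulus=700.0, k=130.0, n_hard=0.05)
        assert law.stress(0.0) == 0.0
        # nearly flat beyond yield
        assert law.stress(2.0) / law.stress(0.5) < 1.1


class TestChildDeflectionsVsAdult:
    def test_fifty_percent_increase_stays_below_adult_failure_deflections(self, default_sf):
        """Across every packaged fixture ligament, the +50 % child failure
        deflection must not exceed the corresponding adult one."""
        from cspine10.geometry import build_segment_geometry

        checked = 0
        for level in ("C0-C2", "C4-C5", "C6-C7"):
            geom = build_segment_geometry(level)
            for lig in geom.ligaments:
                spec = library.make_ligament_spec(
                    lig.library_level, lig.ligament_type, lig.length, lig.n_elements
                )
                curve = scale_failure_strain(
                    build_child_ligament_curve(spec, default_sf), 50.0
                )
                adult = spec.adult_failure_deflection
                assert adult is not None
                assert curve.failure_deflection <= adult + 1e-9, (
                    f"{level} {lig.ligament_type}: child +50% deflection "
                    f"{curve.failure_deflection:.3f} exceeds adult {adult:.3f}"
                )
                checked += 1
        assert checked == 20
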