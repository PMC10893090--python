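"""Spherical-cap geometry, mixing shear, and detachment force balance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spherodrop import (
    LiquidProperties,
    MixingConfig,
    angular_velocity_to_rcf,
    cap_from_volume_and_angle,
    min_detach_acceleration,
    rcf_to_angular_velocity,
    shear_safety_check,
    wall_shear_stress,
    worst_case_detach_acceleration,
)


def _numeric_cap_volume(sphere_radius, theta_deg, n=200_000):
    """Independent oracle: integrate the cap's circular cross-sections.

    The cap is the part of the sphere below the contact plane; slicing
    perpendicular to the symmetry axis at height z from the apex gives
    disks of radius sqrt(R^2 - (R - z)^2) up to the cap height
    R*(1 - cos(theta)).
    """
    height = sphere_radius * (1 - math.cos(math.radians(theta_deg)))
    z = np.linspace(0.0, height, n)
    r2 = sphere_radius**2 - (sphere_radius - z) ** 2
    return float(np.trapezoid(np.pi * r2, z))


class TestSphericalCap:
    def test_hemisphere_baseline_radius(self):
        # V = (2/3)*pi mm^3 with theta = 90 deg is exactly a 1 mm hemisphere
        volume_ul = (2.0 / 3.0) * math.pi * 1e-3 * 1e3  # mm^3 -> µL
        cap = cap_from_volume_and_angle(volume_ul, 90.0)
        assert cap.baseline_radius == pytest.approx(1e-3, rel=1e-12)

    def test_one_microliter_hemisphere(self):
        cap = cap_from_volume_and_angle(1.0, 90.0)
        assert cap.baseline_radius == pytest.approx((3e-9 / (2 * math.pi)) ** (1 / 3), rel=1e-12)
        assert cap.baseline_radius == pytest.approx(0.782e-3, rel=1e-3)

    def test_volume_matches_numeric_integration(self):
        cap = cap_from_volume_and_angle(1.0, 90.0)
        numeric = _numeric_cap_volume(cap.cap_sphere_radius, cap.contact_angle)
        assert numeric == pytest.approx(1e-9, rel=1e-6)

    def test_detached_sphere_limit(self):
        # theta -> 180 deg: contact line shrinks to a point
        cap = cap_from_volume_and_angle(1.0, 179.999)
        assert cap.baseline_radius < 1e-7

    @given(
        volume_ul=st.floats(0.1, 10.0),
        theta=st.floats(1.0, 179.0),
    )
    def test_roundtrip_volume(self, volume_ul, theta):
        cap = cap_from_volume_and_angle(volume_ul, theta)
        c = math.cos(math.radians(theta))
        recomputed = (math.pi / 3) * cap.cap_sphere_radius**3 * (2 - 3 * c + c**3)
        assert recomputed == pytest.approx(cap.volume, rel=1e-10)
        assert cap.volume_ul == pytest.approx(volume_ul, rel=1e-10)

    @pytest.mark.parametrize("volume,angle", [(-1.0, 90.0), (0.0, 90.0), (1.0, 0.0), (1.0, 180.0)])
    def test_domain_errors(self, volume, angle):
        with pytest.raises(ValueError):
            cap_from_volume_and_angle(volume, angle)


class TestWallShear:
    def test_printed_parameters(self, water_like):
        # mu = 0.9 mPa*s, Q = 2 mL/s, 4 mm ID tube (R = 2 mm radius)
        mixing = MixingConfig.from_ml_per_s(2.0, 4.0)
        tau = wall_shear_stress(mixing, water_like)
        assert tau == pytest.approx(71.6e-3, rel=2e-3)
        assert tau <= 80e-3

    def test_zero_flow(self, water_like):
        mixing = MixingConfig(flow_rate=0.0, tube_radius=2e-3)
        assert wall_shear_stress(mixing, water_like) == 0.0

    def test_cubic_radius_scaling(self, water_like):
        a = wall_shear_stress(MixingConfig.from_ml_per_s(2.0, 4.0), water_like)
        b = wall_shear_stress(MixingConfig.from_ml_per_s(2.0, 8.0), water_like)
        assert a == pytest.approx(8 * b, rel=1e-12)

    def test_poiseuille_variant_is_factor_four(self, water_like):
        mixing = MixingConfig.from_ml_per_s(2.0, 4.0)
        assert wall_shear_stress(mixing, water_like, formula="poiseuille") == pytest.approx(
            4 * wall_shear_stress(mixing, water_like), rel=1e-12
        )

    def test_safety_check_margin(self, water_like):
        report = shear_safety_check(MixingConfig.from_ml_per_s(2.0, 4.0), water_like)
        assert report.passed
        assert report.margin_ratio == pytest.approx(750 / 71.62, rel=1e-2)

    def test_safety_check_boundary_is_strict(self, water_like):
        mixing = MixingConfig.from_ml_per_s(2.0, 4.0)
        tau = wall_shear_stress(mixing, water_like)
        report = shear_safety_check(mixing, water_like, critical=tau)
        assert not report.passed

    def test_zero_shear_passes(self, water_like):
        report = shear_safety_check(MixingConfig(flow_rate=0.0, tube_radius=2e-3), water_like)
        assert report.passed and math.isinf(report.margin_ratio)


class TestDetachment:
    def test_hemisphere_one_microliter(self, water_like):
        cap = cap_from_volume_and_angle(1.0, 90.0)
        result = min_detach_acceleration(cap, water_like)
        # a_C = 2*pi*r*gamma/(rho*V) with r = (3V/2pi)^(1/3)
        r = (3e-9 / (2 * math.pi)) ** (1 / 3)
        assert result.min_acceleration == pytest.approx(
            2 * math.pi * r * 0.058 / (1000 * 1e-9), rel=1e-9
        )
        assert result.min_rcf == pytest.approx(29.0, abs=0.1)

    def test_detachment_consistency(self, water_like):
        cap = cap_from_volume_and_angle(2.0, 60.0)
        result = min_detach_acceleration(cap, water_like)
        assert result.min_acceleration == pytest.approx(
            result.retention_force / cap.mass(water_like), rel=1e-12
        )

    def test_near_detached_sphere_needs_no_force(self, water_like):
        cap = cap_from_volume_and_angle(1.0, 179.99)
        assert min_detach_acceleration(cap, water_like).min_rcf < 0.01

    @given(theta=st.floats(5.0, 175.0))
    def test_volume_scaling_exponent(self, water_like, theta):
        # a_C ∝ V^(-2/3) at fixed contact angle
        volumes = [0.5, 1.0, 2.0, 4.0, 8.0]
        accels = [
            min_detach_acceleration(cap_from_volume_and_angle(v, theta), water_like).min_acceleration
            for v in volumes
        ]
        slope = np.polyfit(np.log(volumes), np.log(accels), 1)[0]
        assert slope == pytest.approx(-2.0 / 3.0, abs=1e-6)

    def test_retention_force_monotone_in_surface_tension(self):
        cap = cap_from_volume_and_angle(2.0, 90.0)
        forces = [
            min_detach_acceleration(
                cap, LiquidProperties(surface_tension=g)
            ).retention_force
            for g in (0.03, 0.05, 0.07)
        ]
        assert forces[0] < forces[1] < forces[2]

    def test_below_40g_for_any_angle_at_one_microliter(self, water_like):
        worst = worst_case_detach_acceleration(1.0, water_like)
        assert worst.min_rcf < 40.0

    def test_worst_case_dominates_hemisphere(self, water_like):
        worst = worst_case_detach_acceleration(1.0, water_like)
        at_90 = min_detach_acceleration(cap_from_volume_and_angle(1.0, 90.0), water_like)
        assert worst.min_acceleration >= at_90.min_acceleration

    def test_worst_case_angle_and_value(self, water_like):
        worst = worst_case_detach_acceleration(1.0, water_like, angle_grid_step=0.1)
        assert 65.0 <= worst.maximizing_angle <= 70.0
        assert worst.min_rcf == pytest.approx(32.3, abs=0.3)

    def test_worst_case_volume_scaling(self, water_like):
        # 8x volume at the maximizing angle -> worst case / 4
        w1 = worst_case_detach_acceleration(1.0, water_like)
        w8 = worst_case_detach_acceleration(8.0, water_like)
        assert w8.min_acceleration == pytest.approx(w1.min_acceleration / 4.0, rel=1e-3)

    def test_worst_case_non_increasing_in_volume(self, water_like):
        values = [
            worst_case_detach_acceleration(v, water_like).min_rcf for v in (1.0, 1.5, 2.0, 3.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestRcfConversion:
    def test_zero_rcf(self):
        assert rcf_to_angular_velocity(0.0, 0.15) == 0.0

    def test_known_value(self):
        assert rcf_to_angular_velocity(25.0, 0.15) == pytest.approx(40.43, abs=0.01)

    @given(rcf=st.floats(0.01, 1000.0), radius=st.floats(0.05, 0.5))
    def test_roundtrip(self, rcf, radius):
        omega = rcf_to_angular_velocity(rcf, radius)
        assert angular_velocity_to_rcf(omega, radius) == pytest.approx(rcf, rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            rcf_to_angular_velocity(25.0, 0.0)


class TestLiquidProperties:
    @pytest.mark.parametrize("field", ["density", "surface_tension", "viscosity"])
    def test_positivity_enforced(self, field):
        with pytest.raises(ValueError):
            LiquidProperties(**{field: 0.0})
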