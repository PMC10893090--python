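"""Rotating-frame transfer simulator: oracles, symmetry, capture accounting."""

import math

import pytest

from spherodrop import (
    PlatePose,
    RotorConfig,
    cap_from_volume_and_angle,
    capture_report,
    deflection_angle_map,
    rear_row_advisory,
    simulate_drop_flight,
)

CENTER_384 = (51.75, 33.75)  # plate center in plate-map mm


class TestGeometricOracle:
    def test_center_site_no_coriolis_no_deflection(self, default_rotor, well_opening_pose):
        result = simulate_drop_flight(
            CENTER_384, default_rotor, well_opening_pose, include_coriolis=False
        )
        assert result.deflection_length < 1e-9

    @pytest.mark.parametrize("u_mm", [-40.0, -10.0, 10.0, 40.0])
    def test_uniform_acceleration_matches_closed_form(
        self, default_rotor, well_opening_pose, u_mm
    ):
        # frozen launch-site acceleration -> straight line, offset = h*tan(angle)
        site = (CENTER_384[0] + u_mm, CENTER_384[1])
        result = simulate_drop_flight(
            site, default_rotor, well_opening_pose,
            include_coriolis=False, position_dependent=False,
        )
        expected = 0.8 * (u_mm / 150.0)  # h * tan(geometric angle), mm
        assert result.landing_offset[0] == pytest.approx(expected, rel=1e-9)
        assert result.landing_offset[1] == pytest.approx(0.0, abs=1e-12)

    def test_position_dependent_close_to_geometric_at_small_gap(
        self, default_rotor, well_opening_pose
    ):
        site = (CENTER_384[0] + 10.0, CENTER_384[1])
        result = simulate_drop_flight(
            site, default_rotor, well_opening_pose, include_coriolis=False
        )
        assert result.deflection_length == pytest.approx(0.8 * 10.0 / 150.0, rel=0.01)

    def test_crossing_time_matches_constant_acceleration(
        self, default_rotor, well_opening_pose
    ):
        result = simulate_drop_flight(CENTER_384, default_rotor, well_opening_pose)
        analytic = math.sqrt(2 * 0.8e-3 / (25 * 9.80665))
        assert result.crossing_time == pytest.approx(analytic, rel=0.01)

    def test_angle_consistent_with_length_and_gap(self, default_rotor, well_opening_pose):
        result = simulate_drop_flight(
            (CENTER_384[0] + 30.0, CENTER_384[1]), default_rotor, well_opening_pose
        )
        expected = math.degrees(math.atan(result.deflection_length / 0.8))
        assert result.deflection_angle == pytest.approx(expected, abs=1e-9)


class TestCoriolisAndSymmetry:
    def test_trailing_exceeds_leading(self, default_rotor, well_opening_pose):
        trailing = simulate_drop_flight((0.0, CENTER_384[1]), default_rotor, well_opening_pose)
        leading = simulate_drop_flight((103.5, CENTER_384[1]), default_rotor, well_opening_pose)
        assert trailing.deflection_length > leading.deflection_length

    def test_mirrored_spin_mirrors_deflection(self, well_opening_pose):
        cw = RotorConfig(rotor_radius=0.15, rcf=25.0, spin_direction=1)
        ccw = RotorConfig(rotor_radius=0.15, rcf=25.0, spin_direction=-1)
        site = (20.0, CENTER_384[1])
        mirror_site = (2 * CENTER_384[0] - site[0], CENTER_384[1])
        a = simulate_drop_flight(site, cw, well_opening_pose)
        b = simulate_drop_flight(mirror_site, ccw, well_opening_pose)
        assert a.landing_offset[0] == pytest.approx(-b.landing_offset[0], rel=1e-9)
        assert a.deflection_length == pytest.approx(b.deflection_length, rel=1e-9)

    def test_coriolis_shift_independent_of_rcf(self, well_opening_pose):
        # crossing time scales as 1/omega while the Coriolis acceleration
        # scales as omega*v, so the Coriolis landing shift is the same at
        # any spin speed: (2h)^(3/2) / (3*sqrt(R)) to leading order
        site = (CENTER_384[0] + 20.0, CENTER_384[1])

        def coriolis_shift(rcf):
            on = simulate_drop_flight(site, RotorConfig(rcf=rcf), well_opening_pose)
            off = simulate_drop_flight(
                site, RotorConfig(rcf=rcf), well_opening_pose, include_coriolis=False
            )
            return on.landing_offset[0] - off.landing_offset[0]

        shift_slow, shift_fast = coriolis_shift(2.0), coriolis_shift(25.0)
        analytic = -((2 * 0.8e-3) ** 1.5) / (3 * math.sqrt(0.15)) * 1e3  # mm
        assert shift_slow == pytest.approx(shift_fast, rel=1e-3)
        assert shift_fast == pytest.approx(analytic, rel=0.01)

    def test_coriolis_negligible_in_small_gap_limit(self, default_rotor):
        # Coriolis shift scales as h^(3/2) against the geometric h*u/R,
        # so the geometric limit is approached as the gap shrinks
        site = (CENTER_384[0] + 20.0, CENTER_384[1])

        def relative_coriolis(gap_mm):
            pose = PlatePose.from_gap_mm(gap_mm)
            on = simulate_drop_flight(site, default_rotor, pose)
            off = simulate_drop_flight(site, default_rotor, pose, include_coriolis=False)
            return abs(on.deflection_length - off.deflection_length) / off.deflection_length

        # valid in the small-rotation-angle regime omega*t << 1, where the
        # ratio scales as sqrt(h)
        assert relative_coriolis(0.2) < relative_coriolis(0.4) < relative_coriolis(0.8)

    def test_step_halving_convergence(self, default_rotor, well_opening_pose):
        site = (10.0, 10.0)
        coarse = simulate_drop_flight(site, default_rotor, well_opening_pose, n_steps=200)
        fine = simulate_drop_flight(site, default_rotor, well_opening_pose, n_steps=400)
        assert abs(coarse.deflection_length - fine.deflection_length) < 1e-3 * max(
            fine.deflection_length, 1e-9
        )


class TestDetachmentGating:
    def test_retained_below_threshold(self, well_opening_pose, water_like):
        drop = cap_from_volume_and_angle(1.0, 90.0)  # needs ~29 g
        rotor = RotorConfig(rotor_radius=0.15, rcf=5.0)
        result = simulate_drop_flight(
            CENTER_384, rotor, well_opening_pose, drop=drop, liquid=water_like
        )
        assert not result.detached
        assert result.deflection_length == 0.0

    def test_detached_above_threshold(self, well_opening_pose, water_like):
        drop = cap_from_volume_and_angle(3.0, 90.0)
        rotor = RotorConfig(rotor_radius=0.15, rcf=25.0)
        result = simulate_drop_flight(
            CENTER_384, rotor, well_opening_pose, drop=drop, liquid=water_like
        )
        assert result.detached


class TestCaptureAccounting:
    def test_full_384_all_captured_below_one_mm(self, default_rotor, well_opening_pose):
        report = capture_report(
            384, default_rotor, well_opening_pose, well_opening_radius_mm=1.55, n_steps=200
        )
        assert report.max_deflection_mm < 1.0
        assert report.capture_fraction == 100.0

    def test_zero_radius_captures_nothing(self, default_rotor, well_opening_pose):
        report = capture_report(
            384, default_rotor, well_opening_pose, well_opening_radius_mm=0.0, n_steps=200
        )
        assert report.capture_fraction == 0.0

    def test_large_gap_loses_drops(self, default_rotor):
        report = capture_report(
            384, default_rotor, PlatePose.from_gap_mm(11.8),
            well_opening_radius_mm=1.55, n_steps=200,
        )
        assert report.capture_fraction < 100.0
        assert report.max_deflection_mm > 2.0

    def test_angle_monotone_along_tangential_axis(self, default_rotor):
        # measurement geometry: h = 11.8 mm onto an unstructured receiver
        pose = PlatePose.from_gap_mm(11.8)
        row = [(x * 4.5, CENTER_384[1]) for x in range(24)]
        results = deflection_angle_map(
            [_pos(x, y) for x, y in row], default_rotor, pose, n_steps=200
        )
        signed = [r.landing_offset[0] for r in results]
        assert all(a < b for a, b in zip(signed, signed[1:]))


class TestRearRowAdvisory:
    def test_tight_margin_flags_nothing_when_central(self, default_rotor, well_opening_pose):
        report = capture_report(384, default_rotor, well_opening_pose, n_steps=200)
        advisory = rear_row_advisory(report, margin_mm=0.0)
        assert advisory.flagged_sites == ()

    def test_margin_equal_radius_flags_everything(self, default_rotor, well_opening_pose):
        report = capture_report(384, default_rotor, well_opening_pose, n_steps=200)
        advisory = rear_row_advisory(report, margin_mm=report.well_opening_radius_mm)
        assert len(advisory.flagged_sites) == len(report.results)

    def test_flags_concentrate_at_rear(self, default_rotor, well_opening_pose):
        report = capture_report(384, default_rotor, well_opening_pose, n_steps=200)
        # choose a margin that flags roughly the most-deflected sites
        lengths = sorted(r.deflection_length for r in report.results)
        margin = report.well_opening_radius_mm - lengths[-30]
        advisory = rear_row_advisory(report, margin_mm=margin)
        assert advisory.flagged_sites
        # rear = trailing tangential side = small plate-x for positive spin
        assert all(site[0] <= 2 * 4.5 for site in advisory.flagged_sites)


def _pos(x_mm, y_mm):
    from spherodrop.planner import PlatePosition

    return PlatePosition(plate=0, well="A1", x_mm=x_mm, y_mm=y_mm)


class TestValidation:
    def test_rotor_invariants(self):
        with pytest.raises(ValueError):
            RotorConfig(rotor_radius=0.0)
        with pytest.raises(ValueError):
            RotorConfig(rcf=-1.0)
        with pytest.raises(ValueError):
            RotorConfig(spin_direction=0)

    def test_pose_invariants(self):
        with pytest.raises(ValueError):
            PlatePose(gap=0.0)
        with pytest.raises(ValueError):
            PlatePose(gap=1e-3, plate_orientation="diagonal")
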