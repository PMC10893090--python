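"""Rotating-frame simulator for centrifugal hanging-drop transfer.

During harvesting, the donor plate (hanging drops pointing outward) and
the receiver plate ride in a swing-bucket carrier, so at speed the plate
surface is perpendicular to the centrifugal acceleration. A detached drop
is a point mass moving in the rotating frame under

* the centrifugal acceleration ``Omega**2 * rho_vec`` — position
  dependent, directed radially outward from the spin axis, and
* the Coriolis acceleration ``-2 * Omega_vec x v``.

Gravity and air drag are neglected: at >= 25 g over sub-millimeter travel
both are second-order. Drops start from rest in the rotating frame (no
detachment recoil).

Geometry (rotating frame, right-handed): the spin axis is ``z``; the
plate center sits at ``(rotor_radius, 0, 0)`` with the plate surface in
the plane ``x = rotor_radius``; ``y`` is the tangential direction (``+y``
leading for positive spin) and ``z`` is along the spin axis. A site at
plate coordinates ``(x_mm, y_mm)`` is offset from the plate center in the
``(y, z)`` plane according to the plate orientation. The drop is
integrated (fixed-step RK4) until it crosses the receiver plane
``x = rotor_radius + gap``; the in-plane ``(y, z)`` displacement between
launch and crossing is the landing offset.

Because a drop at a tangential offset ``u`` is accelerated radially
*through its own position*, its path tilts tangentially by the geometric
angle ``arctan(u / rotor_radius)``; the Coriolis term adds a deflection
toward the trailing side. The two effects add at the trailing end of the
plate and partially cancel at the leading end, which is why rear-end
drops deflect most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from spherodrop.physics import (
    LiquidProperties,
    STANDARD_GRAVITY,
    SphericalCapDrop,
    min_detach_acceleration,
    rcf_to_angular_velocity,
)
from spherodrop.planner import PLATE_FORMATS, PlatePosition, _format_geometry

#: Radius of a 384-well plate well opening (mm), the capture criterion.
WELL_OPENING_RADIUS_384_MM = 1.55

#: Donor-surface to well-opening gap (mm) when the lid rests on a 384 plate.
DEFAULT_WELL_OPENING_GAP_MM = 0.8


@dataclass(frozen=True)
class RotorConfig:
    """Swing-bucket centrifuge configuration.

    Parameters
    ----------
    rotor_radius : float
        Distance from the spin axis to the donor plate center (m).
    rcf : float
        Relative centrifugal acceleration at the plate center, in
        multiples of standard gravity.
    spin_direction : int
        +1 or -1, the sign of the angular velocity about the axis.
    """

    rotor_radius: float = 0.15
    rcf: float = 25.0
    spin_direction: int = 1

    def __post_init__(self) -> None:
        if not self.rotor_radius > 0:
            raise ValueError(f"rotor_radius must be positive, got {self.rotor_radius!r}")
        if not self.rcf > 0:
            raise ValueError(f"rcf must be positive, got {self.rcf!r}")
        if self.spin_direction not in (-1, 1):
            raise ValueError(f"spin_direction must be +1 or -1, got {self.spin_direction!r}")

    @property
    def omega(self) -> float:
        """Signed angular velocity (rad/s)."""
        return self.spin_direction * rcf_to_angular_velocity(self.rcf, self.rotor_radius)

    @property
    def centrifugal_acceleration(self) -> float:
        """Centrifugal acceleration at the plate center (m/s^2)."""
        return self.rcf * STANDARD_GRAVITY


@dataclass(frozen=True)
class PlatePose:
    """Donor/receiver geometry inside the bucket.

    Parameters
    ----------
    gap : float
        Perpendicular distance h from the donor drop plane to the receiver
        measurement plane (m).
    plate_orientation : str
        Which plate axis lies along the tangential (y) direction:
        ``"long"`` (the column/x axis of the plate map) or ``"short"``
        (the row/y axis).
    """

    gap: float = DEFAULT_WELL_OPENING_GAP_MM * 1e-3
    plate_orientation: str = "long"

    def __post_init__(self) -> None:
        if not self.gap > 0:
            raise ValueError(f"gap must be positive, got {self.gap!r}")
        if self.plate_orientation not in ("long", "short"):
            raise ValueError(
                f"plate_orientation must be 'long' or 'short', got {self.plate_orientation!r}"
            )

    @classmethod
    def from_gap_mm(cls, gap_mm: float, plate_orientation: str = "long") -> "PlatePose":
        return cls(gap=gap_mm * 1e-3, plate_orientation=plate_orientation)


@dataclass(frozen=True)
class DeflectionResult:
    """Landing offset of one drop at the receiver plane.

    ``landing_offset`` is the (tangential, axial) displacement (mm)
    between launch point and plane crossing; ``deflection_angle`` is
    ``arctan(deflection_length / h)`` in degrees.
    """

    site: tuple[float, float]  # plate coordinates (x_mm, y_mm)
    landing_offset: tuple[float, float]  # mm, (tangential, axial)
    deflection_length: float  # mm
    deflection_angle: float  # degrees
    crossing_time: float  # s
    detached: bool = True

    def __post_init__(self) -> None:
        if self.deflection_length < 0:
            raise ValueError("deflection_length must be non-negative")


@dataclass(frozen=True)
class CaptureReport:
    """Per-site capture outcome for a full plate transfer."""

    results: tuple[DeflectionResult, ...]
    captured: tuple[bool, ...]
    well_opening_radius_mm: float
    capture_fraction: float  # %

    @property
    def max_deflection_mm(self) -> float:
        return max(r.deflection_length for r in self.results)

    @property
    def max_angle_deg(self) -> float:
        return max(r.deflection_angle for r in self.results)


def _site_offsets_m(
    site_xy_mm: tuple[float, float],
    plate_format: int,
    pose: PlatePose,
) -> tuple[float, float]:
    """Map plate-map coordinates (mm) to (tangential, axial) offsets (m) from plate center."""
    rows, cols, pitch = _format_geometry(plate_format)
    cx = (cols - 1) * pitch / 2.0
    cy = (rows - 1) * pitch / 2.0
    dx = (site_xy_mm[0] - cx) * 1e-3
    dy = (site_xy_mm[1] - cy) * 1e-3
    if pose.plate_orientation == "long":
        return dx, dy  # plate x tangential, plate y axial
    return dy, dx


def _integrate_flight(
    u0: float,
    v0: float,
    rotor: RotorConfig,
    pose: PlatePose,
    include_coriolis: bool,
    position_dependent: bool,
    n_steps: int,
) -> tuple[float, float, float]:
    """Integrate one drop from rest; return (tangential offset m, axial offset m, time s).

    State is (x, y, z, vx, vy, vz) in the rotating frame with the launch
    point at (rotor_radius, u0, v0). When ``position_dependent`` is false
    the centrifugal acceleration is frozen at its launch-site value
    (magnitude and direction), which makes the trajectory a straight line
    and provides the closed-form oracle ``offset = h * tan(geometric
    angle)``.
    """
    omega = rotor.omega
    omega2 = omega * omega
    r0 = rotor.rotor_radius
    h = pose.gap
    target_x = r0 + h

    if position_dependent:
        def accel(p: np.ndarray, vel: np.ndarray) -> np.ndarray:
            a = np.array([omega2 * p[0], omega2 * p[1], 0.0])
            if include_coriolis:
                a[0] += 2.0 * omega * vel[1]
                a[1] += -2.0 * omega * vel[0]
            return a
    else:
        rho0 = math.hypot(r0, u0)
        a_mag = omega2 * rho0
        fixed = np.array([a_mag * r0 / rho0, a_mag * u0 / rho0, 0.0])

        def accel(p: np.ndarray, vel: np.ndarray) -> np.ndarray:
            a = fixed.copy()
            if include_coriolis:
                a[0] += 2.0 * omega * vel[1]
                a[1] += -2.0 * omega * vel[0]
            return a

    def rk4_step(state: np.ndarray, dt: float) -> np.ndarray:
        def deriv(s: np.ndarray) -> np.ndarray:
            return np.concatenate([s[3:], accel(s[:3], s[3:])])

        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    a_center = omega2 * r0
    t_scale = math.sqrt(2.0 * h / a_center)
    dt = t_scale / n_steps
    state = np.array([r0, u0, v0, 0.0, 0.0, 0.0])
    t = 0.0
    max_steps = 20 * n_steps
    for _ in range(max_steps):
        new_state = rk4_step(state, dt)
        if new_state[0] >= target_x:
            break
        state, t = new_state, t + dt
    else:
        raise RuntimeError("drop failed to reach the receiver plane (check geometry)")

    # bisect the crossing time within the final step to machine precision
    lo, hi = 0.0, dt
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        trial = rk4_step(state, mid)
        if trial[0] >= target_x:
            hi = mid
        else:
            lo = mid
    final = rk4_step(state, hi)
    return final[1] - u0, final[2] - v0, t + hi


def simulate_drop_flight(
    site_xy_mm: tuple[float, float],
    rotor: RotorConfig,
    pose: PlatePose,
    plate_format: int = 384,
    drop: SphericalCapDrop | None = None,
    liquid: LiquidProperties | None = None,
    include_coriolis: bool = True,
    position_dependent: bool = True,
    n_steps: int = 400,
) -> DeflectionResult:
    """Simulate one drop's flight from the donor surface to the receiver plane.

    Parameters
    ----------
    site_xy_mm : tuple
        Plate-map coordinates of the drop (mm, A1 at the origin).
    rotor, pose : RotorConfig, PlatePose
        Centrifuge and plate geometry.
    plate_format : int
        96 or 384; fixes the plate center used to place the site.
    drop, liquid : optional
        When both are given, the detachment force balance is checked
        first; if the configured rcf is below the drop's detachment
        threshold the result is returned with ``detached=False`` and zero
        offsets (the drop never leaves the plate).
    include_coriolis : bool
        Disable to isolate the geometric (radial-spreading) deflection.
    position_dependent : bool
        Freeze the centrifugal acceleration at its launch-site value when
        false (straight-line closed-form limit).
    n_steps : int
        RK4 steps across the gap (>= 200 recommended).
    """
    if n_steps < 10:
        raise ValueError("n_steps too small for a meaningful trajectory")
    if drop is not None and liquid is not None:
        threshold = min_detach_acceleration(drop, liquid)
        if rotor.centrifugal_acceleration < threshold.min_acceleration:
            return DeflectionResult(
                site=site_xy_mm,
                landing_offset=(0.0, 0.0),
                deflection_length=0.0,
                deflection_angle=0.0,
                crossing_time=math.inf,
                detached=False,
            )
    u0, v0 = _site_offsets_m(site_xy_mm, plate_format, pose)
    du, dv, t_cross = _integrate_flight(
        u0, v0, rotor, pose, include_coriolis, position_dependent, n_steps
    )
    length_mm = math.hypot(du, dv) * 1e3
    angle = math.degrees(math.atan2(length_mm * 1e-3, pose.gap))
    return DeflectionResult(
        site=site_xy_mm,
        landing_offset=(du * 1e3, dv * 1e3),
        deflection_length=length_mm,
        deflection_angle=angle,
        crossing_time=t_cross,
        detached=True,
    )


def _layout_sites(layout: int | Sequence[PlatePosition]) -> tuple[list[tuple[float, float]], int]:
    """Normalize a layout argument to ((x_mm, y_mm) sites, plate_format)."""
    if isinstance(layout, int):
        rows, cols, pitch = _format_geometry(layout)
        sites = [
            (col * pitch, row * pitch) for row in range(rows) for col in range(cols)
        ]
        return sites, layout
    sites = [(p.x_mm, p.y_mm) for p in layout]
    # infer format from extent: anything beyond the 96 grid must be 384
    rows96, cols96, pitch96 = PLATE_FORMATS[96]
    max_x = max(s[0] for s in sites)
    max_y = max(s[1] for s in sites)
    fmt = 96 if (max_x <= (cols96 - 1) * pitch96 + 1e-9 and len(sites) <= 96) else 384
    return sites, fmt


def deflection_angle_map(
    layout: int | Sequence[PlatePosition],
    rotor: RotorConfig,
    pose: PlatePose,
    include_coriolis: bool = True,
    n_steps: int = 400,
) -> list[DeflectionResult]:
    """Deflection result for every site of a plate layout.

    ``layout`` is either a plate format (96/384, full grid) or an explicit
    sequence of plate positions.
    """
    sites, fmt = _layout_sites(layout)
    return [
        simulate_drop_flight(
            site, rotor, pose, plate_format=fmt,
            include_coriolis=include_coriolis, n_steps=n_steps,
        )
        for site in sites
    ]


def capture_report(
    layout: int | Sequence[PlatePosition],
    rotor: RotorConfig,
    pose: PlatePose,
    well_opening_radius_mm: float = WELL_OPENING_RADIUS_384_MM,
    include_coriolis: bool = True,
    n_steps: int = 400,
) -> CaptureReport:
    """Well-capture accounting for a full plate transfer.

    A drop is captured when its landing offset at the well-opening plane
    is strictly smaller than the well-opening radius (i.e. it enters the
    well under its source position).
    """
    if well_opening_radius_mm < 0:
        raise ValueError("well_opening_radius must be non-negative")
    results = deflection_angle_map(
        layout, rotor, pose, include_coriolis=include_coriolis, n_steps=n_steps
    )
    captured = tuple(r.deflection_length < well_opening_radius_mm for r in results)
    fraction = 100.0 * sum(captured) / len(captured)
    return CaptureReport(
        results=tuple(results),
        captured=captured,
        well_opening_radius_mm=well_opening_radius_mm,
        capture_fraction=fraction,
    )


@dataclass(frozen=True)
class RearRowAdvisory:
    """Sites whose landing point comes close to the well wall."""

    flagged_sites: tuple[tuple[float, float], ...]
    flagged_ranks: tuple[int, ...]  # tangential-axis rank (0 = most leading)


def rear_row_advisory(report: CaptureReport, margin_mm: float) -> RearRowAdvisory:
    """Flag sites landing within ``margin_mm`` of the well wall.

    Sites whose offset magnitude is at least ``well_opening_radius -
    margin`` are flagged; their tangential-coordinate ranks identify the
    columns/rows (typically the rear edge) to leave unseeded when
    imaging quality matters.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    threshold = report.well_opening_radius_mm - margin_mm
    tangential = sorted({r.site[0] for r in report.results}, reverse=True)
    rank = {x: i for i, x in enumerate(tangential)}
    flagged = [r for r in report.results if r.deflection_length >= threshold]
    return RearRowAdvisory(
        flagged_sites=tuple(r.site for r in flagged),
        flagged_ranks=tuple(sorted({rank[r.site[0]] for r in flagged})),
    )
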