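"""Closed-form biophysics of hanging-drop generation and centrifugal release.

Three pieces of physics govern the workflow:

1. **Mixing shear.** The cell suspension is kept homogeneous by periodically
   aspirating and dispensing a fraction of the reservoir through a tube.
   The resulting maximum wall shear stress on the cells is estimated from
   the tube flow and must stay well below the ~750 mPa regime where
   adherent mammalian cells are affected.

2. **Sessile-drop geometry.** A hanging drop on a flat substrate is modeled
   as a spherical cap, fully determined by its volume ``V`` and contact
   angle ``theta``. The cap links ``V`` to the contact-line radius ``r``
   via the generating-sphere radius ``R_s``:

   ``V = (pi/3) * R_s**3 * (2 - 3*cos(theta) + cos(theta)**3)``,
   ``r = R_s * sin(theta)``.

3. **Centrifugal detachment.** A drop releases from the plate when the
   centrifugal body force exceeds the surface-tension retention force along
   the contact line, ``rho * a_C * V >= 2*pi*r*gamma*sin(theta)``, giving a
   minimum detachment acceleration ``a_C = 2*pi*r*gamma*sin(theta) / m``
   with drop mass ``m = rho * V``. This is a static force balance; dynamic
   shape change during spin-up is intentionally not modeled.

Interfaces accept volumes in microliters and angles in degrees; all
internal arithmetic is SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: Standard acceleration of gravity (m/s^2), used for all rcf conversions.
STANDARD_GRAVITY = 9.80665

#: Wall shear stress (Pa) above which effects on adherent mammalian cells
#: are expected; default threshold for :func:`shear_safety_check`.
CRITICAL_SHEAR_PA = 0.750

#: Default surface tension (N/m) of serum-supplemented culture medium.
#: Protein adsorption lowers it well below pure water (~0.072 N/m);
#: 0.058 N/m is a typical, deliberately conservative value. Override with
#: measured data whenever available.
DEFAULT_MEDIUM_SURFACE_TENSION = 0.058

_UL_TO_M3 = 1e-9


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class LiquidProperties:
    """Bulk properties of the culture medium.

    Parameters
    ----------
    density : float
        Mass density rho (kg/m^3).
    surface_tension : float
        Liquid–air surface tension gamma (N/m).
    viscosity : float
        Dynamic viscosity mu (Pa*s).
    """

    density: float = 1000.0
    surface_tension: float = DEFAULT_MEDIUM_SURFACE_TENSION
    viscosity: float = 0.9e-3

    def __post_init__(self) -> None:
        _require_positive("density", self.density)
        _require_positive("surface_tension", self.surface_tension)
        _require_positive("viscosity", self.viscosity)


#: Water-like culture medium at room temperature.
WATER_LIKE_MEDIUM = LiquidProperties()


@dataclass(frozen=True)
class SphericalCapDrop:
    """A sessile/pendant drop modeled as a spherical cap.

    Attributes
    ----------
    volume : float
        Liquid volume (m^3).
    contact_angle : float
        Contact angle theta between liquid and substrate (degrees, in the
        open interval (0, 180)).
    baseline_radius : float
        Radius r of the contact line on the substrate (m).
    cap_sphere_radius : float
        Radius R_s of the generating sphere (m).
    """

    volume: float
    contact_angle: float
    baseline_radius: float
    cap_sphere_radius: float

    def __post_init__(self) -> None:
        _require_positive("volume", self.volume)
        if not 0.0 < self.contact_angle < 180.0:
            raise ValueError(
                f"contact_angle must lie in (0, 180) degrees, got {self.contact_angle!r}"
            )
        theta = math.radians(self.contact_angle)
        if not math.isclose(
            self.baseline_radius, self.cap_sphere_radius * math.sin(theta), rel_tol=1e-9
        ):
            raise ValueError("baseline_radius inconsistent with cap_sphere_radius*sin(theta)")
        if not math.isclose(
            self.volume, _cap_volume(self.cap_sphere_radius, theta), rel_tol=1e-9
        ):
            raise ValueError("stored volume inconsistent with cap geometry")

    @property
    def volume_ul(self) -> float:
        """Volume in microliters."""
        return self.volume / _UL_TO_M3

    def mass(self, liquid: LiquidProperties) -> float:
        """Drop mass (kg) for the given medium."""
        return liquid.density * self.volume


def _cap_volume(sphere_radius: float, theta_rad: float) -> float:
    """Volume of a spherical cap with generating-sphere radius and contact angle."""
    c = math.cos(theta_rad)
    return (math.pi / 3.0) * sphere_radius**3 * (2.0 - 3.0 * c + c**3)


def cap_from_volume_and_angle(volume_ul: float, contact_angle_deg: float) -> SphericalCapDrop:
    """Solve the spherical-cap geometry for a given volume and contact angle.

    Parameters
    ----------
    volume_ul : float
        Drop volume in microliters (> 0).
    contact_angle_deg : float
        Contact angle in degrees, open interval (0, 180).

    Returns
    -------
    SphericalCapDrop
        The unique cap with the requested volume and contact angle.

    Notes
    -----
    Inverts ``V = (pi/3)*R_s**3*(2 - 3*cos(theta) + cos(theta)**3)`` for
    ``R_s`` in closed form; the bracketed polynomial is strictly positive
    on (0, 180) degrees so the cube root is well defined.
    """
    if not volume_ul > 0:
        raise ValueError(f"volume must be strictly positive, got {volume_ul!r}")
    if not 0.0 < contact_angle_deg < 180.0:
        raise ValueError(
            f"contact_angle must lie in (0, 180) degrees, got {contact_angle_deg!r}"
        )
    volume = volume_ul * _UL_TO_M3
    theta = math.radians(contact_angle_deg)
    c = math.cos(theta)
    shape_factor = 2.0 - 3.0 * c + c**3
    sphere_radius = (3.0 * volume / (math.pi * shape_factor)) ** (1.0 / 3.0)
    return SphericalCapDrop(
        volume=volume,
        contact_angle=contact_angle_deg,
        baseline_radius=sphere_radius * math.sin(theta),
        cap_sphere_radius=sphere_radius,
    )


@dataclass(frozen=True)
class MixingConfig:
    """Reservoir-mixing parameters of the syringe pump.

    Parameters
    ----------
    flow_rate : float
        Volumetric flow rate Q (m^3/s). The constructor helper
        :meth:`from_ml_per_s` accepts mL/s.
    tube_radius : float
        Inner radius R of the mixing tube (m).
    frequency : float
        Aspirate/dispense cycle frequency (Hz).
    exchanged_fraction : float
        Fraction of the reservoir volume moved per cycle, in (0, 1].
    """

    flow_rate: float
    tube_radius: float
    frequency: float = 0.5
    exchanged_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError(f"flow_rate must be non-negative, got {self.flow_rate!r}")
        _require_positive("tube_radius", self.tube_radius)
        _require_positive("frequency", self.frequency)
        if not 0.0 < self.exchanged_fraction <= 1.0:
            raise ValueError(
                f"exchanged_fraction must lie in (0, 1], got {self.exchanged_fraction!r}"
            )

    @classmethod
    def from_ml_per_s(
        cls,
        flow_ml_per_s: float,
        tube_inner_diameter_mm: float,
        frequency_hz: float = 0.5,
        exchanged_fraction: float = 0.3,
    ) -> "MixingConfig":
        """Build a config from bench units (mL/s flow, mm tube inner diameter)."""
        return cls(
            flow_rate=flow_ml_per_s * 1e-6,
            tube_radius=tube_inner_diameter_mm * 1e-3 / 2.0,
            frequency=frequency_hz,
            exchanged_fraction=exchanged_fraction,
        )


def wall_shear_stress(
    mixing: MixingConfig,
    liquid: LiquidProperties = WATER_LIKE_MEDIUM,
    formula: Literal["paper", "poiseuille"] = "paper",
) -> float:
    """Maximum wall shear stress (Pa) on cells during reservoir mixing.

    Parameters
    ----------
    mixing : MixingConfig
        Flow rate Q and tube radius R.
    liquid : LiquidProperties
        Provides the dynamic viscosity mu.
    formula : {"paper", "poiseuille"}
        ``"paper"`` evaluates ``tau = mu*Q / (pi*R**3)`` with R the tube
        radius. ``"poiseuille"`` evaluates the classical laminar-tube-flow
        wall shear ``tau = 4*mu*Q / (pi*R**3)``, a factor 4 larger.

    Notes
    -----
    The two variants are exposed because the simple estimate and the full
    Poiseuille result differ by the constant factor only; both scale as
    ``Q/R**3``, so safety margins relative to the ~750 mPa critical regime
    are large under either reading.
    """
    tau = liquid.viscosity * mixing.flow_rate / (math.pi * mixing.tube_radius**3)
    if formula == "poiseuille":
        tau *= 4.0
    elif formula != "paper":
        raise ValueError(f"formula must be 'paper' or 'poiseuille', got {formula!r}")
    return tau


@dataclass(frozen=True)
class ShearSafetyReport:
    """Outcome of a mixing shear-stress safety check."""

    shear_stress: float  # Pa
    critical: float  # Pa
    passed: bool
    margin_ratio: float  # critical / shear_stress (inf when shear is zero)


def shear_safety_check(
    mixing: MixingConfig,
    liquid: LiquidProperties = WATER_LIKE_MEDIUM,
    critical: float = CRITICAL_SHEAR_PA,
    formula: Literal["paper", "poiseuille"] = "paper",
) -> ShearSafetyReport:
    """Check the mixing shear stress against a critical threshold.

    Passes iff the computed wall shear stress is strictly below
    ``critical`` (default 750 mPa, the regime where effects on adherent
    mammalian cells are expected).
    """
    _require_positive("critical", critical)
    tau = wall_shear_stress(mixing, liquid, formula=formula)
    margin = critical / tau if tau > 0 else math.inf
    return ShearSafetyReport(
        shear_stress=tau, critical=critical, passed=tau < critical, margin_ratio=margin
    )


@dataclass(frozen=True)
class DetachmentResult:
    """Centrifugal detachment threshold for a hanging drop.

    Attributes
    ----------
    min_acceleration : float
        Centrifugal acceleration at the detachment threshold (m/s^2).
    retention_force : float
        Surface-tension retention force ``2*pi*r*gamma*sin(theta)`` (N).
    drop_weight_per_g : float
        Drop mass times standard gravity (N); the drop weight at 1 g.
    maximizing_angle : float | None
        Contact angle (degrees) at the worst case, set only by
        :func:`worst_case_detach_acceleration`.
    """

    min_acceleration: float
    retention_force: float
    drop_weight_per_g: float
    maximizing_angle: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.min_acceleration < 0:
            raise ValueError("min_acceleration must be non-negative")

    @property
    def min_rcf(self) -> float:
        """Detachment threshold in multiples of standard gravity."""
        return self.min_acceleration / STANDARD_GRAVITY


def min_detach_acceleration(
    drop: SphericalCapDrop, liquid: LiquidProperties = WATER_LIKE_MEDIUM
) -> DetachmentResult:
    """Minimum centrifugal acceleration to detach a hanging drop.

    Static force balance along the contact line: the drop releases when
    the centrifugal body force ``rho*a_C*V`` exceeds the surface-tension
    retention force ``2*pi*r*gamma*sin(theta)``, so

    ``a_C = 2*pi*r*gamma*sin(theta) / (rho*V)``.
    """
    theta = math.radians(drop.contact_angle)
    retention = 2.0 * math.pi * drop.baseline_radius * liquid.surface_tension * math.sin(theta)
    mass = drop.mass(liquid)
    return DetachmentResult(
        min_acceleration=retention / mass,
        retention_force=retention,
        drop_weight_per_g=mass * STANDARD_GRAVITY,
    )


def worst_case_detach_acceleration(
    volume_ul: float,
    liquid: LiquidProperties = WATER_LIKE_MEDIUM,
    angle_grid_step: float = 0.1,
) -> DetachmentResult:
    """Detachment threshold maximized over all contact angles at fixed volume.

    Scans theta on a regular grid covering (0, 180) degrees with the given
    step and returns the detachment result at the maximizing angle. Because
    the required acceleration is proportional to ``r(theta)*sin(theta)`` at
    fixed volume — a smooth single-peaked function of theta — a 0.1 degree
    grid resolves the maximum far beyond any practical need.

    This is the conservative planning bound: a centrifuge setting above the
    worst case detaches the drop regardless of its (often poorly known)
    contact angle.
    """
    _require_positive("volume", volume_ul)
    if not 0.0 < angle_grid_step <= 1.0:
        raise ValueError(f"angle_grid_step must lie in (0, 1] degrees, got {angle_grid_step!r}")
    thetas = np.arange(angle_grid_step, 180.0, angle_grid_step)
    volume = volume_ul * _UL_TO_M3
    theta_rad = np.radians(thetas)
    c = np.cos(theta_rad)
    sphere_radius = (3.0 * volume / (np.pi * (2.0 - 3.0 * c + c**3))) ** (1.0 / 3.0)
    # a_C proportional to r*sin(theta) = R_s*sin^2(theta) at fixed V
    accel = (
        2.0
        * np.pi
        * sphere_radius
        * np.sin(theta_rad) ** 2
        * liquid.surface_tension
        / (liquid.density * volume)
    )
    i = int(np.argmax(accel))
    best = min_detach_acceleration(cap_from_volume_and_angle(volume_ul, float(thetas[i])), liquid)
    return DetachmentResult(
        min_acceleration=best.min_acceleration,
        retention_force=best.retention_force,
        drop_weight_per_g=best.drop_weight_per_g,
        maximizing_angle=float(thetas[i]),
    )


def rcf_to_angular_velocity(rcf: float, rotor_radius: float) -> float:
    """Angular velocity (rad/s) producing a given rcf at a given rotor radius.

    From ``a_C = R*omega**2``: ``omega = sqrt(rcf*g0 / R)``.
    """
    if rcf < 0:
        raise ValueError(f"rcf must be non-negative, got {rcf!r}")
    _require_positive("rotor_radius", rotor_radius)
    return math.sqrt(rcf * STANDARD_GRAVITY / rotor_radius)


def angular_velocity_to_rcf(omega: float, rotor_radius: float) -> float:
    """Relative centrifugal acceleration (multiples of g) at a rotor radius."""
    _require_positive("rotor_radius", rotor_radius)
    return rotor_radius * omega**2 / STANDARD_GRAVITY
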