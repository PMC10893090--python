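"""Dispense planning: dose counts, cell numbers, and microplate array layouts.

A hanging drop of target volume ``V_HD`` (microliters) is built up from
``n`` single nanodroplet ejections of calibrated volume ``V_D``
(nanoliters), ``n = V_HD / V_D`` rounded to the nearest integer. Because
the ejected droplet volume drifts with the reservoir filling level, the
calibration can carry a fill-level correction curve that rescales ``V_D``
before the division.

Array layouts follow the SBS microplate standard: 96-well format is an
8x12 grid at 9.0 mm pitch (rows A–H), 384-well format a 16x24 grid at
4.5 mm pitch (rows A–P). Coordinates are millimeters with well A1 at the
origin, x increasing with column number and y with row letter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from spherodrop.physics import (
    LiquidProperties,
    MixingConfig,
    ShearSafetyReport,
    WATER_LIKE_MEDIUM,
    shear_safety_check,
)

#: SBS plate geometry: format -> (n_rows, n_cols, pitch_mm)
PLATE_FORMATS: dict[int, tuple[int, int, float]] = {
    96: (8, 12, 9.0),
    384: (16, 24, 4.5),
}

#: Hanging-drop volume (µL) at or below which perimeter guard drops
#: (e.g. water) are recommended to buffer edge evaporation.
GUARD_BAND_VOLUME_UL = 1.5


def well_name(row: int, col: int) -> str:
    """SBS well name from 0-based row and column indices (e.g. (0, 0) -> 'A1')."""
    if row < 0 or col < 0 or row >= 26:
        raise ValueError(f"row/col out of range: ({row}, {col})")
    return f"{chr(ord('A') + row)}{col + 1}"


def parse_well_name(name: str, plate_format: int) -> tuple[int, int]:
    """Parse an SBS well name into 0-based (row, col), validating the format."""
    rows, cols, _ = _format_geometry(plate_format)
    name = name.strip()
    if not name or not name[0].isalpha() or not name[1:].isdigit():
        raise ValueError(f"malformed well name {name!r}")
    row = ord(name[0].upper()) - ord("A")
    col = int(name[1:]) - 1
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"well {name!r} outside {plate_format}-well format")
    return row, col


def _format_geometry(plate_format: int) -> tuple[int, int, float]:
    try:
        return PLATE_FORMATS[plate_format]
    except KeyError:
        raise ValueError(
            f"unsupported plate format {plate_format!r}; expected one of {sorted(PLATE_FORMATS)}"
        ) from None


@dataclass(frozen=True)
class DropletCalibration:
    """Measured single-ejection nanodroplet volume, with optional fill-level curve.

    Parameters
    ----------
    droplet_volume : float
        Measured single-ejection volume V_D (nL).
    droplet_volume_sd : float
        Standard deviation of the measurement (nL).
    fill_level_curve : tuple of (fill_volume_mL, relative_factor) pairs, optional
        Relative droplet-volume factor as a function of the reservoir fill
        volume. Factors multiply ``droplet_volume``; the curve is
        interpolated piecewise-linearly and clamped at its ends.
    """

    droplet_volume: float
    droplet_volume_sd: float = 0.0
    fill_level_curve: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.droplet_volume > 0:
            raise ValueError(f"droplet_volume must be positive, got {self.droplet_volume!r}")
        if self.droplet_volume_sd < 0:
            raise ValueError("droplet_volume_sd must be non-negative")
        if self.fill_level_curve is not None:
            if len(self.fill_level_curve) < 2:
                raise ValueError("fill_level_curve needs at least two points")
            fills = [f for f, _ in self.fill_level_curve]
            factors = [fac for _, fac in self.fill_level_curve]
            if any(fac <= 0 for fac in factors):
                raise ValueError("fill_level_curve factors must be strictly positive")
            increasing = all(a < b for a, b in zip(fills, fills[1:]))
            decreasing = all(a > b for a, b in zip(fills, fills[1:]))
            if not (increasing or decreasing):
                raise ValueError("fill_level_curve fill volumes must be strictly monotone")

    def effective_droplet_volume(self, fill_volume_ml: float | None = None) -> float:
        """Droplet volume (nL) corrected for the reservoir fill level.

        Returns ``droplet_volume`` unchanged when no curve or no fill
        volume is supplied; otherwise applies the interpolated factor,
        clamped at the table ends.
        """
        if self.fill_level_curve is None or fill_volume_ml is None:
            return self.droplet_volume
        pts = sorted(self.fill_level_curve)
        fills = np.array([f for f, _ in pts])
        factors = np.array([fac for _, fac in pts])
        factor = float(np.interp(fill_volume_ml, fills, factors))
        return self.droplet_volume * factor


@dataclass(frozen=True)
class HangingDropSpec:
    """Target hanging-drop array: drop volume, cell concentration, plate layout."""

    target_volume: float  # µL per hanging drop
    cell_concentration: float = 3.2e4  # cells per mL of suspension
    plate_format: int = 384
    n_plates: int = 1

    def __post_init__(self) -> None:
        if not self.target_volume > 0:
            raise ValueError(f"target_volume must be positive, got {self.target_volume!r}")
        if self.cell_concentration < 0:
            raise ValueError("cell_concentration must be non-negative")
        _format_geometry(self.plate_format)
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")


@dataclass(frozen=True)
class PlatePosition:
    """One dispense target: plate index, SBS well name, and mm coordinates."""

    plate: int
    well: str
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class DispensePlan:
    """Complete dispense plan for a hanging-drop array run."""

    positions: tuple[PlatePosition, ...]
    doses_per_position: int
    expected_cells_per_drop: float
    target_volume: float  # µL
    total_doses: int = field(init=False)

    def __post_init__(self) -> None:
        if self.doses_per_position < 1:
            raise ValueError("doses_per_position must be >= 1")
        object.__setattr__(self, "total_doses", self.doses_per_position * len(self.positions))


def doses_per_drop(
    target_volume_ul: float,
    calibration: DropletCalibration,
    fill_volume_ml: float | None = None,
) -> int:
    """Number of nanodroplet ejections needed for one hanging drop.

    ``n = round_half_up(V_HD / V_D')`` with ``V_D'`` the fill-level
    corrected droplet volume; always at least 1.

    Raises
    ------
    ValueError
        If the target volume is below half the single-droplet volume, i.e.
        below the dispenser's resolution.
    """
    if not target_volume_ul > 0:
        raise ValueError(f"target_volume must be positive, got {target_volume_ul!r}")
    effective_nl = calibration.effective_droplet_volume(fill_volume_ml)
    ratio = target_volume_ul * 1e3 / effective_nl
    if ratio < 0.5:
        raise ValueError(
            f"target volume {target_volume_ul} µL is below single-droplet resolution "
            f"({effective_nl} nL per ejection)"
        )
    return max(1, math.floor(ratio + 0.5))


def expected_cells_per_drop(spec: HangingDropSpec) -> float:
    """Expected cell count per hanging drop: concentration x drop volume."""
    return spec.cell_concentration * spec.target_volume * 1e-3  # cells/mL * µL * mL/µL


def generate_array(
    spec: HangingDropSpec,
    calibration: DropletCalibration | None = None,
    fill_volume_ml: float | None = None,
    serpentine: bool = False,
) -> DispensePlan:
    """Generate the SBS-format dispense plan for a hanging-drop array.

    Positions are ordered row-major from A1 (optionally serpentine: even
    rows traversed right-to-left), repeated for each plate. Dose counts
    come from the droplet calibration when given, otherwise one dose per
    position.
    """
    rows, cols, pitch = _format_geometry(spec.plate_format)
    positions: list[PlatePosition] = []
    for plate in range(spec.n_plates):
        for row in range(rows):
            col_order = range(cols)
            if serpentine and row % 2 == 1:
                col_order = range(cols - 1, -1, -1)
            for col in col_order:
                positions.append(
                    PlatePosition(
                        plate=plate,
                        well=well_name(row, col),
                        x_mm=col * pitch,
                        y_mm=row * pitch,
                    )
                )
    doses = (
        doses_per_drop(spec.target_volume, calibration, fill_volume_ml)
        if calibration is not None
        else 1
    )
    return DispensePlan(
        positions=tuple(positions),
        doses_per_position=doses,
        expected_cells_per_drop=expected_cells_per_drop(spec),
        target_volume=spec.target_volume,
    )


def guard_band_recommendation(spec: HangingDropSpec) -> list[PlatePosition]:
    """Perimeter wells to fill with water for small hanging drops.

    Drops at the array boundary evaporate faster; for target volumes at or
    below 1.5 µL the recommendation is to surround the array with empty
    (water) drops. Returns the perimeter wells of each plate, or an empty
    list for larger drops.
    """
    if spec.target_volume > GUARD_BAND_VOLUME_UL:
        return []
    rows, cols, pitch = _format_geometry(spec.plate_format)
    out: list[PlatePosition] = []
    for plate in range(spec.n_plates):
        for row in range(rows):
            for col in range(cols):
                if row in (0, rows - 1) or col in (0, cols - 1):
                    out.append(
                        PlatePosition(
                            plate=plate,
                            well=well_name(row, col),
                            x_mm=col * pitch,
                            y_mm=row * pitch,
                        )
                    )
    return out


@dataclass(frozen=True)
class MixingPlanReport:
    """Feasibility of a reservoir mixing plan plus its shear safety check."""

    feasible: bool
    exchanged_volume_ml: float
    round_trip_time_s: float
    cycle_period_s: float
    shear: ShearSafetyReport
    reason: str = ""


def mixing_plan_check(
    reservoir_volume_ml: float,
    mixing: MixingConfig,
    liquid: LiquidProperties = WATER_LIKE_MEDIUM,
) -> MixingPlanReport:
    """Check that a mixing configuration can move the requested volume.

    Each cycle aspirates and dispenses ``exchanged_fraction`` of the
    reservoir, so the round trip moves twice the exchanged volume through
    the tube. Feasible iff the cycle period ``1/frequency`` is at least
    the round-trip time at the configured flow rate. A shear safety check
    is attached.
    """
    if not reservoir_volume_ml > 0:
        raise ValueError(f"reservoir_volume must be positive, got {reservoir_volume_ml!r}")
    exchanged_ml = mixing.exchanged_fraction * reservoir_volume_ml
    period = 1.0 / mixing.frequency
    if mixing.flow_rate <= 0:
        return MixingPlanReport(
            feasible=False,
            exchanged_volume_ml=exchanged_ml,
            round_trip_time_s=math.inf,
            cycle_period_s=period,
            shear=shear_safety_check(mixing, liquid),
            reason="zero flow rate cannot move any volume",
        )
    round_trip = 2.0 * exchanged_ml * 1e-6 / mixing.flow_rate
    feasible = round_trip <= period
    reason = (
        ""
        if feasible
        else (
            f"round trip of {round_trip:.2f} s for {exchanged_ml:.2f} mL exceeds the "
            f"{period:.2f} s cycle period"
        )
    )
    return MixingPlanReport(
        feasible=feasible,
        exchanged_volume_ml=exchanged_ml,
        round_trip_time_s=round_trip,
        cycle_period_s=period,
        shear=shear_safety_check(mixing, liquid),
        reason=reason,
    )
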