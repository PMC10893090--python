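"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Three generators emulate the data the workflow consumes, each a pure
function of its spec (including the seed), so identical calls give
bit-identical outputs:

* :func:`render_droplet` — a strobe image of a free-flying nanodroplet:
  a dark antialiased disk (the projected silhouette of a sphere of the
  requested volume) on a bright field, plus a matching clean background,
  optional Gaussian intensity noise and satellite droplets.
* :func:`render_spheroid_plate` — per-well brightfield micrographs of
  spheroids with diameters drawn from a truncated normal distribution at
  a requested mean and CV; a configurable fraction of wells is blank
  (failed drops) or contains loose low-solidity aggregates (failed
  spheroid formation).
* :func:`generate_dispense_log` — a per-dose nanodroplet volume log with
  a deterministic fill-level drift plus seeded jitter, paired with the
  calibration table a planner can use to invert the drift.

The renderers produce idealized images: no optical point-spread function,
no illumination gradients, no debris. They exercise the geometry and the
statistics of the analysis chain, not its robustness to real microscopy
artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spherodrop.planner import DropletCalibration, well_name
from spherodrop.volumetry import StrobeImage
from spherodrop.morphometry import Micrograph

_UM3_PER_NL = 1e6


def sphere_radius_um(volume_nl: float) -> float:
    """Radius (µm) of a sphere with the given volume (nL)."""
    return (3.0 * volume_nl * _UM3_PER_NL / (4.0 * math.pi)) ** (1.0 / 3.0)


def _disk(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
) -> np.ndarray:
    """Antialiased disk coverage map in [0, 1] (1 inside, 0 outside)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    dist = np.hypot(yy - center[0], xx - center[1])
    return np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


@dataclass(frozen=True)
class DropletRenderSpec:
    """Recipe for one synthetic droplet strobe image."""

    true_volume: float = 50.0  # nL
    pixel_size: float = 10.0  # µm/px
    image_size: int = 96  # px (square)
    noise_sd: float = 0.01  # intensity fraction of full scale
    n_satellites: int = 0
    satellite_volume_fraction: float = 0.05  # of the main volume, per satellite
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_volume > 0:
            raise ValueError("true_volume must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_satellites < 0:
            raise ValueError("n_satellites must be non-negative")
        if not 0 < self.satellite_volume_fraction < 1:
            raise ValueError("satellite_volume_fraction must lie in (0, 1)")


def render_droplet(spec: DropletRenderSpec) -> tuple[StrobeImage, dict]:
    """Render a droplet strobe image with known ground truth.

    Returns the image (with its clean background attached) and a truth
    record with the true volume, silhouette radius, and satellite volumes.

    Raises
    ------
    ValueError
        If the silhouette does not fit the frame with a 5 px margin.
    """
    radius_px = sphere_radius_um(spec.true_volume) / spec.pixel_size
    n = spec.image_size
    if 2 * radius_px + 10 > n:
        raise ValueError(
            f"sphere of radius {radius_px:.1f} px does not fit a {n} px frame "
            "with a 5 px margin"
        )
    rng = np.random.default_rng(spec.seed)
    bg_level, drop_level = 0.85, 0.15
    background = np.full((n, n), bg_level)
    coverage = _disk((n, n), (n / 2.0, n / 2.0), radius_px)

    satellite_volumes: list[float] = []
    if spec.n_satellites:
        sat_radius = sphere_radius_um(
            spec.true_volume * spec.satellite_volume_fraction
        ) / spec.pixel_size
        placed: list[tuple[float, float, float]] = [(n / 2.0, n / 2.0, radius_px)]
        for _ in range(spec.n_satellites):
            for _attempt in range(200):
                cy = rng.uniform(sat_radius + 2, n - sat_radius - 2)
                cx = rng.uniform(sat_radius + 2, n - sat_radius - 2)
                if all(
                    math.hypot(cy - py, cx - px) > sat_radius + pr + 3
                    for py, px, pr in placed
                ):
                    placed.append((cy, cx, sat_radius))
                    coverage = np.maximum(coverage, _disk((n, n), (cy, cx), sat_radius))
                    satellite_volumes.append(
                        spec.true_volume * spec.satellite_volume_fraction
                    )
                    break
            else:
                raise ValueError("could not place satellites without overlap")

    image = background + (drop_level - bg_level) * coverage
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    truth = {
        "true_volume_nl": spec.true_volume,
        "silhouette_radius_px": radius_px,
        "satellite_volumes_nl": tuple(satellite_volumes),
    }
    return (
        StrobeImage(pixels=image, pixel_size=spec.pixel_size, background=background),
        truth,
    )


@dataclass(frozen=True)
class PlateRenderSpec:
    """Recipe for a plate of synthetic per-well spheroid micrographs."""

    n_wells: int = 384
    mean_diameter: float = 150.0  # µm
    cv_percent: float = 7.4
    missing_fraction: float = 0.0
    irregular_fraction: float = 0.0
    pixel_size: float = 2.0  # µm/px
    image_size: int = 256  # px (square)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if not self.mean_diameter > 0:
            raise ValueError("mean_diameter must be positive")
        if self.cv_percent < 0:
            raise ValueError("cv_percent must be non-negative")
        for name in ("missing_fraction", "irregular_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_fraction + self.irregular_fraction > 1.0:
            raise ValueError("missing + irregular fractions exceed 1")


def _render_spheroid_image(
    n: int, diameter_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Brightfield-style well image: dark compact disk with a darker rim."""
    bg = 0.85
    center = (n / 2.0 + rng.uniform(-3, 3), n / 2.0 + rng.uniform(-3, 3))
    body = _disk((n, n), center, diameter_px / 2.0)
    rim = body - _disk((n, n), center, max(diameter_px / 2.0 - 3.0, 1.0))
    image = bg - 0.45 * body - 0.25 * rim
    return image


def _render_aggregate_image(n: int, rng: np.random.Generator) -> np.ndarray:
    """Loose scattered-blob image: low-solidity failed aggregate."""
    bg = 0.85
    image = np.full((n, n), bg)
    n_blobs = rng.integers(8, 15)
    for _ in range(n_blobs):
        r = rng.uniform(2.0, 5.0)
        cy = rng.uniform(n * 0.2, n * 0.8)
        cx = rng.uniform(n * 0.2, n * 0.8)
        image -= 0.5 * _disk((n, n), (cy, cx), r)
    return np.clip(image, 0.0, 1.0)


def render_spheroid_plate(spec: PlateRenderSpec) -> tuple[list[Micrograph], pd.DataFrame]:
    """Render per-well spheroid micrographs with a matching truth table.

    Diameters are drawn from Normal(mean, cv*mean/100) truncated at ±3 sd.
    ``missing_fraction`` of wells are blank and ``irregular_fraction``
    contain loose low-solidity aggregates; assignments are seeded draws.
    The truth table has columns ``well``, ``class`` ("spheroid", "blank",
    "aggregate"), and ``true_diameter_um`` (NaN unless a spheroid).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    sd = spec.cv_percent * spec.mean_diameter / 100.0
    images: list[Micrograph] = []
    rows: list[dict] = []
    classes = rng.choice(
        ["blank", "aggregate", "spheroid"],
        size=spec.n_wells,
        p=[
            spec.missing_fraction,
            spec.irregular_fraction,
            1.0 - spec.missing_fraction - spec.irregular_fraction,
        ],
    )
    for i in range(spec.n_wells):
        wid = well_name(i // 24, i % 24) if spec.n_wells <= 384 else f"W{i + 1}"
        cls = classes[i]
        if cls == "blank":
            pixels = np.full((n, n), 0.85)
            true_d = math.nan
        elif cls == "aggregate":
            pixels = _render_aggregate_image(n, rng)
            true_d = math.nan
        else:
            true_d = float(np.clip(rng.normal(spec.mean_diameter, sd),
                                   spec.mean_diameter - 3 * sd,
                                   spec.mean_diameter + 3 * sd))
            d_px = true_d / spec.pixel_size
            if d_px + 10 > n:
                raise ValueError(
                    f"spheroid of {true_d:.0f} µm does not fit a {n} px frame at "
                    f"{spec.pixel_size} µm/px"
                )
            pixels = _render_spheroid_image(n, d_px, rng)
        images.append(Micrograph(pixels=pixels, pixel_size=spec.pixel_size, well_id=wid))
        rows.append({"well": wid, "class": cls, "true_diameter_um": true_d})
    return images, pd.DataFrame(rows)


def generate_dispense_log(
    n_drops: int,
    base_droplet_nl: float = 50.0,
    fill_decay_per_ml: float = 0.0,
    doses_per_drop: int = 40,
    initial_fill_ml: float = 5.0,
    jitter_sd_nl: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, DropletCalibration]:
    """Simulate a dispense run with fill-level-dependent droplet volume.

    The ejected droplet volume shrinks linearly with the cumulative volume
    dispensed: ``v = base * (1 - fill_decay_per_ml * dispensed_mL)``, plus
    optional seeded Gaussian jitter. Returns a per-dose log (columns
    ``drop``, ``dose``, ``fill_ml``, ``droplet_nl``) and the matching
    :class:`~spherodrop.planner.DropletCalibration` whose fill-level curve
    inverts the drift.
    """
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    if not base_droplet_nl > 0:
        raise ValueError("base_droplet_nl must be positive")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    dispensed_ml = 0.0
    for drop in range(n_drops):
        for dose in range(doses_per_drop):
            factor = max(1.0 - fill_decay_per_ml * dispensed_ml, 0.05)
            vol = base_droplet_nl * factor
            if jitter_sd_nl > 0:
                vol += rng.normal(0.0, jitter_sd_nl)
            rows.append(
                {
                    "drop": drop,
                    "dose": dose,
                    "fill_ml": initial_fill_ml - dispensed_ml,
                    "droplet_nl": vol,
                }
            )
            dispensed_ml += vol * 1e-6  # nL -> mL
    log = pd.DataFrame(rows)
    # calibration curve: droplet-volume factor vs reservoir fill volume
    fills = np.linspace(initial_fill_ml - dispensed_ml, initial_fill_ml, 9)
    curve = tuple(
        (float(f), max(1.0 - fill_decay_per_ml * (initial_fill_ml - float(f)), 0.05))
        for f in fills
    )
    calibration = DropletCalibration(
        droplet_volume=base_droplet_nl,
        droplet_volume_sd=jitter_sd_nl,
        fill_level_curve=curve,
    )
    return log, calibration
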