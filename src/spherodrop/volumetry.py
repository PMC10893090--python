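"""Nanodroplet volumetry from calibrated strobe images.

Free-flying droplets are imaged stroboscopically against a bright
background. The volume of a droplet is estimated in three steps:

1. absolute-difference background subtraction,
2. segmentation (Otsu threshold, hole filling, connected components;
   the largest sufficiently large component is the droplet, smaller
   ones are satellites),
3. cylinder-stack integration: each pixel row of the droplet mask is
   treated as a cylinder of height one pixel whose diameter is the row's
   pixel count, and the cylinder volumes are summed:

   ``V = sum_i pi * (w_i / 2)**2 * s**3``

   with ``w_i`` the row width in pixels and ``s`` the pixel size.

This assumes the droplet is rotationally symmetric about the vertical
(flight) axis, which holds well for nanoliter droplets in free flight.
Volumes are reported in nanoliters (1 nL = 1e6 µm^3).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)

#: Plausible single-ejection volume range (nL) of the nanoliter dispenser.
DEFAULT_EXPECTED_RANGE_NL = (40.0, 100.0)

_UM3_PER_NL = 1e6


@dataclass(frozen=True)
class StrobeImage:
    """A calibrated grayscale strobe image of a free-flying droplet.

    Parameters
    ----------
    pixels : ndarray
        2-D grayscale intensity array.
    pixel_size : float
        Isotropic pixel size (µm per pixel).
    background : ndarray, optional
        Droplet-free reference image of identical shape.
    """

    pixels: np.ndarray
    pixel_size: float
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size!r}")
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.background is not None and self.background.shape != self.pixels.shape:
            raise ValueError(
                f"background shape {self.background.shape} does not match "
                f"image shape {self.pixels.shape}"
            )


@dataclass(frozen=True)
class DropletSegment:
    """Segmented droplet: main mask, per-row widths, and satellite masks."""

    mask: np.ndarray
    row_widths: np.ndarray
    satellite_masks: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        widths = self.mask.sum(axis=1)
        if not np.array_equal(widths, self.row_widths):
            raise ValueError("row_widths inconsistent with mask")


@dataclass(frozen=True)
class VolumeEstimate:
    """Volume estimate (nL), optionally over an image sequence."""

    volume: float
    per_image_volumes: tuple[float, ...] = field(default_factory=tuple)
    sd: float = 0.0
    satellite_volumes: tuple[float, ...] = ()
    plausible: bool = True

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be non-negative")


def subtract_background(image: StrobeImage) -> np.ndarray:
    """Absolute-difference background subtraction.

    Returns ``|image - background|`` as a float array, so the droplet is
    bright on a near-zero background regardless of imaging polarity.
    """
    if image.background is None:
        raise ValueError("StrobeImage has no background reference")
    fg = np.abs(
        np.asarray(image.pixels, dtype=float) - np.asarray(image.background, dtype=float)
    )
    return fg


def segment_droplet(
    foreground: np.ndarray,
    min_area_px: int = 50,
    threshold: float | None = None,
) -> DropletSegment:
    """Segment the main droplet and any satellites from a foreground image.

    Thresholds the foreground (Otsu by default, or a fixed ``threshold``),
    fills holes, and labels connected components. The largest component
    with area >= ``min_area_px`` is the droplet; all other components of
    at least that area are reported as satellites.

    Raises
    ------
    ValueError
        If no component reaches ``min_area_px`` ("no droplet detected").
    """
    fg = np.asarray(foreground, dtype=float)
    if fg.size == 0:
        raise ValueError("empty foreground image")
    if threshold is None:
        if np.ptp(fg) == 0:
            raise ValueError("no droplet detected: foreground is constant")
        threshold = threshold_otsu(fg)
    binary = ndimage.binary_fill_holes(fg > threshold)
    labels = label(binary, connectivity=2)
    regions = [r for r in regionprops(labels) if r.area >= min_area_px]
    if not regions:
        raise ValueError(f"no droplet detected: no component with area >= {min_area_px} px")
    regions.sort(key=lambda r: r.area, reverse=True)
    main = labels == regions[0].label
    satellites = tuple(labels == r.label for r in regions[1:])
    return DropletSegment(
        mask=main,
        row_widths=main.sum(axis=1),
        satellite_masks=satellites,
    )


def _stack_volume_nl(mask: np.ndarray, pixel_size_um: float) -> float:
    widths = mask.sum(axis=1).astype(float)
    volume_px3 = float(np.sum(np.pi * (widths / 2.0) ** 2))  # row height = 1 px
    return volume_px3 * pixel_size_um**3 / _UM3_PER_NL


def volume_from_segment(segment: DropletSegment, pixel_size_um: float) -> VolumeEstimate:
    """Cylinder-stack volume of a segmented droplet.

    Each mask row becomes a cylinder of one-pixel height whose diameter is
    the row's pixel count; satellite volumes are computed the same way but
    excluded from the main estimate.
    """
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size_um!r}")
    if not segment.mask.any():
        raise ValueError("empty droplet mask")
    main = _stack_volume_nl(segment.mask, pixel_size_um)
    satellites = tuple(_stack_volume_nl(m, pixel_size_um) for m in segment.satellite_masks)
    return VolumeEstimate(
        volume=main,
        per_image_volumes=(main,),
        satellite_volumes=satellites,
    )


def estimate_volume(image: StrobeImage, min_area_px: int = 50) -> VolumeEstimate:
    """Full single-image pipeline: subtract background, segment, integrate."""
    fg = subtract_background(image)
    segment = segment_droplet(fg, min_area_px=min_area_px)
    return volume_from_segment(segment, image.pixel_size)


def estimate_volume_sequence(
    images: list[StrobeImage],
    expected_range_nl: tuple[float, float] = DEFAULT_EXPECTED_RANGE_NL,
    min_area_px: int = 50,
) -> VolumeEstimate:
    """Estimate the droplet volume over a strobe image sequence.

    Per-image volumes are averaged; images where segmentation fails are
    skipped with a warning. The plausibility flag is set when the mean
    falls inside ``expected_range_nl`` (default 40–100 nL, the dispenser's
    working range).
    """
    if not images:
        raise ValueError("need at least one image")
    volumes: list[float] = []
    satellite_volumes: list[float] = []
    for i, image in enumerate(images):
        try:
            est = estimate_volume(image, min_area_px=min_area_px)
        except ValueError as exc:
            logger.warning("image %d skipped: %s", i, exc)
            continue
        volumes.append(est.volume)
        satellite_volumes.extend(est.satellite_volumes)
    if not volumes:
        raise ValueError("segmentation failed for every image in the sequence")
    mean = math.fsum(volumes) / len(volumes)
    sd = statistics.stdev(volumes) if len(volumes) > 1 else 0.0
    lo, hi = expected_range_nl
    return VolumeEstimate(
        volume=mean,
        per_image_volumes=tuple(volumes),
        sd=sd,
        satellite_volumes=tuple(satellite_volumes),
        plausible=lo <= mean <= hi,
    )
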