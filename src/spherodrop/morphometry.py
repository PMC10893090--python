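"""Spheroid morphometry and workflow efficiency statistics.

Spheroids imaged in brightfield appear as dark, compact, roughly circular
objects. Each micrograph is segmented (Otsu threshold on the dark side,
hole filling, largest connected component) and the object is accepted as a
spheroid when it is both large enough and compact enough:

* equivalent diameter ``d = 2*sqrt(A/pi)`` at least ``min_diameter_um``
  (default 50 µm), and
* solidity (region area / convex hull area) at least ``min_solidity``
  (default 0.85) — loose cell aggregates have ragged, low-solidity
  outlines and are rejected.

Size consistency is summarized by the coefficient of variation
``CV = 100 * sd / mean`` over detected diameters (sample sd, n-1
denominator). Workflow efficiency distinguishes drop generation (printed
drops / target positions) from spheroid generation (formed spheroids /
target positions), both in percent.

Two-group comparisons follow a normality-gated decision tree: if both
groups pass the D'Agostino–Pearson normality test, a two-sided t-test is
used; otherwise a two-sided Mann–Whitney U test. Significance labels:
p >= 0.05 "n.s.", p < 0.05 "*", p < 0.001 "**", p < 0.0001 "***".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass(frozen=True)
class Micrograph:
    """A calibrated grayscale micrograph of one well's spheroid."""

    pixels: np.ndarray
    pixel_size: float  # µm per pixel
    well_id: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size!r}")
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("pixels must be a 2-D array")


@dataclass(frozen=True)
class SpheroidMeasurement:
    """Per-well spheroid measurement; ``detected=False`` means no spheroid."""

    area: float  # µm²
    equivalent_diameter: float  # µm
    solidity: float
    detected: bool
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if self.detected and not math.isclose(
            self.equivalent_diameter, 2.0 * math.sqrt(self.area / math.pi), rel_tol=1e-9
        ):
            raise ValueError("equivalent_diameter inconsistent with area")


@dataclass(frozen=True)
class SizeStats:
    """Spheroid diameter statistics: mean, sample sd, CV in percent."""

    n: int
    mean: float  # µm
    sd: float  # µm
    cv_percent: float


@dataclass(frozen=True)
class EfficiencyReport:
    """Drop- and spheroid-generation efficiency of one array run."""

    target_count: int
    printed_count: int
    spheroid_count: int
    drop_generation_efficiency: float  # %
    spheroid_generation_efficiency: float  # %


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the same area: ``d = 2*sqrt(A/pi)``."""
    if area_um2 < 0:
        raise ValueError(f"area must be non-negative, got {area_um2!r}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def segment_spheroid(
    image: Micrograph,
    min_diameter_um: float = 50.0,
    min_solidity: float = 0.85,
    min_class_separation: float = 4.0,
) -> SpheroidMeasurement:
    """Segment and gate the spheroid in a single-well micrograph.

    The darker side of an Otsu split is taken as foreground (brightfield
    convention), holes are filled, and the largest connected component is
    measured. ``detected`` is true iff the equivalent diameter and
    solidity both clear their thresholds; an undetected well is a valid
    outcome (blank drop, loose aggregate), not an error.

    Otsu always produces a split, even on a featureless image, so the
    split is accepted only when the two intensity classes separate by at
    least ``min_class_separation`` times the larger within-class spread;
    pure noise gives a ratio near 2.7 while real object/background
    contrast is far higher.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    if np.ptp(pixels) == 0:
        return SpheroidMeasurement(
            area=0.0, equivalent_diameter=0.0, solidity=0.0, detected=False,
            well_id=image.well_id,
        )
    threshold = threshold_otsu(pixels)
    dark, bright = pixels[pixels < threshold], pixels[pixels >= threshold]
    if dark.size == 0 or bright.size == 0:
        return SpheroidMeasurement(
            area=0.0, equivalent_diameter=0.0, solidity=0.0, detected=False,
            well_id=image.well_id,
        )
    within = max(dark.std(), bright.std(), 1e-12)
    if (bright.mean() - dark.mean()) / within < min_class_separation:
        return SpheroidMeasurement(
            area=0.0, equivalent_diameter=0.0, solidity=0.0, detected=False,
            well_id=image.well_id,
        )
    binary = ndimage.binary_fill_holes(pixels < threshold)
    labels = label(binary, connectivity=2)
    regions = regionprops(labels)
    if not regions:
        return SpheroidMeasurement(
            area=0.0, equivalent_diameter=0.0, solidity=0.0, detected=False,
            well_id=image.well_id,
        )
    main = max(regions, key=lambda r: r.area)
    area_um2 = float(main.area) * image.pixel_size**2
    diameter = equivalent_diameter(area_um2)
    solidity = float(main.solidity)
    detected = diameter >= min_diameter_um and solidity >= min_solidity
    return SpheroidMeasurement(
        area=area_um2,
        equivalent_diameter=diameter,
        solidity=solidity,
        detected=detected,
        well_id=image.well_id,
    )


def size_stats(measurements: Sequence[SpheroidMeasurement]) -> SizeStats:
    """Mean, sample sd, and CV (%) of detected spheroid diameters.

    Undetected wells are excluded. Requires at least two detected
    spheroids (sample sd needs n >= 2) and a nonzero mean.
    """
    diameters = [m.equivalent_diameter for m in measurements if m.detected]
    if len(diameters) < 2:
        raise ValueError(
            f"need at least 2 detected spheroids for size statistics, got {len(diameters)}"
        )
    mean = float(np.mean(diameters))
    sd = float(np.std(diameters, ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean diameter")
    return SizeStats(n=len(diameters), mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def efficiency_report(target: int, printed: int, detected_spheroids: int) -> EfficiencyReport:
    """Drop- and spheroid-generation efficiency relative to the target count.

    ``drop_generation_efficiency = 100 * printed / target`` and
    ``spheroid_generation_efficiency = 100 * detected / target``.
    """
    if target <= 0:
        raise ValueError(f"target count must be positive, got {target!r}")
    if not 0 <= printed <= target:
        raise ValueError(f"printed count {printed!r} outside [0, target]")
    if not 0 <= detected_spheroids <= target:
        raise ValueError(f"spheroid count {detected_spheroids!r} outside [0, target]")
    return EfficiencyReport(
        target_count=target,
        printed_count=printed,
        spheroid_count=detected_spheroids,
        drop_generation_efficiency=100.0 * printed / target,
        spheroid_generation_efficiency=100.0 * detected_spheroids / target,
    )


def significance_label(p_value: float) -> str:
    """Map a p-value to the conventional significance label."""
    if p_value < 1e-4:
        return "***"
    if p_value < 1e-3:
        return "**"
    if p_value < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    """Result of a normality-gated two-group comparison."""

    test: str  # "t-test" or "mann-whitney"
    p_value: float
    label: str
    normality_p: tuple[float, float]


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-sided two-group comparison with a normality-gated test choice.

    Both groups are tested for normality (D'Agostino–Pearson). If both
    pass at ``alpha_normality``, a two-sided independent t-test is used;
    otherwise a two-sided Mann–Whitney U test. Groups need n >= 8 (the
    normality test's minimum); for smaller samples choose a test
    explicitly with :func:`scipy.stats.ttest_ind` or
    :func:`scipy.stats.mannwhitneyu`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 8 or len(b) < 8:
        raise ValueError(
            "normality-gated comparison needs n >= 8 per group; "
            "choose the test explicitly for smaller samples"
        )
    norm_a = stats.normaltest(a).pvalue
    norm_b = stats.normaltest(b).pvalue
    if np.array_equal(a, b):
        # identical samples: no difference by construction
        return GroupComparison(
            test="t-test", p_value=1.0, label="n.s.",
            normality_p=(float(norm_a), float(norm_b)),
        )
    if norm_a >= alpha_normality and norm_b >= alpha_normality:
        test = "t-test"
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        test = "mann-whitney"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison(
        test=test, p_value=p, label=significance_label(p),
        normality_p=(float(norm_a), float(norm_b)),
    )
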