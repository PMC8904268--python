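"""Percent-positive-nuclei quantification in fluorescence images.

Pipeline: Otsu segmentation of the nuclei channel (holes filled,
8-connected components, size-gated), a marker intensity threshold
calibrated as an upper quantile of a negative-control image, size-gated
marker objects, and a localization-aware rule associating marker signal
with nuclei (overlap of the nucleus footprint, of a perinuclear ring, or
proximity to the nucleus boundary).  The reported quantity is
``n_positive / n_nuclei`` per image.

Rasters are row-major with origin at top-left; all geometry is in pixel
units.  Touching nuclei are not split (no watershed): the upstream
protocol assumes well-separated nuclei and the synthetic generator
renders non-overlapping fields by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .stats_tests import TestResult, dunn_posthoc, kruskal_wallis, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "ImageChannelSet",
    "ThresholdCalibration",
    "NucleusSet",
    "QuantResult",
    "SegmentationParams",
    "segment_nuclei",
    "calibrate_marker_threshold",
    "marker_objects",
    "associate_nuclei",
    "percent_positive",
    "compare_image_groups",
]

Localization = Literal["nuclear", "cytoplasmic", "apical"]


class ImageQuantError(ValueError):
    pass


@dataclass(frozen=True)
class ImageChannelSet:
    """Matched nuclei and marker intensity rasters with an optional
    exclusion mask (True = excluded) and physical pixel size."""

    nuclei_channel: np.ndarray
    marker_channel: np.ndarray
    exclusion_mask: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        nuc, mk = self.nuclei_channel, self.marker_channel
        if nuc.ndim != 2 or mk.ndim != 2:
            raise ImageQuantError("channels must be 2-D rasters")
        if nuc.shape != mk.shape:
            raise ImageQuantError(
                f"channel shapes differ: {nuc.shape} vs {mk.shape}"
            )
        if (nuc < 0).any() or (mk < 0).any():
            raise ImageQuantError("intensities must be non-negative")
        if self.exclusion_mask is not None:
            if self.exclusion_mask.shape != nuc.shape:
                raise ImageQuantError("exclusion mask shape mismatch")
            if self.exclusion_mask.dtype != bool:
                object.__setattr__(
                    self, "exclusion_mask", self.exclusion_mask != 0
                )

    def included(self) -> np.ndarray:
        if self.exclusion_mask is None:
            return np.ones(self.nuclei_channel.shape, dtype=bool)
        return ~self.exclusion_mask


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus size gate (pixel areas) for connected components."""

    nucleus_min_area: int = 20
    nucleus_max_area: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_min_area <= self.nucleus_max_area:
            raise ImageQuantError("require 0 < nucleus_min_area <= nucleus_max_area")


@dataclass(frozen=True)
class ThresholdCalibration:
    """Marker intensity threshold and marker-object size gate, with the
    localization class governing nucleus association."""

    marker_threshold: float
    size_min: int = 20
    size_max: int = 5000
    localization: Localization = "nuclear"
    f_nuc: float = 0.3
    f_cyt: float = 0.1
    ring_width: int = 4
    apical_distance: int = 6

    def __post_init__(self) -> None:
        if self.marker_threshold < 0:
            raise ImageQuantError("marker_threshold must be >= 0")
        if self.size_min > self.size_max:
            raise ImageQuantError("size_min must be <= size_max")
        if self.localization not in ("nuclear", "cytoplasmic", "apical"):
            raise ImageQuantError(f"unknown localization {self.localization!r}")


@dataclass(frozen=True)
class NucleusSet:
    """Labeled nuclei (0 = background) with centroids and pixel areas."""

    labels: np.ndarray
    centroids: tuple[tuple[float, float], ...]
    areas: tuple[int, ...]
    flagged_empty: bool = False

    @property
    def n_nuclei(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class QuantResult:
    """Per-image positive-nucleus counts and fraction."""

    n_nuclei: int
    n_positive: int
    fraction: float
    flagged: bool = False
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= max(self.n_nuclei, 0):
            raise ImageQuantError("require 0 <= n_positive <= n_nuclei")
        if not 0.0 <= self.fraction <= 1.0:
            raise ImageQuantError("fraction must be in [0, 1]")


def segment_nuclei(
    img: ImageChannelSet, params: SegmentationParams | None = None
) -> NucleusSet:
    """Otsu threshold + hole filling + 8-connected size-gated labeling."""
    params = params or SegmentationParams()
    included = img.included()
    if not included.any():
        raise ImageQuantError("all pixels excluded; nothing to segment")
    pixels = img.nuclei_channel[included]
    if np.ptp(pixels) == 0:
        # constant field (e.g. blank image): no nuclei, flagged
        logger.warning("segment_nuclei: constant nuclei channel; 0 nuclei")
        return NucleusSet(
            labels=np.zeros(img.nuclei_channel.shape, dtype=np.int32),
            centroids=(), areas=(), flagged_empty=True,
        )
    thr = threshold_otsu(pixels)
    mask = (img.nuclei_channel > thr) & included
    mask = ndi.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    centroids: list[tuple[float, float]] = []
    areas: list[int] = []
    nxt = 1
    for prop in regionprops(labels):
        if params.nucleus_min_area <= prop.area <= params.nucleus_max_area:
            out[labels == prop.label] = nxt
            centroids.append(tuple(prop.centroid))
            areas.append(int(prop.area))
            nxt += 1
    return NucleusSet(
        labels=out,
        centroids=tuple(centroids),
        areas=tuple(areas),
        flagged_empty=nxt == 1,
    )


def calibrate_marker_threshold(
    negative_control: ImageChannelSet,
    quantile: float = 0.999,
    *,
    min_pixels: int = 10_000,
    **calibration_kwargs,
) -> ThresholdCalibration:
    """Set the marker threshold to an upper quantile of the negative
    control's marker intensities over non-excluded pixels.

    Extra keyword arguments (size gate, localization, association
    fractions) are forwarded to :class:`ThresholdCalibration`.
    """
    if not 0 < quantile < 1:
        raise ImageQuantError(f"quantile must be in (0, 1), got {quantile}")
    included = negative_control.included()
    pixels = negative_control.marker_channel[included]
    if pixels.size < min_pixels:
        raise ImageQuantError(
            f"negative control has only {pixels.size} non-excluded pixels "
            f"(need >= {min_pixels})"
        )
    thr = float(np.quantile(pixels, quantile))
    if thr >= float(pixels.max()):
        # degenerate control (e.g. constant image): nudge above the constant
        step = np.spacing(thr) if thr > 0 else np.finfo(float).tiny
        logger.warning(
            "calibrate_marker_threshold: degenerate control; threshold "
            "raised from %g by one representable step", thr
        )
        thr = thr + step
    return ThresholdCalibration(marker_threshold=thr, **calibration_kwargs)


def marker_objects(
    img: ImageChannelSet, cal: ThresholdCalibration
) -> np.ndarray:
    """Labeled marker mask: pixels above threshold, size-gated components.

    The exclusion mask is applied before labeling.  An empty mask is a
    valid result.
    """
    mask = (img.marker_channel > cal.marker_threshold) & img.included()
    labels = cc_label(mask, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for prop in regionprops(labels):
        if cal.size_min <= prop.area <= cal.size_max:
            out[labels == prop.label] = nxt
            nxt += 1
    return out


def associate_nuclei(
    nuclei: NucleusSet, marker_mask: np.ndarray, cal: ThresholdCalibration
) -> np.ndarray:
    """Per-nucleus positive flags under the calibrated localization rule.

    nuclear: marker covers >= ``f_nuc`` of the nucleus footprint.
    cytoplasmic: marker occupies >= ``f_cyt`` of a ring of width
    ``ring_width`` dilated around the nucleus, excluding all nuclei.
    apical: any marker pixel lies within ``apical_distance`` of the
    nucleus footprint.  A marker object may flag several nuclei.
    """
    if marker_mask.shape != nuclei.labels.shape:
        raise ImageQuantError("marker mask and nucleus labels shape mismatch")
    marker = marker_mask > 0
    n = nuclei.n_nuclei
    flags = np.zeros(n, dtype=bool)
    if n == 0 or not marker.any():
        return flags
    any_nucleus = nuclei.labels > 0
    for i in range(1, n + 1):
        footprint = nuclei.labels == i
        if cal.localization == "nuclear":
            overlap = np.count_nonzero(marker & footprint)
            flags[i - 1] = overlap >= cal.f_nuc * nuclei.areas[i - 1]
        elif cal.localization == "cytoplasmic":
            ring = ndi.binary_dilation(footprint, structure=disk(cal.ring_width))
            ring &= ~any_nucleus
            ring_area = np.count_nonzero(ring)
            if ring_area == 0:
                continue
            overlap = np.count_nonzero(marker & ring)
            flags[i - 1] = overlap >= cal.f_cyt * ring_area
        else:  # apical
            near = ndi.binary_dilation(
                footprint, structure=disk(cal.apical_distance)
            )
            flags[i - 1] = bool(np.count_nonzero(marker & near))
    return flags


def percent_positive(
    flags: Sequence[bool], cal: ThresholdCalibration | None = None
) -> QuantResult:
    """Fraction of positive nuclei; 0 with a flag when there are no nuclei."""
    arr = np.asarray(flags, dtype=bool)
    n = int(arr.size)
    pos = int(arr.sum())
    params = {}
    if cal is not None:
        params = {
            "marker_threshold": cal.marker_threshold,
            "size_min": cal.size_min,
            "size_max": cal.size_max,
            "localization": cal.localization,
            "f_nuc": cal.f_nuc,
            "f_cyt": cal.f_cyt,
            "ring_width": cal.ring_width,
            "apical_distance": cal.apical_distance,
        }
    if n == 0:
        return QuantResult(0, 0, 0.0, flagged=True, parameters=params)
    return QuantResult(n, pos, pos / n, parameters=params)


def quantify_image(
    img: ImageChannelSet,
    cal: ThresholdCalibration,
    seg_params: SegmentationParams | None = None,
) -> QuantResult:
    """Convenience wrapper: segment, build marker objects, associate, count."""
    nuclei = segment_nuclei(img, seg_params)
    mask = marker_objects(img, cal)
    flags = associate_nuclei(nuclei, mask, cal)
    return percent_positive(flags, cal)


def compare_image_groups(
    fractions_by_group: dict[str, Sequence[float]],
    control_group: str | None = None,
    alpha: float = 0.05,
) -> dict[str, TestResult]:
    """Compare per-image positive fractions between groups.

    Two groups: Wilcoxon rank-sum.  More: Kruskal-Wallis omnibus plus
    Dunn tests of each group versus ``control_group`` (defaults to the
    first group).  A single group yields a warning and an empty result.
    """
    names = list(fractions_by_group)
    if len(names) < 2:
        logger.warning("compare_image_groups: single group; comparison skipped")
        return {}
    if control_group is None:
        control_group = names[0]
    if control_group not in names:
        raise ImageQuantError(f"control group {control_group!r} not present")
    vecs = [np.asarray(fractions_by_group[n], dtype=float) for n in names]
    out: dict[str, TestResult] = {}
    if len(names) == 2:
        other = [n for n in names if n != control_group][0]
        res = wilcoxon_rank_sum(
            fractions_by_group[other], fractions_by_group[control_group]
        )
        out["omnibus"] = res
        out[other] = res
        return out
    out["omnibus"] = kruskal_wallis(vecs)
    for res in dunn_posthoc(vecs, control_index=names.index(control_group)):
        out[names[res.extra["group_index"]]] = res
    return out
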