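"""Plaque segmentation under uniform and dynamic HU thresholds, with
Agatston-style scoring.

Two threshold schemes are supported: *uniform* (one fixed HU cutoff,
classically 130 HU on non-contrast CT, shared by all scans) and
*dynamic* (per scan and vertebral level, mean AoHU + N standard
deviations, computed from that scan's own central zone).  Pixels inside
the vessel mask at or above the effective threshold are connected-
component labelled into lesions.

Agatston scoring weights each lesion's area by a density bin from its
peak HU: 1 for 130-199, 2 for 200-299, 3 for 300-399, 4 for >= 400 HU.
The classical lesion-max convention is the default; a per-pixel variant
is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .central_zone import CentralZoneStats
from .phantom import AortaScan

__all__ = [
    "ThresholdScheme",
    "Lesion",
    "PlaqueSegmentation",
    "AgatstonResult",
    "effective_threshold",
    "segment_plaque",
    "agatston_weight",
    "agatston_score",
]


@dataclass(frozen=True)
class ThresholdScheme:
    kind: str  # "uniform" | "dynamic"
    T: float | None = None  # HU, uniform
    N: float | None = None  # SD multiplier, dynamic

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if self.T is None or self.T < 0:
                raise ValueError("uniform scheme requires T >= 0")
        elif self.kind == "dynamic":
            # N = 0 is the degenerate cutoff-at-the-mean case, still valid
            if self.N is None or self.N < 0:
                raise ValueError("dynamic scheme requires N >= 0")
        else:
            raise ValueError(f"unknown scheme kind {self.kind!r}")


@dataclass(frozen=True)
class Lesion:
    slice_index: int
    area_px: int
    area_mm2: float
    max_HU: float


@dataclass
class PlaqueSegmentation:
    plaque_mask: np.ndarray
    lesions: list[Lesion]
    effective_threshold_HU: np.ndarray  # per slice


@dataclass
class AgatstonResult:
    lesion_weights: list[int]
    lesion_scores: list[float]
    total_score: float
    total_area_mm2: float
    total_volume_mm3: float | None = None


def effective_threshold(scheme: ThresholdScheme, stats: CentralZoneStats | None = None) -> float:
    """HU cutoff implied by a scheme; dynamic needs central-zone stats."""
    if scheme.kind == "uniform":
        return float(scheme.T)
    if stats is None:
        raise ValueError("dynamic scheme requires central-zone statistics")
    return float(stats.mean_AoHU + scheme.N * stats.sd_AoHU)


def segment_plaque(
    scan: AortaScan,
    scheme: ThresholdScheme,
    stats=None,
    min_lesion_px: int = 1,
    pixel_spacing_mm: float = 1.0,
    connectivity: int = 2,
) -> PlaqueSegmentation:
    """Threshold the vessel interior and label lesions per slice.

    ``stats`` feeds the dynamic scheme: a single CentralZoneStats applied
    scan-wide, or a mapping from vertebral level to per-level stats (a
    slice whose level is missing from the mapping is skipped).  The
    comparison is inclusive (HU >= threshold); 8-connectivity by default.
    """
    n_slices = scan.image.shape[0]
    thresholds = np.full(n_slices, np.nan)
    mask = np.zeros_like(scan.aorta_mask)
    lesions: list[Lesion] = []
    px_area = pixel_spacing_mm**2

    for k in range(n_slices):
        if scheme.kind == "dynamic":
            if isinstance(stats, dict):
                st = stats.get(scan.vertebral_labels[k])
                if st is None:
                    continue
            else:
                st = stats
            thr = effective_threshold(scheme, st)
        else:
            thr = effective_threshold(scheme)
        thresholds[k] = thr
        sl = scan.aorta_mask[k] & (scan.image[k] >= thr)
        if not sl.any():
            continue
        labels = cc_label(sl, connectivity=connectivity)
        keep = np.zeros_like(sl)
        for region in regionprops(labels, intensity_image=scan.image[k]):
            if region.area < min_lesion_px:
                continue
            keep |= labels == region.label
            lesions.append(
                Lesion(
                    slice_index=k,
                    area_px=int(region.area),
                    area_mm2=float(region.area * px_area),
                    max_HU=float(region.intensity_max),
                )
            )
        mask[k] = keep

    return PlaqueSegmentation(plaque_mask=mask, lesions=lesions, effective_threshold_HU=thresholds)


_AGATSTON_BREAKS = (200.0, 300.0, 400.0)


def agatston_weight(lesion_max_HU: float) -> int:
    """Density weight from peak HU: 130-199 -> 1 ... >= 400 -> 4."""
    if lesion_max_HU < 130:
        raise ValueError("peak HU below 130 is not a scoreable lesion")
    return 1 + int(np.searchsorted(_AGATSTON_BREAKS, lesion_max_HU, side="right"))


def agatston_score(
    segmentation: PlaqueSegmentation,
    pixel_spacing_mm: float,
    slice_thickness_mm: float | None = None,
    per_pixel_weights: bool = False,
    image: np.ndarray | None = None,
) -> AgatstonResult:
    """Score a segmentation: sum over lesions of weight x area (mm^2).

    ``per_pixel_weights`` scores each pixel by its own HU bin instead of
    the lesion max (sensitivity variant; requires ``image``).  Volume is
    plaque pixel count x voxel volume when slice thickness is given.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    px_area = pixel_spacing_mm**2
    weights, scores = [], []
    if per_pixel_weights:
        if image is None:
            raise ValueError("per-pixel weighting requires the HU image")
        # each pixel scored by its own density bin; sub-130 pixels excluded
        for k in range(segmentation.plaque_mask.shape[0]):
            hu = np.asarray(image[k][segmentation.plaque_mask[k]], dtype=float)
            hu = hu[hu >= 130]
            if not hu.size:
                continue
            w = 1 + np.searchsorted(_AGATSTON_BREAKS, hu, side="right")
            weights.append(int(w.max()))
            scores.append(float(w.sum() * px_area))
    else:
        for les in segmentation.lesions:
            if les.max_HU < 130:
                continue  # not calcification under the bin table
            w = agatston_weight(les.max_HU)
            weights.append(w)
            scores.append(w * les.area_px * px_area)
    n_px = int(segmentation.plaque_mask.sum())
    total_area = n_px * px_area
    volume = total_area * slice_thickness_mm if slice_thickness_mm is not None else None
    return AgatstonResult(
        lesion_weights=weights,
        lesion_scores=scores,
        total_score=float(sum(scores)),
        total_area_mm2=float(total_area),
        total_volume_mm3=volume,
    )
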