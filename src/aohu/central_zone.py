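"""Central-zone extraction and attenuation statistics (AoHU).

The blood pool is sampled from a *central zone*: the vessel cross-section
eroded to a fraction (default 50%) of its equivalent radius, which avoids
wall calcification and partial-volume edge pixels.  Erosion is defined
through the Euclidean distance transform — keep pixels whose distance to
the mask complement is at least (1 - fraction) times the equivalent
radius sqrt(area/pi) — which is well defined for non-circular
cross-sections and respects anisotropic pixel spacing.

Per-scan, per-vertebral-level mean and SD of the central-zone pixels are
the AoHU statistics that drive dynamic thresholding and the cohort
regressions.  Levels outside L4..T8 are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .phantom import LEVEL_CODE, S1_COLUMNS, AortaScan

__all__ = ["CentralZoneStats", "erode_to_fraction", "zone_stats", "scan_zone_stats", "stats_table"]


@dataclass(frozen=True)
class CentralZoneStats:
    """Mean/SD attenuation of central-zone pixels at one vertebral level."""

    scan_id: str
    level: str
    level_code: int
    mean_AoHU: float
    sd_AoHU: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.sd_AoHU < 0:
            raise ValueError("sd_AoHU must be >= 0")
        if LEVEL_CODE.get(self.level) != self.level_code:
            raise ValueError(f"level code {self.level_code} inconsistent with label {self.level!r}")


def erode_to_fraction(
    mask: np.ndarray,
    fraction: float,
    pixel_spacing: tuple[float, float] | None = None,
) -> np.ndarray:
    """Shrink a vessel mask to ``fraction`` of its equivalent radius.

    Works per slice on 3-D input.  For ``fraction == 1`` the mask is
    returned unchanged.  A slice whose central zone comes out empty
    (thin or degenerate cross-section) stays empty; callers exclude such
    slices from statistics.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        return np.stack([erode_to_fraction(sl, fraction, pixel_spacing) for sl in mask])
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D or 3-D")
    if fraction == 1.0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    sampling = pixel_spacing if pixel_spacing is not None else (1.0, 1.0)
    pixel_area = float(sampling[0]) * float(sampling[1])
    r_eq = np.sqrt(mask.sum() * pixel_area / np.pi)
    dist = distance_transform_edt(mask, sampling=sampling)
    return mask & (dist >= (1.0 - fraction) * r_eq)


def zone_stats(
    image: np.ndarray,
    central_mask: np.ndarray,
    vertebral_labels,
    scan_id: str = "",
    ddof: int = 1,
) -> list[CentralZoneStats]:
    """Per-level mean/SD of central-zone pixels, pooled across slices.

    Slices labelled outside L4..T8 are excluded; slices with an empty
    central mask are dropped with a warning.  SD uses the sample
    convention (``ddof=1``) by default; set ``ddof=0`` for population SD.
    """
    image = np.asarray(image)
    central_mask = np.asarray(central_mask, dtype=bool)
    if image.shape != central_mask.shape:
        raise ValueError("image and central mask shapes disagree")
    if image.ndim == 2:
        image = image[None]
        central_mask = central_mask[None]
    labels = list(vertebral_labels)
    if len(labels) != image.shape[0]:
        raise ValueError("one vertebral label per slice is required")

    pixels_by_level: dict[str, list[np.ndarray]] = {}
    for k, level in enumerate(labels):
        if level not in LEVEL_CODE:
            continue  # outside the L4..T8 range
        sl = central_mask[k]
        if not sl.any():
            warnings.warn(f"{scan_id}: empty central zone on slice {k} ({level}), excluded", stacklevel=2)
            continue
        pixels_by_level.setdefault(level, []).append(image[k][sl].astype(float))

    if not pixels_by_level:
        warnings.warn(f"{scan_id}: no eligible slices for zone statistics", stacklevel=2)
        return []

    out = []
    for level in sorted(pixels_by_level, key=LEVEL_CODE.get):
        vals = np.concatenate(pixels_by_level[level])
        sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
        out.append(
            CentralZoneStats(
                scan_id=scan_id,
                level=level,
                level_code=LEVEL_CODE[level],
                mean_AoHU=float(vals.mean()),
                sd_AoHU=sd,
                n_pixels=int(vals.size),
            )
        )
    return out


def scan_zone_stats(scan: AortaScan, fraction: float = 0.5, ddof: int = 1,
                    exclude_contaminated: bool = False) -> list[CentralZoneStats]:
    """Erode the scan's aorta mask and compute its per-level statistics.

    ``exclude_contaminated`` drops slices whose central zone touches the
    ground-truth plaque mask, reproducing a review-based exclusion of
    calcification-contaminated measurements; by default they are kept.
    """
    central = erode_to_fraction(scan.aorta_mask, fraction)
    if exclude_contaminated:
        contaminated = (central & scan.plaque_truth_mask).any(axis=(1, 2))
        central = central.copy()
        central[contaminated] = False
    return zone_stats(scan.image, central, scan.vertebral_labels, scan_id=scan.meta.scan_id, ddof=ddof)


def stats_table(stats_by_scan: dict, metas: dict) -> pd.DataFrame:
    """Assemble measured central-zone statistics into the canonical table.

    ``stats_by_scan`` maps scan_id -> list[CentralZoneStats]; ``metas``
    maps scan_id -> ScanMeta.
    """
    rows = []
    for scan_id, stats in stats_by_scan.items():
        meta = metas[scan_id]
        for st in stats:
            rows.append(
                {
                    S1_COLUMNS[0]: scan_id,
                    S1_COLUMNS[1]: st.level,
                    S1_COLUMNS[2]: scan_id.replace(meta.cohort_tag, "P", 1),
                    S1_COLUMNS[3]: meta.cohort_tag,
                    S1_COLUMNS[4]: meta.age,
                    S1_COLUMNS[5]: meta.sex,
                    S1_COLUMNS[6]: meta.weight,
                    S1_COLUMNS[7]: st.mean_AoHU,
                    S1_COLUMNS[8]: st.sd_AoHU,
                }
            )
    return pd.DataFrame(rows, columns=list(S1_COLUMNS))
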