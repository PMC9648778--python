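"""Synthetic contrast-enhanced CT vessel phantoms with ground truth.

Each phantom scan is a stack of 2-D axial slices containing one circular
vessel (the aorta cross-section) filled with normally distributed
blood-pool attenuation, optionally carrying wall-adjacent calcified
lesions whose core HU are drawn from the plaque law and blurred with a
Gaussian point-spread function to produce partial-volume rims.

The generative hierarchy mirrors what a multi-cohort attenuation survey
reports:

* a contrast *phase* sets the cohort mean and the between-scan SD of the
  per-scan blood-pool mean (e.g. arterial 326 +/- 68 HU, delayed
  110 +/- 16 HU);
* per-scan covariates shift that mean: a sex offset (females enhance
  higher, up to +65 HU in arterial phase), a weight slope (default
  -2.3 HU per 10 kg, arterial), and a vertebral-level trend applied
  per slice, centred so it leaves the scan mean untouched;
* within a scan, non-plaque pixels are Normal(scan mean, within-scan SD),
  the central assumption behind the threshold error model.

The phase population SDs are the *residual* spread at reference
covariates (male, cohort-mean weight); mixed demographics widen the
marginal spread accordingly.  Venous and non-contrast phase parameters
are plausible defaults, not survey-measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .plaque import PlaqueHUDistribution, make_plaque_law

__all__ = [
    "VERTEBRAL_LEVELS",
    "LEVEL_CODE",
    "HU_MIN",
    "HU_MAX",
    "S1_COLUMNS",
    "PhantomParams",
    "ScanMeta",
    "AortaScan",
    "DemographicsSpec",
    "sample_scan",
    "make_cohort",
]

#: Vertebral levels in ascending (inferior -> superior) order; codes start
#: at L4 = 1 and increase moving up the spine.
VERTEBRAL_LEVELS: tuple[str, ...] = ("L4", "L3", "L2", "L1", "T12", "T11", "T10", "T9", "T8")
LEVEL_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(VERTEBRAL_LEVELS)}

HU_MIN, HU_MAX = -1024, 3071

#: Canonical column schema for per-(scan, vertebra) metadata tables.
S1_COLUMNS: tuple[str, ...] = (
    "MAG scan identification number",
    "vertebra index identifier",
    "patient identification number",
    "dataset tag",
    "participant age",
    "participant sex",
    "participant weight (in kg)",
    "aortic attenuation mean",
    "aortic attenuation standard deviation",
)

PHASES = ("non-contrast", "arterial", "venous", "delayed")


def _freeze(d: dict) -> dict:
    return dict(d)


@dataclass(frozen=True)
class PhantomParams:
    """Full generative configuration for a synthetic vessel cohort.

    ``phase_mean_HU`` / ``phase_popSD_HU`` give the cohort mean and the
    between-scan SD of scan means per contrast phase.  Arterial and
    delayed values follow the printed survey summaries; venous and
    non-contrast are configurable placeholders.  ``within_scan_SD_HU`` is
    the pixel SD inside one vessel.  ``sex_offset_HU`` is added for
    female subjects; ``weight_slope_HU_per_10kg`` multiplies
    (weight - cohort mean)/10; ``vertebral_slope_HU_per_level`` is the HU
    change per level code step (codes increase superiorly, so the
    observed inferior-ward enhancement gives negative values), applied
    centred on each scan's mid level.
    """

    phase_mean_HU: dict = field(
        default_factory=lambda: {
            "non-contrast": 40.0,
            "arterial": 326.0,
            "venous": 180.0,
            "delayed": 110.0,
        }
    )
    phase_popSD_HU: dict = field(
        default_factory=lambda: {
            "non-contrast": 5.0,
            "arterial": 68.0,
            "venous": 30.0,
            "delayed": 16.0,
        }
    )
    within_scan_SD_HU: float = 30.0
    sex_offset_HU: dict = field(
        default_factory=lambda: {
            "non-contrast": 0.0,
            "arterial": 65.0,
            "venous": 22.0,
            "delayed": 20.0,
        }
    )
    weight_slope_HU_per_10kg: dict = field(
        default_factory=lambda: {
            "non-contrast": 0.0,
            "arterial": -2.3,
            "venous": 0.0,
            "delayed": 0.0,
        }
    )
    vertebral_slope_HU_per_level: dict = field(
        default_factory=lambda: {
            "non-contrast": -1.5,
            "arterial": -4.5,
            "venous": -2.0,
            "delayed": -2.0,
        }
    )
    cohort_mean_weight_kg: float = 80.0
    plaque_law: PlaqueHUDistribution = field(default_factory=make_plaque_law)
    plaque_prevalence: float = 0.3
    lesions_per_scan: tuple[int, int] = (1, 3)
    lesion_arc_deg: tuple[float, float] = (30.0, 110.0)
    lesion_radial_band: tuple[float, float] = (0.60, 0.95)
    psf_sigma_px: float = 0.7
    pixel_spacing_mm: float = 0.7
    vessel_radius_px: tuple[int, int] = (8, 14)
    slice_shape: tuple[int, int] = (64, 64)
    levels: tuple[str, ...] = VERTEBRAL_LEVELS
    background_mean_HU: float = 30.0
    background_SD_HU: float = 15.0
    quantize: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for phase in PHASES:
            if self.phase_popSD_HU[phase] < 0:
                raise ValueError(f"phase_popSD_HU[{phase}] must be >= 0")
        if self.within_scan_SD_HU < 0:
            raise ValueError("within_scan_SD_HU must be >= 0")
        if not 0.0 <= self.plaque_prevalence <= 1.0:
            raise ValueError("plaque_prevalence must lie in [0, 1]")
        if self.plaque_law.offset_HU < 130:
            raise ValueError("plaque law offset must be >= 130 HU")
        unknown = set(self.levels) - set(VERTEBRAL_LEVELS)
        if unknown:
            raise ValueError(f"unknown vertebral levels: {sorted(unknown)}")


@dataclass(frozen=True)
class ScanMeta:
    scan_id: str
    cohort_tag: str
    phase: str
    sex: str
    age: float
    weight: float
    slice_thickness: float = 3.0
    rng_stream_id: int = 0

    def __post_init__(self) -> None:
        if self.phase not in PHASES + ("mixed",):
            raise ValueError(f"unknown contrast phase {self.phase!r}")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not 16 <= self.age <= 94:
            raise ValueError("age outside the supported 16-94 year range")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class AortaScan:
    """One synthetic scan: HU grid, masks, per-slice levels, metadata.

    ``image`` has shape (n_slices, ny, nx); masks share it.  The
    ground-truth plaque mask is the pre-blur lesion support, so every
    truth pixel's generating core HU was >= the plaque-law offset even
    though blurring may drag the observed pixel below it.
    """

    image: np.ndarray
    aorta_mask: np.ndarray
    plaque_truth_mask: np.ndarray
    vertebral_labels: tuple[str, ...]
    meta: ScanMeta
    scan_mean_HU: float = float("nan")  # generative truth, for recovery tests
    slice_mean_HU: np.ndarray | None = None

    def validate(self) -> None:
        if not (self.image.shape == self.aorta_mask.shape == self.plaque_truth_mask.shape):
            raise ValueError("image and mask shapes disagree")
        if len(self.vertebral_labels) != self.image.shape[0]:
            raise ValueError("one vertebral label per slice is required")
        if np.any(self.plaque_truth_mask & ~self.aorta_mask):
            raise ValueError("plaque truth mask must be contained in the aorta mask")
        if not self.aorta_mask.reshape(self.aorta_mask.shape[0], -1).any(axis=1).all():
            raise ValueError("aorta mask empty on a labeled slice")


@dataclass(frozen=True)
class DemographicsSpec:
    """Cohort composition: sex fractions, phase mix, age/weight laws."""

    sex_fractions: dict = field(default_factory=lambda: {"M": 0.5, "F": 0.5})
    phase_mix: dict = field(default_factory=lambda: {"arterial": 1.0})
    age_mean: float = 55.0
    age_sd: float = 14.0
    weight_mean: float = 80.0
    weight_sd: float = 15.0
    slice_thickness: float = 3.0
    cohort_tag: str = "SYN"

    def __post_init__(self) -> None:
        for name, fractions in (("sex_fractions", self.sex_fractions), ("phase_mix", self.phase_mix)):
            total = sum(fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        for phase in self.phase_mix:
            if phase not in PHASES:
                raise ValueError(f"phase_mix contains unknown phase {phase!r}")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _lesion_support(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    band: tuple[float, float],
    theta0: float,
    arc: float,
) -> np.ndarray:
    """Wall-adjacent arc: radial band x angular window inside the vessel."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx) - theta0 + np.pi, 2 * np.pi) - np.pi
    return (r >= band[0] * radius) & (r <= band[1] * radius) & (np.abs(ang) <= arc / 2)


def sample_scan(params: PhantomParams, meta: ScanMeta) -> AortaScan:
    """Draw one scan from the generative model; deterministic in (params, meta).

    The scan-level blood-pool mean is

        m = phase_mean + sex_offset * 1[F]
            + weight_slope * (weight - cohort_mean_weight)/10
            + Normal(0, phase_popSD),

    each slice adds the centred vertebral trend, and pixels are
    Normal(slice mean, within-scan SD).  Lesions, when present, are
    wall-adjacent arcs with core HU from the plaque law, blurred by the
    PSF before integer clipping.
    """
    if meta.phase not in params.phase_mean_HU:
        raise ValueError(f"no configured phase mean for {meta.phase!r}")
    rng = np.random.default_rng([params.rng_seed, meta.rng_stream_id])

    phase = meta.phase
    m = params.phase_mean_HU[phase]
    m += params.sex_offset_HU[phase] * (meta.sex == "F")
    m += params.weight_slope_HU_per_10kg[phase] * (meta.weight - params.cohort_mean_weight_kg) / 10.0
    m += rng.normal(0.0, params.phase_popSD_HU[phase])

    levels = params.levels
    codes = np.array([LEVEL_CODE[lv] for lv in levels], dtype=float)
    vslope = params.vertebral_slope_HU_per_level[phase]
    slice_means = m + vslope * (codes - codes.mean())

    ny, nx = params.slice_shape
    n_slices = len(levels)
    radius = int(rng.integers(params.vessel_radius_px[0], params.vessel_radius_px[1] + 1))
    center = (
        ny / 2 + rng.uniform(-2, 2),
        nx / 2 + rng.uniform(-2, 2),
    )

    image = rng.normal(params.background_mean_HU, params.background_SD_HU, size=(n_slices, ny, nx))
    aorta = np.zeros((n_slices, ny, nx), dtype=bool)
    truth = np.zeros((n_slices, ny, nx), dtype=bool)

    disk = _disk_mask((ny, nx), center, radius)
    for k in range(n_slices):
        aorta[k] = disk
        blood = rng.normal(slice_means[k], params.within_scan_SD_HU, size=int(disk.sum()))
        image[k][disk] = blood

    if rng.random() < params.plaque_prevalence:
        lo, hi = params.lesions_per_scan
        n_lesions = int(rng.integers(lo, hi + 1))
        for _ in range(n_lesions):
            k = int(rng.integers(0, n_slices))
            theta0 = rng.uniform(0, 2 * np.pi)
            arc = np.deg2rad(rng.uniform(*params.lesion_arc_deg))
            support = _lesion_support((ny, nx), center, radius, params.lesion_radial_band, theta0, arc)
            support &= disk
            if not support.any():
                warnings.warn(
                    f"{meta.scan_id}: vessel radius {radius}px too small for lesion, skipped",
                    stacklevel=2,
                )
                continue
            core = params.plaque_law.sample(int(support.sum()), rng)
            delta = np.zeros((ny, nx))
            delta[support] = core - image[k][support]
            if params.psf_sigma_px > 0:
                delta = gaussian_filter(delta, params.psf_sigma_px)
            image[k] += delta
            truth[k] |= support

    if params.quantize:
        image = np.clip(np.rint(image), HU_MIN, HU_MAX).astype(np.int16)
    else:
        image = np.clip(image, HU_MIN, HU_MAX)

    scan = AortaScan(
        image=image,
        aorta_mask=aorta,
        plaque_truth_mask=truth,
        vertebral_labels=tuple(levels),
        meta=meta,
        scan_mean_HU=float(m),
        slice_mean_HU=slice_means,
    )
    scan.validate()
    return scan


def make_cohort(
    params: PhantomParams,
    n_scans: int,
    demographics: DemographicsSpec | None = None,
    seed: int | None = None,
) -> tuple[list[AortaScan], pd.DataFrame]:
    """Generate a reproducible cohort and its per-(scan, vertebra) table.

    The returned table uses the canonical metadata column schema; its
    attenuation columns hold the *generative* per-slice mean and the
    within-scan SD (ground truth), which downstream central-zone
    measurement re-estimates from pixels.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    demographics = demographics or DemographicsSpec()
    if seed is not None:
        params = replace(params, rng_seed=seed)
    # demographics use a dedicated sub-stream so per-scan streams stay stable
    rng = np.random.default_rng([params.rng_seed, 900_001])

    sexes = list(demographics.sex_fractions)
    sex_p = [demographics.sex_fractions[s] for s in sexes]
    phases = list(demographics.phase_mix)
    phase_p = [demographics.phase_mix[p] for p in phases]

    scans: list[AortaScan] = []
    rows: list[dict] = []
    for i in range(n_scans):
        age = float(np.clip(rng.normal(demographics.age_mean, demographics.age_sd), 16, 94))
        weight = float(max(30.0, rng.normal(demographics.weight_mean, demographics.weight_sd)))
        meta = ScanMeta(
            scan_id=f"{demographics.cohort_tag}-{i:05d}",
            cohort_tag=demographics.cohort_tag,
            phase=str(rng.choice(phases, p=phase_p)),
            sex=str(rng.choice(sexes, p=sex_p)),
            age=age,
            weight=weight,
            slice_thickness=demographics.slice_thickness,
            rng_stream_id=i + 1,
        )
        scan = sample_scan(params, meta)
        scans.append(scan)
        for k, level in enumerate(scan.vertebral_labels):
            rows.append(
                {
                    S1_COLUMNS[0]: meta.scan_id,
                    S1_COLUMNS[1]: level,
                    S1_COLUMNS[2]: f"P{i:05d}",
                    S1_COLUMNS[3]: meta.cohort_tag,
                    S1_COLUMNS[4]: meta.age,
                    S1_COLUMNS[5]: meta.sex,
                    S1_COLUMNS[6]: meta.weight,
                    S1_COLUMNS[7]: float(scan.slice_mean_HU[k]),
                    S1_COLUMNS[8]: params.within_scan_SD_HU,
                }
            )
    table = pd.DataFrame(rows, columns=list(S1_COLUMNS))
    return scans, table
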