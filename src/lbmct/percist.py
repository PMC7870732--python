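"""PERCIST 1.0 machinery: SUL normalization, lesion segmentation,
SUL_peak, measurability and response classification.

SUL is SUV normalized by lean body mass instead of total weight,
``SUL = SUV x LBM / W``.  Because the weight cancels, a SUL_peak computed
under one LBM algorithm converts to another algorithm's value by the pure
ratio ``SUL_b = SUL_a x LBM_b / LBM_a`` — the mechanism by which the choice
of LBM algorithm can flip a response classification when LBM changes
between baseline and follow-up.

Response classes (ordinal, worst to best): PMD < SMD < PMR.  A complete
metabolic response class is deliberately not emitted; cohorts assessed
here have residual avid lesions at follow-up, so the three-class scheme
is the native output.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .ct_io import ImageVolume
from .exceptions import (
    ConfigError,
    ContentError,
    DomainError,
    GeometryError,
    SegmentationError,
)


class ResponseClass(enum.IntEnum):
    """PERCIST response, ordinal-coded PMD=1 < SMD=2 < PMR=3."""

    PMD = 1
    SMD = 2
    PMR = 3


@dataclass(frozen=True)
class BackgroundStats:
    liver_sul_mean: float
    liver_sul_sd: float
    blood_sul_mean: Optional[float] = None
    roi_description: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LesionMeasurement:
    sul_peak: float
    timepoint: str  # "baseline" | "followup"
    lesion_id: str = ""
    lbm_used_kg: Optional[float] = None
    weight_kg: Optional[float] = None
    suv_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sul_peak <= 0:
            raise DomainError(f"SUL_peak must be positive, got {self.sul_peak}")
        if self.timepoint not in ("baseline", "followup"):
            raise DomainError(f"timepoint must be baseline/followup, got {self.timepoint!r}")


@dataclass(frozen=True)
class PercistResult:
    percent_change: float
    abs_change: float
    response: ResponseClass
    algorithm: str = ""  # "PE" | "LC" | other tag


# --- SUL arithmetic ---------------------------------------------------------


def suv_to_sul(suv_bw: float, lbm_kg: float, weight_kg: float) -> float:
    """Convert body-weight SUV to lean-body-mass SUL: SUV x LBM / W."""
    if suv_bw <= 0 or lbm_kg <= 0 or weight_kg <= 0:
        raise DomainError("suv, lbm and weight must all be positive")
    return suv_bw * lbm_kg / weight_kg


def rescale_sul_peak(sul_pe: float, lbm_pe_kg: float, lbm_lc_kg: float) -> float:
    """Re-normalize a SUL_peak from one LBM algorithm to another.

    Weight cancels: SUL_LC = SUL_PE x LBM_LC / LBM_PE.
    """
    if sul_pe <= 0 or lbm_pe_kg <= 0 or lbm_lc_kg <= 0:
        raise DomainError("sul and both LBM values must be positive")
    return sul_pe * lbm_lc_kg / lbm_pe_kg


# --- lesion segmentation and SUL_peak --------------------------------------

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    thresholds: tuple[float, ...]
    converged: bool
    n_iter: int


def adaptive_threshold_segment(
    pet: ImageVolume,
    seed_region: np.ndarray,
    weight_factor: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> SegmentationResult:
    """Iterative adaptive thresholding of a lesion.

    Starting from the seed region, iterate

        T_{k+1} = w * max(SUV in mask_k) + (1 - w) * mean(SUV in mask_k)
        mask_{k+1} = voxels >= T_{k+1}, 26-connected to the seed maximum

    until the threshold moves less than ``tol`` or ``max_iter`` is reached
    (the default weighting factor is 0.5).
    """
    if not 0 < weight_factor < 1:
        raise DomainError(f"weight_factor must be in (0, 1), got {weight_factor}")
    seed_region = np.asarray(seed_region, dtype=bool)
    if seed_region.shape != pet.voxels.shape:
        raise DomainError("seed_region shape must match the PET volume")
    if not seed_region.any():
        raise SegmentationError("seed region is empty")

    vox = pet.voxels
    # voxel of maximal uptake inside the seed anchors connectivity
    seed_vals = np.where(seed_region, vox, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(seed_vals)), vox.shape)

    mask = seed_region.copy()
    thresholds: list[float] = []
    converged = False
    for _ in range(max_iter):
        inside = vox[mask]
        t_next = weight_factor * float(inside.max()) + (1 - weight_factor) * float(inside.mean())
        candidate = vox >= t_next
        if not candidate[peak_idx]:
            raise SegmentationError(
                f"threshold {t_next:.4g} excludes the seed maximum; empty segmentation"
            )
        labels, _ = ndimage.label(candidate, structure=_STRUCT26)
        mask = labels == labels[peak_idx]
        thresholds.append(t_next)
        if len(thresholds) > 1 and abs(thresholds[-1] - thresholds[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"adaptive segmentation did not converge within {max_iter} iterations",
            stacklevel=2,
        )
    return SegmentationResult(
        mask=mask,
        threshold=thresholds[-1],
        thresholds=tuple(thresholds),
        converged=converged,
        n_iter=len(thresholds),
    )


def sphere_kernel(spacing: Sequence[float], diameter_mm: float) -> np.ndarray:
    """Voxelized sphere (center-in-sphere membership) for a given spacing."""
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing]
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1) * s for h, s in zip(half, spacing)), indexing="ij"
    )
    return zz**2 + yy**2 + xx**2 <= r**2


def sul_peak(
    pet: ImageVolume,
    lesion_mask: np.ndarray,
    sphere_diameter_mm: float = 12.0,
) -> float:
    """Peak SUL: the maximal mean SUL in a ~1 cm^3 sphere centred on a
    lesion voxel (12 mm diameter by default).

    The sphere may extend beyond the lesion mask (PERCIST convention);
    voxels beyond the image edge contribute zero to the mean.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != pet.voxels.shape:
        raise DomainError("lesion_mask shape must match the PET volume")
    if not lesion_mask.any():
        raise ContentError("lesion mask is empty")
    kernel = sphere_kernel(pet.spacing, sphere_diameter_mm)
    if any(k > s for k, s in zip(kernel.shape, pet.voxels.shape)):
        raise GeometryError(
            f"{sphere_diameter_mm} mm sphere ({kernel.shape} voxels) exceeds the "
            f"image extent {pet.voxels.shape}"
        )
    weights = kernel / kernel.sum()
    means = ndimage.correlate(pet.voxels.astype(float), weights, mode="constant", cval=0.0)
    return float(means[lesion_mask].max())


def liver_background(
    pet: ImageVolume,
    center_mm: Sequence[float],
    diameter_mm: float = 30.0,
    ddof: int = 1,
) -> BackgroundStats:
    """Mean and SD of SUL in a spherical liver ROI (3 cm diameter default).

    ``center_mm`` is a physical coordinate in (slice, row, col) axis order.
    SD uses the sample convention (ddof=1) by default; pass ddof=0 for the
    population convention.
    """
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(pet.spacing)
    origin = np.asarray(pet.origin)
    r = diameter_mm / 2.0
    extent_lo = origin
    extent_hi = origin + (np.asarray(pet.voxels.shape) - 1) * spacing
    if np.any(center - r < extent_lo - spacing / 2) or np.any(center + r > extent_hi + spacing / 2):
        raise GeometryError(
            f"{diameter_mm} mm sphere at {tuple(center)} does not fit in the volume"
        )
    coords = [origin[i] + np.arange(pet.voxels.shape[i]) * spacing[i] for i in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    member = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r**2
    if not member.any():
        raise GeometryError("spherical ROI contains no voxel centers")
    vals = pet.voxels[member]
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    return BackgroundStats(
        liver_sul_mean=float(vals.mean()),
        liver_sul_sd=sd,
        roi_description={
            "center_mm": tuple(float(c) for c in center),
            "diameter_mm": diameter_mm,
            "n_voxels": int(vals.size),
            "sd_ddof": ddof,
        },
    )


# --- measurability and classification --------------------------------------


@dataclass(frozen=True)
class MeasurabilityResult:
    measurable: bool
    threshold: float
    rule: str  # "liver" | "blood_pool"


def is_measurable(
    baseline_sul_peak: float,
    bg: BackgroundStats,
    use_blood_pool: bool = False,
    strict_parse: bool = False,
) -> MeasurabilityResult:
    """PERCIST measurability of a baseline lesion.

    Liver rule (default): SUL_peak >= 1.5 * liver_mean + 2 * liver_SD.
    ``strict_parse=True`` uses the alternate reading 1.5 * (mean + 2 SD).
    Blood-pool rule (abnormal liver): SUL_peak > 2.0 * blood-pool mean.
    """
    if use_blood_pool:
        if bg.blood_sul_mean is None:
            raise ConfigError("blood-pool rule requested but blood_sul_mean is missing")
        thr = 2.0 * bg.blood_sul_mean
        return MeasurabilityResult(baseline_sul_peak > thr, thr, "blood_pool")
    if strict_parse:
        thr = 1.5 * (bg.liver_sul_mean + 2.0 * bg.liver_sul_sd)
    else:
        thr = 1.5 * bg.liver_sul_mean + 2.0 * bg.liver_sul_sd
    return MeasurabilityResult(baseline_sul_peak >= thr, thr, "liver")


def percent_change(baseline: float, followup: float) -> float:
    """100 x (followup - baseline) / baseline."""
    if baseline <= 0:
        raise DomainError(f"baseline must be positive, got {baseline}")
    return 100.0 * (followup - baseline) / baseline


def classify_change(
    baseline_sul: float,
    followup_sul: float,
    threshold_pct: float = 30.0,
    min_abs_change: float = 0.8,
    algorithm: str = "",
) -> PercistResult:
    """Classify a SUL_peak change under PERCIST 1.0.

    PMR: change <= -threshold AND |change| >= min_abs_change (SUL units);
    PMD: change >= +threshold AND |change| >= min_abs_change;
    otherwise SMD.  Both thresholds are inclusive.
    """
    pct = percent_change(baseline_sul, followup_sul)
    abs_change = followup_sul - baseline_sul
    if pct <= -threshold_pct and abs(abs_change) >= min_abs_change:
        response = ResponseClass.PMR
    elif pct >= threshold_pct and abs(abs_change) >= min_abs_change:
        response = ResponseClass.PMD
    else:
        response = ResponseClass.SMD
    return PercistResult(
        percent_change=pct, abs_change=abs_change, response=response, algorithm=algorithm
    )


def classify_response(
    baseline: LesionMeasurement,
    followup: LesionMeasurement,
    threshold_pct: float = 30.0,
    min_abs_change: float = 0.8,
    algorithm: str = "",
) -> PercistResult:
    """Classify response from paired lesion measurements (see classify_change)."""
    if baseline.timepoint != "baseline" or followup.timepoint != "followup":
        raise DomainError("expected one baseline and one followup measurement")
    return classify_change(
        baseline.sul_peak, followup.sul_peak, threshold_pct, min_abs_change, algorithm
    )


def select_target_lesion(lesions: Sequence[LesionMeasurement]) -> LesionMeasurement:
    """The hottest lesion of one scan; ties broken by lesion_id (lexicographic)."""
    if not lesions:
        raise ContentError("no lesions to select from")
    timepoints = {m.timepoint for m in lesions}
    if len(timepoints) > 1:
        raise DomainError("all lesions must belong to the same timepoint")
    return min(lesions, key=lambda m: (-m.sul_peak, m.lesion_id))
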