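"""CT fat segmentation and volumetry.

Adipose tissue is segmented by a Hounsfield-unit window, by convention
[-190, -30] HU with both bounds inclusive.  Fat volume is the voxel count
times the voxel volume; fat mass uses the average adipose density of
0.923 kg/L.  The limited-coverage (LC) region — the axial range a routine
PET/CT actually covers, from the top of the thorax to the distal ischium —
is expressed as a half-open slice interval supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .ct_io import ImageVolume, crop_axial, voxel_volume_ml
from .exceptions import ContentError, DimensionError, DomainError

#: average density of adipose tissue, kg per litre
FAT_DENSITY_KG_PER_L = 0.923


@dataclass(frozen=True)
class HUWindow:
    """Inclusive Hounsfield-unit window for a tissue class."""

    lo: float = -190.0
    hi: float = -30.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise DomainError(f"HU window requires lo < hi, got ({self.lo}, {self.hi})")


#: the standard adipose-tissue window
ADIPOSE_WINDOW = HUWindow(-190.0, -30.0)


@dataclass(frozen=True)
class FatVolumetryResult:
    voxel_count: int
    fat_volume_ml: float
    region_label: str = "custom"  # whole_body | limited_coverage | custom
    slice_range: Optional[tuple[int, int]] = None

    @property
    def fat_volume_l(self) -> float:
        return self.fat_volume_ml / 1000.0


def body_mask(ct: ImageVolume, air_threshold: float = -500.0) -> np.ndarray:
    """Binary mask of the patient body on CT.

    Largest 3D connected component of voxels above ``air_threshold``,
    morphologically closed and hole-filled so internal air (lung, bowel gas)
    is part of the body; excludes detached objects such as the couch.
    """
    if ct.modality != "CT":
        raise DomainError("body_mask requires a CT volume")
    fg = ct.voxels > air_threshold
    if not fg.any():
        raise ContentError("no voxel above the air threshold; cannot build a body mask")
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    else:
        mask = fg
    mask = ndimage.binary_closing(mask, structure=structure, iterations=1)
    mask = ndimage.binary_fill_holes(mask)
    # closing can merge nothing new but fill_holes guarantees no cavities;
    # re-keep the largest component so the invariant "single component" holds
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def segment_fat(
    ct: ImageVolume,
    window: HUWindow = ADIPOSE_WINDOW,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary fat mask: ``window.lo <= HU <= window.hi`` (both inclusive),
    intersected with ``mask`` when given."""
    if ct.modality != "CT":
        raise DomainError("segment_fat requires a CT volume")
    fat = (ct.voxels >= window.lo) & (ct.voxels <= window.hi)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ct.voxels.shape:
            raise DimensionError(
                f"mask shape {mask.shape} does not match volume shape {ct.voxels.shape}"
            )
        fat &= mask
    return fat


def fat_volume(
    mask: np.ndarray,
    vol: ImageVolume,
    region_label: str = "custom",
    slice_range: Optional[tuple[int, int]] = None,
) -> FatVolumetryResult:
    """Fat volume = (number of true voxels) x voxel volume, optionally
    restricted to an axial half-open ``slice_range``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.voxels.shape:
        raise DimensionError(
            f"mask shape {mask.shape} does not match volume shape {vol.voxels.shape}"
        )
    if slice_range is not None:
        lo, hi = slice_range
        mask = mask[lo:hi]
    count = int(mask.sum())
    return FatVolumetryResult(
        voxel_count=count,
        fat_volume_ml=count * voxel_volume_ml(vol),
        region_label=region_label,
        slice_range=tuple(slice_range) if slice_range is not None else None,
    )


def fat_mass_from_volume(fv_l: float, density: float = FAT_DENSITY_KG_PER_L) -> float:
    """Convert a fat volume in litres to fat mass in kg."""
    if fv_l < 0:
        raise DomainError(f"fat volume must be non-negative, got {fv_l}")
    if density <= 0:
        raise DomainError(f"density must be positive, got {density}")
    return density * fv_l


@dataclass(frozen=True)
class LimitedCoverageRegion:
    """An axially cropped volume with its provenance."""

    volume: ImageVolume
    slice_range: tuple[int, int]
    region_label: str = "limited_coverage"


def limited_coverage_region(ct: ImageVolume, lo: int, hi: int) -> LimitedCoverageRegion:
    """Crop the CT to the limited-coverage axial range ``[lo, hi)``.

    The landmarks (top of the thorax, distal ischium) must be located by the
    user; this function only performs the crop and records provenance.
    """
    return LimitedCoverageRegion(volume=crop_axial(ct, lo, hi), slice_range=(lo, hi))


def measure_fat(
    ct: ImageVolume,
    window: HUWindow = ADIPOSE_WINDOW,
    slice_range: Optional[tuple[int, int]] = None,
    use_body_mask: bool = False,
    air_threshold: float = -500.0,
) -> FatVolumetryResult:
    """One-call volumetry: optional body mask, fat window, optional LC crop."""
    mask = body_mask(ct, air_threshold) if use_body_mask else None
    fat = segment_fat(ct, window, mask)
    label = "whole_body" if slice_range is None else "limited_coverage"
    return fat_volume(fat, ct, region_label=label, slice_range=slice_range)
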