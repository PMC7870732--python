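"""Reading, writing and axial manipulation of CT/PET voxel volumes.

The in-memory container is :class:`ImageVolume`: a 3D array in
``(slice, row, column)`` order with per-axis spacing in millimetres.  CT
volumes carry Hounsfield units; PET volumes carry SUV or SUL in g/mL.
NIfTI-1 is the native on-disk format (lossless round trip); DICOM series
are read-only, with the rescale slope/intercept applied so downstream
code always sees HU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .exceptions import BoundsError, FormatError

HU_PLAUSIBLE_RANGE = (-1024.0, 3071.0)

_MODALITIES = ("CT", "PET")


@dataclass
class ImageVolume:
    """A 3D voxel grid with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU for CT, SUV/SUL (g/mL) for PET.
    spacing : tuple of float
        Physical size of one voxel along each array axis, mm.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0), mm, same axis order.
    modality : {"CT", "PET"}
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    #: array axis that indexes axial slices; fixed to 0 by normalization at read time
    axial_axis: int = field(default=0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive components, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in _MODALITIES:
            raise FormatError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if self.axial_axis != 0:
            raise FormatError("axial_axis is normalized to 0; transpose before construction")
        if self.modality == "CT" and self.voxels.size:
            lo, hi = HU_PLAUSIBLE_RANGE
            vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
            if vmin < lo or vmax > hi:
                warnings.warn(
                    f"CT voxel values [{vmin:.1f}, {vmax:.1f}] exceed the plausible HU "
                    f"range [{lo}, {hi}]",
                    stacklevel=3,
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


def voxel_volume_ml(vol: ImageVolume) -> float:
    """Volume of a single voxel in mL (= cm^3); spacing is mm so divide by 1000."""
    sz, sy, sx = vol.spacing
    return sz * sy * sx / 1000.0


def crop_axial(vol: ImageVolume, lo: int, hi: int) -> ImageVolume:
    """Keep axial slices in the half-open interval ``[lo, hi)``.

    Spacing is unchanged; the origin shifts by ``lo`` times the axial spacing
    so physical coordinates of retained voxels are preserved.
    """
    n = vol.n_slices
    if not (0 <= lo < hi <= n):
        raise BoundsError(f"invalid axial range [{lo}, {hi}) for {n} slices")
    new_origin = (vol.origin[0] + lo * vol.spacing[0], vol.origin[1], vol.origin[2])
    return replace(vol, voxels=vol.voxels[lo:hi].copy(), origin=new_origin)


# --- NIfTI (native format) -------------------------------------------------
#
# Array axes (slice, row, col) are stored as NIfTI (i, j, k) = (col, row, slice)
# so that viewers see the conventional x/y/z ordering; the transpose is undone
# on read, making write -> read an exact identity for voxels/spacing/shape.


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz).

    The modality tag is carried in the NIfTI ``descrip`` header field.
    """
    path = Path(path)
    data = np.transpose(vol.voxels, (2, 1, 0))
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([sx, sy, sz, 1.0]).astype(float)
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header["descrip"] = f"lbmct:modality={vol.modality}".encode()
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def _read_nifti(path: Path, format_hint: str | None) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    descrip = bytes(img.header["descrip"]).decode(errors="replace")
    if "modality=PET" in descrip:
        modality = "PET"
    elif "modality=CT" in descrip:
        modality = "CT"
    else:
        modality = format_hint if format_hint in _MODALITIES else "CT"
    voxels = np.transpose(np.asarray(data, dtype=np.float64), (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return ImageVolume(voxels, spacing, origin, modality)


# --- DICOM series (read-only) ----------------------------------------------


def _slice_position(ds) -> float:
    """Project ImagePositionPatient onto the slice normal."""
    ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    try:
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])
    except Exception:
        normal = np.array([0.0, 0.0, 1.0])
    return float(np.dot(ipp, normal))


def _read_dicom_series(directory: Path, format_hint: str | None) -> ImageVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append((f, pydicom.dcmread(str(f))))
        except Exception:
            continue  # non-DICOM clutter (e.g. DICOMDIR text) is skipped
    if not datasets:
        raise FormatError(f"{directory}: no readable DICOM slices")
    uids = {ds.get("SeriesInstanceUID", "") for _, ds in datasets}
    if len(uids) > 1:
        raise FormatError(
            f"{directory}: mixed series ({len(uids)} SeriesInstanceUIDs) — "
            f"files: {', '.join(f.name for f, _ in datasets)}"
        )
    datasets.sort(key=lambda item: _slice_position(item[1]))
    positions = np.array([_slice_position(ds) for _, ds in datasets])
    if len(datasets) > 1:
        gaps = np.diff(positions)
        mean_gap = float(gaps.mean())
        if mean_gap <= 0:
            raise FormatError(f"{directory}: duplicate or unordered slice positions")
        bad = np.where(np.abs(gaps - mean_gap) > 0.01 * abs(mean_gap))[0]
        if bad.size:
            names = ", ".join(datasets[i + 1][0].name for i in bad)
            raise FormatError(
                f"{directory}: inconsistent slice spacing beyond 1% at slices: {names}"
            )
        axial_spacing = mean_gap
    else:
        axial_spacing = float(datasets[0][1].get("SliceThickness", 1.0))

    slices = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(slope * arr + intercept)
    voxels = np.stack(slices, axis=0)

    first = datasets[0][1]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    ipp = [float(v) for v in first.ImagePositionPatient]
    dicom_modality = str(first.get("Modality", "CT"))
    modality = "PET" if dicom_modality in ("PT", "PET") else "CT"
    if format_hint in _MODALITIES:
        modality = format_hint
    return ImageVolume(
        voxels,
        spacing=(axial_spacing, row_sp, col_sp),
        origin=(ipp[2], ipp[1], ipp[0]),
        modality=modality,
    )


def read_volume(path: str | Path, format_hint: str | None = None) -> ImageVolume:
    """Read a NIfTI file or a directory containing one DICOM series.

    DICOM slices are ordered by physical slice position (not filename) and
    rescaled to HU at read time; spacing comes from the headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_dicom_series(path, format_hint)
    return _read_nifti(path, format_hint)
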