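"""Volume containers, NIfTI/DICOM I/O, and SUV conversion.

The package works on 3-D grids indexed ``(slice, row, col)`` with voxel
spacing ``(dz, dy, dx)`` in millimetres, ``dz`` being the inter-slice
distance.  A transverse slice is a fixed first index.  NIfTI-1 is the
canonical interchange format; DICOM series directories are read-only.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

Modality = Literal["PET", "CT", "PHANTOM"]
IntensityKind = Literal["activity_kBq_per_mL", "SUV", "arbitrary"]

#: Plausible injected-dose window from typical FDG protocols (MBq); used
#: only for a warning, never an error.
_PLAUSIBLE_DOSE_MBQ = (370.0, 555.0)


@dataclass
class VolumeImage:
    """A 3-D intensity grid with per-axis voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Non-negative finite intensities.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, all strictly positive.
    modality : {"PET", "CT", "PHANTOM"}
    intensity_kind : {"activity_kBq_per_mL", "SUV", "arbitrary"}
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = "PHANTOM"
    intensity_kind: IntensityKind = "arbitrary"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass(frozen=True)
class SuvCalibration:
    """Injected dose (MBq, decay-corrected to scan start) and body weight (kg)."""

    injected_dose_MBq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be strictly positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be strictly positive")
        lo, hi = _PLAUSIBLE_DOSE_MBQ
        if not (lo <= self.injected_dose_MBq <= hi):
            warnings.warn(
                f"injected dose {self.injected_dose_MBq:.1f} MBq is outside the "
                f"typical FDG window [{lo:.0f}, {hi:.0f}] MBq",
                stacklevel=2,
            )


@dataclass
class SegmentationMask:
    """Binary tumor labeling congruent with a source :class:`VolumeImage`."""

    mask: np.ndarray
    central_slice: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not (0 <= self.central_slice < self.mask.shape[0]):
            raise ValueError("central_slice outside mask extent")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def nonempty_slices(self) -> np.ndarray:
        """Indices of slices containing at least one true voxel."""
        return np.flatnonzero(self.mask.any(axis=(1, 2)))


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # Our array axes are (slice, row, col) = (z, y, x); nibabel stores
    # fastest-varying axis first, so we write the transposed (x, y, z) array
    # with a diagonal affine carrying (dx, dy, dz).
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def write_volume(v: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing in the header.

    The (slice, row, col) array is stored transposed to nibabel's
    (x, y, z) order so that header zooms read back as (dx, dy, dz).
    """
    import nibabel as nib

    path = Path(path)
    data = np.ascontiguousarray(v.voxels.T.astype(np.float32))
    img = nib.Nifti1Image(data, affine=_nifti_affine(v.spacing))
    img.header.set_zooms(tuple(reversed(v.spacing)))
    nib.save(img, str(path))
    return path


def write_mask(m: SegmentationMask, path: str | Path) -> Path:
    """Write a binary mask as a 0/1 uint8 NIfTI on the image grid."""
    import nibabel as nib

    path = Path(path)
    data = np.ascontiguousarray(m.mask.T.astype(np.uint8))
    img = nib.Nifti1Image(data, affine=_nifti_affine(m.spacing))
    img.header.set_zooms(tuple(reversed(m.spacing)))
    nib.save(img, str(path))
    return path


def read_volume(
    path: str | Path,
    modality: Modality = "PET",
    intensity_kind: IntensityKind = "arbitrary",
) -> VolumeImage:
    """Read a NIfTI file or a directory of single-series DICOM slices.

    DICOM slices are sorted by spatial position along the slice normal;
    inconsistent inter-slice spacing or mixed series raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        return _read_dicom_series(path, modality, intensity_kind)
    return _read_nifti(path, modality, intensity_kind)


def _read_nifti(path: Path, modality: Modality, kind: IntensityKind) -> VolumeImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return VolumeImage(
        voxels=np.asarray(data, dtype=np.float64).T,
        spacing=spacing,
        modality=modality,
        intensity_kind=kind,
    )


def _read_dicom_series(path: Path, modality: Modality, kind: IntensityKind) -> VolumeImage:
    import pydicom

    files = sorted(
        p for p in path.iterdir() if p.is_file() and not p.name.startswith(".")
    )
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM slices under {path}")
    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series")

    def z_of(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0) or (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            raise ValueError("inconsistent inter-slice spacing in DICOM series")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    dy, dx = float(ps[0]), float(ps[1])

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    vox = np.stack(slices, axis=0)
    return VolumeImage(vox, (dz, dy, dx), modality=modality, intensity_kind=kind)


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def to_suv(v: VolumeImage, cal: SuvCalibration) -> VolumeImage:
    """Convert activity concentration (kBq/mL) to body-weight SUV.

    SUV = C [kBq/mL] * body weight [g] / injected dose [kBq], taking tissue
    density as 1 g/mL.  Decay correction of the dose to scan time is the
    caller's responsibility.
    """
    if v.intensity_kind != "activity_kBq_per_mL":
        raise ValueError(
            f"to_suv requires activity_kBq_per_mL input, got {v.intensity_kind!r}"
        )
    dose_kBq = cal.injected_dose_MBq * 1000.0
    weight_g = cal.body_weight_kg * 1000.0
    suv = v.voxels * (weight_g / dose_kBq)
    return replace(v, voxels=suv, intensity_kind="SUV")
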