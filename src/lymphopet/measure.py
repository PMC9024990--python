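"""Size metrics from segmentation masks: MTDmax, MTAmax, MTV, SUVmax.

Diameters are measured between pixel centers (a single pixel has diameter
zero).  The default slice policy is the mask's central slice, matching the
clinical practice of reading maximum diameter and area off a single
transverse image; ``max_over_slices`` scans every slice instead.  The CT
metrics Dmax/Amax/TV are the same operations applied to a CT mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .imaging import SegmentationMask, VolumeImage
from .roi import EllipseROI

SlicePolicy = Literal["central", "max_over_slices"]

#: above this pixel count the diameter switches from all-pairs to convex hull
_BRUTE_FORCE_LIMIT = 2000


@dataclass
class TumorMeasurements:
    """One lesion's size metrics at one time point."""

    mtd_max_mm: float
    mta_max_mm2: float
    mtv_mm3: float
    suv_max: float | None = None
    modality: str = "PET"
    timepoint: Literal["pre", "post"] = "pre"

    def as_row(self) -> dict:
        return asdict(self)


def _slice_diameter(rows: np.ndarray, cols: np.ndarray, dy: float, dx: float) -> float:
    """Max pairwise distance between pixel centers, in mm."""
    if len(rows) < 2:
        return 0.0
    pts = np.column_stack([rows * dy, cols * dx])
    if len(pts) <= _BRUTE_FORCE_LIMIT:
        return float(pdist(pts).max())
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    return float(pdist(hp).max())


def _select_slices(mask: SegmentationMask, policy: SlicePolicy) -> list[int]:
    if policy == "central":
        return [mask.central_slice]
    return list(mask.nonempty_slices())


def max_diameter(
    mask: SegmentationMask,
    spacing: tuple[float, float, float] | None = None,
    slice_policy: SlicePolicy = "central",
) -> float:
    """MTDmax in mm on the selected transverse slice(s)."""
    dz, dy, dx = spacing or mask.spacing
    slices = _select_slices(mask, slice_policy)
    best = 0.0
    any_pixels = False
    for s in slices:
        rows, cols = np.nonzero(mask.mask[s])
        if len(rows):
            any_pixels = True
        best = max(best, _slice_diameter(rows, cols, dy, dx))
    if not any_pixels and slice_policy == "central":
        warnings.warn("central slice of mask is empty; diameter is 0", stacklevel=2)
    return best


def max_area(
    mask: SegmentationMask,
    spacing: tuple[float, float, float] | None = None,
    slice_policy: SlicePolicy = "central",
) -> float:
    """MTAmax in mm^2: true-pixel count on the selected slice times dy*dx."""
    dz, dy, dx = spacing or mask.spacing
    counts = [int(mask.mask[s].sum()) for s in _select_slices(mask, slice_policy)]
    return (max(counts) if counts else 0) * dy * dx


def volume(mask: SegmentationMask, spacing: tuple[float, float, float] | None = None) -> float:
    """MTV in mm^3: total true-voxel count times the voxel volume."""
    dz, dy, dx = spacing or mask.spacing
    return mask.voxel_count() * dz * dy * dx


def suv_max(
    v: VolumeImage,
    mask: SegmentationMask,
    scope: Literal["mask_3d", "central_slice"] = "mask_3d",
) -> float:
    """Maximum SUV within the mask (3-D) or on its central slice."""
    if v.intensity_kind != "SUV":
        raise ValueError(f"suv_max requires an SUV image, got {v.intensity_kind!r}")
    if scope == "central_slice":
        sel = np.zeros_like(mask.mask)
        sel[mask.central_slice] = mask.mask[mask.central_slice]
    else:
        sel = mask.mask
    if not sel.any():
        raise ValueError("mask is empty within the requested scope")
    return float(v.voxels[sel].max())


def elliptical_volume(
    rois: list[EllipseROI],
    spacing: tuple[float, float, float],
    slice_shape: tuple[int, int] = (168, 168),
) -> float:
    """Volume of expert-stacked ellipses (manual MTV surrogate), in mm^3.

    Each ellipse contributes its in-ellipse pixel-center count; the counts
    are summed over slices and scaled by the voxel volume.
    """
    seen: set[int] = set()
    for r in rois:
        if r.slice_index in seen:
            raise ValueError(f"duplicate slice index {r.slice_index} in ROI stack")
        seen.add(r.slice_index)
    dz, dy, dx = spacing
    total = sum(int(r.footprint(slice_shape).sum()) for r in rois)
    return total * dz * dy * dx


def measure_mask(
    mask: SegmentationMask,
    image: VolumeImage | None = None,
    modality: str = "PET",
    timepoint: Literal["pre", "post"] = "pre",
    slice_policy: SlicePolicy = "central",
) -> TumorMeasurements:
    """Bundle MTDmax/MTAmax/MTV (and SUVmax if an SUV image is given)."""
    suv = None
    if image is not None and image.intensity_kind == "SUV" and mask.mask.any():
        suv = suv_max(image, mask)
    return TumorMeasurements(
        mtd_max_mm=max_diameter(mask, slice_policy=slice_policy),
        mta_max_mm2=max_area(mask, slice_policy=slice_policy),
        mtv_mm3=volume(mask),
        suv_max=suv,
        modality=modality,
        timepoint=timepoint,
    )
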