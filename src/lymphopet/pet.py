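"""Semi-automated adaptive-threshold PET tumor segmentation.

The clinical procedure this reproduces: an expert draws an ellipse around
the lesion on the transverse slice of maximum diameter; a 3-pixel-wide
background ring is placed automatically at the ellipse border and its mean
intensity anchors the threshold; pixels inside the ellipse whose value
exceeds a chosen fraction of that reference are kept, and the connected
component at the lesion seed becomes the tumor ROI.  The same elliptical
footprint is then projected to the slices above and below, each with its own
ring, until the lesion disappears.

The ring is placed just inside the ellipse by default (the expert draws the
ellipse *around* the tumor, so the inner margin samples background and edge
tissue); an outside ring is available via ``ring_inside=False``.  Because the
ring straddles the tumor boundary in practice, its mean sits between
background and lesion uptake, which is what makes a fixed fraction of it a
usable adaptive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .imaging import SegmentationMask, VolumeImage
from .roi import EllipseROI

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class BackgroundRing:
    """Pixels at the margin of the ellipse whose mean anchors the threshold."""

    pixel_set: frozenset[tuple[int, int]]
    width: float
    mean_value: float


@dataclass
class SegmentationParams:
    """Knobs of the adaptive-threshold segmentation.

    threshold_fraction
        Fraction f in (0, 1] of the reference intensity; 0.5 is the
        clinically optimal value found by the threshold sweep.
    threshold_reference
        ``ring_mean`` (the procedure's literal rule) or ``roi_max``
        (fraction of the maximum intensity inside the ellipse, the
        conventional PET alternative).
    """

    threshold_fraction: float = 0.5
    threshold_reference: Literal["ring_mean", "roi_max"] = "ring_mean"
    connectivity: Literal[4, 8] = 8
    min_component_pixels: int = 1
    max_slices_each_side: int = 20
    ring_width: float = 3.0
    ring_inside: bool = True
    reuse_central_ring: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.ring_width < 1:
            raise ValueError("ring width must be >= 1 pixel")
        if self.min_component_pixels < 1:
            raise ValueError("min_component_pixels must be >= 1")


def background_ring(
    v: VolumeImage,
    roi: EllipseROI,
    width: float = 3.0,
    slice_index: int | None = None,
    inside: bool = True,
) -> BackgroundRing:
    """Ring of pixels within ``width`` pixels of the ellipse boundary.

    By default the ring lies just inside the ellipse.  Its arithmetic mean
    intensity is the adaptive-threshold reference.
    """
    if width < 1:
        raise ValueError("ring width must be >= 1 pixel")
    s = roi.slice_index if slice_index is None else slice_index
    if not (0 <= s < v.n_slices):
        raise ValueError(f"slice index {s} outside volume with {v.n_slices} slices")
    plane = v.voxels[s]
    roi.validate_for_slice(plane.shape, margin=0.0 if inside else width)

    rr, cc = np.meshgrid(np.arange(plane.shape[0]), np.arange(plane.shape[1]), indexing="ij")
    rho = roi.normalized_radius(rr, cc)
    side = rho <= 1.0 if inside else rho > 1.0
    # restrict the (costly) boundary-distance query to a band around rho=1
    band = side & (np.abs(rho - 1.0) <= (width + 1.0) / float(min(roi.semi_axes)) + 0.25)
    if not band.any():
        raise ValueError("background ring is empty (ellipse too small for the ring width)")
    d = roi.distance_to_boundary(rr[band], cc[band])
    sel = d <= width
    if not sel.any():
        raise ValueError("background ring is empty (ellipse too small for the ring width)")
    ring_rows = rr[band][sel]
    ring_cols = cc[band][sel]
    mean_value = float(plane[ring_rows, ring_cols].mean())
    pixel_set = frozenset(zip(ring_rows.tolist(), ring_cols.tolist()))
    return BackgroundRing(pixel_set=pixel_set, width=float(width), mean_value=mean_value)


def _seed_pixel(roi: EllipseROI, footprint: np.ndarray) -> tuple[int, int]:
    """In-footprint pixel nearest the ellipse center (Euclidean, lexicographic ties)."""
    rows, cols = np.nonzero(footprint)
    d2 = (rows - roi.center[0]) ** 2 + (cols - roi.center[1]) ** 2
    order = np.lexsort((cols, rows, d2))
    i = order[0]
    return int(rows[i]), int(cols[i])


def segment_slice(
    v: VolumeImage,
    slice_index: int,
    roi: EllipseROI,
    ring_mean: float,
    params: SegmentationParams,
) -> np.ndarray:
    """Threshold one slice inside the ellipse footprint.

    Candidate pixels are those inside the ellipse strictly exceeding
    ``f * reference`` (reference = ring mean, or the in-ellipse maximum for
    ``roi_max`` mode).  Of the candidate connected components, the one
    containing the pixel nearest the ellipse center is returned, falling
    back to the largest component (lexicographic smallest seed on ties).
    An empty mask is a valid outcome (lesion resolved).
    """
    plane = v.voxels[slice_index]
    footprint = roi.footprint(plane.shape)
    if params.threshold_reference == "ring_mean":
        if ring_mean <= 0:
            raise ValueError("ring mean must be > 0 for ring_mean thresholding")
        reference = ring_mean
    else:
        if not footprint.any():
            return np.zeros_like(footprint)
        reference = float(plane[footprint].max())

    candidates = footprint & (plane > params.threshold_fraction * reference)
    if not candidates.any():
        return candidates

    labels, n = ndimage.label(candidates, structure=_STRUCTURES[params.connectivity])
    if n == 1:
        return candidates
    seed = _seed_pixel(roi, footprint)
    lab = labels[seed]
    if lab == 0:  # seed not a candidate: largest component, ties lexicographic
        sizes = ndimage.sum_labels(candidates, labels, index=np.arange(1, n + 1))
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if len(best) > 1:
            rows, cols = np.nonzero(np.isin(labels, best))
            order = np.lexsort((cols, rows))
            lab = labels[rows[order[0]], cols[order[0]]]
        else:
            lab = int(best[0])
    return labels == lab


def project_and_segment(
    v: VolumeImage,
    central_roi: EllipseROI,
    params: SegmentationParams | None = None,
) -> SegmentationMask:
    """Segment the central slice, then project the ellipse up and down.

    Each projected slice recomputes its own ring mean (unless
    ``reuse_central_ring``) and is thresholded at the same fraction.
    Projection in a direction stops at the first slice whose mask falls
    below ``min_component_pixels``, or after ``max_slices_each_side``
    slices.  A projected slice whose ring mean is not positive falls back
    to the in-ellipse maximum as reference; an all-zero slice is empty and
    stops the projection.
    """
    params = params or SegmentationParams()
    s0 = central_roi.slice_index
    if not (0 <= s0 < v.n_slices):
        raise ValueError("central slice outside volume")

    central_ring = background_ring(
        v, central_roi, params.ring_width, slice_index=s0, inside=params.ring_inside
    )

    mask = np.zeros(v.shape, dtype=bool)
    mask[s0] = _segment_projected_slice(v, s0, central_roi, central_ring.mean_value, params)

    for direction in (-1, +1):
        for step in range(1, params.max_slices_each_side + 1):
            s = s0 + direction * step
            if not (0 <= s < v.n_slices):
                break
            if params.reuse_central_ring:
                ref = central_ring.mean_value
            else:
                ring = background_ring(
                    v, central_roi, params.ring_width, slice_index=s, inside=params.ring_inside
                )
                ref = ring.mean_value
            m = _segment_projected_slice(v, s, central_roi, ref, params)
            if m.sum() < params.min_component_pixels:
                break
            mask[s] = m

    return SegmentationMask(mask=mask, central_slice=s0, spacing=v.spacing)


def _segment_projected_slice(
    v: VolumeImage,
    slice_index: int,
    roi: EllipseROI,
    ring_mean: float,
    params: SegmentationParams,
) -> np.ndarray:
    """segment_slice with the degenerate-ring fallback used during projection."""
    if params.threshold_reference == "ring_mean" and ring_mean <= 0:
        plane = v.voxels[slice_index]
        footprint = roi.footprint(plane.shape)
        peak = float(plane[footprint].max()) if footprint.any() else 0.0
        if peak <= 0:
            return np.zeros_like(footprint)
        fallback = SegmentationParams(
            threshold_fraction=params.threshold_fraction,
            threshold_reference="roi_max",
            connectivity=params.connectivity,
            min_component_pixels=params.min_component_pixels,
            max_slices_each_side=params.max_slices_each_side,
            ring_width=params.ring_width,
            ring_inside=params.ring_inside,
        )
        return segment_slice(v, slice_index, roi, ring_mean, fallback)
    return segment_slice(v, slice_index, roi, ring_mean, params)
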