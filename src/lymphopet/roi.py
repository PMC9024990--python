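"""Elliptical region-of-interest geometry.

The expert seeds the segmentation by drawing an ellipse around the lesion on
one chosen "central" transverse slice.  All geometry is decided by
pixel-center inclusion in pixel units (row, col), with an optional rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class EllipseROI:
    """Expert ellipse on a transverse slice, in pixel units.

    ``center`` is (row, col) and may be fractional; ``semi_axes`` is (a, b)
    with ``a`` along the row axis before rotation; ``rotation`` is in
    radians, counter-clockwise in (row, col) coordinates.
    """

    slice_index: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def normalized_radius(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """rho(p) with rho<=1 inside the ellipse, =1 on the boundary."""
        r0, c0 = self.center
        a, b = self.semi_axes
        dr = np.asarray(rows, dtype=float) - r0
        dc = np.asarray(cols, dtype=float) - c0
        if self.rotation != 0.0:
            ct, st = np.cos(self.rotation), np.sin(self.rotation)
            dr, dc = ct * dr + st * dc, -st * dr + ct * dc
        return np.sqrt((dr / a) ** 2 + (dc / b) ** 2)

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.normalized_radius(rows, cols) <= 1.0

    def footprint(self, slice_shape: tuple[int, int]) -> np.ndarray:
        """Boolean (rows, cols) mask of pixel centers inside the ellipse."""
        rr, cc = np.meshgrid(
            np.arange(slice_shape[0]), np.arange(slice_shape[1]), indexing="ij"
        )
        return self.contains(rr, cc)

    def boundary_points(self, n: int = 2048) -> np.ndarray:
        """(n, 2) array of (row, col) points sampled along the boundary."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        dr, dc = a * np.cos(t), b * np.sin(t)
        if self.rotation != 0.0:
            ct, st = np.cos(self.rotation), np.sin(self.rotation)
            dr, dc = ct * dr - st * dc, st * dr + ct * dc
        r0, c0 = self.center
        return np.column_stack([r0 + dr, c0 + dc])

    def distance_to_boundary(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Euclidean pixel distance from points to the ellipse boundary.

        Computed against a dense boundary sample; exact to the sampling
        resolution (adequate at the ring widths used here).
        """
        pts = np.column_stack(
            [np.asarray(rows, float).ravel(), np.asarray(cols, float).ravel()]
        )
        tree = cKDTree(self.boundary_points())
        d, _ = tree.query(pts)
        return d.reshape(np.shape(rows))

    def validate_for_slice(self, slice_shape: tuple[int, int], margin: float = 0.0) -> None:
        """Raise if the ellipse (plus ``margin`` pixels) leaves the slice."""
        bp = self.boundary_points(512)
        lo = bp.min(axis=0) - margin
        hi = bp.max(axis=0) + margin
        if lo[0] < -0.5 or lo[1] < -0.5 or hi[0] > slice_shape[0] - 0.5 or hi[1] > slice_shape[1] - 0.5:
            raise ValueError(
                f"ellipse (with margin {margin}) exceeds slice bounds {slice_shape}"
            )


def roi_from_json(path: str | Path) -> EllipseROI:
    """Load a one-line JSON sidecar: slice, row, col, a, b, angle (radians)."""
    d = json.loads(Path(path).read_text())
    return EllipseROI(
        slice_index=int(d["slice"]),
        center=(float(d["row"]), float(d["col"])),
        semi_axes=(float(d["a"]), float(d["b"])),
        rotation=float(d.get("angle", 0.0)),
    )


def roi_to_json(roi: EllipseROI, path: str | Path) -> None:
    d = {
        "slice": roi.slice_index,
        "row": roi.center[0],
        "col": roi.center[1],
        "a": roi.semi_axes[0],
        "b": roi.semi_axes[1],
        "angle": roi.rotation,
    }
    Path(path).write_text(json.dumps(d) + "\n")
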