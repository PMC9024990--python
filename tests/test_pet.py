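"""Adaptive-threshold segmentation: ring, slice thresholding, projection."""

from dataclasses import replace

import numpy as np
import pytest

from lymphopet import (
    EllipseROI,
    PhantomSpec,
    SegmentationParams,
    VolumeImage,
    background_ring,
    make_phantom,
    project_and_segment,
    segment_slice,
    suggest_roi,
)
from lymphopet.pet import _STRUCTURES

from conftest import two_level_slice


def flood_fill_components(candidates: np.ndarray, connectivity: int):
    """Brute-force BFS connected components (test oracle)."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(candidates, bool)
    comps = []
    for r0, c0 in zip(*np.nonzero(candidates)):
        if seen[r0, c0]:
            continue
        comp = np.zeros_like(candidates, bool)
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = comp[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < candidates.shape[0] and 0 <= cc < candidates.shape[1]:
                    if candidates[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = comp[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(comp)
    return comps


def oracle_select(candidates, roi, footprint, connectivity):
    """Reference component-selection rule: seed component, else largest."""
    comps = flood_fill_components(candidates, connectivity)
    if not comps:
        return np.zeros_like(candidates)
    rows, cols = np.nonzero(footprint)
    d2 = (rows - roi.center[0]) ** 2 + (cols - roi.center[1]) ** 2
    order = np.lexsort((cols, rows, d2))
    seed = (int(rows[order[0]]), int(cols[order[0]]))
    for comp in comps:
        if comp[seed]:
            return comp
    sizes = [c.sum() for c in comps]
    best = max(sizes)
    tied = [c for c, s in zip(comps, sizes) if s == best]
    keyed = [(min(zip(*np.nonzero(c))), i) for i, c in enumerate(tied)]
    return tied[min(keyed)[1]]


class TestBackgroundRing:
    def test_constant_field_mean(self):
        v = VolumeImage(np.full((1, 40, 40), 7.0), (1, 1, 1))
        roi = EllipseROI(0, (20, 20), (12, 10))
        ring = background_ring(v, roi, width=3)
        assert ring.mean_value == pytest.approx(7.0)
        assert len(ring.pixel_set) > 0

    def test_ring_in_background_of_two_level_slice(self):
        # disk radius 8 centred, ellipse radius 14: ring lies in background
        v, _ = two_level_slice(radius=8, hot=10.0, cold=1.0)
        roi = EllipseROI(0, (20, 20), (14, 14))
        ring = background_ring(v, roi, width=3)
        assert ring.mean_value == pytest.approx(1.0)

    def test_ring_pixels_near_boundary(self):
        v = VolumeImage(np.zeros((1, 60, 60)), (1, 1, 1))
        roi = EllipseROI(0, (30, 30), (20, 15))
        ring = background_ring(v, roi, width=3)
        rows, cols = zip(*ring.pixel_set)
        d = roi.distance_to_boundary(np.array(rows), np.array(cols))
        assert d.max() <= 3.0 + 1e-6
        assert np.all(roi.contains(np.array(rows), np.array(cols)))

    def test_zero_width_rejected(self):
        v = VolumeImage(np.zeros((1, 40, 40)), (1, 1, 1))
        with pytest.raises(ValueError, match="width"):
            background_ring(v, EllipseROI(0, (20, 20), (10, 10)), width=0)

    def test_ellipse_exceeding_slice_rejected(self):
        v = VolumeImage(np.zeros((1, 40, 40)), (1, 1, 1))
        with pytest.raises(ValueError, match="bounds"):
            background_ring(v, EllipseROI(0, (20, 20), (25, 10)), width=3)


class TestSegmentSlice:
    def test_literal_reading_includes_warm_background(self, centered_ellipse):
        # background 1 > 0.5 * ring mean 1: whole footprint is candidate
        v, disk = two_level_slice(hot=10.0, cold=1.0)
        mask = segment_slice(v, 0, centered_ellipse, 1.0, SegmentationParams())
        foot = centered_ellipse.footprint((40, 40))
        assert np.array_equal(mask, foot)

    def test_cold_background_recovers_exact_disk(self, centered_ellipse):
        v, disk = two_level_slice(hot=10.0, cold=0.4)
        mask = segment_slice(v, 0, centered_ellipse, 1.0, SegmentationParams())
        np.testing.assert_array_equal(mask, disk)

    def test_strict_inequality_gives_empty_mask_at_f1(self, centered_ellipse):
        v = VolumeImage(np.full((1, 40, 40), 5.0), (1, 1, 1))
        params = SegmentationParams(threshold_fraction=1.0)
        mask = segment_slice(v, 0, centered_ellipse, 5.0, params)
        assert not mask.any()

    def test_component_selection_keeps_disk_at_center(self):
        plane = np.full((40, 40), 0.1)
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        disk_a = (rr - 20) ** 2 + (cc - 14) ** 2 <= 9
        disk_b = (rr - 20) ** 2 + (cc - 28) ** 2 <= 9
        plane[disk_a] = plane[disk_b] = 10.0
        v = VolumeImage(plane[None], (1, 1, 1))
        roi = EllipseROI(0, (20, 19), (13, 15))  # center pixel inside disk A
        mask = segment_slice(v, 0, roi, 1.0, SegmentationParams())
        np.testing.assert_array_equal(mask, disk_a)

    def test_non_positive_ring_mean_rejected(self, centered_ellipse):
        v = VolumeImage(np.ones((1, 40, 40)), (1, 1, 1))
        with pytest.raises(ValueError, match="ring mean"):
            segment_slice(v, 0, centered_ellipse, 0.0, SegmentationParams())

    def test_roi_max_mode_thresholds_on_in_ellipse_maximum(self, centered_ellipse):
        v, disk = two_level_slice(hot=10.0, cold=1.0)
        params = SegmentationParams(threshold_reference="roi_max")
        mask = segment_slice(v, 0, centered_ellipse, 1.0, params)
        np.testing.assert_array_equal(mask, disk)  # 0.5*10 excludes warm bg

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_slices(self, connectivity):
        rng = np.random.default_rng(42)
        params = SegmentationParams(connectivity=connectivity)
        for _ in range(120):
            n = int(rng.integers(16, 33))
            plane = rng.random((n, n)) * 10
            a = rng.uniform(3, n / 2 - 1)
            b = rng.uniform(3, n / 2 - 1)
            roi = EllipseROI(0, (n / 2, n / 2), (a, b), rotation=rng.uniform(0, np.pi))
            v = VolumeImage(plane[None], (1, 1, 1))
            f = rng.uniform(0.2, 0.9)
            ring_mean = float(rng.uniform(2, 8))
            mask = segment_slice(
                v, 0, roi, ring_mean, replace(params, threshold_fraction=f)
            )
            foot = roi.footprint((n, n))
            candidates = foot & (plane > f * ring_mean)
            if not candidates.any():
                assert not mask.any()
                continue
            expected = oracle_select(candidates, roi, foot, connectivity)
            np.testing.assert_array_equal(mask, expected)


class TestProjectAndSegment:
    def test_mask_extent_matches_ellipsoid_extent(self, default_phantom, default_roi):
        spec, v, truth = default_phantom
        mask = project_and_segment(v, default_roi)
        np.testing.assert_array_equal(
            mask.nonempty_slices(), truth.truth_mask.nonempty_slices()
        )

    def test_noiseless_phantom_recovered_voxel_for_voxel(self, default_phantom, default_roi):
        spec, v, truth = default_phantom
        mask = project_and_segment(v, default_roi)
        np.testing.assert_array_equal(mask.mask, truth.truth_mask.mask)

    def test_single_slice_lesion_stops_immediately(self):
        vox = np.zeros((9, 40, 40))
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 36
        vox[4][disk] = 10.0
        v = VolumeImage(vox, (1, 1, 1))
        roi = EllipseROI(4, (20, 20), (10, 10))
        mask = project_and_segment(v, roi)
        np.testing.assert_array_equal(mask.nonempty_slices(), [4])

    def test_lesion_extents_fall_in_clinical_slice_range(self):
        # axial semi-axes spanning the generator's realistic range: the
        # segmented extent stays within the 5-20 slices seen clinically
        for az, seed in [(8.0, 1), (15.0, 2), (24.0, 3)]:
            spec = PhantomSpec(lesion_semi_axes_mm=(az, 25.0, 20.0), seed=seed)
            v, truth = make_phantom(spec)
            mask = project_and_segment(v, suggest_roi(spec, truth))
            n = len(mask.nonempty_slices())
            assert 5 <= n <= 20
            assert n == len(truth.truth_mask.nonempty_slices())

    def test_threshold_nesting_on_random_phantoms(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec = PhantomSpec(
                shape=(24, 96, 96),
                lesion_semi_axes_mm=(
                    rng.uniform(8, 14), rng.uniform(15, 30), rng.uniform(15, 30)
                ),
                lesion_activity=rng.uniform(5, 15),
                seed=int(rng.integers(1 << 16)),
            )
            v, truth = make_phantom(spec)
            roi = suggest_roi(spec, truth)
            prev = None
            for f in (0.3, 0.4, 0.5, 0.6, 0.7):
                m = project_and_segment(
                    v, roi, SegmentationParams(threshold_fraction=f)
                ).mask
                if prev is not None:
                    assert np.all(m <= prev), f"mask at {f} not nested"
                prev = m

    def test_containment_in_projected_footprint(self, default_phantom, default_roi):
        spec, v, truth = default_phantom
        mask = project_and_segment(v, default_roi)
        foot = default_roi.footprint(v.voxels.shape[1:])
        assert not np.any(mask.mask & ~foot[None, :, :])

    def test_idempotent(self, default_phantom, default_roi):
        spec, v, truth = default_phantom
        m1 = project_and_segment(v, default_roi)
        m2 = project_and_segment(v, default_roi)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert m1.central_slice == m2.central_slice
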