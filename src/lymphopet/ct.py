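"""CT lesion segmentation: wavelet denoising, fuzzy C-means, MRF refinement.

A simplified faithful sketch of a three-stage CT pipeline: per-slice
orthogonal wavelet shrinkage to tame the poor soft-tissue contrast of
low-dose CT, fuzzy C-means (FCM) intensity clustering within the projected
expert ellipse to initialise tissue classes, and a Potts Markov-random-field
step solved by iterated conditional modes (ICM) to regularise the labeling.
The tumor mask is the refined class whose mean intensity is highest inside
the ROI (lesions are the bright soft-tissue class in the windows used
here).  All defaults (3 clusters, fuzzifier 2, beta 1) are this package's
own choices and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pywt
from scipy import ndimage

from .imaging import SegmentationMask, VolumeImage
from .pet import SegmentationParams, _STRUCTURES, _seed_pixel
from .roi import EllipseROI

_VAR_FLOOR = 1e-6  # per-class variance floor, avoids degenerate likelihoods


# ---------------------------------------------------------------------------
# Wavelet preprocessing
# ---------------------------------------------------------------------------

def wavelet_denoise(v: VolumeImage, levels: int = 1, wavelet: str = "db2") -> VolumeImage:
    """Per-slice wavelet shrinkage with the universal threshold.

    Each transverse slice is decomposed to ``levels`` scales, detail
    coefficients are soft-thresholded at sigma * sqrt(2 log n) with sigma
    estimated from the finest diagonal band (MAD / 0.6745), and the slice
    is reconstructed.  Shape and spacing are preserved.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    wav = pywt.Wavelet(wavelet)
    out = np.empty_like(v.voxels)
    for s in range(v.n_slices):
        plane = v.voxels[s]
        if min(plane.shape) < wav.dec_len:
            raise ValueError(
                f"slice {plane.shape} smaller than the {wavelet} filter support"
            )
        coeffs = pywt.wavedec2(plane, wav, level=levels, mode="symmetric")
        hh = coeffs[-1][2]
        sigma = np.median(np.abs(hh)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(plane.size)) if sigma > 0 else 0.0
        if thr > 0:
            shrunk = [coeffs[0]] + [
                tuple(pywt.threshold(d, thr, mode="soft") for d in level)
                for level in coeffs[1:]
            ]
        else:  # noise-free slice: nothing to shrink
            shrunk = coeffs
        rec = pywt.waverec2(shrunk, wav, mode="symmetric")
        out[s] = rec[: plane.shape[0], : plane.shape[1]]
    return replace(v, voxels=out)


# ---------------------------------------------------------------------------
# Fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass
class FcmModel:
    """Converged fuzzy C-means clustering of intensities."""

    cluster_count: int
    fuzzifier: float
    cluster_means: np.ndarray           # ascending order not guaranteed
    memberships: np.ndarray             # (n_voxels, c), rows sum to 1
    objective: float
    objective_trace: np.ndarray
    n_iter: int


def fcm_cluster(
    values: np.ndarray | VolumeImage,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = 0,
) -> FcmModel:
    """Standard FCM on a 1-D intensity sample.

    Means are initialised from seeded, slightly jittered quantiles of the
    intensity histogram; memberships and means alternate until the
    objective J_m = sum_i sum_k u_ik^m (x_i - mu_k)^2 changes by less than
    ``tol`` (relatively) or ``max_iter`` is reached.  J_m is non-increasing
    across iterations.
    """
    if isinstance(values, VolumeImage):
        values = values.voxels
    x = np.asarray(values, dtype=float).ravel()
    if c < 2:
        raise ValueError("cluster count must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    if np.unique(x).size < c:
        raise ValueError(f"fewer distinct intensities than clusters ({c})")

    rng = np.random.default_rng(seed)
    q = np.linspace(0.0, 1.0, c + 2)[1:-1]
    means = np.quantile(x, q)
    span = x.max() - x.min()
    means = means + rng.normal(0.0, 1e-3 * span + 1e-12, size=c)

    trace = []
    u = _fcm_memberships(x, means, m)
    for it in range(1, max_iter + 1):
        um = u**m
        means = um.T @ x / um.sum(axis=0)
        u = _fcm_memberships(x, means, m)
        obj = float((u**m * (x[:, None] - means[None, :]) ** 2).sum())
        trace.append(obj)
        if it > 1 and abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            break
    return FcmModel(
        cluster_count=c,
        fuzzifier=m,
        cluster_means=means,
        memberships=u,
        objective=trace[-1],
        objective_trace=np.asarray(trace),
        n_iter=len(trace),
    )


def _fcm_memberships(x: np.ndarray, means: np.ndarray, m: float) -> np.ndarray:
    d2 = (x[:, None] - means[None, :]) ** 2
    exact = d2 < 1e-24
    d2 = np.maximum(d2, 1e-24)
    u = 1.0 / (d2 ** (1.0 / (m - 1.0)))
    u /= u.sum(axis=1, keepdims=True)
    # voxels sitting exactly on a mean get crisp membership there
    rows = exact.any(axis=1)
    if rows.any():
        u[rows] = exact[rows] / exact[rows].sum(axis=1, keepdims=True)
    return u


def hard_labels(model: FcmModel) -> np.ndarray:
    return np.argmax(model.memberships, axis=1)


# ---------------------------------------------------------------------------
# MRF refinement (Potts model, ICM)
# ---------------------------------------------------------------------------

@dataclass
class MrfParams:
    """Potts smoothness weight and ICM iteration limits."""

    beta: float = 1.0
    max_iterations: int = 20
    neighborhood: Literal["6-3d", "4-2d"] = "6-3d"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _neighbor_shifts(neighborhood: str) -> list[tuple[int, int, int]]:
    if neighborhood == "6-3d":
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    return [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def mrf_energy(labels, values, means, sigmas, beta, neighborhood="6-3d") -> float:
    """E = sum_i (x_i - mu_l)^2 / (2 sigma_l^2) + beta * #{unequal neighbor pairs}."""
    data = ((values - means[labels]) ** 2 / (2.0 * sigmas[labels] ** 2)).sum()
    pair = 0
    for dz, dy, dx in _neighbor_shifts(neighborhood):
        if dz + dy + dx < 0:
            continue  # count each undirected pair once
        a = labels[max(dz, 0):labels.shape[0] - max(-dz, 0) or None,
                   max(dy, 0):labels.shape[1] - max(-dy, 0) or None,
                   max(dx, 0):labels.shape[2] - max(-dx, 0) or None]
        b = labels[max(-dz, 0):labels.shape[0] - max(dz, 0) or None,
                   max(-dy, 0):labels.shape[1] - max(dy, 0) or None,
                   max(-dx, 0):labels.shape[2] - max(dx, 0) or None]
        pair += int((a != b).sum())
    return float(data + beta * pair)


def mrf_refine(
    labels: np.ndarray,
    v: VolumeImage | np.ndarray,
    params: MrfParams | None = None,
    n_classes: int | None = None,
) -> np.ndarray:
    """ICM refinement of a hard labeling under a Gaussian + Potts energy.

    Per sweep, class means and SDs are re-estimated from the current
    labeling, then every voxel takes the label minimising its local
    energy (x - mu_l)^2 / (2 sigma_l^2) + beta * (# disagreeing
    neighbors).  Total energy is non-increasing within a sweep's update
    pattern; iteration stops when no label changes or at max_iterations.
    An emptied class is re-seeded at the voxel nearest its last mean.
    """
    params = params or MrfParams()
    values = v.voxels if isinstance(v, VolumeImage) else np.asarray(v, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != values.shape:
        raise ValueError("labels must be congruent with the image grid")
    labels = labels.astype(np.int64).copy()
    k = n_classes or int(labels.max()) + 1
    shifts = _neighbor_shifts(params.neighborhood)

    means = np.zeros(k)
    sigmas = np.ones(k)
    for _ in range(params.max_iterations):
        for lab in range(k):
            sel = labels == lab
            if not sel.any():
                # re-seed an emptied class from the voxel nearest its mean
                import warnings

                warnings.warn(f"MRF class {lab} emptied; re-seeded", stacklevel=2)
                idx = np.unravel_index(np.argmin(np.abs(values - means[lab])), values.shape)
                labels[idx] = lab
                sel = labels == lab
            means[lab] = values[sel].mean()
            sigmas[lab] = max(values[sel].std(), np.sqrt(_VAR_FLOOR))

        data_cost = (values[..., None] - means) ** 2 / (2.0 * sigmas**2)
        disagree = np.zeros(values.shape + (k,))
        for dz, dy, dx in shifts:
            shifted = np.roll(labels, (dz, dy, dx), axis=(0, 1, 2))
            valid = np.ones(values.shape, dtype=bool)
            for ax, d in enumerate((dz, dy, dx)):
                if d == 1:
                    sl = [slice(None)] * 3
                    sl[ax] = 0
                    valid[tuple(sl)] = False
                elif d == -1:
                    sl = [slice(None)] * 3
                    sl[ax] = -1
                    valid[tuple(sl)] = False
            neq = shifted[..., None] != np.arange(k)
            disagree += neq * valid[..., None]
        new_labels = np.argmin(data_cost + params.beta * disagree, axis=-1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


# ---------------------------------------------------------------------------
# Full CT pipeline
# ---------------------------------------------------------------------------

def segment_ct(
    v: VolumeImage,
    roi: EllipseROI,
    params: SegmentationParams | None = None,
    mrf: MrfParams | None = None,
    clusters: int = 3,
    fuzzifier: float = 2.0,
    wavelet_levels: int = 1,
    seed: int | None = 0,
) -> SegmentationMask:
    """Wavelet denoise -> FCM inside the projected ROI -> ICM -> tumor mask.

    The lesion class is the refined label whose mean intensity is closest
    to the highest FCM cluster mean inside the ROI.  Slice projection and
    the stop rule mirror the PET segmenter: the ellipse footprint is
    applied to successive slices and projection stops at the first slice
    where the lesion class has fewer than ``min_component_pixels`` pixels.
    """
    params = params or SegmentationParams()
    mrf = mrf or MrfParams()
    s0 = roi.slice_index
    if not (0 <= s0 < v.n_slices):
        raise ValueError("central slice outside volume")

    den = wavelet_denoise(v, levels=wavelet_levels)
    footprint = roi.footprint(den.voxels[s0].shape)

    lo = max(0, s0 - params.max_slices_each_side)
    hi = min(v.n_slices, s0 + params.max_slices_each_side + 1)
    block = den.voxels[lo:hi]
    fp3 = np.broadcast_to(footprint, block.shape)
    vals = block[fp3]

    try:
        model = fcm_cluster(vals, c=clusters, m=fuzzifier, seed=seed)
    except ValueError:
        # fewer distinct intensities than clusters: flat ROI, no lesion
        return SegmentationMask(np.zeros(v.shape, bool), central_slice=s0, spacing=v.spacing)
    labels_flat = hard_labels(model)
    labels_block = np.zeros(block.shape, dtype=np.int64)
    labels_block[fp3] = labels_flat + 1  # 0 reserved for outside-ROI
    # outside-ROI voxels join the background class so ICM has full support
    bg = int(np.argmin(model.cluster_means)) + 1
    labels_block[~fp3] = bg
    refined = mrf_refine(labels_block - 1, block, mrf, n_classes=clusters)

    lesion_fcm = int(np.argmax(model.cluster_means))
    # match refined classes to FCM's lesion class by mean intensity
    ref_means = np.array(
        [block[refined == lab].mean() if (refined == lab).any() else -np.inf
         for lab in range(clusters)]
    )
    lesion_lab = int(np.argmin(np.abs(ref_means - model.cluster_means[lesion_fcm])))

    lesion_block = (refined == lesion_lab) & fp3
    mask = np.zeros(v.shape, dtype=bool)

    # central slice: keep the component at the lesion seed
    central = _component_at_seed(lesion_block[s0 - lo], roi, footprint, params)
    if central.sum() < params.min_component_pixels:
        import warnings

        warnings.warn(
            "no lesion: central-slice component below min_component_pixels",
            stacklevel=2,
        )
        return SegmentationMask(mask, central_slice=s0, spacing=v.spacing)
    mask[s0] = central
    for direction in (-1, +1):
        for step in range(1, params.max_slices_each_side + 1):
            s = s0 + direction * step
            if not (lo <= s < hi):
                break
            m = _component_at_seed(lesion_block[s - lo], roi, footprint, params)
            if m.sum() < params.min_component_pixels:
                break
            mask[s] = m
    return SegmentationMask(mask, central_slice=s0, spacing=v.spacing)


def _component_at_seed(
    plane: np.ndarray, roi: EllipseROI, footprint: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    if not plane.any():
        return plane
    labels, n = ndimage.label(plane, structure=_STRUCTURES[params.connectivity])
    if n == 1:
        return plane
    seed = _seed_pixel(roi, footprint)
    lab = labels[seed]
    if lab == 0:
        sizes = ndimage.sum_labels(plane, labels, index=np.arange(1, n + 1))
        lab = int(np.argmax(sizes)) + 1
    return labels == lab
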