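"""Digital phantoms with analytic ground truth, and simulated cohorts.

Stands in for patient scans: an ellipsoidal hot lesion over a (default
cold) background on a PET-like grid, optionally blurred by a Gaussian PSF
and degraded by noise.  Ground truth (mask, analytic and rasterized
volume, central-slice area/diameter, true SUVmax) is fixed *before* blur
and noise — the PSF is a measurement degradation, not a change of truth.

Paired pre/post phantoms scale the lesion semi-axes by the cube root of a
volume factor so the true percent change in volume is exact by
construction.  Measurement-level cohorts (expert vs CAD with lognormal
reading noise) and rater-pair cohorts drawn from an explicit joint
class-probability table feed the agreement statistics without images.

Default geometry mirrors a whole-body FDG PET reconstruction: 168x168
in-plane matrix, 4.06 x 4.06 x 2.5 mm voxels, lesion extents spanning
5-20 slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import SegmentationMask, VolumeImage
from .measure import max_area, max_diameter, volume as mask_volume
from .recil import ResponseClass
from .roi import EllipseROI
from .stats import linear_weights

DEFAULT_SPACING = (2.5, 4.06, 4.06)
DEFAULT_SHAPE = (40, 168, 168)

#: open/closed percent-change intervals per response class, used when a
#: target class (not an explicit scale) drives pre/post pair generation;
#: draws stay 1 point clear of the boundaries shared with a neighbour.
_CLASS_DELTA_RANGES: dict[ResponseClass, tuple[float, float]] = {
    ResponseClass.CMR: (-100.0, -100.0),
    ResponseClass.PMR: (-99.0, -30.0),
    ResponseClass.SMD: (-29.0, 19.0),
    ResponseClass.PMD: (20.0, 100.0),
}

_CLASS_DELTA_MIDPOINTS: dict[ResponseClass, float] = {
    ResponseClass.CMR: -100.0,
    ResponseClass.PMR: -65.0,
    ResponseClass.SMD: -5.0,
    ResponseClass.PMD: 60.0,
}


@dataclass
class PhantomSpec:
    """Geometry, contrast and degradation of one synthetic lesion volume."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    lesion_center_mm: tuple[float, float, float] | None = None  # grid centre if None
    lesion_semi_axes_mm: tuple[float, float, float] = (15.0, 25.0, 20.0)
    lesion_activity: float = 8.0
    background_activity: float = 0.0
    psf_fwhm_mm: float = 0.0
    noise: Literal["none", "gaussian", "poisson"] = "none"
    noise_sigma: float = 0.0       # absolute SD for gaussian noise
    poisson_scale: float = 100.0   # counts per intensity unit for poisson noise
    rotation: float = 0.0          # in-plane lesion rotation, radians
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lesion_activity <= self.background_activity:
            raise ValueError("lesion activity must exceed background activity")
        if self.background_activity < 0:
            raise ValueError("activities must be >= 0")
        if self.lesion_center_mm is None:
            self.lesion_center_mm = tuple(
                (n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing)
            )


@dataclass
class PhantomTruth:
    """Analytic and rasterized ground truth, computed pre-blur/noise."""

    truth_mask: SegmentationMask
    analytic_volume_mm3: float
    rasterized_volume_mm3: float
    central_slice: int
    central_slice_area_mm2: float
    central_slice_diameter_mm: float
    true_suv_max: float


def _rasterize_ellipsoid(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    cz, cy, cx = spec.lesion_center_mm
    az, ay, ax_ = spec.lesion_semi_axes_mm
    z = np.arange(nz) * dz - cz
    y = np.arange(ny) * dy - cy
    x = np.arange(nx) * dx - cx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    if spec.rotation != 0.0:
        ct, st = np.cos(spec.rotation), np.sin(spec.rotation)
        yy, xx = ct * yy + st * xx, -st * yy + ct * xx
    return (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax_) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Build the phantom volume and its ground truth.

    Voxel values (pixel-center rasterization) are lesion activity inside
    the ellipsoid, background outside; optional Gaussian PSF blur of the
    stated FWHM and seeded noise follow.  Raises if the lesion touches the
    grid boundary.
    """
    inside = _rasterize_ellipsoid(spec)
    if not inside.any():
        raise ValueError("lesion does not cover any voxel center")
    edge = (
        inside[0].any() or inside[-1].any()
        or inside[:, 0].any() or inside[:, -1].any()
        or inside[:, :, 0].any() or inside[:, :, -1].any()
    )
    if edge:
        raise ValueError("lesion touches the grid boundary")

    dz, dy, dx = spec.spacing
    cz = spec.lesion_center_mm[0]
    central = int(np.clip(round(cz / dz), 0, spec.shape[0] - 1))
    truth_mask = SegmentationMask(inside, central_slice=central, spacing=spec.spacing)
    az, ay, ax_ = spec.lesion_semi_axes_mm
    truth = PhantomTruth(
        truth_mask=truth_mask,
        analytic_volume_mm3=4.0 / 3.0 * np.pi * az * ay * ax_,
        rasterized_volume_mm3=mask_volume(truth_mask),
        central_slice=central,
        central_slice_area_mm2=max_area(truth_mask),
        central_slice_diameter_mm=max_diameter(truth_mask),
        true_suv_max=spec.lesion_activity,
    )

    vox = np.where(inside, spec.lesion_activity, spec.background_activity).astype(float)
    if spec.psf_fwhm_mm > 0:
        sigma_mm = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        ndimage.gaussian_filter(vox, sigma=[sigma_mm / s for s in spec.spacing], output=vox)
    if spec.noise != "none":
        rng = np.random.default_rng(spec.seed)
        if spec.noise == "gaussian":
            vox = np.maximum(vox + rng.normal(0.0, spec.noise_sigma, vox.shape), 0.0)
        else:
            vox = rng.poisson(np.maximum(vox, 0.0) * spec.poisson_scale) / spec.poisson_scale
    v = VolumeImage(vox, spec.spacing, modality="PHANTOM", intensity_kind="SUV")
    return v, truth


def suggest_roi(spec: PhantomSpec, truth: PhantomTruth, margin_px: float = 1.5) -> EllipseROI:
    """Expert-like ellipse on the central slice: lesion cross-section + margin.

    The margin is chosen so the 3-pixel background ring straddles the
    lesion boundary, which is what anchors the ring-mean threshold between
    background and lesion uptake.
    """
    dz, dy, dx = spec.spacing
    cz, cy, cx = spec.lesion_center_mm
    az, ay, ax_ = spec.lesion_semi_axes_mm
    s = truth.central_slice
    z_off = s * dz - cz
    frac = max(1.0 - (z_off / az) ** 2, 0.0)
    a_rows = np.sqrt(frac) * ay / dy + margin_px
    b_cols = np.sqrt(frac) * ax_ / dx + margin_px
    return EllipseROI(
        slice_index=s,
        center=(cy / dy, cx / dx),
        semi_axes=(max(a_rows, 2.0), max(b_cols, 2.0)),
        rotation=spec.rotation,
    )


# ---------------------------------------------------------------------------
# Paired pre/post phantoms
# ---------------------------------------------------------------------------

def _scale_for_class(target: ResponseClass, rng: np.random.Generator) -> float:
    lo, hi = _CLASS_DELTA_RANGES[target]
    delta = lo if lo == hi else rng.uniform(lo, hi)
    return 1.0 + delta / 100.0


def make_pre_post_pair(
    spec: PhantomSpec,
    volume_scale: float | None = None,
    target_class: ResponseClass | None = None,
    seed: int | None = None,
):
    """Pre/post phantom pair with a known true percent change.

    Post-lesion semi-axes are the pre axes times ``volume_scale**(1/3)``,
    so the true volume change is exactly ``(volume_scale - 1) * 100`` %.
    ``volume_scale = 0`` produces a lesion-free post volume (CMR).  If a
    target class is given instead, the scale is drawn (seeded) from that
    class's percent-change interval.  Returns
    ``(pre, pre_truth), (post, post_truth), true_deltas`` where the deltas
    are percent changes per metric.
    """
    rng = np.random.default_rng(seed)
    if volume_scale is None:
        if target_class is None:
            raise ValueError("give either volume_scale or target_class")
        volume_scale = _scale_for_class(ResponseClass(target_class), rng)
    elif target_class is not None:
        from .recil import classify

        implied = classify((volume_scale - 1.0) * 100.0)
        if implied != target_class:
            raise ValueError(
                f"volume_scale {volume_scale} implies {implied.name}, not "
                f"{ResponseClass(target_class).name}"
            )
    if volume_scale < 0:
        raise ValueError("volume_scale must be >= 0")

    pre = make_phantom(spec)
    if volume_scale == 0.0:
        dz, dy, dx = spec.spacing
        vox = np.full(spec.shape, spec.background_activity, dtype=float)
        if spec.noise != "none":
            noisy_spec = replace(spec, seed=None if spec.seed is None else spec.seed + 1)
            rng2 = np.random.default_rng(noisy_spec.seed)
            if spec.noise == "gaussian":
                vox = np.maximum(vox + rng2.normal(0, spec.noise_sigma, vox.shape), 0)
            else:
                vox = rng2.poisson(vox * spec.poisson_scale) / spec.poisson_scale
        post_v = VolumeImage(vox, spec.spacing, modality="PHANTOM", intensity_kind="SUV")
        empty = SegmentationMask(
            np.zeros(spec.shape, bool), central_slice=pre[1].central_slice, spacing=spec.spacing
        )
        post_truth = PhantomTruth(
            truth_mask=empty,
            analytic_volume_mm3=0.0,
            rasterized_volume_mm3=0.0,
            central_slice=pre[1].central_slice,
            central_slice_area_mm2=0.0,
            central_slice_diameter_mm=0.0,
            true_suv_max=spec.background_activity,
        )
        post = (post_v, post_truth)
    else:
        lin = volume_scale ** (1.0 / 3.0)
        post_spec = replace(
            spec,
            lesion_semi_axes_mm=tuple(a * lin for a in spec.lesion_semi_axes_mm),
            seed=None if spec.seed is None else spec.seed + 1,
        )
        post = make_phantom(post_spec)

    lin = volume_scale ** (1.0 / 3.0)
    true_deltas = {
        "mtv_mm3": (volume_scale - 1.0) * 100.0,
        "mtd_max_mm": (lin - 1.0) * 100.0,
        "mta_max_mm2": (lin**2 - 1.0) * 100.0,
        "suv_max": -100.0 if volume_scale == 0.0 else 0.0,
    }
    return pre, post, true_deltas


# ---------------------------------------------------------------------------
# Measurement-level cohorts (no images)
# ---------------------------------------------------------------------------

#: default class mix for simulated cohorts, keyed by code order (CMR, PMR,
#: SMD, PMD): a mostly-responding treated-lymphoma cohort.
DEFAULT_CLASS_MIX = {
    ResponseClass.CMR: 0.45,
    ResponseClass.PMR: 0.25,
    ResponseClass.SMD: 0.15,
    ResponseClass.PMD: 0.15,
}

#: plausible baseline magnitudes per metric: (log-mean, log-sd)
_BASELINE_LOGNORMAL = {
    "mtv_mm3": (np.log(1.2e5), 0.6),
    "mtd_max_mm": (np.log(70.0), 0.35),
    "mta_max_mm2": (np.log(2.5e3), 0.5),
    "suv_max": (np.log(10.0), 0.4),
}


def simulate_measurement_cohort(
    n: int,
    class_mix: dict[ResponseClass, float] | None = None,
    expert_noise: float = 0.1,
    cad_noise: float = 0.1,
    seed: int | None = None,
    metrics: tuple[str, ...] = tuple(_BASELINE_LOGNORMAL),
) -> pd.DataFrame:
    """Per-subject true and noisy expert/CAD pre/post measurements.

    Each subject gets a true response class from ``class_mix``, a true
    percent change drawn from that class's interval (applied to every
    metric), and lognormally distributed baselines.  Expert and CAD
    readings are the true values times independent lognormal noise of the
    stated relative SD; a true post of zero is read as zero by both
    (a vanished lesion is recognised by either reader).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    mix = class_mix or DEFAULT_CLASS_MIX
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("class mix must be non-negative and sum to 1")
    if expert_noise < 0 or cad_noise < 0:
        raise ValueError("noise levels must be >= 0")
    rng = np.random.default_rng(seed)

    rows = []
    for subject in range(n):
        cls = classes[rng.choice(len(classes), p=probs)]
        lo, hi = _CLASS_DELTA_RANGES[cls]
        delta = lo if lo == hi else rng.uniform(lo, hi)
        row: dict = {"subject": subject, "true_class": cls.name, "true_code": int(cls)}
        row["true_delta_percent"] = delta
        for metric in metrics:
            mu, sd = _BASELINE_LOGNORMAL[metric]
            pre_true = float(rng.lognormal(mu, sd))
            post_true = pre_true * (1.0 + delta / 100.0)
            row[f"true_pre_{metric}"] = pre_true
            row[f"true_post_{metric}"] = post_true
            for rater, rel in (("expert", expert_noise), ("cad", cad_noise)):
                noise_pre = float(rng.lognormal(0.0, rel)) if rel > 0 else 1.0
                noise_post = float(rng.lognormal(0.0, rel)) if rel > 0 else 1.0
                row[f"{rater}_pre_{metric}"] = pre_true * noise_pre
                row[f"{rater}_post_{metric}"] = 0.0 if post_true == 0.0 else post_true * noise_post
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_classes(
    cohort: pd.DataFrame, rater: str, metric: str, cmr_tolerance: float = 0.0
) -> np.ndarray:
    """Response codes a rater assigns from its noisy pre/post readings."""
    from .recil import classify, percent_change

    pre = cohort[f"{rater}_pre_{metric}"].to_numpy(float)
    post = cohort[f"{rater}_post_{metric}"].to_numpy(float)
    return np.array(
        [int(classify(percent_change(p, q), cmr_tolerance=cmr_tolerance)) for p, q in zip(pre, post)]
    )


# ---------------------------------------------------------------------------
# Rater pairs from an explicit joint distribution (known population kappa)
# ---------------------------------------------------------------------------

def confusion_joint(
    truth_probs: np.ndarray, accuracy: float = 0.7, k: int = 4
) -> np.ndarray:
    """Joint class table of two conditionally independent noisy raters.

    Each rater reports the true class with probability ``accuracy`` and
    spills the remainder evenly onto the adjacent classes (all of it to
    the single neighbour at the ends of the scale).
    """
    truth_probs = np.asarray(truth_probs, float)
    q = np.zeros((k, k))  # q[t, r] = P(report r | truth t)
    for t in range(k):
        q[t, t] = accuracy
        nbrs = [j for j in (t - 1, t + 1) if 0 <= j < k]
        for j in nbrs:
            q[t, j] = (1.0 - accuracy) / len(nbrs)
    return np.einsum("t,ti,tj->ij", truth_probs, q, q)


def population_weighted_kappa(joint: np.ndarray) -> float:
    """Closed-form linearly weighted kappa of a joint class distribution."""
    p = np.asarray(joint, float)
    p = p / p.sum()
    w = linear_weights(p.shape[0])
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(p.sum(1), p.sum(0))).sum())
    return (p_o - p_e) / (1.0 - p_e)


def simulate_rater_pairs(
    joint: np.ndarray, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw an n-subject contingency table from a joint class distribution."""
    rng = np.random.default_rng(seed)
    p = np.asarray(joint, float)
    k = p.shape[0]
    counts = rng.multinomial(n, (p / p.sum()).ravel())
    return counts.reshape(k, k)
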