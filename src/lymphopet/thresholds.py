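"""Threshold sweep against ground-truth outlines.

Runs the adaptive segmentation at several threshold fractions and scores
each against a reference mask, mirroring the ROC-style study used to pick
the clinically optimal fraction.  Dice is the primary selection criterion;
sensitivity and specificity are reported alongside, specificity being
computed within the projected ellipse footprint (outside it the negatives
are trivially correct and would saturate the score).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import SegmentationMask, VolumeImage
from .pet import SegmentationParams, project_and_segment
from .roi import EllipseROI

DEFAULT_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class ThresholdSweepResult:
    table: pd.DataFrame  # fraction, dice, sensitivity, specificity, volume_error_percent
    best_fraction: float

    @property
    def fractions(self) -> np.ndarray:
        return self.table["fraction"].to_numpy()


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, truth).sum() / denom


def sweep_thresholds(
    v: VolumeImage,
    roi: EllipseROI,
    truth: SegmentationMask,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    params: SegmentationParams | None = None,
    criterion: str = "dice",
) -> ThresholdSweepResult:
    """Segment at each fraction and score against the reference mask."""
    if truth.shape != v.shape:
        raise ValueError("truth mask must be congruent with the volume")
    if truth.voxel_count() == 0:
        raise ValueError("truth mask is empty")
    fractions = tuple(sorted(float(f) for f in fractions))
    if len(set(fractions)) != len(fractions):
        raise ValueError("fractions must be strictly increasing")
    base = params or SegmentationParams()

    # evaluation footprint: the projected ellipse over the reachable slices
    fp2 = roi.footprint(v.voxels.shape[1:])
    lo = max(0, roi.slice_index - base.max_slices_each_side)
    hi = min(v.n_slices, roi.slice_index + base.max_slices_each_side + 1)
    fp3 = np.zeros(v.shape, dtype=bool)
    fp3[lo:hi] = fp2

    t = truth.mask
    rows = []
    for f in fractions:
        pred = project_and_segment(v, roi, replace(base, threshold_fraction=f)).mask
        tp = np.logical_and(pred, t).sum()
        fn = np.logical_and(~pred, t).sum()
        neg = fp3 & ~t
        tn = np.logical_and(neg, ~pred).sum()
        fp = np.logical_and(neg, pred).sum()
        vol_err = (pred.sum() - t.sum()) / t.sum() * 100.0
        rows.append(
            {
                "fraction": f,
                "dice": dice_coefficient(pred, t),
                "sensitivity": tp / (tp + fn) if (tp + fn) else 0.0,
                "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
                "volume_error_percent": vol_err,
                "predicted_voxels": int(pred.sum()),
            }
        )
    table = pd.DataFrame(rows)
    result = ThresholdSweepResult(table=table, best_fraction=float("nan"))
    result.best_fraction = select_best(result, criterion=criterion)
    return result


def select_best(r: ThresholdSweepResult, criterion: str = "dice") -> float:
    """Argmax of the criterion; ties broken toward the lower fraction."""
    if len(r.table) == 0:
        raise ValueError("empty sweep result")
    vals = r.table[criterion].to_numpy()
    return float(r.table["fraction"].to_numpy()[int(np.argmax(vals))])
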