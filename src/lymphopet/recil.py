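"""RECIL-style four-class response classification of percent change.

Treatment response is scored from the percent change of a size metric
between baseline and post-treatment:

* CMR (complete metabolic response, code 3): lesion gone, delta = -100%.
* PMR (partial, code 2): at least 30% reduction, -100% < delta <= -30%.
* SMD (stable, code 1): -30% < delta < 20% and no new lesions.
* PMD (progressive, code 0): delta >= 20% or new lesions appeared.

Codes decrease as response worsens so that an ordered (linearly weighted)
agreement statistic can penalize distant misclassifications more.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd


class ResponseClass(IntEnum):
    PMD = 0
    SMD = 1
    PMR = 2
    CMR = 3

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "ResponseClass":
        return cls[label.upper()]


DEFAULT_METRICS = ("mtv_mm3", "mtd_max_mm", "mta_max_mm2", "suv_max")


def percent_change(pre: float, post: float) -> float:
    """delta = (post - pre) / pre * 100; baseline must be positive."""
    if pre <= 0:
        raise ValueError(f"baseline measurement must be > 0, got {pre}")
    if post < 0:
        raise ValueError(f"post measurement must be >= 0, got {post}")
    return (post - pre) / pre * 100.0


def classify(
    delta: float,
    new_lesions: bool = False,
    cmr_tolerance: float = 0.0,
) -> ResponseClass:
    """Map a percent change onto the four response classes.

    ``cmr_tolerance`` (percentage points above -100) lets a caller accept a
    few residual segmented voxels as complete response; default 0 requires
    delta = -100 exactly.
    """
    if not np.isfinite(delta) or delta < -100.0:
        raise ValueError(f"invalid percent change {delta}")
    if new_lesions:
        return ResponseClass.PMD
    if delta <= -100.0 + cmr_tolerance:
        return ResponseClass.CMR
    if delta <= -30.0:
        return ResponseClass.PMR
    if delta < 20.0:
        return ResponseClass.SMD
    return ResponseClass.PMD


def classify_cohort(
    rows: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    cmr_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Per-metric response-class frequency table for a paired cohort.

    ``rows`` must have ``pre_<metric>`` and ``post_<metric>`` columns and
    optionally a boolean ``new_lesions`` column.  Rows with a non-positive
    baseline are reported via ``ValueError``, never silently dropped.
    Returns a (metric x class-label) count table whose rows sum to the
    cohort size.
    """
    metrics = tuple(m for m in metrics if f"pre_{m}" in rows.columns)
    labels = [c.name for c in sorted(ResponseClass, key=lambda c: -c.value)]
    counts = pd.DataFrame(0, index=list(metrics), columns=labels, dtype=int)
    bad: list[int] = []
    for metric in metrics:
        pre = rows[f"pre_{metric}"].to_numpy(dtype=float)
        if np.any(pre <= 0):
            bad.extend(np.asarray(rows.index)[pre <= 0].tolist())
    if bad:
        raise ValueError(
            f"rows with non-positive baseline measurements: {sorted(set(bad))}"
        )
    new_lesions = (
        rows["new_lesions"].to_numpy(dtype=bool)
        if "new_lesions" in rows.columns
        else np.zeros(len(rows), dtype=bool)
    )
    for metric in metrics:
        pre = rows[f"pre_{metric}"].to_numpy(dtype=float)
        post = rows[f"post_{metric}"].to_numpy(dtype=float)
        for p, q, nl in zip(pre, post, new_lesions):
            cls = classify(percent_change(p, q), new_lesions=bool(nl), cmr_tolerance=cmr_tolerance)
            counts.loc[metric, cls.name] += 1
    return counts


def classify_table(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    metric: str,
    on: str = "patient_id",
    cmr_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Join pre/post tables on an id column and classify one metric.

    Returns a table of id, pre, post, delta_percent, label, code.
    """
    merged = pre[[on, metric]].merge(post[[on, metric]], on=on, suffixes=("_pre", "_post"))
    out = []
    for _, row in merged.iterrows():
        d = percent_change(float(row[f"{metric}_pre"]), float(row[f"{metric}_post"]))
        cls = classify(d, cmr_tolerance=cmr_tolerance)
        out.append(
            {
                on: row[on],
                "pre": row[f"{metric}_pre"],
                "post": row[f"{metric}_post"],
                "delta_percent": d,
                "label": cls.name,
                "code": int(cls),
            }
        )
    return pd.DataFrame(out)
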