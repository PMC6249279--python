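"""Threshold-based detection metrics: accuracy, precision, recall, Jaccard.

These are the metrics the SMLM software challenges use to score
localization algorithms.  Each ground-truth emitter s_j owns a circular
true-positive (TP) region of radius equal to the PSF FWHM.  An estimated
point is TP if it lies in any emitter's circle (closed disk), FP
otherwise; an emitter is FN if its circle contains no estimate.  Then

    Accuracy  = sqrt( mean over TP points of a_i^2 )   [nm]
    Precision = |TP| / (|TP| + |FP|)
    Recall    = |TP| / (|TP| + |FN|)
    JAC       = |TP| / (|TP| + |FP| + |FN|)

with a_i the distance from a TP point to its nearest emitter.  Accuracy
is undefined when there are no TP points (``None`` here, "NA" in
serialized tables).  These metrics are discontinuous at the circle
boundary and blind to where FP/FN points actually sit — properties the
continuous RMSMD metric is designed to avoid; both are exposed so they
can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import min_sq_dists, rmsmd
from .pointset import PointSet, _check_pair

__all__ = [
    "TPRegionClassification",
    "classify",
    "accuracy",
    "precision",
    "recall",
    "jaccard",
    "metrics_record",
    "format_value",
]


@dataclass(frozen=True)
class TPRegionClassification:
    """TP/FP split of the estimates and FN set of the emitters.

    ``tp_dist[k]`` is the distance (nm) from the k-th TP point to its
    nearest emitter; every entry is <= ``radius``.  ``tp_idx`` and
    ``fp_idx`` partition the indices of X; ``fn_idx`` indexes S.
    """

    radius: float
    tp_idx: np.ndarray
    fp_idx: np.ndarray
    fn_idx: np.ndarray
    tp_dist: np.ndarray


def classify(x: PointSet, s: PointSet, radius: float) -> TPRegionClassification:
    """Classify estimates X against emitters S with a TP radius (nm).

    Membership is by Euclidean distance <= radius (closed disk).  A point
    inside several circles is a single TP; an emitter is rescued from FN
    by any estimate inside its circle, even one shared with another
    emitter.
    """
    _check_pair(x, s)
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    d2_x, _ = min_sq_dists(x, s)
    dist_x = np.sqrt(d2_x)
    tp_mask = dist_x <= radius
    d2_s, _ = min_sq_dists(s, x)
    fn_mask = np.sqrt(d2_s) > radius
    return TPRegionClassification(
        radius=float(radius),
        tp_idx=np.flatnonzero(tp_mask),
        fp_idx=np.flatnonzero(~tp_mask),
        fn_idx=np.flatnonzero(fn_mask),
        tp_dist=dist_x[tp_mask],
    )


def accuracy(c: TPRegionClassification) -> float | None:
    """RMS distance of TP points to their nearest emitter; None if no TP."""
    if c.tp_idx.size == 0:
        return None
    return float(math.sqrt(np.mean(c.tp_dist**2)))


def precision(c: TPRegionClassification) -> float:
    """|TP| / (|TP| + |FP|); 0 when X classifies to nothing (empty denominator)."""
    denom = c.tp_idx.size + c.fp_idx.size
    return c.tp_idx.size / denom if denom else 0.0


def recall(c: TPRegionClassification) -> float:
    """|TP| / (|TP| + |FN|); 0 on empty denominator."""
    denom = c.tp_idx.size + c.fn_idx.size
    return c.tp_idx.size / denom if denom else 0.0


def jaccard(c: TPRegionClassification) -> float:
    """|TP| / (|TP| + |FP| + |FN|); 0 on empty denominator."""
    denom = c.tp_idx.size + c.fp_idx.size + c.fn_idx.size
    return c.tp_idx.size / denom if denom else 0.0


def format_value(v: float | None, fmt: str = "{:.6g}") -> str:
    """Serialize a metric value; the undefined sentinel becomes "NA"."""
    return "NA" if v is None else fmt.format(v)


def metrics_record(x: PointSet, s: PointSet, radius: float) -> dict:
    """One-row summary: RMSMD plus the four detection metrics and counts."""
    c = classify(x, s, radius)
    return {
        "rmsmd": rmsmd(x, s),
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "jac": jaccard(c),
        "n_tp": int(c.tp_idx.size),
        "n_fp": int(c.fp_idx.size),
        "n_fn": int(c.fn_idx.size),
    }
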