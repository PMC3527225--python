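"""Ranking metrics: exact ROC/AUC via the Mann-Whitney statistic."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["roc_auc", "roc_points"]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as the exact Mann-Whitney statistic.

    Equals ``P(score+ > score-) + 0.5 * P(tie)`` over all positive-negative
    pairs, computed from average ranks (identical to trapezoidal ROC
    integration, but exact and deterministic). Labels are binary with 1 the
    positive class; both classes must be present.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks give half credit to ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as (false-positive rate, true-positive rate) pairs.

    Starts at (0, 0), ends at (1, 1), both coordinates non-decreasing.
    """
    y = np.asarray(labels)
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=np.float64))
    return np.column_stack([fpr, tpr])
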