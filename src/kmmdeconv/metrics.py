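"""Benchmark metrics: mean L1 error, Jensen-Shannon divergence, Pearson r."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .io import ValidationError

__all__ = ["mean_l1_error", "jsd", "pcc"]


def mean_l1_error(est: np.ndarray, truth: np.ndarray, as_percent: bool = True) -> float:
    """Mean absolute difference between estimated and true proportions,
    averaged over cell types; in percentage points by default."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValidationError("est and truth lengths differ")
    err = float(np.mean(np.abs(est - truth)))
    return err * 100.0 if as_percent else err


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2, so the range is [0, 1]).

    Inputs are normalized to probability vectors internally.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("p and q lengths differ")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("inputs must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValidationError("zero vector has no distribution")
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need two equal-length vectors of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input")
    return float(pearsonr(x, y).statistic)
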