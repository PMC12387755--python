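"""Histogram reverse-integration ROC classification of L-L vs L-U sessions.

Center-bin correlations of the two session groups are histogrammed on a
fixed grid (0 to 0.5 in steps of 0.001), the counts are reverse-integrated
(cumulative sum from high correlation to low) and normalized by group size
to yield the true-positive rate (L-L) and false-positive rate (L-U) as the
decision threshold sweeps downward; the trapezoidal area of TPR vs FPR is
the AUROC, reported in percent. 50% is chance discrimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ROC_HIST_BIN_WIDTH, ROC_HIST_RANGE

log = logging.getLogger("epscorr")


@dataclass(frozen=True)
class ROCResult:
    edges: np.ndarray           # 501 histogram edges, 0..0.5
    true_counts: np.ndarray     # 500 per-bin counts, true (L-L) group
    false_counts: np.ndarray
    tpr: np.ndarray             # reverse-cumulative rates, high->low threshold
    fpr: np.ndarray
    auroc_percent: float


def _histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed, right-open binning; the final bin is closed at 0.5."""
    # np.histogram uses exactly this convention (last bin closed)
    counts, _ = np.histogram(values, bins=edges)
    return counts


def auroc_center_bin(
    true_values: Sequence[float], false_values: Sequence[float]
) -> ROCResult:
    """Classify true (L-L) vs false (L-U) center-bin correlations by AUROC.

    Values must be >= 0; values above 0.5 are clipped into the top histogram
    bin with a warning.
    """
    t = np.asarray(true_values, dtype=float)
    f = np.asarray(false_values, dtype=float)
    if t.size == 0 or f.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.any(t < 0) or np.any(f < 0):
        raise ValueError("correlation values must be >= 0")
    lo, hi = ROC_HIST_RANGE
    if np.any(t > hi) or np.any(f > hi):
        log.warning("correlation values above %.2f clipped into the top bin", hi)
        t = np.minimum(t, hi)
        f = np.minimum(f, hi)
    n_bins = int(round((hi - lo) / ROC_HIST_BIN_WIDTH))
    edges = lo + ROC_HIST_BIN_WIDTH * np.arange(n_bins + 1)
    tc = _histogram(t, edges)
    fc = _histogram(f, edges)
    # reverse integration: cumulative count of values at or above each bin,
    # swept from the highest correlation bin down to the lowest
    tpr = np.concatenate([[0.0], np.cumsum(tc[::-1])]) / t.size
    fpr = np.concatenate([[0.0], np.cumsum(fc[::-1])]) / f.size
    auroc = float(np.trapezoid(tpr, fpr)) * 100.0
    return ROCResult(
        edges=edges, true_counts=tc, false_counts=fc,
        tpr=tpr, fpr=fpr, auroc_percent=auroc,
    )
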