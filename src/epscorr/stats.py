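"""Per-cell spontaneous-EPSC statistics and group comparisons.

Covers inter-event intervals (IEI) and amplitudes per cell, equal-count
subsampling for pooled cumulative-distribution comparisons, the two-sample
Kolmogorov-Smirnov test, Cohen's d effect size and paired fold change
(e.g. the IEI increase after blocking action potentials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .datatypes import EventTrain


@dataclass(frozen=True)
class EventStatSummary:
    """One cell's IEI and amplitude samples with median (IQR) summaries."""

    cell_id: str
    iei: np.ndarray             # seconds, length n_events - 1
    amplitudes: Optional[np.ndarray]
    n_events: int

    @property
    def iei_median_iqr(self) -> Tuple[float, float]:
        return _median_iqr(self.iei)

    @property
    def amplitude_median_iqr(self) -> Tuple[float, float]:
        if self.amplitudes is None:
            return (float("nan"), float("nan"))
        return _median_iqr(self.amplitudes)


def _median_iqr(x: np.ndarray) -> Tuple[float, float]:
    if x.size == 0:
        return (float("nan"), float("nan"))
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return float(q2), float(q3 - q1)


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    statistic: float
    p_value: float
    effect_size: float          # |Cohen's d|
    n_x: int
    n_y: int


def interevent_intervals(train: EventTrain) -> np.ndarray:
    """Successive differences of the sorted event times (empty if < 2 events)."""
    if train.n_events < 2:
        return np.array([])
    return np.diff(train.event_times)


def summarize_train(train: EventTrain) -> EventStatSummary:
    return EventStatSummary(
        cell_id=train.cell_id,
        iei=interevent_intervals(train),
        amplitudes=train.amplitudes,
        n_events=train.n_events,
    )


def equalize_counts(
    values_per_cell: Sequence[np.ndarray], seed: int = 0
) -> List[np.ndarray]:
    """Subsample every cell to the minimum per-cell count, without replacement.

    Pooling the equal-count per-cell samples gives each cell the same weight
    in a group cumulative distribution. Deterministic under a fixed seed.
    """
    if len(values_per_cell) == 0:
        raise ValueError("need at least one cell")
    arrays = [np.asarray(v, dtype=float) for v in values_per_cell]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every cell must contribute at least one value")
    n_star = min(a.size for a in arrays)
    rng = np.random.default_rng(seed)
    out = []
    for a in arrays:
        if a.size == n_star:
            out.append(a.copy())
        else:
            out.append(rng.choice(a, size=n_star, replace=False))
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    d = cohens_d(x, y) if min(x.size, y.size) >= 2 else float("nan")
    return GroupComparison(
        statistic_name="KS_D",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=abs(d),
        n_x=x.size,
        n_y=y.size,
    )


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with (n-1)-weighted pooled SD; sign is mean(x) - mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 values")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ZeroDivisionError("pooled SD is zero with unequal means")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def fold_change(
    before: Sequence[float], after: Sequence[float]
) -> Tuple[np.ndarray, float, float]:
    """Per-cell after/before ratios with their mean and SEM.

    Cells with a zero before-value are excluded (their ratio is undefined).
    Returns ``(ratios, mean, sem)``.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must be paired per cell")
    ok = before != 0
    ratios = after[ok] / before[ok]
    if ratios.size == 0:
        return ratios, float("nan"), float("nan")
    sem = float(sps.sem(ratios)) if ratios.size > 1 else float("nan")
    return ratios, float(ratios.mean()), sem


def group_ecdf(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF coordinates (sorted values, cumulative probability)."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size


def load_per_cell_table(path, value_column: str, cell_column: str = "cell_id",
                        group_column: str = "group") -> Dict[str, List[np.ndarray]]:
    """Load a per-cell long-format CSV into ``{group: [per-cell value arrays]}``.

    Expected columns: ``cell_id``, ``group`` and the requested value column —
    the layout used for published per-cell IEI/amplitude source tables.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in (cell_column, group_column, value_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    out: Dict[str, List[np.ndarray]] = {}
    for (grp, _), rows in df.groupby([group_column, cell_column], sort=True):
        out.setdefault(str(grp), []).append(
            rows[value_column].dropna().to_numpy(dtype=float))
    return out
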