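"""Session quality control and group matching.

Before correlation analysis, sessions with too few events or too short a
recording are excluded, and the remaining L-L and L-U groups are checked for
matched event counts, durations and rates by two-sample t-tests — mirroring
the sub-selection of pairs whose activity statistics do not differ between
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .datatypes import PairClass, PairedSession

log = logging.getLogger("epscorr")


class QCFailure(RuntimeError):
    """Raised when a pair-class group is empty after exclusion."""


@dataclass
class QCReport:
    """Outcome of session QC and LL-vs-LU group matching.

    ``group_stats`` maps (pair_class, metric) -> (mean, sem);
    ``p_values`` maps metric -> two-sample t-test p between LL and LU.
    Metrics are ``count`` (events per session, summed over the two cells is
    not used — the per-session value is the mean of the two cells),
    ``duration`` (s) and ``rate`` (Hz, mean of the two cells).
    """

    included: List[PairedSession] = field(default_factory=list)
    excluded: List[Tuple[str, str]] = field(default_factory=list)  # (session_id, reason)
    group_stats: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    p_values: Dict[str, float] = field(default_factory=dict)


def session_metrics(session: PairedSession) -> Dict[str, float]:
    """Per-session count / duration / rate (count and rate averaged over cells)."""
    counts = (session.train_a.n_events, session.train_b.n_events)
    return {
        "count": float(np.mean(counts)),
        "duration": float(session.duration),
        "rate": float(np.mean(counts) / session.duration),
    }


def exclusion_reason(session: PairedSession, config: PipelineConfig) -> str | None:
    """Return why a session fails QC, or None if it passes all minima."""
    if min(session.train_a.n_events, session.train_b.n_events) < config.qc_min_events:
        return "too few events"
    if session.duration < config.qc_min_duration:
        return "recording too short"
    if min(session.train_a.rate, session.train_b.rate) < config.qc_min_rate:
        return "event rate too low"
    return None


def qc_match_groups(
    sessions: Sequence[PairedSession],
    config: PipelineConfig,
    equal_var: bool = True,
) -> QCReport:
    """Exclude under-sampled sessions and test LL/LU matching of activity stats.

    Parameters
    ----------
    equal_var : bool
        If True (default) use Student's pooled-variance two-sample t-test;
        otherwise Welch's test.
    """
    report = QCReport()
    for s in sessions:
        reason = exclusion_reason(s, config)
        if reason is not None:
            report.excluded.append((s.session_id, reason))
            log.info("qc: excluding session %s (%s)", s.session_id, reason)
        else:
            report.included.append(s)

    groups: Dict[PairClass, List[PairedSession]] = {PairClass.LL: [], PairClass.LU: []}
    for s in report.included:
        if s.pair_class in groups:
            groups[s.pair_class].append(s)
    for pc, members in groups.items():
        if not members:
            raise QCFailure(f"no {pc.value} sessions left after QC exclusion")

    for metric in ("count", "duration", "rate"):
        values = {
            pc: np.array([session_metrics(s)[metric] for s in members])
            for pc, members in groups.items()
        }
        for pc, v in values.items():
            sem = float(stats.sem(v)) if v.size > 1 else float("nan")
            report.group_stats[(pc.value, metric)] = (float(np.mean(v)), sem)
        t = stats.ttest_ind(values[PairClass.LL], values[PairClass.LU], equal_var=equal_var)
        p = float(t.pvalue)
        report.p_values[metric] = 1.0 if np.isnan(p) else p
    log.info("qc: %d included / %d excluded; p = %s",
             len(report.included), len(report.excluded), report.p_values)
    return report
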