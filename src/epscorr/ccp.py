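"""Cross-correlation profiles of paired event trains and the jitter null.

The session-wise cross-correlation profile (CCP) bins each cell's event
times into binary occupancy vectors (bin width Delta = W/10 for a detection
window of half-width W) and evaluates the non-centered cross-correlation

    R(k) = sum_t x_t y_{t+k} / sqrt(sum_t x_t^2 * sum_t y_t^2)

at the 21 lags k = -10..10, i.e. lag times k*Delta spanning +/-W. For binary
vectors the numerator is the number of coincident occupied bins at lag k and
the denominator is the geometric mean of the occupied-bin counts, so R is a
coincidence rate normalized to lie in [0, 1]. Correlation over the full
timeline (mean-centered) is deliberately not used: joint *absence* of events
would otherwise inflate the correlation.

The significance of the aligned profile is assessed against a circular
jitter null: the second cell's whole timeline is shifted by a uniform random
offset within +/-J (default 0.5 s, 100 iterations), wrapping around the
recording duration so event counts and rates are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .config import ConfigError, N_LAG_BINS, THRESHOLD_SD_MULTIPLIER
from .datatypes import EventTrain, PairedSession

log = logging.getLogger("epscorr")


class EmptyTrainError(ValueError):
    """Raised when a CCP is requested for a session with an empty train."""


@dataclass(frozen=True)
class CCPResult:
    """One session's 21-lag cross-correlation profile for one window."""

    session_id: str
    pair_class: str
    window_half_width: float
    bin_width: float
    lags: np.ndarray            # 21 lag times in seconds, k*Delta for k=-10..10
    r: np.ndarray               # 21 correlation values in [0, 1]
    n_a: int                    # event count, train A
    n_b: int                    # event count, train B

    @property
    def r_center(self) -> float:
        """Co-occurrence: correlation in the center (zero-lag) bin."""
        return float(self.r[N_LAG_BINS // 2])

    @property
    def r_max(self) -> float:
        """Maximum correlation over all 21 lags."""
        return float(self.r.max())

    @property
    def r_max_peri(self) -> float:
        """Peri-occurrence: maximum correlation excluding the center bin."""
        mask = np.ones(N_LAG_BINS, dtype=bool)
        mask[N_LAG_BINS // 2] = False
        return float(self.r[mask].max())


def bin_events(train: EventTrain, bin_width: float) -> np.ndarray:
    """Binary bin-occupancy vector: bin b is 1 iff >=1 event in [b*D, (b+1)*D)."""
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    if bin_width >= train.duration:
        raise ConfigError(
            f"bin_width {bin_width} s must be smaller than duration {train.duration} s")
    n_bins = int(np.ceil(train.duration / bin_width))
    vec = np.zeros(n_bins, dtype=np.int8)
    if train.n_events:
        idx = np.floor(train.event_times / bin_width).astype(int)
        idx = np.minimum(idx, n_bins - 1)  # an event at exactly t == duration
        vec[idx] = 1
    return vec


def _lagged_dot(x: np.ndarray, y: np.ndarray, k: int) -> int:
    """sum_t x[t] * y[t + k] with out-of-range terms zero."""
    if k >= 0:
        return int(np.dot(x[: x.size - k] if k else x, y[k:]))
    return int(np.dot(x[-k:], y[: y.size + k]))


def compute_ccp(session: PairedSession, window_half_width: float) -> CCPResult:
    """Compute the 21-lag CCP of a session for one detection window."""
    if session.train_a.n_events == 0 or session.train_b.n_events == 0:
        raise EmptyTrainError(f"session {session.session_id}: empty event train")
    delta = window_half_width / 10.0
    x = bin_events(session.train_a, delta)
    y = bin_events(session.train_b, delta)
    denom = np.sqrt(float(x.sum()) * float(y.sum()))
    ks = np.arange(-(N_LAG_BINS // 2), N_LAG_BINS // 2 + 1)
    r = np.array([_lagged_dot(x, y, int(k)) for k in ks], dtype=float) / denom
    return CCPResult(
        session_id=session.session_id,
        pair_class=session.pair_class.value,
        window_half_width=window_half_width,
        bin_width=delta,
        lags=ks * delta,
        r=r,
        n_a=session.train_a.n_events,
        n_b=session.train_b.n_events,
    )


def poisson_chance_level(n_a: int, n_b: int, bin_width: float, duration: float) -> float:
    """Expected CCP value for independent Poisson trains: sqrt(Na*Nb)*Delta/T."""
    return float(np.sqrt(n_a * n_b) * bin_width / duration)


@dataclass(frozen=True)
class ThresholdSpec:
    """Pooled 2SD correlation threshold for one detection window.

    The pool is every lag value of every session's CCP (both pair classes);
    theta = pooled mean + 2 * sample SD. Crossings use strict inequality.
    """

    window_half_width: float
    pooled_mean: float
    pooled_sd: float
    threshold: float
    session_ids: tuple
    r_max_crossing: tuple       # bool per session: R_max > theta
    r_center_crossing: tuple    # bool per session: R_center > theta


def pooled_threshold(ccps: Sequence[CCPResult]) -> ThresholdSpec:
    """Pool all 21 x n_sessions correlations and derive theta = mean + 2 SD."""
    if not ccps:
        raise ValueError("need at least one CCP")
    windows = {c.window_half_width for c in ccps}
    if len(windows) != 1:
        raise ValueError(f"CCPs mix detection windows: {sorted(windows)}")
    pool = np.concatenate([c.r for c in ccps])
    mean = float(pool.mean())
    sd = float(pool.std(ddof=1)) if pool.size > 1 else 0.0
    theta = mean + THRESHOLD_SD_MULTIPLIER * sd
    return ThresholdSpec(
        window_half_width=windows.pop(),
        pooled_mean=mean,
        pooled_sd=sd,
        threshold=theta,
        session_ids=tuple(c.session_id for c in ccps),
        r_max_crossing=tuple(c.r_max > theta for c in ccps),
        r_center_crossing=tuple(c.r_center > theta for c in ccps),
    )


@dataclass(frozen=True)
class JitterEnsemble:
    """Per-iteration CCPs of one session under the circular-offset null."""

    session_id: str
    window_half_width: float
    offsets: np.ndarray         # K drawn offsets in seconds
    r_matrix: np.ndarray        # K x 21 correlation values
    aligned: CCPResult

    @property
    def center_values(self) -> np.ndarray:
        return self.r_matrix[:, N_LAG_BINS // 2]

    @property
    def lag_mean(self) -> np.ndarray:
        return self.r_matrix.mean(axis=0)

    @property
    def lag_sd(self) -> np.ndarray:
        return self.r_matrix.std(axis=0, ddof=1)


def _shift_train(train: EventTrain, offset: float) -> EventTrain:
    """Circularly shift every event by ``offset`` modulo the duration."""
    times = np.sort(np.mod(train.event_times + offset, train.duration))
    return EventTrain(
        cell_id=train.cell_id,
        label=train.label,
        duration=train.duration,
        event_times=times,
        amplitudes=None,
    )


def jitter_null(
    session: PairedSession,
    window_half_width: float,
    iterations: int = 100,
    jitter_bound: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> JitterEnsemble:
    """Build the jitter null ensemble for one session.

    Per iteration a single offset ~ Uniform(-J, +J) is drawn and applied to
    every event of the second cell (train_b) with circular wrap, and the CCP
    is recomputed. Event counts are preserved exactly in every iteration.
    """
    if iterations < 1:
        raise ConfigError("iterations must be >= 1")
    if jitter_bound <= 0:
        raise ConfigError("jitter_bound must be > 0")
    if jitter_bound >= session.duration / 2:
        log.warning("jitter bound %.3g s >= half the duration; wrap degenerates",
                    jitter_bound)
    if rng is None:
        rng = np.random.default_rng(seed)
    aligned = compute_ccp(session, window_half_width)
    offsets = rng.uniform(-jitter_bound, jitter_bound, size=iterations)
    rows = []
    for off in offsets:
        shifted = PairedSession(
            session_id=session.session_id,
            train_a=session.train_a,
            train_b=_shift_train(session.train_b, float(off)),
        )
        rows.append(compute_ccp(shifted, window_half_width).r)
    return JitterEnsemble(
        session_id=session.session_id,
        window_half_width=window_half_width,
        offsets=offsets,
        r_matrix=np.vstack(rows),
        aligned=aligned,
    )


def estimate_shared_fraction(
    ccp: CCPResult,
    duration: float,
    coincidence_jitter: float = 0.0,
) -> float:
    """Estimate the shared-input fraction c from the center-bin correlation.

    The center-bin correlation in excess of the Poisson chance level
    sqrt(Na*Nb)*Delta/T estimates c attenuated by the probability that both
    jittered copies of a shared event fall in the same bin; dividing by that
    closed-form detection probability de-biases the estimate.
    """
    from .synth import coincidence_detection_probability

    chance = poisson_chance_level(ccp.n_a, ccp.n_b, ccp.bin_width, duration)
    p_det = coincidence_detection_probability(coincidence_jitter, ccp.bin_width)
    return (ccp.r_center - chance) / p_det
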