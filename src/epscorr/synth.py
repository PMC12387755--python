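"""Synthetic paired event trains, EPSC amplitudes and current-clamp sweeps.

The generators emulate the study conditions of the recorded data so that
every analysis stage is testable without recordings:

* paired spontaneous-EPSC event trains with a controllable *shared-input*
  component — a common presynaptic Poisson source whose events appear in
  both cells with independent per-cell latency jitter — superimposed on
  independent background Poisson input (~0.9–1.1 Hz per cell over ~400–500 s,
  i.e. ~400–500 events per cell);
* lognormal EPSC amplitudes with medians near 15–20 pA;
* current-clamp step sweeps built by template insertion: a passive
  exponential response plus piecewise-linear action-potential templates with
  programmed threshold, amplitude, half-width, afterhyperpolarizations,
  geometric inter-spike-interval adaptation and per-spike amplitude
  attenuation, so every extracted feature has exact ground truth.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ConfigError
from .datatypes import EventTrain, Label, PairClass, PairedSession, Sweep


# ---------------------------------------------------------------------------
# paired event trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairGenConfig:
    """Ground-truth parameters of one synthetic paired recording session.

    ``shared_fraction`` (c) is the fraction of each cell's events that
    originate from the shared source; each shared event is copied into both
    trains with independent Gaussian latency jitter ``coincidence_jitter``
    (seconds), so the pairwise time difference of a shared event has SD
    ``sqrt(2) * coincidence_jitter``. ``dead_time`` emulates detector
    refractoriness: within a train, events closer than this are merged,
    keeping the earliest.
    """

    duration: float = 450.0
    rate: float = 1.0
    shared_fraction: float = 0.0
    coincidence_jitter: float = 0.002
    dead_time: float = 0.002
    amplitude_median: float = 16.69
    amplitude_sigma: float = 0.39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not (0 <= self.shared_fraction < 1):
            raise ConfigError("shared_fraction must be in [0, 1)")
        if self.rate < 0 or self.coincidence_jitter < 0 or self.dead_time < 0:
            raise ConfigError("rate, jitter and dead time must be >= 0")
        if self.amplitude_sigma <= 0:
            raise ConfigError("amplitude_sigma must be > 0")


def generate_amplitudes(
    n: int,
    median: float = 16.69,
    sigma: float = 0.39,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw ``n`` lognormal EPSC amplitudes (pA) with the given median.

    The log-amplitudes are normal with mean ``log(median)`` and SD ``sigma``,
    so the distribution median equals ``median`` exactly in the large-n limit.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    if sigma <= 0:
        raise ConfigError("sigma must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.exp(rng.normal(math.log(median), sigma, size=n))


def _enforce_dead_time(times: np.ndarray, dead_time: float) -> np.ndarray:
    """Merge events closer than ``dead_time``, keeping the earliest of a run."""
    if dead_time <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead_time:
            kept.append(t)
    return np.asarray(kept)


def generate_pair(config: PairGenConfig, session_id: str = "synth",
                  labels: Tuple[Label, Label] = (Label.LABELED, Label.LABELED),
                  ) -> PairedSession:
    """Generate one paired session with the configured shared-input structure.

    Shared events are a homogeneous Poisson process at rate ``c * r`` copied
    into both trains with independent N(0, sigma_c^2) jitter; each cell adds
    independent background at rate ``(1 - c) * r``. Events falling outside
    [0, duration] are dropped; dead-time violations are merged.
    """
    rng = np.random.default_rng(config.seed)
    T, r, c = config.duration, config.rate, config.shared_fraction
    n_shared = rng.poisson(c * r * T)
    shared = rng.uniform(0.0, T, size=n_shared)
    trains = []
    for cell_idx, label in enumerate(labels):
        jitter = rng.normal(0.0, config.coincidence_jitter, size=n_shared) \
            if config.coincidence_jitter > 0 else np.zeros(n_shared)
        own_shared = shared + jitter
        n_bg = rng.poisson((1.0 - c) * r * T)
        background = rng.uniform(0.0, T, size=n_bg)
        times = np.concatenate([own_shared, background])
        times = np.sort(times[(times >= 0.0) & (times <= T)])
        times = _enforce_dead_time(times, config.dead_time)
        amps = generate_amplitudes(
            times.size, config.amplitude_median, config.amplitude_sigma, rng=rng
        )
        trains.append(EventTrain(
            cell_id=f"{session_id}_cell{'ab'[cell_idx]}",
            label=label,
            duration=T,
            event_times=times,
            amplitudes=amps,
        ))
    return PairedSession(session_id=session_id, train_a=trains[0], train_b=trains[1])


@dataclass(frozen=True)
class CohortGenConfig:
    """Study-scale synthetic cohort: 7 L-L sessions with a shared-input
    component and 8 L-U sessions without one.

    Group-level defaults reproduce the activity envelope of the recorded
    cohort: mean rates near 0.89 Hz (L-L) and 1.06 Hz (L-U), durations near
    498 s and 397 s, hence ~400–500 events per cell. Per-session durations
    and rates are drawn from truncated normals whose SDs match the reported
    group SEMs scaled by sqrt(n).
    """

    n_ll: int = 7
    n_lu: int = 8
    shared_fraction_ll: float = 0.08
    shared_fraction_lu: float = 0.0
    rate_ll: float = 0.89
    rate_lu: float = 1.06
    rate_sd_ll: float = 0.24
    rate_sd_lu: float = 0.31
    duration_ll: float = 498.0
    duration_lu: float = 397.0
    duration_sd_ll: float = 116.0
    duration_sd_lu: float = 136.0
    min_rate: float = 0.5
    min_duration: float = 200.0
    coincidence_jitter: float = 0.002
    seed: int = 0


def generate_cohort(config: CohortGenConfig = CohortGenConfig()) -> List[PairedSession]:
    """Generate the full L-L + L-U cohort of paired sessions."""
    rng = np.random.default_rng(config.seed)
    sessions: List[PairedSession] = []
    specs = [
        (PairClass.LL, config.n_ll, config.shared_fraction_ll, config.rate_ll,
         config.rate_sd_ll, config.duration_ll, config.duration_sd_ll,
         (Label.LABELED, Label.LABELED)),
        (PairClass.LU, config.n_lu, config.shared_fraction_lu, config.rate_lu,
         config.rate_sd_lu, config.duration_lu, config.duration_sd_lu,
         (Label.LABELED, Label.UNLABELED)),
    ]
    for pc, n, c, mu_r, sd_r, mu_T, sd_T, labels in specs:
        for i in range(n):
            rate = max(config.min_rate, rng.normal(mu_r, sd_r))
            dur = max(config.min_duration, rng.normal(mu_T, sd_T))
            pair_cfg = PairGenConfig(
                duration=float(dur),
                rate=float(rate),
                shared_fraction=c,
                coincidence_jitter=config.coincidence_jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sessions.append(generate_pair(
                pair_cfg, session_id=f"{pc.value}{i:02d}", labels=labels))
    return sessions


def coincidence_detection_probability(coincidence_jitter: float, bin_width: float) -> float:
    """Probability that both copies of a shared event land in the same bin.

    With independent per-cell jitter N(0, sigma_c^2) the pairwise offset u is
    N(0, 2 sigma_c^2); conditioning on a uniform position within the bin, the
    same-bin probability is E[(1 - |u|/Delta)+] in closed form.
    """
    if coincidence_jitter <= 0:
        return 1.0
    from scipy import stats

    sigma = math.sqrt(2.0) * coincidence_jitter
    z = bin_width / sigma
    # E[(1 - |u|/Delta)+] for u ~ N(0, sigma^2)
    p_in = 2.0 * stats.norm.cdf(z) - 1.0
    e_abs = sigma * math.sqrt(2.0 / math.pi) * (1.0 - math.exp(-z * z / 2.0))
    return p_in - e_abs / bin_width


# ---------------------------------------------------------------------------
# current-clamp sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepGenConfig:
    """Ground truth for template-insertion current-clamp sweeps.

    The current protocol starts at −200 pA and increments by +40 pA per
    sweep (1 s pulses). Below rheobase the response is passive exponential
    charging toward ``rmp + rin * I``; at and above rheobase a spike train is
    inserted whose inter-spike intervals grow geometrically (programmed
    divisor adaptation ratio = first ISI / last ISI) and whose per-spike
    amplitudes decay geometrically (programmed 15th/1st attenuation ratio).
    """

    sampling_rate: float = 10_000.0
    rmp: float = -70.0                  # mV
    tau_m: float = 0.015                # s, membrane time constant
    rin: float = 150.0                  # MOhm
    ap_threshold: float = -40.0         # mV
    ap_amplitude: float = 80.0          # mV above threshold, first spike
    ap_amplitude_floor: float = 45.0    # mV; attenuation saturates here
    ap_half_width: float = 0.8          # ms
    fahp_depth: float = 8.0             # mV below threshold, minimum at +2 ms
    mahp_depth: float = 4.0             # mV below threshold, minimum at +25 ms
    plateau_gap: float = 1.5            # mV: suprathreshold plateau = threshold - gap
    first_spike_latency: float = 0.030  # s from pulse onset to first AP peak
    rheobase: float = 120.0             # pA, first current that fires
    spikes_at_rheobase: int = 6
    fi_slope: float = 0.08              # spikes per pA above rheobase
    block_current: Optional[float] = None   # pA; above this, count declines
    block_slope: float = 0.06           # spikes lost per pA above block_current
    adaptation_ratio: float = 0.5       # programmed first/last ISI divisor ratio
    attenuation_ratio: float = 1.0      # programmed 15th/1st amplitude ratio
    noise_sd: float = 0.2               # mV additive Gaussian noise
    pulse_onset: float = 0.1            # s
    pulse_duration: float = 1.0         # s
    sweep_duration: float = 1.3         # s
    current_start: float = -200.0       # pA
    current_step: float = 40.0          # pA
    n_sweeps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.pulse_onset + self.pulse_duration > self.sweep_duration:
            raise ConfigError("current pulse must fit within the sweep")
        if self.adaptation_ratio <= 0 or self.attenuation_ratio <= 0:
            raise ConfigError("adaptation and attenuation ratios must be > 0")
        if self.mahp_depth <= self.plateau_gap:
            raise ConfigError("mahp_depth must exceed plateau_gap so the medium "
                              "afterhyperpolarization is the window minimum")

    @property
    def currents(self) -> np.ndarray:
        """The graded current protocol in pA."""
        return self.current_start + self.current_step * np.arange(self.n_sweeps)

    def n_spikes(self, current: float) -> int:
        """Programmed spike count for a current step (F-I ground truth)."""
        if current < self.rheobase:
            return 0
        n = self.spikes_at_rheobase + self.fi_slope * (current - self.rheobase)
        if self.block_current is not None and current > self.block_current:
            n_at_block = self.spikes_at_rheobase + self.fi_slope * (
                self.block_current - self.rheobase)
            n = max(1.0, n_at_block - self.block_slope * (current - self.block_current))
        return int(round(n))


@dataclass(frozen=True)
class SweepGroundTruth:
    """Programmed per-sweep truth recorded alongside a generated sweep."""

    spike_peak_times: np.ndarray        # s, absolute
    spike_amplitudes: np.ndarray        # mV above threshold
    threshold: float
    half_width: float                   # ms
    fahp_depth: float
    mahp_depth: float
    rmp: float
    rin: float
    current: float


def _planned_spike_times(config: SweepGenConfig, n: int) -> Tuple[np.ndarray, float]:
    """Spike peak times for an n-spike train with geometric ISI growth.

    Returns the times and the ISI growth factor. The first ISI is chosen so
    the train spans the pulse; if the programmed train would overrun the
    pulse, trailing spikes are dropped.
    """
    onset = config.pulse_onset
    t0 = onset + config.first_spike_latency
    if n <= 0:
        return np.array([]), 1.0
    if n == 1:
        return np.array([t0]), 1.0
    # ratio = first ISI / last ISI = growth ** -(n - 2) over the n - 1 ISIs
    growth = config.adaptation_ratio ** (-1.0 / (n - 2)) if n >= 3 else 1.0
    span = config.pulse_duration - config.first_spike_latency - 0.02
    weights = growth ** np.arange(n - 1)
    isi0 = span / weights.sum()
    times = t0 + np.concatenate([[0.0], np.cumsum(isi0 * weights)])
    return times[times < onset + config.pulse_duration - 0.005], growth


def generate_sweep(config: SweepGenConfig, current: float,
                   rng: Optional[np.random.Generator] = None,
                   ) -> Tuple[Sweep, SweepGroundTruth]:
    """Generate one sweep at the given current step, with its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.sweep_duration * fs))
    t = np.arange(n_samples) / fs
    onset, offset = config.pulse_onset, config.pulse_onset + config.pulse_duration

    n = config.n_spikes(current)
    # steady-state level during the pulse: passive deflection below rheobase,
    # a depolarized plateau just under threshold when the cell fires
    if n > 0:
        v_ss = config.ap_threshold - config.plateau_gap
    else:
        v_ss = config.rmp + config.rin * current / 1000.0  # MOhm * pA -> mV (/1000)

    v = np.full(n_samples, config.rmp, dtype=float)
    in_pulse = (t >= onset) & (t < offset)
    v[in_pulse] = config.rmp + (v_ss - config.rmp) * (
        1.0 - np.exp(-(t[in_pulse] - onset) / config.tau_m))
    after = t >= offset
    v_end = config.rmp + (v_ss - config.rmp) * (
        1.0 - np.exp(-config.pulse_duration / config.tau_m))
    v[after] = config.rmp + (v_end - config.rmp) * np.exp(-(t[after] - offset) / config.tau_m)

    spike_times, _ = _planned_spike_times(config, n)
    # snap peaks onto the sample grid so programmed node values are exact
    spike_times = np.round(spike_times * fs) / fs
    amp_decay = config.attenuation_ratio ** (1.0 / 14.0)
    amplitudes = config.ap_amplitude * amp_decay ** np.arange(spike_times.size)
    amplitudes = np.maximum(amplitudes, config.ap_amplitude_floor)

    for i, (tp, amp) in enumerate(zip(spike_times, amplitudes)):
        _insert_spike(v, t, fs, config, tp, amp,
                      next_peak=spike_times[i + 1] if i + 1 < spike_times.size else None,
                      pulse_end=offset)

    if config.noise_sd > 0:
        v = v + rng.normal(0.0, config.noise_sd, size=n_samples)

    sweep = Sweep(voltage=v, sampling_rate=fs, current=current,
                  pulse_onset=onset, pulse_offset=offset)
    truth = SweepGroundTruth(
        spike_peak_times=spike_times,
        spike_amplitudes=amplitudes,
        threshold=config.ap_threshold,
        half_width=config.ap_half_width,
        fahp_depth=config.fahp_depth,
        mahp_depth=config.mahp_depth,
        rmp=config.rmp,
        rin=config.rin,
        current=current,
    )
    return sweep, truth


def _insert_spike(v: np.ndarray, t: np.ndarray, fs: float, config: SweepGenConfig,
                  tp: float, amp: float, next_peak: Optional[float],
                  pulse_end: float) -> None:
    """Overwrite the trace with one piecewise-linear spike template.

    Node layout (times relative to the peak, all snapped to samples):
    a slow ramp (< 20 mV/ms) from the local baseline to threshold, a
    symmetric triangular spike whose width at half amplitude equals the
    programmed half-width, a fast AHP trough at +2 ms, recovery to the
    plateau by +6 ms, and — when the gap to the next spike allows — a
    medium AHP dip with its minimum at +25 ms recovering by +45 ms.
    """
    thr = config.ap_threshold
    plateau = thr - config.plateau_gap
    hw = config.ap_half_width / 1000.0  # s; also the rise time and fall time
    i_peak = int(round(tp * fs))
    v_peak = thr + amp

    # slow approach ramp: start early enough that the ramp slope stays shallow
    i_thr = i_peak - max(1, int(round(hw * fs)))
    v_base = v[max(i_thr - 1, 0)]
    ramp_time = max(0.001, (thr - min(v_base, thr)) / 5.0 / 1000.0)  # <=5 mV/ms
    i_ramp0 = max(0, i_thr - max(1, int(round(ramp_time * fs))))

    nodes = [
        (i_ramp0, v[i_ramp0]),
        (i_thr, thr),
        (i_peak, v_peak),
        (i_peak + max(1, int(round(hw * fs))), thr),
        (i_peak + int(round(0.002 * fs)), thr - config.fahp_depth),
        (i_peak + int(round(0.006 * fs)), plateau),
    ]
    gap_limit = next_peak if next_peak is not None else pulse_end
    if gap_limit - tp > 0.048:
        nodes += [
            (i_peak + int(round(0.010 * fs)), plateau),
            (i_peak + int(round(0.025 * fs)), thr - config.mahp_depth),
            (i_peak + int(round(0.045 * fs)), plateau),
        ]
    idx = np.array([i for i, _ in nodes])
    vals = np.array([val for _, val in nodes])
    lo, hi = idx[0], min(idx[-1], v.size - 1)
    seg = np.arange(lo, hi + 1)
    v[lo:hi + 1] = np.interp(seg, idx, vals)


def generate_sweep_series(config: SweepGenConfig) -> List[Tuple[Sweep, SweepGroundTruth]]:
    """Generate the full graded-current protocol for one synthetic cell."""
    rng = np.random.default_rng(config.seed)
    return [generate_sweep(config, float(cur), rng=rng) for cur in config.currents]
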