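"""Intrinsic and action-potential feature extraction from current-clamp sweeps.

Features mirror standard patch-clamp practice: AP threshold by the first
derivative criterion (default 20 mV/ms), amplitude as peak minus threshold
baseline, half-width between the two half-amplitude crossings on a 200 kHz
interpolated waveform, fast/medium afterhyperpolarization minima searched
0-3 ms and 10-50 ms after the spike peak, first-spike latency, divisor
spike-frequency adaptation ratio (first ISI / last ISI), 15th/1st spike
amplitude attenuation, the F-I curve, and passive properties (resting
membrane potential and input resistance) from a hyperpolarizing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .datatypes import Sweep, ValidationError

#: dV/dt criterion of the first-derivative threshold method, mV/ms
DEFAULT_DVDT_CRITERION = 20.0
#: voltage a detected peak must exceed, mV
DEFAULT_PEAK_LEVEL = 0.0
#: interpolation rate for kinetic measurements, Hz
INTERP_RATE = 200_000.0


@dataclass(frozen=True)
class SpikeFeatures:
    """Per-spike kinetics; all voltages in mV, times in ms."""

    peak_time: float            # s, absolute
    peak_voltage: float
    threshold: float            # mV, first-derivative method
    amplitude: float            # peak minus threshold baseline
    half_width: float           # ms
    fahp: float                 # mV below threshold (nan if window unavailable)
    mahp: float


@dataclass
class CellFeatureSet:
    """Per-cell summary extracted from a graded current-step series."""

    rmp: float = float("nan")               # mV
    rin: float = float("nan")               # MOhm
    first_spike_latency: float = float("nan")   # ms, first firing sweep
    threshold: float = float("nan")
    amplitude: float = float("nan")
    half_width: float = float("nan")
    fahp: float = float("nan")
    mahp: float = float("nan")
    adaptation_ratio: float = float("nan")
    attenuation_ratio: float = float("nan")
    fi_table: Dict[float, float] = field(default_factory=dict)  # pA -> Hz
    f_max: float = float("nan")
    f_at_520: float = float("nan")


def detect_aps(
    sweep: Sweep,
    dvdt_criterion: float = DEFAULT_DVDT_CRITERION,
    peak_level: float = DEFAULT_PEAK_LEVEL,
    min_separation: float = 0.001,
) -> np.ndarray:
    """Indices of action-potential peaks in a sweep.

    A spike is a local voltage maximum above ``peak_level`` preceded within
    2 ms by a dV/dt excursion beyond ``dvdt_criterion``; peaks closer than
    ``min_separation`` are collapsed to the larger one. Zero spikes is a
    valid result.
    """
    v = sweep.voltage
    fs = sweep.sampling_rate
    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    peaks, _ = find_peaks(v, height=peak_level, distance=max(1, int(min_separation * fs)))
    look_back = max(1, int(0.002 * fs))
    good = [p for p in peaks if np.any(dvdt[max(0, p - look_back): p + 1] > dvdt_criterion)]
    return np.asarray(good, dtype=int)


def _upsample(v: np.ndarray, fs: float, lo: int, hi: int) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of samples [lo, hi] onto the 200 kHz grid.

    Shape-preserving cubic Hermite (PCHIP) rather than a natural spline:
    a global spline rings at the fast rising/falling phases of a spike,
    biasing the derivative-criterion threshold by ~1 mV.
    """
    lo = max(lo, 0)
    hi = min(hi, v.size - 1)
    t = np.arange(lo, hi + 1) / fs
    spline = PchipInterpolator(t, v[lo: hi + 1])
    tt = np.arange(t[0], t[-1], 1.0 / INTERP_RATE)
    return tt, spline(tt)


def ap_features(
    sweep: Sweep,
    peak_index: int,
    next_peak_index: Optional[int] = None,
    dvdt_criterion: float = DEFAULT_DVDT_CRITERION,
) -> Optional[SpikeFeatures]:
    """Extract one spike's kinetics from its waveform window.

    Returns None when no dV/dt criterion crossing precedes the peak. The
    afterhyperpolarization search windows (0-3 ms fast, 10-50 ms medium,
    measured from the spike peak) are truncated at the onset of the next
    spike; a feature whose window vanishes is reported as NaN.
    """
    fs = sweep.sampling_rate
    v = sweep.voltage
    pre = int(0.004 * fs)
    tt, vv = _upsample(v, fs, peak_index - pre, peak_index + int(0.004 * fs))
    t_peak = peak_index / fs
    dvdt = np.gradient(vv) * INTERP_RATE / 1000.0

    before = tt <= t_peak
    crossings = np.flatnonzero((dvdt > dvdt_criterion) & before)
    if crossings.size == 0:
        return None
    i_thr = crossings[0]
    threshold = float(vv[i_thr])

    i_peak_up = int(np.argmin(np.abs(tt - t_peak)))
    peak_voltage = float(vv[i_peak_up])
    amplitude = peak_voltage - threshold
    if amplitude <= 0:
        return None

    half_level = threshold + amplitude / 2.0
    above = vv >= half_level
    rise_candidates = np.flatnonzero(above[: i_peak_up + 1])
    fall_candidates = np.flatnonzero(~above[i_peak_up:])
    if rise_candidates.size == 0 or fall_candidates.size == 0:
        half_width = float("nan")
    else:
        t_rise = _crossing_time(tt, vv, rise_candidates[0] - 1, half_level)
        i_fall = i_peak_up + fall_candidates[0]
        t_fall = _crossing_time(tt, vv, i_fall - 1, half_level)
        half_width = (t_fall - t_rise) * 1000.0

    limit = next_peak_index / fs - 0.002 if next_peak_index is not None else np.inf
    limit = min(limit, sweep.pulse_offset)  # past the step the cell repolarizes
    fahp = _window_min_depth(sweep, t_peak, 0.0, 0.003, threshold, limit)
    mahp = _window_min_depth(sweep, t_peak, 0.010, 0.050, threshold, limit)

    return SpikeFeatures(
        peak_time=t_peak,
        peak_voltage=peak_voltage,
        threshold=threshold,
        amplitude=amplitude,
        half_width=half_width,
        fahp=fahp,
        mahp=mahp,
    )


def _crossing_time(tt: np.ndarray, vv: np.ndarray, i: int, level: float) -> float:
    """Linear sub-sample crossing time of ``level`` between samples i and i+1."""
    i = int(np.clip(i, 0, tt.size - 2))
    v0, v1 = vv[i], vv[i + 1]
    if v1 == v0:
        return float(tt[i])
    frac = np.clip((level - v0) / (v1 - v0), 0.0, 1.0)
    return float(tt[i] + frac * (tt[i + 1] - tt[i]))


def _window_min_depth(sweep: Sweep, t_peak: float, start: float, end: float,
                      threshold: float, limit: float) -> float:
    """Depth (threshold minus minimum) in [t_peak+start, min(t_peak+end, limit)]."""
    fs = sweep.sampling_rate
    lo = int(round((t_peak + start) * fs))
    hi_full = int(round((t_peak + end) * fs))
    hi = min(hi_full, int(round(limit * fs)), sweep.voltage.size - 1)
    # a window truncated below 80% of its span no longer isolates the AHP
    if hi - lo < 3 or (hi - lo) < 0.8 * (hi_full - lo):
        return float("nan")
    _, vv = _upsample(sweep.voltage, fs, lo, hi)
    return float(threshold - vv.min())


def adaptation_ratio(spike_times: Sequence[float]) -> float:
    """Divisor adaptation ratio: ISI of the first pair / ISI of the last pair.

    Requires >= 3 spikes (with exactly 3, the two intervals share the middle
    spike). Larger values mean less adaptation; 1 is a regular train.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 3:
        return float("nan")
    return float((t[1] - t[0]) / (t[-1] - t[-2]))


def attenuation_ratio(spike_amplitudes: Sequence[float]) -> float:
    """Amplitude of the 15th spike / amplitude of the 1st (needs >= 15 spikes)."""
    a = np.asarray(spike_amplitudes, dtype=float)
    if a.size < 15:
        return float("nan")
    return float(a[14] / a[0])


def fi_curve(
    sweeps: Sequence[Sweep],
    dvdt_criterion: float = DEFAULT_DVDT_CRITERION,
) -> Dict[float, float]:
    """Firing frequency (spike count / pulse duration, Hz) per current step."""
    table: Dict[float, float] = {}
    for sw in sweeps:
        n = detect_aps(sw, dvdt_criterion=dvdt_criterion).size
        table[float(sw.current)] = n / sw.pulse_duration
    return table


def passive_properties(sweep: Sweep, baseline_window: float = 0.1,
                       steady_window: float = 0.1) -> Tuple[float, float]:
    """RMP (mV) and input resistance (MOhm) from a hyperpolarizing step.

    RMP is the mean voltage over ``baseline_window`` seconds before pulse
    onset; the steady-state deflection is the mean over the last
    ``steady_window`` seconds of the pulse. Rin = deflection / current,
    reported in MOhm (mV / pA * 1000). Spiking during the step invalidates
    the sweep.
    """
    if sweep.current >= 0:
        raise ValidationError("passive properties need a negative current step")
    if detect_aps(sweep).size:
        raise ValidationError("spiking during the negative step; invalid sweep")
    fs = sweep.sampling_rate
    i_on = int(round(sweep.pulse_onset * fs))
    i_off = int(round(sweep.pulse_offset * fs))
    i_base = max(0, i_on - int(round(baseline_window * fs)))
    if i_on - i_base < 2:
        raise ValidationError("need >= 100 ms of pre-stimulus baseline")
    rmp = float(sweep.voltage[i_base:i_on].mean())
    i_ss = max(i_on, i_off - int(round(steady_window * fs)))
    deflection = float(sweep.voltage[i_ss:i_off].mean()) - rmp
    rin = deflection / sweep.current * 1000.0
    return rmp, rin


def extract_cell_features(
    sweeps: Sequence[Sweep],
    dvdt_criterion: float = DEFAULT_DVDT_CRITERION,
    adaptation_current: float = 120.0,
    attenuation_current: float = 400.0,
    passive_current: float = -200.0,
    fi_report_current: float = 520.0,
) -> CellFeatureSet:
    """Run the full per-cell feature extraction over a graded sweep series.

    AP threshold, amplitude, half-width and latency come from the first
    sweep that fires; fAHP, mAHP and the adaptation ratio from the
    ``adaptation_current`` sweep; the attenuation ratio from the
    ``attenuation_current`` sweep; passive properties from the
    ``passive_current`` sweep.
    """
    out = CellFeatureSet()
    by_current = {float(sw.current): sw for sw in sweeps}
    detected = {c: detect_aps(sw, dvdt_criterion=dvdt_criterion)
                for c, sw in by_current.items()}

    if passive_current in by_current:
        out.rmp, out.rin = passive_properties(by_current[passive_current])

    firing = sorted(c for c, peaks in detected.items() if peaks.size > 0)
    if firing:
        first = by_current[firing[0]]
        peaks = detected[firing[0]]
        feats = ap_features(first, int(peaks[0]),
                            next_peak_index=int(peaks[1]) if peaks.size > 1 else None,
                            dvdt_criterion=dvdt_criterion)
        if feats is not None:
            out.threshold = feats.threshold
            out.amplitude = feats.amplitude
            out.half_width = feats.half_width
        out.first_spike_latency = (peaks[0] / first.sampling_rate
                                   - first.pulse_onset) * 1000.0

    if adaptation_current in by_current:
        sw = by_current[adaptation_current]
        peaks = detected[adaptation_current]
        out.adaptation_ratio = adaptation_ratio(peaks / sw.sampling_rate)
        spike_feats = _spike_features_for_sweep(sw, peaks, dvdt_criterion)
        fahps = [f.fahp for f in spike_feats if np.isfinite(f.fahp)]
        mahps = [f.mahp for f in spike_feats if np.isfinite(f.mahp)]
        if fahps:
            out.fahp = float(np.mean(fahps))
        if mahps:
            out.mahp = float(np.mean(mahps))

    if attenuation_current in by_current:
        sw = by_current[attenuation_current]
        peaks = detected[attenuation_current]
        amps = [f.amplitude
                for f in _spike_features_for_sweep(sw, peaks, dvdt_criterion)]
        out.attenuation_ratio = attenuation_ratio(amps)

    out.fi_table = fi_curve(sweeps, dvdt_criterion=dvdt_criterion)
    if out.fi_table:
        out.f_max = max(out.fi_table.values())
        out.f_at_520 = out.fi_table.get(fi_report_current, float("nan"))
    return out


def _spike_features_for_sweep(sweep: Sweep, peaks: np.ndarray,
                              dvdt_criterion: float) -> List[SpikeFeatures]:
    feats = []
    for j, p in enumerate(peaks):
        nxt = int(peaks[j + 1]) if j + 1 < peaks.size else None
        f = ap_features(sweep, int(p), next_peak_index=nxt,
                        dvdt_criterion=dvdt_criterion)
        if f is not None:
            feats.append(f)
    return feats
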