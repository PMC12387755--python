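"""Spike detection and intrinsic-feature extraction."""

import numpy as np
import pytest

from epscorr import (
    Sweep,
    SweepGenConfig,
    adaptation_ratio,
    attenuation_ratio,
    ap_features,
    detect_aps,
    extract_cell_features,
    fi_curve,
    generate_sweep,
    generate_sweep_series,
    passive_properties,
)
from epscorr.datatypes import ValidationError


def triangular_spike_sweep(baseline=0.0, peak=80.0, half_width_ms=1.0, fs=10_000.0):
    """Analytic symmetric triangular spike on a flat baseline (no noise)."""
    n = int(0.2 * fs)
    v = np.full(n, baseline)
    i_peak = n // 2
    rise = int(round(half_width_ms / 1000.0 * fs))
    for j in range(rise + 1):
        v[i_peak - rise + j] = baseline + (peak - baseline) * j / rise
        v[i_peak + rise - j] = baseline + (peak - baseline) * j / rise
    return Sweep(voltage=v, sampling_rate=fs, current=120.0,
                 pulse_onset=0.0, pulse_offset=n / fs), i_peak


class TestDetectAps:
    def test_passive_sweep_has_no_spikes(self):
        sweep, _ = generate_sweep(SweepGenConfig(seed=0, noise_sd=0.2), -80.0)
        assert detect_aps(sweep).size == 0

    def test_all_programmed_spikes_found_at_programmed_times(self):
        cfg = SweepGenConfig(seed=1)
        sweep, truth = generate_sweep(cfg, 400.0)
        peaks = detect_aps(sweep)
        assert peaks.size == truth.spike_peak_times.size
        np.testing.assert_allclose(peaks / cfg.sampling_rate,
                                   truth.spike_peak_times,
                                   atol=1.0 / cfg.sampling_rate)

    def test_count_invariant_to_noise(self):
        counts = set()
        for seed in range(50):
            cfg = SweepGenConfig(seed=seed, noise_sd=0.3, rheobase=120.0,
                                 spikes_at_rheobase=10)
            sweep, truth = generate_sweep(cfg, 120.0)
            assert truth.spike_peak_times.size == 10
            counts.add(detect_aps(sweep).size)
        assert counts == {10}


class TestApFeatures:
    def test_triangular_spike_amplitude_and_half_width(self):
        sweep, i_peak = triangular_spike_sweep(baseline=0.0, peak=80.0,
                                               half_width_ms=1.0)
        feats = ap_features(sweep, i_peak)
        assert feats is not None
        assert feats.amplitude == pytest.approx(80.0, abs=1.0)
        # width at half amplitude (40 mV) of a symmetric triangle = rise time
        assert feats.half_width == pytest.approx(1.0, abs=0.05)

    def test_programmed_fahp_depth(self):
        cfg = SweepGenConfig(seed=2, fahp_depth=5.0, noise_sd=0.0)
        sweep, truth = generate_sweep(cfg, 120.0)
        peaks = detect_aps(sweep)
        feats = ap_features(sweep, int(peaks[0]), next_peak_index=int(peaks[1]))
        assert feats.fahp == pytest.approx(5.0, abs=0.5)

    def test_no_derivative_crossing_returns_none(self):
        fs = 10_000.0
        n = int(0.05 * fs)
        # slow hump: peak above 0 mV but dV/dt stays below criterion
        v = 5.0 * np.sin(np.linspace(0, np.pi, n))
        sweep = Sweep(voltage=v, sampling_rate=fs, current=120.0,
                      pulse_onset=0.0, pulse_offset=n / fs)
        assert ap_features(sweep, int(np.argmax(v))) is None

    def test_voltage_offset_shifts_threshold_not_shape_features(self):
        cfg = SweepGenConfig(seed=3, noise_sd=0.0)
        sweep, _ = generate_sweep(cfg, 120.0)
        peaks = detect_aps(sweep)
        base = ap_features(sweep, int(peaks[0]), next_peak_index=int(peaks[1]))
        shifted_sweep = Sweep(voltage=sweep.voltage + 7.0,
                              sampling_rate=sweep.sampling_rate,
                              current=sweep.current,
                              pulse_onset=sweep.pulse_onset,
                              pulse_offset=sweep.pulse_offset)
        shifted = ap_features(shifted_sweep, int(peaks[0]),
                              next_peak_index=int(peaks[1]))
        assert shifted.threshold - base.threshold == pytest.approx(7.0, abs=0.2)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=0.2)
        assert shifted.half_width == pytest.approx(base.half_width, abs=0.02)
        assert shifted.fahp == pytest.approx(base.fahp, abs=0.2)


class TestTrainRatios:
    def test_regular_train_adaptation_one(self):
        assert adaptation_ratio([0.1, 0.2, 0.3, 0.4]) == pytest.approx(1.0)

    def test_divisor_definition(self):
        # first ISI 10 ms, last ISI 40 ms
        assert adaptation_ratio([0.0, 0.01, 0.03, 0.07]) == pytest.approx(0.25)

    def test_three_spikes_share_middle_interval(self):
        assert adaptation_ratio([0.0, 0.01, 0.05]) == pytest.approx(0.25)

    def test_too_few_spikes_nan(self):
        assert np.isnan(adaptation_ratio([0.0, 0.01]))

    @pytest.mark.parametrize("isis,expected", [
        (np.full(9, 0.02), 1.0),        # regular
        (np.linspace(0.01, 0.04, 9), 0.25),
    ])
    def test_monotone_isi_bounds(self, isis, expected):
        times = np.concatenate([[0.0], np.cumsum(isis)])
        ratio = adaptation_ratio(times)
        assert ratio == pytest.approx(expected, rel=1e-9)
        if np.all(np.diff(isis) >= 0):
            assert ratio <= 1.0 + 1e-9

    def test_attenuation_examples(self):
        assert attenuation_ratio(np.full(15, 80.0)) == pytest.approx(1.0)
        amps = np.full(15, 80.0)
        amps[14] = 40.0
        assert attenuation_ratio(amps) == pytest.approx(0.5)
        assert np.isnan(attenuation_ratio(np.full(14, 80.0)))


class TestFICurve:
    def test_subthreshold_all_zero(self):
        cfg = SweepGenConfig(seed=4)
        sweeps = [generate_sweep(cfg, c)[0] for c in (-200.0, -80.0, 40.0)]
        assert all(v == 0.0 for v in fi_curve(sweeps).values())

    def test_spike_count_over_pulse_duration(self):
        cfg = SweepGenConfig(seed=5, rheobase=120.0, spikes_at_rheobase=12)
        sweep, _ = generate_sweep(cfg, 120.0)
        assert fi_curve([sweep])[120.0] == pytest.approx(12.0)

    def test_depolarization_block_profile(self):
        """A cell with programmed block peaks below 520 pA and F(520) < Fmax."""
        cfg = SweepGenConfig(seed=6, block_current=400.0, block_slope=0.06)
        feats = extract_cell_features([s for s, _ in generate_sweep_series(cfg)])
        currents = np.array(sorted(feats.fi_table))
        freqs = np.array([feats.fi_table[c] for c in currents])
        assert currents[np.argmax(freqs)] < 520.0
        assert feats.f_at_520 < feats.f_max


class TestPassiveProperties:
    def test_ohmic_rin(self):
        cfg = SweepGenConfig(seed=7, rin=100.0, noise_sd=0.0)
        sweep, _ = generate_sweep(cfg, -200.0)
        rmp, rin = passive_properties(sweep)
        assert rin == pytest.approx(100.0, rel=0.01)

    def test_flat_prestimulus_rmp(self):
        cfg = SweepGenConfig(seed=8, rmp=-70.0, noise_sd=0.0)
        sweep, _ = generate_sweep(cfg, -200.0)
        rmp, _ = passive_properties(sweep)
        assert rmp == pytest.approx(-70.0, abs=0.01)

    def test_positive_step_rejected(self):
        cfg = SweepGenConfig(seed=9)
        sweep, _ = generate_sweep(cfg, 40.0)
        with pytest.raises(ValidationError):
            passive_properties(sweep)


class TestGeneratorRoundTrip:
    def test_adaptation_round_trip(self):
        cfg = SweepGenConfig(seed=10, adaptation_ratio=0.25, noise_sd=0.2)
        sweep, truth = generate_sweep(cfg, 120.0)
        peaks = detect_aps(sweep) / cfg.sampling_rate
        assert adaptation_ratio(peaks) == pytest.approx(0.25, abs=0.02)

    def test_regular_train_extracted_ratio_one(self):
        cfg = SweepGenConfig(seed=11, adaptation_ratio=1.0)
        sweep, _ = generate_sweep(cfg, 120.0)
        peaks = detect_aps(sweep) / cfg.sampling_rate
        assert adaptation_ratio(peaks) == pytest.approx(1.0, abs=0.01)

    def test_attenuation_round_trip(self):
        cfg = SweepGenConfig(seed=12, attenuation_ratio=0.7, noise_sd=0.2)
        feats = extract_cell_features([s for s, _ in generate_sweep_series(cfg)])
        assert feats.attenuation_ratio == pytest.approx(0.7, abs=0.05)
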