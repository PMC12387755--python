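"""Cross-correlation profile: examples, brute-force oracle, jitter null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epscorr import (
    N_LAG_BINS,
    EventTrain,
    Label,
    PairedSession,
    bin_events,
    compute_ccp,
    jitter_null,
    pooled_threshold,
    poisson_chance_level,
)
from epscorr.ccp import EmptyTrainError, _shift_train
from epscorr.synth import PairGenConfig, generate_pair


def brute_force_ccp(session, window_half_width):
    """Independent oracle: count occupied-bin coincidences by explicit loops."""
    delta = window_half_width / 10.0
    n_bins = int(np.ceil(session.duration / delta))

    def occupied(train):
        bins = set()
        for t in train.event_times:
            # same floor-division convention as the implementation; the
            # oracle independently verifies the coincidence *counting*
            bins.add(min(int(np.floor(t / delta)), n_bins - 1))
        return bins

    xa, xb = occupied(session.train_a), occupied(session.train_b)
    denom = np.sqrt(len(xa) * len(xb))
    r = []
    for k in range(-10, 11):
        count = 0
        for b in xa:
            if 0 <= b + k < n_bins and (b + k) in xb:
                count += 1
        r.append(count / denom)
    return np.array(r)


class TestBinEvents:
    def test_one_event_per_bin(self, make_train):
        train = make_train([0.005, 0.012], duration=0.03)
        np.testing.assert_array_equal(bin_events(train, 0.01), [1, 1, 0])

    def test_no_events_all_zero(self, make_train):
        assert bin_events(make_train([], duration=0.05), 0.01).sum() == 0

    def test_multiplicity_binarized(self, make_train):
        train = make_train([0.001, 0.002, 0.003], duration=0.03)
        np.testing.assert_array_equal(bin_events(train, 0.01), [1, 0, 0])


class TestComputeCCP:
    def test_identical_trains_unit_center(self, make_session):
        times = [1.0, 2.2, 3.5, 7.1]
        ccp = compute_ccp(make_session(times, times), 0.1)
        assert ccp.r_center == pytest.approx(1.0)
        assert np.all(ccp.r <= 1.0)

    def test_far_apart_trains_all_zero(self, make_session):
        ccp = compute_ccp(make_session([1.0, 3.0], [2.0, 4.0], duration=10.0), 0.1)
        assert np.all(ccp.r == 0)

    def test_profile_has_21_lags_spanning_window(self, make_session):
        ccp = compute_ccp(make_session([1.0], [1.0]), 0.1)
        assert ccp.lags.size == N_LAG_BINS == ccp.r.size
        assert ccp.lags[0] == pytest.approx(-0.1)
        assert ccp.lags[-1] == pytest.approx(0.1)
        assert ccp.lags[10] == 0.0

    def test_empty_train_raises(self, make_session):
        with pytest.raises(EmptyTrainError):
            compute_ccp(make_session([], [1.0]), 0.1)

    def test_matches_brute_force_oracle_on_random_pairs(self, make_session):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_a, n_b = rng.integers(1, 100, size=2)
            s = make_session(np.sort(rng.uniform(0, 30, n_a)),
                             np.sort(rng.uniform(0, 30, n_b)), duration=30.0)
            ccp = compute_ccp(s, 0.1)
            np.testing.assert_allclose(ccp.r, brute_force_ccp(s, 0.1), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.data(),
        n_a=st.integers(1, 60),
        n_b=st.integers(1, 60),
        w=st.sampled_from([0.05, 0.1, 0.5]),
    )
    def test_oracle_equivalence_property(self, data, n_a, n_b, w):
        times_a = sorted(data.draw(st.lists(
            st.floats(0, 20, allow_nan=False), min_size=n_a, max_size=n_a)))
        times_b = sorted(data.draw(st.lists(
            st.floats(0, 20, allow_nan=False), min_size=n_b, max_size=n_b)))
        s = PairedSession(
            "s",
            EventTrain("a", Label.LABELED, 20.0, np.array(times_a)),
            EventTrain("b", Label.LABELED, 20.0, np.array(times_b)),
        )
        np.testing.assert_allclose(
            compute_ccp(s, w).r, brute_force_ccp(s, w), atol=1e-12)

    def test_swap_symmetry(self, make_session):
        rng = np.random.default_rng(1)
        s = make_session(np.sort(rng.uniform(0, 50, 40)),
                         np.sort(rng.uniform(0, 50, 45)), duration=50.0)
        fwd = compute_ccp(s, 0.1)
        swapped = PairedSession("s", s.train_b, s.train_a)
        rev = compute_ccp(swapped, 0.1)
        np.testing.assert_allclose(rev.r, fwd.r[::-1], atol=1e-12)
        assert rev.r_center == pytest.approx(fwd.r_center)
        assert rev.r_max == pytest.approx(fwd.r_max)

    def test_r_max_orderings(self, make_session):
        rng = np.random.default_rng(2)
        s = make_session(np.sort(rng.uniform(0, 50, 40)),
                         np.sort(rng.uniform(0, 50, 45)), duration=50.0)
        ccp = compute_ccp(s, 0.1)
        assert ccp.r_max >= ccp.r_center
        assert ccp.r_max >= ccp.r_max_peri


class TestPooledThreshold:
    def test_degenerate_pool_no_crossings(self, make_session):
        times = [1.0, 2.0]
        # identical trains: R = 1 at center, elsewhere 0 -> craft constant pool
        # using two sessions with identical profiles
        s = make_session(times, [5.0, 8.0])
        ccp = compute_ccp(s, 0.1)
        spec = pooled_threshold([ccp])
        # all values 0 -> SD 0, theta = 0, strict inequality -> no crossing
        assert spec.pooled_sd == 0.0
        assert spec.threshold == spec.pooled_mean
        assert not any(spec.r_max_crossing)

    def test_two_value_pool_hand_summation(self):
        # direct formula check on a pool {0, 0.2}: mean .1, sd sqrt(.02)
        pool = np.array([0.0, 0.2])
        mean, sd = pool.mean(), pool.std(ddof=1)
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(np.sqrt(0.02))
        assert mean + 2 * sd == pytest.approx(0.1 + 2 * np.sqrt(0.02))

    def test_mixed_windows_rejected(self, make_session):
        s = make_session([1.0], [1.0])
        with pytest.raises(ValueError, match="windows"):
            pooled_threshold([compute_ccp(s, 0.1), compute_ccp(s, 0.05)])

    def test_threshold_matches_hand_pool(self, make_session):
        rng = np.random.default_rng(3)
        ccps = []
        for i in range(4):
            ccps.append(compute_ccp(make_session(
                np.sort(rng.uniform(0, 60, 50)), np.sort(rng.uniform(0, 60, 50)),
                duration=60.0, session_id=f"s{i}"), 0.1))
        pool = np.concatenate([c.r for c in ccps])
        spec = pooled_threshold(ccps)
        assert spec.pooled_mean == pytest.approx(pool.mean(), abs=1e-12)
        assert spec.threshold == pytest.approx(
            pool.mean() + 2 * pool.std(ddof=1), abs=1e-12)


class TestJitterNull:
    def test_zero_offset_reproduces_aligned_profile(self, make_session):
        s = make_session([1.0, 2.5, 7.3], [1.01, 2.51, 9.0])
        shifted = PairedSession("s", s.train_a, _shift_train(s.train_b, 0.0))
        np.testing.assert_allclose(
            compute_ccp(shifted, 0.1).r, compute_ccp(s, 0.1).r, atol=1e-12)

    def test_wrap_preserves_event_count(self, make_session):
        s = make_session([1.0, 2.0], [0.1, 9.9])
        shifted = _shift_train(s.train_b, 0.3)
        assert shifted.n_events == 2
        assert np.all(shifted.event_times <= s.duration)

    def test_default_ensemble_has_100_iterations(self):
        pair = generate_pair(PairGenConfig(duration=120.0, rate=1.0, seed=4))
        ens = jitter_null(pair, 0.1, seed=0)
        assert ens.r_matrix.shape == (100, N_LAG_BINS)

    def test_deterministic_under_seed(self):
        pair = generate_pair(PairGenConfig(duration=120.0, rate=1.0, seed=4))
        a = jitter_null(pair, 0.1, iterations=10, seed=11)
        b = jitter_null(pair, 0.1, iterations=10, seed=11)
        np.testing.assert_array_equal(a.r_matrix, b.r_matrix)

    def test_jitter_destroys_perfect_coincidence(self, make_session):
        """Coincident trains fall to the analytic chance level under jitter."""
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 400, 380))
        s = make_session(times, times, duration=400.0)
        ens = jitter_null(s, 0.1, iterations=200, seed=6)
        chance = poisson_chance_level(380, 380, 0.01, 400.0)
        # only offsets well beyond the window destroy the shared structure
        far = np.abs(ens.offsets) > 0.12
        vals = ens.center_values[far]
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - chance) < 3 * se + 1e-12
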