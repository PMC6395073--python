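"""Spike/burst segmentation, ISI analysis and the stability rule."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from stgscape.trace_metrics import (
    ThresholdSet,
    burst_statistics,
    detect_crossings,
    distinct_isi_count,
    isi_values,
    spike_times,
    _segment_bursts,
)


class TestDetectCrossings:
    def test_single_upward(self):
        assert detect_crossings(np.array([-30.0, -10.0]), -20.0, "up").tolist() == [0]

    def test_constant_sequence(self):
        assert detect_crossings(np.zeros(100), -20.0, "up").size == 0
        assert detect_crossings(np.zeros(100), -20.0, "down").size == 0

    def test_sine_period_crosses_once_each_way(self):
        t = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        x = np.sin(t + 0.1)
        assert detect_crossings(x, 0.0, "up").size == 1
        assert detect_crossings(x, 0.0, "down").size == 1

    def test_boundary_value_counts_as_below(self):
        # x[n] == T counts toward an upward crossing (V_n <= T < V_{n+1})
        assert detect_crossings(np.array([-20.0, -10.0]), -20.0, "up").size == 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_crossings(np.array([1.0]), 0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-100, 50, allow_nan=False), min_size=2, max_size=200),
           st.floats(-80, 20))
    def test_up_down_counts_differ_by_at_most_one(self, x, T):
        x = np.asarray(x)
        assume(np.all(x != T))      # samples exactly on the threshold are degenerate
        ups = detect_crossings(x, T, "up").size
        downs = detect_crossings(x, T, "down").size
        assert abs(ups - downs) <= 1

    def test_crossing_count_invariant_under_refinement(self):
        # a band-limited signal keeps its crossing count when sampled finer
        for n in (500, 1000, 4000):
            t = np.linspace(0, 1, n, endpoint=False)
            x = np.sin(2 * np.pi * 5 * t)
            assert detect_crossings(x, 0.3, "up").size == 5


class TestBurstStatistics:
    def test_hand_worked_burst(self):
        # bursts of 3 spikes 10 ms apart, next burst 1000 ms later:
        # delta_b = 20, tau_b = 20 + 980 = 1000 ms -> f_b = 1 Hz, d_c = 0.02
        S = np.array([1000.0, 1010.0, 1020.0,
                      2000.0, 2010.0, 2020.0,
                      3000.0, 3010.0, 3020.0])
        stats = burst_statistics(S, window_end=4000.0)
        assert stats.n_bursts == 3
        assert stats.fb_samples == pytest.approx([1.0, 1.0])
        assert stats.dc_samples == pytest.approx([0.02, 0.02])
        assert stats.stable

    def test_isolated_spike_zero_duration(self):
        S = np.array([500.0, 1500.0, 2500.0, 3500.0])
        stats = burst_statistics(S, window_end=4000.0)
        assert np.all(stats.spikes_per_burst() == 1)
        assert stats.dc_samples == pytest.approx([0.0, 0.0, 0.0])

    def test_periodic_train_is_stable(self):
        S = np.arange(20) * 500.0 + 200.0
        stats = burst_statistics(S, window_end=10200.0)
        assert stats.std_fb == pytest.approx(0.0)
        assert stats.stable

    def test_too_few_spikes_unstable_not_error(self):
        stats = burst_statistics(np.array([100.0, 5000.0]))
        assert not stats.stable
        assert stats.n_bursts == 0
        assert stats.n_spikes == 2

    def test_truncated_final_burst_not_counted(self):
        # last burst runs into the window edge: no certified end
        S = np.array([1000.0, 1010.0, 2000.0, 2010.0, 3000.0, 3010.0])
        stats = burst_statistics(S, window_end=3050.0)
        assert stats.n_bursts == 2

    def test_uncertified_start_contributes_no_sample(self):
        # window opens mid-burst: the first burst is counted (it ends) but
        # contributes no duty-cycle sample
        S = np.array([10.0, 20.0, 1000.0, 1010.0, 1020.0, 2000.0])
        stats = burst_statistics(S, window_end=2500.0)
        assert stats.n_bursts == 3
        assert len(stats.dc_samples) == 1

    def test_unstable_duty_cycle_discarded(self):
        # alternating long and short bursts: dc spread beyond 20% of mean
        S = np.concatenate([
            [t, t + 10, t + 20, t + 30] if i % 2 == 0 else [t]
            for i, t in enumerate(np.arange(10) * 1000.0 + 500.0)
        ])
        stats = burst_statistics(np.sort(S), window_end=11000.0)
        assert not stats.stable

    def test_slow_wave_and_mid_counts(self):
        dt = 1.0
        t = np.arange(0, 4000.0, dt)
        V = -50.0 + 30.0 * np.sin(2 * np.pi * t / 1000.0)    # 4 cycles
        ts = ThresholdSet(mid_thresholds=(-35.0,))
        S = spike_times(V, dt)
        stats = burst_statistics(S, V, ts, dt=dt)
        assert stats.n_sw == 8          # 4 downward crossings at each of -49, -51
        assert stats.n_mid == (4,)

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            burst_statistics(np.array([3.0, 1.0, 2.0]))


def brute_force_bursts(S, gap):
    """O(n^2) oracle: transitively merge spikes closer than ``gap``."""
    n = len(S)
    groups = [{i} for i in range(n)]
    for i in range(n):
        for j in range(n):
            if abs(S[i] - S[j]) < gap or any(
                i in g and j in g for g in groups
            ):
                gi = next(g for g in groups if i in g)
                gj = next(g for g in groups if j in g)
                if gi is not gj:
                    groups.remove(gj)
                    gi |= gj
    bursts = sorted((min(g), max(g)) for g in groups)
    return bursts


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0, 5000, allow_nan=False), min_size=1, max_size=40))
def test_segmentation_matches_brute_force(times):
    S = np.sort(np.asarray(times))
    gap = 100.0
    starts, ends = _segment_bursts(S, gap)
    got = list(zip(starts.tolist(), ends.tolist()))
    expected = brute_force_bursts(S, gap)
    assert got == expected


class TestISI:
    def test_first_differences(self):
        assert isi_values(np.array([0.0, 10.0, 20.0])).tolist() == [10.0, 10.0]

    def test_short_sequences_empty(self):
        assert isi_values(np.array([5.0])).size == 0
        assert isi_values(np.array([])).size == 0

    def test_distinct_count_merges_jitter(self):
        assert distinct_isi_count([10.0, 10.05, 500.0], rel_tol=0.02) == 2

    def test_distinct_count_all_equal(self):
        assert distinct_isi_count([7.0] * 50) == 1

    def test_distinct_count_separates_doublets(self):
        assert distinct_isi_count([20.0, 20.1, 60.0, 60.2, 20.05]) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distinct_isi_count([])
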