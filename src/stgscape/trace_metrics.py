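"""Threshold (Poincaré-section) characterization of voltage traces.

Spikes are upward crossings of a spike-detection threshold (default
-20 mV).  Two spikes closer than the burst gap (default 100 ms) belong to
the same burst; a burst running from spike s_i to spike s_k has duration
delta_b = s_k - s_i, period tau_b = delta_b + (s_{k+1} - s_k), burst
frequency f_b = 1/tau_b and duty cycle d_c = delta_b/tau_b.  An isolated
spike is a zero-duration burst.  Slow-wave separation is monitored by
counting downward crossings at a +-1 mV pair of thresholds around -50 mV.

A solution is discarded as unstable when its per-burst frequency spread
exceeds 10% of the mean or its duty-cycle spread exceeds 20% of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ThresholdSet",
    "BurstStatistics",
    "detect_crossings",
    "spike_times",
    "burst_statistics",
    "isi_values",
    "distinct_isi_count",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds of the trace-characterization procedure (mV, ms)."""

    spike_threshold: float = -20.0        # upward crossings = spikes
    slow_wave: Tuple[float, float] = (-49.0, -51.0)   # downward, counted summed
    mid_thresholds: Tuple[float, ...] = ()            # tonic targets only, downward
    burst_gap: float = 100.0              # ms, spikes closer than this share a burst

    def __post_init__(self):
        if self.burst_gap <= 0:
            raise ValueError("burst_gap must be positive")
        if len(self.slow_wave) != 2:
            raise ValueError("slow_wave must be a pair of thresholds")


@dataclass
class BurstStatistics:
    """Spike/burst decomposition of one trace and its summary measures.

    ``burst_starts``/``burst_ends`` index into ``spikes`` (paired one-to-one,
    completed bursts only); ``fb_samples`` (Hz) and ``dc_samples`` carry one
    entry per completed burst that is followed by another spike.
    """

    spikes: np.ndarray                    # spike times, ms
    burst_starts: np.ndarray              # indices into spikes
    burst_ends: np.ndarray
    fb_samples: np.ndarray                # Hz
    dc_samples: np.ndarray                # dimensionless
    n_sw: int                             # downward slow-wave crossings, both thresholds
    n_spikes: int
    n_mid: Tuple[int, ...]                # downward crossings per mid threshold
    stable: bool

    @property
    def n_bursts(self) -> int:
        return len(self.burst_starts)

    @property
    def mean_fb(self) -> float:
        return float(np.mean(self.fb_samples)) if self.fb_samples.size else np.nan

    @property
    def std_fb(self) -> float:
        return float(np.std(self.fb_samples)) if self.fb_samples.size else np.nan

    @property
    def mean_dc(self) -> float:
        return float(np.mean(self.dc_samples)) if self.dc_samples.size else np.nan

    @property
    def std_dc(self) -> float:
        return float(np.std(self.dc_samples)) if self.dc_samples.size else np.nan

    def spikes_per_burst(self) -> np.ndarray:
        """Spike count of each completed burst."""
        return self.burst_ends - self.burst_starts + 1


def detect_crossings(x: np.ndarray, threshold: float, direction: str = "up") -> np.ndarray:
    """Indices n where ``x`` crosses ``threshold``.

    Upward: ``x[n] <= T < x[n+1]``; downward: ``x[n] >= T > x[n+1]``.
    """
    x = np.asarray(x)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if direction == "up":
        return np.flatnonzero((x[:-1] <= threshold) & (x[1:] > threshold))
    elif direction == "down":
        return np.flatnonzero((x[:-1] >= threshold) & (x[1:] < threshold))
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def spike_times(V: np.ndarray, dt: float, threshold: float = -20.0,
                t0: float = 0.0) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings of a sampled trace."""
    return t0 + dt * detect_crossings(V, threshold, "up")


def _segment_bursts(S: np.ndarray, gap: float):
    """Group sorted spike times into maximal runs with internal gaps < ``gap``
    (spikes strictly closer than the gap share a burst; a single spike is a
    zero-duration burst).  Returns (starts, ends) as index pairs into S.
    """
    n = len(S)
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    big = np.flatnonzero(np.diff(S) >= gap)       # gap after index big[i]
    starts = np.concatenate(([0], big + 1))
    ends = np.concatenate((big, [n - 1]))
    return starts, ends


def burst_statistics(S: np.ndarray, V: Optional[np.ndarray] = None,
                     thresholds: ThresholdSet = ThresholdSet(),
                     dt: Optional[float] = None,
                     window_start: float = 0.0,
                     window_end: Optional[float] = None) -> BurstStatistics:
    """Burst decomposition and stability assessment of a spike sequence.

    ``V`` supplies the sampled trace for the slow-wave and mid threshold
    crossing counts (0 when omitted).  Fewer than 3 spikes yields zero
    bursts flagged unstable rather than an error.

    Only *completed* bursts are counted in ``n_bursts``: the burst's end
    must be certified by a spike-free gap of at least ``burst_gap`` after
    its last spike (observed either before the next spike or against
    ``window_end``), so a burst still in progress when the window closes
    is not counted — it has not yet produced its slow-wave descent either,
    keeping ``#sw/2`` and ``#b`` in register.  A (f_b, d_c) sample
    additionally requires a certified start (the first observed spike
    qualifies only when the window provides ``burst_gap`` of spike-free
    lead-in from ``window_start``) and a following spike to measure the
    period against.
    """
    S = np.asarray(S, dtype=float)
    if np.any(np.diff(S) < 0):
        raise ValueError("spike times must be sorted ascending")
    if window_end is None and V is not None and dt is not None:
        window_end = window_start + len(V) * dt
    n_sw = 0
    n_mid: Tuple[int, ...] = ()
    if V is not None:
        n_sw = sum(len(detect_crossings(V, t, "down")) for t in thresholds.slow_wave)
        n_mid = tuple(len(detect_crossings(V, t, "down"))
                      for t in thresholds.mid_thresholds)
    if len(S) < 3:
        return BurstStatistics(
            spikes=S, burst_starts=np.empty(0, dtype=int),
            burst_ends=np.empty(0, dtype=int), fb_samples=np.empty(0),
            dc_samples=np.empty(0), n_sw=n_sw, n_spikes=len(S), n_mid=n_mid,
            stable=False,
        )
    starts, ends = _segment_bursts(S, thresholds.burst_gap)
    gap = thresholds.burst_gap
    counted = []
    fb, dc = [], []
    for b in range(len(starts)):
        i, k = starts[b], ends[b]
        if k + 1 < len(S):
            end_certified = True            # the split guarantees the gap
        elif window_end is not None:
            end_certified = window_end - S[k] >= gap
        else:
            end_certified = False
        if not end_certified:
            continue
        counted.append(b)
        if b == 0 and S[i] - window_start < gap:
            continue        # start not certifiable: window may have opened mid-burst
        if k + 1 >= len(S):
            continue        # no next spike: period unmeasurable
        delta_b = S[k] - S[i]
        tau_b = delta_b + (S[k + 1] - S[k])
        fb.append(1000.0 / tau_b)          # ms -> Hz
        dc.append(delta_b / tau_b)
    starts = starts[counted]
    ends = ends[counted]
    fb = np.asarray(fb)
    dc = np.asarray(dc)
    if fb.size == 0:
        stable = False
    else:
        # zero spread is stationary by definition (a perfectly periodic
        # tonic spiker has mean dc = std dc = 0 and must not be discarded)
        sf, sd = np.std(fb), np.std(dc)
        stable = not (
            (sf > 0 and sf >= 0.1 * np.mean(fb))
            or (sd > 0 and sd >= 0.2 * np.mean(dc))
        )
    return BurstStatistics(
        spikes=S, burst_starts=starts, burst_ends=ends,
        fb_samples=fb, dc_samples=dc, n_sw=n_sw, n_spikes=len(S),
        n_mid=n_mid, stable=stable,
    )


def isi_values(S: np.ndarray) -> np.ndarray:
    """Inter-spike intervals (ms): first differences of the spike times."""
    S = np.asarray(S, dtype=float)
    if S.size < 2:
        return np.empty(0)
    return np.diff(S)


def distinct_isi_count(isis: Sequence[float], rel_tol: float = 0.02) -> int:
    """Number of distinct ISI values under single-linkage clustering.

    Two ISIs join the same cluster when their gap is below ``rel_tol`` times
    the smaller value; the default 2% merges numerical jitter while keeping
    genuinely different ISIs (doublets/quadruplets differ by far more) apart.
    """
    isis = np.sort(np.asarray(isis, dtype=float))
    if isis.size == 0:
        raise ValueError("need at least one ISI")
    gaps = np.diff(isis)
    splits = gaps > rel_tol * isis[:-1]
    return int(np.count_nonzero(splits)) + 1
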