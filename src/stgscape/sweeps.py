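"""Perturbation experiment drivers.

Graded decrements of one maximal conductance (11 levels 100% -> 0% by
default), complete current deletions (the level-0 special case), and
injected-current scans collecting the inter-spike-interval multiset at
each current level (the data behind ISI bifurcation diagrams).

Every level restarts from the fixed standard initial condition, so sweeps
probe the attractor reached from that state rather than following a
solution branch (no hysteresis ambiguity in a possibly multistable
system).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import stg_model, trace_metrics
from .stg_model import (CHANNEL_NAMES, IntegrationError, KineticsTable,
                        ModelParameters, TraceRecord)
from .trace_metrics import BurstStatistics, ThresholdSet

__all__ = [
    "DecrementResult",
    "InjectionLevel",
    "decrement_traces",
    "delete_channel",
    "injection_scan",
]


@dataclass
class DecrementResult:
    """One decrement level: the retained trace and its burst statistics."""

    level: float
    trace: Optional[TraceRecord]
    stats: Optional[BurstStatistics]
    failed: bool = False


def decrement_traces(params: ModelParameters, channel: Union[int, str],
                     levels: Sequence[float] = None,
                     duration: float = 2.0e4, transient: float = 1.0e4,
                     dt: float = 0.1, record_currents: bool = False,
                     thresholds: ThresholdSet = ThresholdSet(),
                     kinetics: Optional[KineticsTable] = None) -> List[DecrementResult]:
    """Simulate the model with one conductance scaled by each level.

    Default levels: 11 values equally spaced from 1 (control) to 0
    (removed).  Integration failure flags the level, not the sweep.
    """
    if levels is None:
        levels = np.linspace(1.0, 0.0, 11)
    levels = np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("levels must lie in [0, 1]")
    out: List[DecrementResult] = []
    for level in levels:
        scaled = params.with_scaled(channel, float(level))
        try:
            trace = stg_model.integrate(
                scaled, duration=duration, dt=dt, transient=transient,
                record_currents=record_currents, kinetics=kinetics,
            )
        except IntegrationError:
            out.append(DecrementResult(level=float(level), trace=None,
                                       stats=None, failed=True))
            continue
        S = trace_metrics.spike_times(trace.V, trace.dt,
                                      thresholds.spike_threshold, t0=trace.t0)
        stats = trace_metrics.burst_statistics(S, trace.V, thresholds, dt=trace.dt,
                                               window_start=trace.t0)
        out.append(DecrementResult(level=float(level), trace=trace, stats=stats))
    return out


def delete_channel(params: ModelParameters, channel: Union[int, str],
                   **kwargs) -> DecrementResult:
    """Complete removal of one current (a decrement sweep at level 0)."""
    return decrement_traces(params, channel, levels=[0.0], **kwargs)[0]


@dataclass
class InjectionLevel:
    """ISI multiset of one injected-current level."""

    Ie: float                   # nA
    isis: np.ndarray            # ms, empty when silent
    n_spikes: int
    silent: bool

    def distinct_isis(self, rel_tol: float = 0.02) -> int:
        if self.isis.size == 0:
            return 0
        return trace_metrics.distinct_isi_count(self.isis, rel_tol)

    @property
    def max_isi(self) -> float:
        return float(self.isis.max()) if self.isis.size else np.nan

    def mean_rate(self, window_ms: float) -> float:
        """Mean firing rate (Hz) over the retained window."""
        return 1000.0 * self.n_spikes / window_ms


def injection_scan(params: ModelParameters, I_range: Tuple[float, float] = (-1.0, 5.0),
                   n_levels: int = 25, duration: float = 2.0e4,
                   transient: float = 1.0e4, dt: float = 0.1,
                   spike_threshold: float = -20.0,
                   kinetics: Optional[KineticsTable] = None) -> List[InjectionLevel]:
    """ISI multisets over a grid of constant injected currents.

    Each level restarts from the standard initial condition, runs
    ``duration`` ms and analyzes the window after ``transient``.  Levels
    with fewer than 2 spikes yield an empty ISI set flagged silent.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 current levels")
    I_values = np.linspace(I_range[0], I_range[1], n_levels)
    out: List[InjectionLevel] = []
    for Ie in I_values:
        trace = stg_model.integrate(
            params, duration=duration, dt=dt, transient=transient,
            Ie=float(Ie), record_currents=False, kinetics=kinetics,
        )
        S = trace_metrics.spike_times(trace.V, trace.dt, spike_threshold)
        isis = trace_metrics.isi_values(S)
        out.append(InjectionLevel(Ie=float(Ie), isis=isis, n_spikes=len(S),
                                  silent=len(S) < 2))
    return out
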