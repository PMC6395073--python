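"""Landscape (objective) functions mapping conductance sets to scores.

A candidate is simulated, its trace reduced to threshold-based measures,
and the mismatch to a target activity combined into a scalar score:

* burster target:  E(g) = a*Ef + b*Edc + c*Esw with
  Ef = (f_tg - <f_b>)^2, Edc = (dc_tg - <d_c>)^2, Esw = (#sw/2 - #b)^2
  (the 1/2 accounts for using two slow-wave thresholds);
* tonic target:    E(g) = a*Ef + b*Edc + c*Emid + d*Esw + e*Elag with
  Emid = sum_i (#mid_i - #s)^2 and Esw = (#sw)^2 (tonic solutions must
  never cross the slow-wave thresholds downward).

Unstable, silent or numerically diverging candidates receive a fixed large
penalty score so that optimizers can rank them below any behaving solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

from . import stg_model, trace_metrics
from .stg_model import IntegrationError, KineticsTable, ModelParameters
from .trace_metrics import BurstStatistics, ThresholdSet

__all__ = [
    "BursterTarget",
    "TonicTarget",
    "ScoreResult",
    "PENALTY_SCORE",
    "burster_penalties",
    "tonic_penalties",
    "lag_penalty",
    "score_trace",
    "evaluate_candidate",
    "make_objective",
]

#: score assigned to discarded candidates (unstable, silent, non-finite)
PENALTY_SCORE = 1.0e6


@dataclass(frozen=True)
class BursterTarget:
    """Bursting activity target: 1 Hz bursts with 20% duty cycle."""

    f_tg: float = 1.0       # Hz
    dc_tg: float = 0.2
    weights: Tuple[float, float, float] = (1.0, 100.0, 1.0)   # (alpha, beta, gamma)
    duration: float = 2.0e4     # ms, total simulated
    transient: float = 1.0e4    # ms, dropped
    dt: float = 0.1             # ms
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)


@dataclass(frozen=True)
class TonicTarget:
    """Tonic-spiking target: zero duty cycle, controlled repolarization.

    Mid thresholds between -35 and -45 mV penalize sub-threshold wiggles;
    the lag term separates tonic spikers from single-spike bursters.
    """

    f_tg: float = 1.0
    dc_tg: float = 0.0
    weights: Tuple[float, float, float, float, float] = (1000.0, 1000.0, 100.0, 100.0, 1.0)
    mid_thresholds: Tuple[float, ...] = (-35.0, -40.0, -45.0)
    t_spk: float = -20.0    # upward reference for the lag
    t_mid: float = -35.0    # downward reference for the lag
    duration: float = 2.0e4
    transient: float = 1.0e4
    dt: float = 0.1

    def threshold_set(self) -> ThresholdSet:
        return ThresholdSet(mid_thresholds=self.mid_thresholds)


@dataclass
class ScoreResult:
    """Weighted total score plus the individual penalty terms."""

    total: float
    E_f: float = np.nan
    E_dc: float = np.nan
    E_sw: float = np.nan
    E_mid: float = np.nan
    E_lag: float = np.nan
    stable: bool = False
    discarded: bool = False
    reason: str = ""


class UnstableSolutionError(ValueError):
    """The statistics come from a discarded (unstable) solution."""


def burster_penalties(stats: BurstStatistics, target: BursterTarget):
    """The three penalty terms (E_f, E_dc, E_sw) of the bursting landscape."""
    if not stats.stable:
        raise UnstableSolutionError("refusing to score an unstable solution")
    E_f = (target.f_tg - stats.mean_fb) ** 2
    E_dc = (target.dc_tg - stats.mean_dc) ** 2
    E_sw = (stats.n_sw / 2.0 - stats.n_bursts) ** 2
    return E_f, E_dc, E_sw


def tonic_penalties(stats: BurstStatistics, lag: float, target: TonicTarget):
    """The five penalty terms (E_f, E_dc, E_mid, E_sw, E_lag)."""
    E_f = (target.f_tg - stats.mean_fb) ** 2
    E_dc = (target.dc_tg - stats.mean_dc) ** 2
    E_mid = float(sum((m - stats.n_spikes) ** 2 for m in stats.n_mid))
    E_sw = float(stats.n_sw) ** 2
    return E_f, E_dc, E_mid, E_sw, lag


def lag_penalty(V: np.ndarray, dt: float, target: TonicTarget) -> float:
    """Mean lag (ms) between spike upstrokes and the next mid-threshold
    downstroke; unpaired spikes contribute the mean ISI as a cap."""
    ups = trace_metrics.detect_crossings(V, target.t_spk, "up")
    downs = trace_metrics.detect_crossings(V, target.t_mid, "down")
    if len(ups) < 2:
        raise ValueError("lag undefined: fewer than two spikes")
    mean_isi = np.mean(np.diff(ups)) * dt
    lags = []
    j = 0
    for u in ups:
        while j < len(downs) and downs[j] <= u:
            j += 1
        if j < len(downs):
            lags.append((downs[j] - u) * dt)
            j += 1
        else:
            lags.append(mean_isi)
    return float(np.mean(lags))


def score_trace(params: ModelParameters, target: BursterTarget,
                kinetics: Optional[KineticsTable] = None) -> ScoreResult:
    """Simulate a model under the target protocol and score it.

    Discarded candidates (integration failure, fewer than 3 spikes, or
    unstable per-burst statistics) receive ``PENALTY_SCORE``.
    """
    try:
        trace = stg_model.integrate(
            params, duration=target.duration, dt=target.dt,
            transient=target.transient, record_currents=False,
            kinetics=kinetics,
        )
    except IntegrationError as err:
        return ScoreResult(total=PENALTY_SCORE, discarded=True,
                           reason=f"integration failure: {err}")
    S = trace_metrics.spike_times(trace.V, trace.dt, target.thresholds.spike_threshold)
    stats = trace_metrics.burst_statistics(S, trace.V, target.thresholds, dt=trace.dt)
    if not stats.stable:
        return ScoreResult(total=PENALTY_SCORE, discarded=True, stable=False,
                           reason="unstable or silent solution")
    E_f, E_dc, E_sw = burster_penalties(stats, target)
    a, b, c = target.weights
    return ScoreResult(total=a * E_f + b * E_dc + c * E_sw,
                       E_f=E_f, E_dc=E_dc, E_sw=E_sw, stable=True)


def score_trace_tonic(params: ModelParameters, target: TonicTarget,
                      kinetics: Optional[KineticsTable] = None) -> ScoreResult:
    """Simulate and score against the tonic-spiking landscape."""
    try:
        trace = stg_model.integrate(
            params, duration=target.duration, dt=target.dt,
            transient=target.transient, record_currents=False,
            kinetics=kinetics,
        )
    except IntegrationError as err:
        return ScoreResult(total=PENALTY_SCORE, discarded=True,
                           reason=f"integration failure: {err}")
    ts = target.threshold_set()
    S = trace_metrics.spike_times(trace.V, trace.dt, ts.spike_threshold)
    stats = trace_metrics.burst_statistics(S, trace.V, ts, dt=trace.dt)
    if stats.n_spikes < 3 or stats.fb_samples.size == 0:
        return ScoreResult(total=PENALTY_SCORE, discarded=True,
                           reason="too few spikes")
    try:
        lag = lag_penalty(trace.V, trace.dt, target)
    except ValueError:
        return ScoreResult(total=PENALTY_SCORE, discarded=True,
                           reason="lag undefined")
    E_f, E_dc, E_mid, E_sw, E_lag = tonic_penalties(stats, lag, target)
    a, b, c, d, e = target.weights
    return ScoreResult(
        total=a * E_f + b * E_dc + c * E_mid + d * E_sw + e * E_lag,
        E_f=E_f, E_dc=E_dc, E_mid=E_mid, E_sw=E_sw, E_lag=E_lag,
        stable=stats.stable,
    )


def candidate_parameters(g_and_tau: np.ndarray) -> ModelParameters:
    """Map a 9-vector (8 conductances uS + tau_Ca ms) to model parameters."""
    g_and_tau = np.asarray(g_and_tau, dtype=float)
    if g_and_tau.shape != (9,):
        raise ValueError("candidate must be a 9-vector (g[8], tau_ca)")
    tau_ca = max(g_and_tau[8], 1e-6)    # box lower edge 0 is degenerate
    return ModelParameters(g=g_and_tau[:8], tau_ca=tau_ca)


def evaluate_candidate(g_and_tau: np.ndarray, target: BursterTarget,
                       kinetics: Optional[KineticsTable] = None,
                       probe: bool = False) -> float:
    """Score a search-space candidate; all failures map to ``PENALTY_SCORE``.

    With ``probe=True`` a short (4 s) pre-simulation rejects diverging
    candidates and candidates that fire no spike between seconds 2 and 4
    before paying for the full protocol.  Solutions silent for that long
    are (in practice) also discarded by the stability rule, but the probe
    is a heuristic: a pathologically slow cell could be rejected early.
    Candidates that pass are re-simulated from the standard initial
    condition and scored by the full protocol.
    """
    params = candidate_parameters(g_and_tau)
    if probe:
        try:
            tr = stg_model.integrate(params, duration=4000.0, dt=target.dt,
                                     transient=2000.0, record_currents=False,
                                     kinetics=kinetics)
        except IntegrationError:
            return PENALTY_SCORE
        if len(trace_metrics.spike_times(tr.V, tr.dt)) == 0:
            return PENALTY_SCORE
    return score_trace(params, target, kinetics=kinetics).total


def make_objective(target: BursterTarget,
                   kinetics: Optional[KineticsTable] = None,
                   probe: bool = True) -> Callable[[np.ndarray], float]:
    """An objective function over 9-vectors for :func:`stgscape.evolve.ga_minimize`."""
    def objective(candidate: np.ndarray) -> float:
        return evaluate_candidate(candidate, target, kinetics=kinetics, probe=probe)
    return objective
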