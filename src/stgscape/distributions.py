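"""Probability-distribution views of waveforms under graded perturbations.

A long stretch of the solution is treated as a stochastic variable: the
number of times a value of V (or of a current's share of the total
inward/outward current) is sampled is proportional to the time the system
spends there, so waveform extrema appear as sharp peaks.  Sweeping one
maximal conductance from 100% to 0% and stacking the histograms row by
row produces a (levels x bins) map whose ridges track how spike
amplitudes, slow-wave features and the overall amplitude deform; ridges
are enhanced by differentiating log10(counts + 1) along the V axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union
import warnings

import numpy as np

from . import stg_model
from .currentscape import split_and_normalize
from .stg_model import CHANNEL_NAMES, IntegrationError, KineticsTable, ModelParameters

__all__ = [
    "SweepHistogram",
    "default_v_edges",
    "default_share_edges",
    "sample_histogram",
    "ridge_map",
    "sweep_distribution",
]


def default_v_edges(n_bins: int = 1001, lo: float = -70.0, hi: float = 35.0) -> np.ndarray:
    """Membrane-potential bin edges: 1001 bins over (-70, 35) mV."""
    return np.linspace(lo, hi, n_bins + 1)


def default_share_edges(n_bins: int = 1001) -> np.ndarray:
    """Current-share bin edges: 1001 bins over [0, 1]."""
    return np.linspace(0.0, 1.0, n_bins + 1)


def sample_histogram(x: np.ndarray, edges: np.ndarray, n_samples: int = 2_000_000,
                     seed: Optional[int] = 0, all_samples: bool = False) -> np.ndarray:
    """Histogram of values drawn at random time stamps of a trace.

    Draws ``n_samples`` indices uniformly with replacement (seeded) and
    histograms the values; ``all_samples=True`` histograms the full
    sequence instead (the difference is sampling noise only).  Bins are
    half-open [lo, hi) with the last bin closed; out-of-range values are
    clipped into the edge bins with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need a sequence of at least 2 samples")
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if all_samples:
        vals = x
    else:
        rng = np.random.default_rng(seed)
        vals = x[rng.integers(0, x.size, size=int(n_samples))]
    lo, hi = edges[0], edges[-1]
    n_out = int(np.count_nonzero((vals < lo) | (vals > hi)))
    if n_out:
        warnings.warn(
            f"{n_out} samples outside histogram range [{lo}, {hi}] clipped to edge bins",
            stacklevel=2,
        )
        vals = np.clip(vals, lo, hi)
    counts, _ = np.histogram(vals, bins=edges)
    return counts


def ridge_map(counts: np.ndarray, bin_edges: Optional[np.ndarray] = None) -> np.ndarray:
    """Ridge-enhanced view of a (levels x bins) count matrix.

    The derivative of ``log10(counts + 1)`` along the bin (V) axis by
    central finite differences, per level row; sharp probability peaks
    (waveform extrema) appear as paired +/- ridges.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    logp = np.log10(counts + 1.0)
    if bin_edges is not None:
        centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
        return np.gradient(logp, centers, axis=-1)
    return np.gradient(logp, axis=-1)


@dataclass
class SweepHistogram:
    """Histogram rows of one observable across conductance-decrement levels.

    ``counts[i]`` is the histogram at ``levels[i]`` (level 1.0 = control,
    descending to 0); rows where integration failed are flagged in
    ``failed`` and left at zero counts.
    """

    variable: str                       # "V" or "share:<channel>"
    channel: str                        # the swept conductance
    bin_edges: np.ndarray
    levels: np.ndarray
    counts: np.ndarray                  # (levels, bins)
    failed: np.ndarray                  # (levels,) bool
    samples_per_level: int
    seed: Optional[int]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _share_observable(trace, index: int, sign: str) -> np.ndarray:
    share_out, share_in, _, _ = split_and_normalize(trace.I)
    return (share_out if sign == "out" else share_in)[index]


#: channels whose share is read off the inward half of the currentscape
_INWARD = {"Na", "CaT", "CaS", "H"}


def sweep_distribution(params: ModelParameters, channel: Union[int, str],
                       observable: Union[str, Tuple[str, str]] = "V",
                       levels: Optional[Sequence[float]] = None,
                       dt: float = 0.01, transient: float = 2.0e4,
                       window: float = 3.0e4, n_samples: int = 2_000_000,
                       seed: Optional[int] = 0, all_samples: bool = False,
                       n_bins: int = 1001,
                       kinetics: Optional[KineticsTable] = None) -> SweepHistogram:
    """Simulate a conductance-decrement sweep and histogram an observable.

    ``channel`` is the conductance scaled by each level in ``levels``
    (default 11 values descending 1 -> 0, row 0 = control).  ``observable``
    is ``"V"`` or ``("share", name)``; shares use the currentscape
    normalization on the current's dominant sign (inward for Na/CaT/CaS/H,
    outward otherwise).  Integration failures flag the row, not the sweep.
    """
    ch_name = channel if isinstance(channel, str) else CHANNEL_NAMES[channel]
    if ch_name not in CHANNEL_NAMES:
        raise ValueError(f"unknown channel {channel!r}")
    if levels is None:
        levels = np.linspace(1.0, 0.0, 11)
    levels = np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("levels must lie in [0, 1]")

    if observable == "V":
        var = "V"
        edges = default_v_edges(n_bins)
        need_currents = False
    else:
        kind, share_name = observable
        if kind != "share" or share_name not in CHANNEL_NAMES:
            raise ValueError(f"observable must be 'V' or ('share', channel), got {observable!r}")
        var = f"share:{share_name}"
        edges = default_share_edges(n_bins)
        need_currents = True
        share_idx = CHANNEL_NAMES.index(share_name)
        share_sign = "in" if share_name in _INWARD else "out"

    counts = np.zeros((len(levels), len(edges) - 1), dtype=np.int64)
    failed = np.zeros(len(levels), dtype=bool)
    for i, level in enumerate(levels):
        scaled = params.with_scaled(ch_name, float(level))
        try:
            trace = stg_model.integrate(
                scaled, duration=transient + window, dt=dt,
                transient=transient, record_currents=need_currents,
                kinetics=kinetics,
            )
        except IntegrationError:
            failed[i] = True
            continue
        if observable == "V":
            values = trace.V
        else:
            values = _share_observable(trace, share_idx, share_sign)
        row_seed = None if seed is None else seed + i
        counts[i] = sample_histogram(values, edges, n_samples=n_samples,
                                     seed=row_seed, all_samples=all_samples)
    return SweepHistogram(
        variable=var, channel=ch_name, bin_edges=edges, levels=levels,
        counts=counts, failed=failed, samples_per_level=n_samples, seed=seed,
    )
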