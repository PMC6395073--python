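"""Currentscapes: stacked percent-contribution images of the ionic currents.

At every time stamp the eight membrane currents are split by sign, each
sign's magnitudes are normalized to shares of the total inward or outward
current at that instant, and the shares are rendered as vertical bars of
an R-row image (one column per time stamp, one contiguous band per
channel, fixed channel stacking order).  The total inward and outward
currents flank the shares as filled curves on a logarithmic scale with
dotted reference lines at 5, 50 and 500 nA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .stg_model import CHANNEL_NAMES

__all__ = [
    "Currentscape",
    "CHANNEL_COLORS",
    "split_and_normalize",
    "build_cs_matrix",
    "compute_currentscape",
    "render_currentscape",
]

#: fixed channel color legend (matplotlib named colors)
CHANNEL_COLORS = (
    "#1f77b4",  # Na
    "#ff7f0e",  # CaT
    "#2ca02c",  # CaS
    "#d62728",  # A
    "#9467bd",  # KCa
    "#8c564b",  # Kd
    "#e377c2",  # H
    "#7f7f7f",  # leak
)

#: CS matrix value for columns with zero total current of that sign
EMPTY_PIXEL = -1


def split_and_normalize(I: np.ndarray):
    """Per-sign share matrices of an 8 x N current matrix.

    Returns ``(share_out, share_in, n_out, n_in)``: outward shares use the
    positive entries, inward shares the magnitudes of the negative entries;
    each column with a non-zero total sums to 1, zero-total columns are
    all-zero (flagged empty downstream).
    """
    I = np.asarray(I, dtype=float)
    if I.ndim != 2 or I.shape[0] != 8:
        raise ValueError("expected an 8 x N current matrix")
    if not np.all(np.isfinite(I)):
        raise ValueError("current matrix must be finite")
    C_out = np.where(I > 0, I, 0.0)
    C_in = np.where(I < 0, -I, 0.0)
    n_out = C_out.sum(axis=0)
    n_in = C_in.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share_out = np.where(n_out > 0, C_out / n_out, 0.0)
        share_in = np.where(n_in > 0, C_in / n_in, 0.0)
    return share_out, share_in, n_out, n_in


def build_cs_matrix(shares: np.ndarray, R: int = 2000) -> np.ndarray:
    """Map a share matrix (columns summing to <= 1) to an R x N index image.

    Column j assigns pixel rows to channels in fixed channel order with
    band boundaries at the floor of the cumulative share*R (the final band
    absorbs rounding so unit-sum columns fill exactly R rows).  Columns
    summing to ~0 are flagged with ``EMPTY_PIXEL``.
    """
    shares = np.asarray(shares, dtype=float)
    if np.any(shares < -1e-12) or np.any(shares > 1.0 + 1e-9):
        raise ValueError("shares must lie in [0, 1]")
    n_ch, N = shares.shape
    colsum = shares.sum(axis=0)
    if np.any(colsum > 1.0 + 1e-6):
        raise ValueError("share columns must sum to at most 1")
    p = shares * R
    cum = np.vstack([np.zeros(N), np.cumsum(p, axis=0)])      # (n_ch+1, N)
    bounds = np.floor(cum + 1e-9).astype(np.int64)
    # unit-sum columns must fill all R rows; absorb rounding in the last band
    unit = np.isclose(colsum, 1.0, atol=1e-6)
    bounds[-1, unit] = R
    counts = np.diff(bounds, axis=0)                          # (n_ch, N)
    tail = R - bounds[-1]                                     # unfilled rows
    all_counts = np.vstack([counts, tail])                    # (n_ch+1, N)
    values = np.tile(np.concatenate([np.arange(n_ch), [EMPTY_PIXEL]]), N)
    cs = np.repeat(values, all_counts.T.ravel()).reshape(N, R).T
    return cs.astype(np.int16)


@dataclass
class Currentscape:
    """Index images and normalization vectors of one trace's currentscape."""

    CS_out: np.ndarray          # R x N, channel index per pixel (-1 empty)
    CS_in: np.ndarray
    n_out: np.ndarray           # total outward current per column, nA
    n_in: np.ndarray            # total inward current magnitude per column, nA
    R: int
    channel_names: Tuple[str, ...] = CHANNEL_NAMES

    @property
    def empty_out(self) -> np.ndarray:
        return self.n_out == 0

    @property
    def empty_in(self) -> np.ndarray:
        return self.n_in == 0


def compute_currentscape(I: np.ndarray, R: int = 2000) -> Currentscape:
    """Full currentscape of an 8 x N current matrix."""
    share_out, share_in, n_out, n_in = split_and_normalize(I)
    return Currentscape(
        CS_out=build_cs_matrix(share_out, R),
        CS_in=build_cs_matrix(share_in, R),
        n_out=n_out, n_in=n_in, R=R,
    )


def render_currentscape(cs: Currentscape, out_path, V: Optional[np.ndarray] = None,
                        time: Optional[np.ndarray] = None, dpi: int = 150):
    """Render a currentscape figure to ``out_path`` (png/svg/pdf).

    Panels top to bottom: membrane potential (if given), total outward
    current on a log scale, outward shares, inward shares, total inward
    current on a log scale.  Dotted reference lines at 5, 50 and 500 nA.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    N = cs.CS_out.shape[1]
    if N == 0:
        raise ValueError("cannot render a zero-length currentscape")
    x = np.arange(N) if time is None else np.asarray(time)

    n_panels = 4 + (V is not None)
    heights = ([1.2] if V is not None else []) + [0.8, 2.4, 2.4, 0.8]
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 2 + 1.3 * n_panels), sharex=True,
        gridspec_kw={"height_ratios": heights, "hspace": 0.08},
    )
    axes = np.atleast_1d(axes)
    i_ax = 0
    if V is not None:
        axes[0].plot(x, V, color="black", lw=0.7)
        axes[0].set_ylabel("V (mV)")
        i_ax = 1

    # empty columns render as gaps: map EMPTY_PIXEL to transparent white
    cmap = ListedColormap(("#ffffff",) + CHANNEL_COLORS)
    extent = (x[0], x[-1], 0, 1)

    def _log_panel(ax, totals, invert):
        tot = np.maximum(totals, 1e-3)
        ax.fill_between(x, tot, 1e-3, color="black")
        ax.set_yscale("log")
        ax.set_ylim(0.5, 2000)
        for ref in (5.0, 50.0, 500.0):
            ax.axhline(ref, ls=":", lw=0.6, color="gray")
        if invert:
            ax.invert_yaxis()
        ax.set_ylabel("nA")

    _log_panel(axes[i_ax], cs.n_out, invert=False)
    axes[i_ax + 1].imshow(cs.CS_out + 1, aspect="auto", origin="upper",
                          cmap=cmap, vmin=0, vmax=8, extent=extent,
                          interpolation="nearest")
    axes[i_ax + 1].set_ylabel("outward %")
    axes[i_ax + 2].imshow(cs.CS_in + 1, aspect="auto", origin="upper",
                          cmap=cmap, vmin=0, vmax=8, extent=extent,
                          interpolation="nearest")
    axes[i_ax + 2].set_ylabel("inward %")
    _log_panel(axes[i_ax + 3], cs.n_in, invert=True)
    axes[-1].set_xlabel("time (ms)")

    handles = [plt.Line2D([], [], color=c, lw=4) for c in CHANNEL_COLORS]
    axes[i_ax + 1].legend(handles, cs.channel_names, loc="upper right",
                          ncol=4, fontsize=7, framealpha=0.8)
    for ax in axes:
        ax.tick_params(labelsize=8)
    fig.savefig(out_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out_path
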