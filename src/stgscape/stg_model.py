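"""Single-compartment, eight-current conductance-based neuron model.

The membrane potential of a cell with capacitance ``C`` obeys

    C dV/dt = Ie - sum_i I_i,      I_i = g_i m^p h^q (V - E_i)

with seven voltage-gated currents (Na, CaT, CaS, A, KCa, Kd, H) plus an
ohmic leak.  Gates relax first-order to voltage-dependent steady states
(the KCa activation additionally saturates with intracellular calcium),
intracellular calcium integrates the calcium currents with buffering time
constant ``tau_ca``, and the calcium reversal potential is computed
dynamically from the Nernst equation.  The system has 13 state variables
and is integrated with a fixed-step 4th-order Runge-Kutta scheme.

Units are mV, ms, nA, uS, nF and uM throughout (self-consistent:
nF*mV/ms = nA = uS*mV).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import _kernels

__all__ = [
    "CHANNEL_NAMES",
    "ChannelKinetics",
    "KineticsTable",
    "ModelParameters",
    "StateVector",
    "TraceRecord",
    "IntegrationError",
    "load_kinetics",
    "default_initial_state",
    "gate_steady_state",
    "nernst_calcium",
    "membrane_currents",
    "derivatives",
    "integrate",
]

#: channel order used everywhere (conductance vectors, current matrices, colors)
CHANNEL_NAMES = ("Na", "CaT", "CaS", "A", "KCa", "Kd", "H", "leak")

_TAU_FORMS = {"sigmoid": 0, "biexp": 1, "product": 2}

#: default Nernst prefactor RT/zF for divalent calcium at ~10 degC (mV)
NERNST_PREFACTOR_CA = 12.2


class IntegrationError(RuntimeError):
    """Raised when the trajectory becomes non-finite.

    Attributes ``step`` and ``time_ms`` identify where integration failed.
    """

    def __init__(self, step: int, time_ms: float):
        self.step = step
        self.time_ms = time_ms
        super().__init__(
            f"non-finite state at integration step {step} (t = {time_ms:.3f} ms)"
        )


@dataclass(frozen=True)
class ChannelKinetics:
    """Gating description of one voltage-gated channel.

    ``m_inf``/``h_inf`` are sigmoid descriptors ``{v_half, slope}`` (mV);
    ``m_inf`` may carry ``ca_half`` (uM) for calcium-saturated activation.
    ``tau_m``/``tau_h`` are time-constant descriptors with a ``form`` key
    (see :mod:`stgscape._kernels` for the closed forms).  ``reversal`` is a
    fixed potential in mV or the string ``"nernst-calcium"``.
    """

    name: str
    p: int
    q: int
    m_inf: dict
    tau_m: dict
    reversal: Union[float, str]
    h_inf: Optional[dict] = None
    tau_h: Optional[dict] = None

    def __post_init__(self):
        if self.p not in (0, 1, 3, 4):
            raise ValueError(f"{self.name}: unsupported activation exponent p={self.p}")
        if self.q not in (0, 1):
            raise ValueError(f"{self.name}: unsupported inactivation exponent q={self.q}")
        if self.q == 1 and (self.h_inf is None or self.tau_h is None):
            raise ValueError(f"{self.name}: q=1 requires h_inf and tau_h")


def _tau_row(spec: Optional[dict]) -> np.ndarray:
    row = np.full(8, np.nan)
    if spec is None:
        row[0] = -1.0
        return row
    row[0] = float(_TAU_FORMS[spec["form"]])
    row[1] = spec.get("c0", 0.0)
    row[2] = spec.get("c1", 0.0)
    row[3] = spec.get("v1", 0.0)
    row[4] = spec.get("k1", 1.0)
    row[5] = spec.get("v2", 0.0)
    row[6] = spec.get("k2", 1.0)
    row[7] = spec.get("c3", 0.0)
    return row


def _tau_value(spec: dict, V: float) -> float:
    return float(_kernels._tau_eval(_tau_row(spec), V))


class KineticsTable:
    """The seven gated channels plus compiled numeric tables for the kernels."""

    def __init__(self, channels: Sequence[ChannelKinetics]):
        if tuple(c.name for c in channels) != CHANNEL_NAMES[:7]:
            raise ValueError(
                f"kinetics must define channels {CHANNEL_NAMES[:7]} in order, "
                f"got {tuple(c.name for c in channels)}"
            )
        nernst = tuple(c.name for c in channels if c.reversal == "nernst-calcium")
        if nernst != ("CaT", "CaS"):
            raise ValueError(
                f"exactly CaT and CaS must use the dynamic calcium reversal, got {nernst}"
            )
        self.channels = tuple(channels)
        self.by_name = {c.name: c for c in channels}
        self.p = np.array([c.p for c in channels], dtype=np.int64)
        self.q = np.array([c.q for c in channels], dtype=np.int64)
        # ca_half 0.0 flags "no calcium dependence" (kernel sentinel)
        self.minf_t = np.array(
            [
                [c.m_inf["v_half"], c.m_inf["slope"], c.m_inf.get("ca_half", 0.0)]
                for c in channels
            ]
        )
        self.hinf_t = np.array(
            [
                [c.h_inf["v_half"], c.h_inf["slope"]] if c.h_inf else [np.nan, np.nan]
                for c in channels
            ]
        )
        self.taum_t = np.vstack([_tau_row(c.tau_m) for c in channels])
        self.tauh_t = np.vstack([_tau_row(c.tau_h) for c in channels])
        self.isca = np.array([c.reversal == "nernst-calcium" for c in channels])
        self.ca_half = self.minf_t[:, 2].copy()
        self._validate_tau_positive()
        self._build_lut()

    def _build_lut(self, v_lo: float = -120.0, v_hi: float = 70.0,
                   step: float = 0.01):
        """Tabulate the 18 voltage-dependent gating functions on a dense grid.

        The integrator evaluates gating by linear interpolation in this
        table; at 0.01 mV spacing the interpolation error is below 1e-6
        for every sigmoid/time-constant in the table.  Row layout:
        0-6 m_inf (voltage part), 7-10 h_inf (Na, CaT, CaS, A),
        11-17 tau_m, 18-21 tau_h.
        """
        n = int(round((v_hi - v_lo) / step)) + 1
        V = v_lo + step * np.arange(n)
        lut = np.empty((22, n))

        def sigmoid(spec):
            return 1.0 / (1.0 + np.exp((V - spec["v_half"]) / spec["slope"]))

        def tau(spec):
            form = spec["form"]
            if form == "sigmoid":
                return spec["c0"] + spec["c1"] / (
                    1.0 + np.exp((V - spec["v1"]) / spec["k1"]))
            if form == "biexp":
                return spec["c0"] + spec["c1"] / (
                    np.exp((V - spec["v1"]) / spec["k1"])
                    + np.exp((V - spec["v2"]) / spec["k2"]))
            return (spec["c0"] / (1.0 + np.exp((V - spec["v1"]) / spec["k1"]))) * (
                spec["c3"] + 1.0 / (1.0 + np.exp((V - spec["v2"]) / spec["k2"])))

        h_row = 7
        th_row = 18
        for i, c in enumerate(self.channels):
            lut[i] = sigmoid(c.m_inf)
            lut[11 + i] = tau(c.tau_m)
            if c.q == 1:
                lut[h_row] = sigmoid(c.h_inf)
                lut[th_row] = tau(c.tau_h)
                h_row += 1
                th_row += 1
        self.lut = lut
        self.lut_v_lo = v_lo
        self.lut_inv_step = 1.0 / step
        self.lut_n = n

    def _validate_tau_positive(self):
        V = np.linspace(-100.0, 60.0, 321)
        for c in self.channels:
            for label, spec in (("tau_m", c.tau_m), ("tau_h", c.tau_h)):
                if spec is None:
                    continue
                vals = np.array([_tau_value(spec, v) for v in V])
                if not np.all(vals > 0):
                    raise ValueError(f"{c.name}.{label} is not strictly positive on [-100, 60] mV")


def load_kinetics(path=None) -> KineticsTable:
    """Load a kinetics configuration; ``None`` loads the packaged default.

    The packaged table transcribes the canonical STG gating functions
    (Liu-1998 lineage) used throughout this package.
    """
    if path is None:
        ref = importlib.resources.files("stgscape").joinpath("data/kinetics.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    channels = []
    for entry in raw["channels"]:
        channels.append(
            ChannelKinetics(
                name=entry["name"],
                p=int(entry["p"]),
                q=int(entry["q"]),
                m_inf=dict(entry["m_inf"]),
                tau_m=dict(entry["tau_m"]),
                reversal=entry["reversal"],
                h_inf=dict(entry["h_inf"]) if "h_inf" in entry else None,
                tau_h=dict(entry["tau_h"]) if "tau_h" in entry else None,
            )
        )
    return KineticsTable(channels)


_DEFAULT_KINETICS: Optional[KineticsTable] = None


def default_kinetics() -> KineticsTable:
    global _DEFAULT_KINETICS
    if _DEFAULT_KINETICS is None:
        _DEFAULT_KINETICS = load_kinetics()
    return _DEFAULT_KINETICS


@dataclass(frozen=True)
class ModelParameters:
    """Maximal conductances and passive/calcium constants of one model cell.

    ``g`` holds the 8 maximal conductances in uS ordered
    (Na, CaT, CaS, A, KCa, Kd, H, leak); ``tau_ca`` is the calcium buffering
    time constant in ms.
    """

    g: np.ndarray
    tau_ca: float
    C: float = 10.0            # nF
    Ca0: float = 0.05          # uM, resting calcium
    CaF: float = 0.94          # uM/nA, current-to-concentration factor
    Ca_out: float = 3.0e3      # uM, extracellular calcium
    E_Na: float = 30.0         # mV
    E_K: float = -80.0
    E_H: float = -20.0
    E_leak: float = -50.0
    nernst_prefactor: float = NERNST_PREFACTOR_CA  # mV (RT/zF, z=2)
    label: Optional[str] = None

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        if g.shape != (8,):
            raise ValueError("g must be an 8-vector (Na, CaT, CaS, A, KCa, Kd, H, leak)")
        if np.any(g < 0):
            raise ValueError("maximal conductances must be non-negative")
        if self.tau_ca <= 0 or self.C <= 0 or self.Ca_out <= 0:
            raise ValueError("tau_ca, C and Ca_out must be positive")
        object.__setattr__(self, "g", g)

    def erev(self) -> np.ndarray:
        """Fixed reversal potentials per channel (NaN for the calcium channels)."""
        return np.array(
            [self.E_Na, np.nan, np.nan, self.E_K, self.E_K, self.E_K, self.E_H, self.E_leak]
        )

    def with_scaled(self, channel: Union[int, str], factor: float) -> "ModelParameters":
        """A copy with one maximal conductance scaled by ``factor``."""
        idx = channel if isinstance(channel, int) else CHANNEL_NAMES.index(channel)
        g = self.g.copy()
        g[idx] *= factor
        return replace(self, g=g, label=None)


#: gate names in state-vector order
GATE_NAMES = (
    "m_Na", "h_Na", "m_CaT", "h_CaT", "m_CaS", "h_CaS",
    "m_A", "h_A", "m_KCa", "m_Kd", "m_H",
)


@dataclass
class StateVector:
    """The 13 dynamical variables: V (mV), 11 gates, intracellular Ca (uM)."""

    V: float
    gates: np.ndarray
    Ca: float

    def __post_init__(self):
        gates = np.asarray(self.gates, dtype=float)
        if gates.shape != (11,):
            raise ValueError("gates must be an 11-vector")
        if self.Ca <= 0:
            raise ValueError("Ca must be positive")
        self.gates = gates

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.V], self.gates, [self.Ca]))

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (13,):
            raise ValueError("state must have exactly 13 entries")
        return cls(V=float(y[0]), gates=y[1:12].copy(), Ca=float(y[12]))


def default_initial_state() -> StateVector:
    """The fixed initial condition used for every run: V=-51 mV, all gates 0
    (inactivation gates start fully inactivated), Ca=5 uM."""
    return StateVector(V=-51.0, gates=np.zeros(11), Ca=5.0)


def nernst_calcium(Ca: float, Ca_out: float = 3.0e3,
                   prefactor: float = NERNST_PREFACTOR_CA) -> float:
    """Calcium reversal potential E_Ca = (RT/zF) ln(Ca_out / Ca) in mV."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca <= 0) or Ca_out <= 0:
        raise ValueError("calcium concentrations must be positive")
    return prefactor * np.log(Ca_out / Ca)


def gate_steady_state(kin: ChannelKinetics, V: float, Ca: Optional[float] = None):
    """Steady states and time constants ``(m_inf, h_inf, tau_m, tau_h)`` at V.

    ``h_inf``/``tau_h`` are None for channels without inactivation.  The KCa
    activation requires ``Ca`` (uM) and multiplies the voltage sigmoid by
    ``Ca / (Ca + ca_half)``.
    """
    m_inf = 1.0 / (1.0 + np.exp((V - kin.m_inf["v_half"]) / kin.m_inf["slope"]))
    if "ca_half" in kin.m_inf:
        if Ca is None or Ca <= 0:
            raise ValueError(f"{kin.name}: calcium-dependent activation needs Ca > 0")
        m_inf *= Ca / (Ca + kin.m_inf["ca_half"])
    tau_m = _tau_value(kin.tau_m, V)
    h_inf = tau_h = None
    if kin.q == 1:
        h_inf = 1.0 / (1.0 + np.exp((V - kin.h_inf["v_half"]) / kin.h_inf["slope"]))
        tau_h = _tau_value(kin.tau_h, V)
    return m_inf, h_inf, tau_m, tau_h


def _state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (13,):
        raise ValueError("state must have exactly 13 entries")
    return y


def membrane_currents(state, params: ModelParameters,
                      kinetics: Optional[KineticsTable] = None) -> np.ndarray:
    """The 8 instantaneous membrane currents (nA, outward positive)."""
    kin = kinetics or default_kinetics()
    y = _state_array(state)
    out = np.empty(8)
    _kernels.currents_kernel(
        y, out, params.g, kin.p, kin.q, params.erev(), kin.isca,
        params.C, params.Ca_out, params.nernst_prefactor,
    )
    return out


def derivatives(state, params: ModelParameters, Ie: float = 0.0,
                kinetics: Optional[KineticsTable] = None) -> np.ndarray:
    """Time derivatives of the 13 state variables (units per ms)."""
    kin = kinetics or default_kinetics()
    y = _state_array(state)
    dy = np.empty(13)
    _kernels.deriv_kernel(
        y, dy, float(Ie), params.g, kin.p, kin.q, params.erev(), kin.isca,
        kin.minf_t, kin.hinf_t, kin.taum_t, kin.tauh_t,
        params.C, params.tau_ca, params.Ca0, params.CaF,
        params.Ca_out, params.nernst_prefactor,
    )
    return dy


@dataclass
class TraceRecord:
    """A simulated trajectory sampled every ``dt`` ms from ``t0`` onward.

    ``I`` is the 8 x N matrix of per-channel currents (nA, outward positive)
    when currents were recorded, else None.  ``Ie`` is the injected current
    (scalar, or the per-sample schedule over the retained window).
    """

    dt: float
    t0: float
    V: np.ndarray
    Ca: np.ndarray
    Ie: Union[float, np.ndarray]
    params: ModelParameters
    I: Optional[np.ndarray] = None
    final_state: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.V.size

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def to_frame(self):
        """Columnar view (t, V, I_Na..I_leak, Ca, Ie) as a pandas DataFrame."""
        import pandas as pd

        data = {"t": self.time, "V": self.V}
        if self.I is not None:
            for i, name in enumerate(CHANNEL_NAMES):
                data[f"I_{name}"] = self.I[i]
        data["Ca"] = self.Ca
        data["Ie"] = np.broadcast_to(np.asarray(self.Ie, dtype=float), (self.n,)) \
            if np.ndim(self.Ie) else np.full(self.n, float(self.Ie))
        return pd.DataFrame(data)


def integrate(params: ModelParameters, duration: float, dt: float = 0.1,
              Ie: Union[float, np.ndarray] = 0.0, transient: float = 0.0,
              init=None, record_currents: bool = True,
              kinetics: Optional[KineticsTable] = None) -> TraceRecord:
    """Integrate the model with fixed-step RK4 and record the trajectory.

    Parameters
    ----------
    duration : float
        Total simulated time (ms), including the transient.
    transient : float
        Leading window (ms) discarded from the returned record.
    Ie : float or array
        Injected current (nA); an array is a step-constant schedule with one
        value per integration step.
    record_currents : bool
        Record all 8 per-channel currents at every retained sample.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite, naming the failing step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (duration > transient >= 0):
        raise ValueError("need duration > transient >= 0")
    kin = kinetics or default_kinetics()
    y0 = _state_array(init if init is not None else default_initial_state())
    n_steps = int(round(duration / dt))
    keep_from = int(round(transient / dt))
    Ie_arr = np.atleast_1d(np.asarray(Ie, dtype=float))
    if Ie_arr.size not in (1, n_steps):
        raise ValueError("Ie schedule must be scalar or have one value per step")
    status, fail_step, V, Ca, I, y_final = _kernels.integrate_kernel(
        y0, dt, n_steps, keep_from, Ie_arr, record_currents,
        params.g, kin.p, kin.q, params.erev(), kin.isca, kin.ca_half,
        kin.lut, kin.lut_v_lo, kin.lut_inv_step, kin.lut_n,
        params.C, params.tau_ca, params.Ca0, params.CaF,
        params.Ca_out, params.nernst_prefactor,
    )
    if status != 0:
        raise IntegrationError(fail_step, fail_step * dt)
    Ie_out = float(Ie_arr[0]) if Ie_arr.size == 1 else Ie_arr[keep_from:]
    return TraceRecord(
        dt=dt, t0=keep_from * dt, V=V, Ca=Ca, Ie=Ie_out, params=params,
        I=I if record_currents else None, final_state=y_final,
    )
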