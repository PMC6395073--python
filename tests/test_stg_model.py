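"""Unit tests of the conductance-based model: gating, currents, RK4."""

import dataclasses
import math

import numpy as np
import pytest

from stgscape import (
    IntegrationError,
    ModelParameters,
    StateVector,
    default_initial_state,
    derivatives,
    gate_steady_state,
    integrate,
    membrane_currents,
    nernst_calcium,
)
from stgscape.stg_model import CHANNEL_NAMES, GATE_NAMES


def passive_params(g_leak=0.0, **kwargs):
    g = np.zeros(8)
    g[7] = g_leak
    return ModelParameters(g=g, tau_ca=100.0, **kwargs)


class TestGateSteadyState:
    def test_sigmoid_midpoint(self, kinetics):
        for kin in kinetics.channels:
            if "ca_half" in kin.m_inf:
                continue
            m_inf, _, tau_m, _ = gate_steady_state(kin, kin.m_inf["v_half"])
            assert m_inf == pytest.approx(0.5)
            assert tau_m > 0

    def test_inactivation_midpoint(self, kinetics):
        na = kinetics.by_name["Na"]
        _, h_inf, _, tau_h = gate_steady_state(na, na.h_inf["v_half"])
        assert h_inf == pytest.approx(0.5)
        assert tau_h > 0

    def test_kca_vanishes_without_calcium(self, kinetics):
        kca = kinetics.by_name["KCa"]
        for V in (-60.0, -20.0, 20.0):
            m_inf, _, _, _ = gate_steady_state(kca, V, Ca=1e-9)
            assert m_inf == pytest.approx(0.0, abs=1e-9)

    def test_kca_at_half_saturation(self, kinetics):
        # Ca = ca_half multiplies the voltage sigmoid by exactly 1/2
        kca = kinetics.by_name["KCa"]
        ca_half = kca.m_inf["ca_half"]
        V = -10.0
        sigmoid = 1.0 / (1.0 + math.exp((V - kca.m_inf["v_half"]) / kca.m_inf["slope"]))
        m_inf, _, _, _ = gate_steady_state(kca, V, Ca=ca_half)
        assert m_inf == pytest.approx(0.5 * sigmoid, rel=1e-12)

    def test_kca_requires_calcium(self, kinetics):
        with pytest.raises(ValueError):
            gate_steady_state(kinetics.by_name["KCa"], -30.0, Ca=0.0)

    def test_bounds_and_positivity(self, kinetics):
        for kin in kinetics.channels:
            for V in np.linspace(-100, 60, 33):
                m_inf, h_inf, tau_m, tau_h = gate_steady_state(kin, V, Ca=1.0)
                assert 0.0 <= m_inf <= 1.0
                assert tau_m > 0
                if kin.q == 1:
                    assert 0.0 <= h_inf <= 1.0
                    assert tau_h > 0


class TestNernstCalcium:
    def test_equal_concentrations(self):
        assert nernst_calcium(3000.0, 3000.0) == pytest.approx(0.0)

    def test_resting_calcium(self):
        # 12.2 * ln(3000 / 0.05) = 12.2 * ln(60000)
        assert nernst_calcium(0.05, 3000.0, 12.2) == pytest.approx(
            12.2 * math.log(60000.0))
        assert nernst_calcium(0.05, 3000.0, 12.2) == pytest.approx(134.2, abs=0.1)

    def test_log_unit(self):
        assert nernst_calcium(3000.0 * math.e, 3000.0, 12.2) == pytest.approx(-12.2)

    def test_monotone_decreasing(self):
        ca = np.linspace(0.01, 100.0, 50)
        E = nernst_calcium(ca, 3000.0)
        assert np.all(np.diff(E) < 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nernst_calcium(0.0, 3000.0)


class TestMembraneCurrents:
    def test_zero_conductances(self):
        s = default_initial_state()
        I = membrane_currents(s, passive_params())
        assert np.allclose(I, 0.0)

    def test_leak_only(self):
        # g_leak = 0.1 uS at V = -40 with E_leak = -50 drives 1 nA outward
        s = StateVector(V=-40.0, gates=np.zeros(11), Ca=0.05)
        I = membrane_currents(s, passive_params(g_leak=0.1))
        assert I[7] == pytest.approx(1.0)
        assert np.allclose(I[:7], 0.0)

    def test_zero_driving_force(self):
        g = np.zeros(8)
        g[CHANNEL_NAMES.index("Kd")] = 100.0
        p = ModelParameters(g=g, tau_ca=100.0)
        gates = np.zeros(11)
        gates[GATE_NAMES.index("m_Kd")] = 0.5
        s = StateVector(V=-80.0, gates=gates, Ca=0.05)
        assert membrane_currents(s, p)[CHANNEL_NAMES.index("Kd")] == pytest.approx(0.0)


class TestDerivatives:
    def test_injected_current_only(self):
        s = default_initial_state()
        dy = derivatives(s, passive_params(), Ie=10.0)
        assert dy[0] == pytest.approx(1.0)     # 10 nA / 10 nF = 1 mV/ms

    def test_calcium_fixed_point_without_currents(self):
        p = passive_params()
        s = StateVector(V=-51.0, gates=np.zeros(11), Ca=p.Ca0)
        assert derivatives(s, p)[12] == pytest.approx(0.0)

    def test_calcium_fixed_point_with_inward_current(self):
        # total calcium current -1 nA balances at Ca = Ca0 + CaF = 0.99 uM
        p = passive_params()
        Ca_star = p.Ca0 + p.CaF * 1.0
        V = -60.0
        E_ca = nernst_calcium(Ca_star, p.Ca_out, p.nernst_prefactor)
        g_cat = 1.0 / (E_ca - V)               # m=h=1 gives exactly -1 nA
        g = np.zeros(8)
        g[CHANNEL_NAMES.index("CaT")] = g_cat
        p = dataclasses.replace(p, g=g)
        gates = np.zeros(11)
        gates[GATE_NAMES.index("m_CaT")] = 1.0
        gates[GATE_NAMES.index("h_CaT")] = 1.0
        s = StateVector(V=V, gates=gates, Ca=Ca_star)
        assert derivatives(s, p)[12] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_is_13(self, table):
        s = default_initial_state()
        assert s.to_array().shape == (13,)
        assert derivatives(s, table["a"]).shape == (13,)


class TestIntegrate:
    def test_rk4_fourth_order_convergence(self):
        # leak-only cell: dV/dt = -(g/C)(V - E), exact exponential relaxation
        p = passive_params(g_leak=1.0)          # time constant C/g = 10 ms
        init = StateVector(V=0.0, gates=np.zeros(11), Ca=0.05)
        T = 10.0
        exact = p.E_leak + (0.0 - p.E_leak) * math.exp(-T / 10.0)

        def global_error(dt):
            tr = integrate(p, duration=T + dt, dt=dt, init=init,
                           record_currents=False)
            return abs(tr.V[int(round(T / dt))] - exact)

        e1, e2 = global_error(0.2), global_error(0.1)
        assert e2 > 0
        assert e1 / e2 == pytest.approx(16.0, rel=0.2)

    def test_single_step_matches_exponential(self):
        p = passive_params(g_leak=1.0)
        init = StateVector(V=-49.0, gates=np.zeros(11), Ca=0.05)
        tr = integrate(p, duration=0.2, dt=0.1, init=init, record_currents=False)
        # dV/dt = -0.1 (V + 50); after one step of 0.1 ms
        exact = -50.0 + 1.0 * math.exp(-0.1 * 0.1)
        assert tr.V[1] == pytest.approx(exact, abs=1e-8)

    def test_leak_relaxes_to_reversal(self):
        p = passive_params(g_leak=0.1)
        tr = integrate(p, duration=2000.0, dt=0.1, record_currents=False)
        assert tr.V[-1] == pytest.approx(p.E_leak, abs=1e-3)

    def test_transient_dropped(self, table):
        tr = integrate(table["a"], duration=1000.0, dt=0.1, transient=400.0,
                       record_currents=False)
        assert tr.t0 == pytest.approx(400.0)
        assert tr.n == 6000
        assert tr.time[0] == pytest.approx(400.0)

    def test_determinism_bit_identical(self, table):
        a = integrate(table["c"], duration=2000.0, dt=0.1, record_currents=True)
        b = integrate(table["c"], duration=2000.0, dt=0.1, record_currents=True)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.I, b.I)
        assert np.array_equal(a.Ca, b.Ca)

    def test_gates_boxed_and_calcium_positive(self, table):
        tr = integrate(table["a"], duration=3.0e4, dt=0.1, record_currents=False)
        assert np.all(tr.Ca > 0)
        assert np.all(np.isfinite(tr.V))
        gates = tr.final_state[1:12]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_current_bookkeeping_residual_shrinks_with_dt(self, table):
        # C dV/dt + sum(I) - Ie -> 0 as dt -> 0 (central finite differences)
        p = table["a"]

        def residual(dt):
            tr = integrate(p, duration=600.0, dt=dt, transient=100.0,
                           record_currents=True)
            dVdt = np.gradient(tr.V, tr.dt)
            r = p.C * dVdt + tr.I.sum(axis=0)
            return np.sqrt(np.mean(r[5:-5] ** 2))

        r1, r2 = residual(0.1), residual(0.05)
        assert r2 < 0.5 * r1

    def test_nonfinite_state_raises(self):
        p = passive_params()
        with pytest.raises(IntegrationError) as err:
            integrate(p, duration=50.0, dt=0.1, Ie=1.0e308, record_currents=False)
        assert err.value.step >= 0

    def test_ie_schedule(self):
        p = passive_params(g_leak=0.1)
        n = 1000
        sched = np.zeros(n)
        sched[500:] = 1.0                      # 1 nA step at 50 ms
        tr = integrate(p, duration=100.0, dt=0.1, Ie=sched, record_currents=False)
        # steady state with 1 nA through 0.1 uS: V = E + I/g = -40
        assert tr.V[-1] > tr.V[400]

    def test_validation_errors(self, table):
        with pytest.raises(ValueError):
            integrate(table["a"], duration=100.0, dt=-0.1)
        with pytest.raises(ValueError):
            integrate(table["a"], duration=100.0, dt=0.1, transient=200.0)
        with pytest.raises(ValueError):
            ModelParameters(g=np.full(8, -1.0), tau_ca=100.0)
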