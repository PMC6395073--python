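"""Numba kernels for the single-compartment model.

All kernels operate on a packed numeric representation of the channel
kinetics (see :mod:`stgscape.stg_model`):

* ``minf_t``  — (7, 3) rows ``(v_half, slope, ca_half)``; ``ca_half`` is 0
  for channels without calcium-dependent activation (fastmath-safe sentinel).
* ``hinf_t``  — (7, 2) rows ``(v_half, slope)``; NaN rows for q = 0 channels.
* ``taum_t`` / ``tauh_t`` — (7, 8) rows ``(form, c0, c1, v1, k1, v2, k2, c3)``
  where form 0 is ``c0 + c1/(1+exp((V-v1)/k1))``, form 1 is
  ``c0 + c1/(exp((V-v1)/k1) + exp((V-v2)/k2))`` and form 2 is
  ``(c0/(1+exp((V-v1)/k1))) * (c3 + 1/(1+exp((V-v2)/k2)))``.

State layout (13 variables): ``V, mNa, hNa, mCaT, hCaT, mCaS, hCaS, mA, hA,
mKCa, mKd, mH, Ca``.  Currents use the outward-positive convention
``I_i = g_i m^p h^q (V - E_i)``.
"""

import numpy as np
from numba import njit

#: gated-channel gate exponents, channel order (Na, CaT, CaS, A, KCa, Kd, H)
P_EXP = np.array([3, 3, 3, 3, 4, 4, 1], dtype=np.int64)
Q_EXP = np.array([1, 1, 1, 1, 0, 0, 0], dtype=np.int64)

TAU_SIGMOID = 0
TAU_BIEXP = 1
TAU_PRODUCT = 2


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _tau_eval(row, V):
    form = row[0]
    if form == 0.0:
        return row[1] + row[2] / (1.0 + np.exp((V - row[3]) / row[4]))
    elif form == 1.0:
        return row[1] + row[2] / (
            np.exp((V - row[3]) / row[4]) + np.exp((V - row[5]) / row[6])
        )
    else:
        return (row[1] / (1.0 + np.exp((V - row[3]) / row[4]))) * (
            row[7] + 1.0 / (1.0 + np.exp((V - row[5]) / row[6]))
        )


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _ipow(x, n):
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=True, fastmath=True, error_model="numpy")
def currents_kernel(y, out, g, p, q, erev, isca, C, Ca_out, npref):
    """Per-channel membrane currents (nA) for state ``y`` into ``out`` (8,)."""
    V = y[0]
    Ca = y[12]
    if Ca < 1e-12:
        Ca = 1e-12
    ECa = npref * np.log(Ca_out / Ca)
    k = 1
    for i in range(7):
        m = y[k]
        k += 1
        gate = _ipow(m, p[i])
        if q[i] == 1:
            gate *= y[k]
            k += 1
        E = ECa if isca[i] else erev[i]
        out[i] = g[i] * gate * (V - E)
    out[7] = g[7] * (V - erev[7])
    return out


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def deriv_kernel(y, dy, Ie, g, p, q, erev, isca,
                 minf_t, hinf_t, taum_t, tauh_t,
                 C, tau_ca, Ca0, CaF, Ca_out, npref):
    """Time derivatives of the 13 state variables into ``dy``."""
    V = y[0]
    Ca = y[12]
    Ca_safe = Ca if Ca > 1e-12 else 1e-12
    ECa = npref * np.log(Ca_out / Ca_safe)
    Isum = 0.0
    ICa = 0.0
    k = 1
    for i in range(7):
        m = y[k]
        minf = 1.0 / (1.0 + np.exp((V - minf_t[i, 0]) / minf_t[i, 1]))
        if minf_t[i, 2] > 0.0:
            minf *= Ca_safe / (Ca_safe + minf_t[i, 2])
        dy[k] = (minf - m) / _tau_eval(taum_t[i], V)
        k += 1
        gate = _ipow(m, p[i])
        if q[i] == 1:
            h = y[k]
            hinf = 1.0 / (1.0 + np.exp((V - hinf_t[i, 0]) / hinf_t[i, 1]))
            dy[k] = (hinf - h) / _tau_eval(tauh_t[i], V)
            k += 1
            gate *= h
        E = ECa if isca[i] else erev[i]
        I = g[i] * gate * (V - E)
        if isca[i]:
            ICa += I
        Isum += I
    Isum += g[7] * (V - erev[7])
    dy[0] = (Ie - Isum) / C
    dy[12] = (-CaF * ICa - Ca + Ca0) / tau_ca
    return dy


# ---------------------------------------------------------------------------
# lookup-table gating evaluation for the integrator hot loop
#
# The 18 voltage-dependent gating functions (7 m_inf sigmoids, 4 h_inf
# sigmoids, 7 tau_m, 4 tau_h) are tabulated once per kinetics table on a
# dense V grid and evaluated by linear interpolation inside the RK4 loop.
# Row layout of ``lut``: 0-6 m_inf, 7-10 h_inf (Na, CaT, CaS, A),
# 11-17 tau_m, 18-21 tau_h.  ``ca_half`` carries the calcium-saturation
# constant per channel (0 = no calcium dependence).
# ---------------------------------------------------------------------------

#: index bookkeeping for the LUT rows
_LUT_HROW = np.array([7, 8, 9, 10, -1, -1, -1], dtype=np.int64)
_LUT_THROW = np.array([18, 19, 20, 21, -1, -1, -1], dtype=np.int64)


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _lut_at(lut, row, pos, frac):
    a = lut[row, pos]
    return a + (lut[row, pos + 1] - a) * frac


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def deriv_lut_kernel(y, dy, Ie, g, p, q, erev, isca, ca_half,
                     lut, v_lo, inv_h, n_grid,
                     C, tau_ca, Ca0, CaF, Ca_out, npref):
    """Time derivatives with LUT gating functions (integrator hot path)."""
    V = y[0]
    Ca = y[12]
    Ca_safe = Ca if Ca > 1e-12 else 1e-12
    ECa = npref * np.log(Ca_out / Ca_safe)
    u = (V - v_lo) * inv_h
    if u < 0.0:
        u = 0.0
    elif u > n_grid - 2:
        u = float(n_grid - 2)
    pos = int(u)
    frac = u - pos
    Isum = 0.0
    ICa = 0.0
    k = 1
    for i in range(7):
        m = y[k]
        minf = _lut_at(lut, i, pos, frac)
        if ca_half[i] > 0.0:
            minf *= Ca_safe / (Ca_safe + ca_half[i])
        dy[k] = (minf - m) / _lut_at(lut, 11 + i, pos, frac)
        k += 1
        gate = _ipow(m, p[i])
        if q[i] == 1:
            h = y[k]
            hinf = _lut_at(lut, _LUT_HROW[i], pos, frac)
            dy[k] = (hinf - h) / _lut_at(lut, _LUT_THROW[i], pos, frac)
            k += 1
            gate *= h
        E = ECa if isca[i] else erev[i]
        I = g[i] * gate * (V - E)
        if isca[i]:
            ICa += I
        Isum += I
    Isum += g[7] * (V - erev[7])
    dy[0] = (Ie - Isum) / C
    dy[12] = (-CaF * ICa - Ca + Ca0) / tau_ca
    return dy


@njit(cache=True, error_model="numpy")
def integrate_kernel(y0, dt, n_steps, keep_from, Ie_arr, record_currents,
                     g, p, q, erev, isca, ca_half, lut, v_lo, inv_h, n_grid,
                     C, tau_ca, Ca0, CaF, Ca_out, npref):
    """Fixed-step RK4 integration.

    Returns ``(status, fail_step, V, Ca, I, y_final)`` where status 0 is
    success and 1 flags a non-finite state first seen at ``fail_step``.
    Samples are recorded at times ``n*dt`` for ``n >= keep_from`` (the state
    *before* the step at n), so the first retained sample sits exactly at the
    end of the transient.
    """
    n_keep = n_steps - keep_from
    V_out = np.empty(n_keep)
    Ca_rec = np.empty(n_keep)
    n_i = n_keep if record_currents else 0
    I_out = np.empty((8, n_i))
    Ibuf = np.empty(8)

    y = y0.copy()
    k1 = np.empty(13)
    k2 = np.empty(13)
    k3 = np.empty(13)
    k4 = np.empty(13)
    yt = np.empty(13)

    status = 0
    fail_step = -1
    idx = 0
    scalar_ie = Ie_arr.size == 1
    for n in range(n_steps):
        Ie = Ie_arr[0] if scalar_ie else Ie_arr[n]
        if n >= keep_from:
            V_out[idx] = y[0]
            Ca_rec[idx] = y[12]
            if record_currents:
                currents_kernel(y, Ibuf, g, p, q, erev, isca, C, Ca_out, npref)
                for c in range(8):
                    I_out[c, idx] = Ibuf[c]
            idx += 1
        deriv_lut_kernel(y, k1, Ie, g, p, q, erev, isca, ca_half,
                         lut, v_lo, inv_h, n_grid,
                         C, tau_ca, Ca0, CaF, Ca_out, npref)
        for j in range(13):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        deriv_lut_kernel(yt, k2, Ie, g, p, q, erev, isca, ca_half,
                         lut, v_lo, inv_h, n_grid,
                         C, tau_ca, Ca0, CaF, Ca_out, npref)
        for j in range(13):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        deriv_lut_kernel(yt, k3, Ie, g, p, q, erev, isca, ca_half,
                         lut, v_lo, inv_h, n_grid,
                         C, tau_ca, Ca0, CaF, Ca_out, npref)
        for j in range(13):
            yt[j] = y[j] + dt * k3[j]
        deriv_lut_kernel(yt, k4, Ie, g, p, q, erev, isca, ca_half,
                         lut, v_lo, inv_h, n_grid,
                         C, tau_ca, Ca0, CaF, Ca_out, npref)
        for j in range(13):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        # gates are confined to [0,1]; RK4 can overshoot by O(dt^5) rounding
        for j in range(1, 12):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if not (np.isfinite(y[0]) and np.isfinite(y[12])):
            status = 1
            fail_step = n
            break
    if status == 1:
        V_out = V_out[:idx]
        Ca_rec = Ca_rec[:idx]
        if record_currents:
            I_out = I_out[:, :idx]
    return status, fail_step, V_out, Ca_rec, I_out, y
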