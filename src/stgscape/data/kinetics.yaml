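# Voltage-(and calcium-)dependent gating kinetics for the seven gated channels
# of the single-compartment STG neuron model (Liu/Prinz lineage).
#
# Conventions (units mV, ms, uM):
#   steady states     x_inf(V) = 1 / (1 + exp((V - v_half) / slope))
#   KCa additionally multiplies m_inf by Ca / (Ca + ca_half).
#   time constants, by `form`:
#     sigmoid  tau(V) = c0 + c1 / (1 + exp((V - v1) / k1))
#     biexp    tau(V) = c0 + c1 / (exp((V - v1) / k1) + exp((V - v2) / k2))
#     product  tau(V) = (c0 / (1 + exp((V - v1) / k1))) * (c3 + 1 / (1 + exp((V - v2) / k2)))
#   reversal: a fixed potential in mV, or "nernst-calcium" for the dynamically
#   computed calcium reversal.
channels:
  - name: Na
    p: 3
    q: 1
    reversal: 30.0
    m_inf: {v_half: -25.5, slope: -5.29}
    h_inf: {v_half: -48.9, slope: 5.18}
    tau_m: {form: sigmoid, c0: 1.32, c1: -1.26, v1: -120.0, k1: -25.0}
    tau_h: {form: product, c0: 0.67, v1: -62.9, k1: -10.0, c3: 1.5, v2: -34.9, k2: 3.6}
  - name: CaT
    p: 3
    q: 1
    reversal: nernst-calcium
    m_inf: {v_half: -27.1, slope: -7.2}
    h_inf: {v_half: -32.1, slope: 5.5}
    tau_m: {form: sigmoid, c0: 21.7, c1: -21.3, v1: -68.1, k1: -20.5}
    tau_h: {form: sigmoid, c0: 105.0, c1: -89.8, v1: -55.0, k1: -16.9}
  - name: CaS
    p: 3
    q: 1
    reversal: nernst-calcium
    m_inf: {v_half: -33.0, slope: -8.1}
    h_inf: {v_half: -60.0, slope: 6.2}
    tau_m: {form: biexp, c0: 1.4, c1: 7.0, v1: -27.0, k1: 10.0, v2: -70.0, k2: -13.0}
    tau_h: {form: biexp, c0: 60.0, c1: 150.0, v1: -55.0, k1: 9.0, v2: -65.0, k2: -16.0}
  - name: A
    p: 3
    q: 1
    reversal: -80.0
    m_inf: {v_half: -27.2, slope: -8.7}
    h_inf: {v_half: -56.9, slope: 4.9}
    tau_m: {form: sigmoid, c0: 11.6, c1: -10.4, v1: -32.9, k1: -15.2}
    tau_h: {form: sigmoid, c0: 38.6, c1: -29.2, v1: -38.9, k1: -26.5}
  - name: KCa
    p: 4
    q: 0
    reversal: -80.0
    m_inf: {v_half: -28.3, slope: -12.6, ca_half: 3.0}
    tau_m: {form: sigmoid, c0: 90.3, c1: -75.1, v1: -46.0, k1: -22.7}
  - name: Kd
    p: 4
    q: 0
    reversal: -80.0
    m_inf: {v_half: -12.3, slope: -11.8}
    tau_m: {form: sigmoid, c0: 7.2, c1: -6.4, v1: -28.3, k1: -19.2}
  - name: H
    p: 1
    q: 0
    reversal: -20.0
    m_inf: {v_half: -75.0, slope: 5.5}
    tau_m: {form: biexp, c0: 0.0, c1: 1.0, v1: -169.7, k1: -11.6, v2: 26.7, k2: 14.3}
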