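# stgscape

Conductance-based models of bursting neurons produce more data than a
voltage trace can show: eight ionic currents spanning orders of magnitude
interact to shape every spike, and cells with very different maximal
conductances ("degenerate" solutions) can produce nearly identical
activity while responding very differently to perturbations.  `stgscape`
is a toolbox for building and dissecting such models, aimed at
computational neuroscientists studying the crustacean stomatogastric
ganglion (STG) and, more generally, anyone exploring degeneracy in
Hodgkin–Huxley-type models.  It provides:

* a fast single-compartment simulator with eight currents
  (Na, CaT, CaS, A, KCa, Kd, H, leak), first-order gating kinetics,
  intracellular calcium dynamics with a dynamic Nernst reversal, and
  fixed-step RK4 integration;
* threshold (Poincaré-section) trace metrics: spike detection, burst
  segmentation, burst frequency f_b, duty cycle d_c, slow-wave crossing
  counts, ISI multisets, and a stationarity (stability) test;
* landscape (objective) functions whose minima are bursting or tonic
  target activities, and a seedable genetic algorithm to minimize them
  over the 9-dimensional conductance search box;
* **currentscapes** — stacked-area images of each current's percent share
  of the total inward/outward current at every time step, flanked by
  log-scale total-current envelopes;
* probability-distribution "ridge maps" of the membrane-potential
  waveform and of the current shares under graded conductance decrements,
  and injected-current ISI bifurcation scans.

## The model and its score

The membrane potential obeys

```
C dV/dt = Ie − Σᵢ Iᵢ,     Iᵢ = gᵢ m^pᵢ h^qᵢ (V − Eᵢ),
τₘ(V) dm/dt = m∞(V) − m,  τₕ(V) dh/dt = h∞(V) − h,
τ_Ca d[Ca]/dt = −F(I_CaT + I_CaS) − [Ca] + Ca₀,
```

with C = 10 nF, F = 0.94 µM/nA, Ca₀ = 0.05 µM and E_Ca from the Nernst
equation against 3 mM extracellular calcium.  Units are mV, ms, nA, µS,
nF, µM throughout.  The kinetics ship as an editable YAML table
(`stgscape/data/kinetics.yaml`, Liu et al. 1998 lineage); eight published
parameter sets (the model cells `a`–`f`, `fig2`, `fig3`) ship as a CSV
fixture.

A simulated trace is scored against a bursting target by

```
E(g) = α·(f_tg − ⟨f_b⟩)² + β·(dc_tg − ⟨d_c⟩)² + γ·(#sw/2 − #b)²
```

with (α, β, γ) = (1, 100, 1), f_tg = 1 Hz, dc_tg = 0.2; the last term
counts downward crossings of a ±1 mV pair of slow-wave thresholds around
−50 mV against the number of bursts, penalizing solutions whose spiking
is not cleanly separated from the slow wave.  Unstable solutions (burst
frequency spread ≥ 10% or duty-cycle spread ≥ 20% of the mean) are
discarded with a fixed penalty score.

## Worked example

Score two of the packaged model cells under the standard protocol
(20 s simulated at dt = 0.1 ms, first 10 s dropped):

```console
$ stgscape score --model-label c
model c: E(g) = 0.0658901  (Ef=0.038834, Edc=0.000270561, Esw=0, stable=True)
$ stgscape score --model-label a
model a: E(g) = 0.144131  (Ef=0.00190283, Edc=0.00142228, Esw=0, stable=True)
```

Model (c) bursts at ⟨f_b⟩ ≈ 0.80 Hz (Ef = (1 − ⟨f_b⟩)² ≈ 0.039) with a
duty cycle within 2 points of 20% (Edc ≈ 0.0003 → ⟨d_c⟩ ≈ 0.183), and
its slow wave never crosses the
−50 ± 1 mV thresholds out of register with its bursts (Esw = 0): a clean,
stable burster with a total score dominated by the small frequency
mismatch.

The same library calls are available programmatically:

```python
from stgscape import load_parameter_table, integrate
from stgscape.currentscape import compute_currentscape, render_currentscape

params = load_parameter_table()["fig2"]
trace = integrate(params, duration=13_000, transient=10_000, dt=0.1)
cs = compute_currentscape(trace.I)          # 8 x N currents -> R x N image
render_currentscape(cs, "currentscape.png", V=trace.V, time=trace.time)
```

Other entry points: `stgscape simulate | evolve | currentscape |
vdist-sweep | share-sweep | isi-scan | decrement | delete` (every run
writes a JSON manifest with all resolved settings).

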