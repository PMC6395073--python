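# Methods

## Model

A single compartment with membrane capacitance C = 10 nF carries eight
currents — fast sodium (Na), transient and slow calcium (CaT, CaS), the
transient potassium A-current, calcium-dependent potassium (KCa), delayed
rectifier (Kd), hyperpolarization-activated inward (H), and an ohmic
leak.  Each gated current is I = g·m^p·h^q·(V − E) with integer gate
exponents p ∈ {1, 3, 4}, q ∈ {0, 1}; activation and inactivation
variables relax first-order toward voltage-dependent steady states with
voltage-dependent time constants.  The KCa activation is additionally
saturated by intracellular calcium through a factor Ca/(Ca + 3 µM).
Intracellular calcium integrates the two calcium currents,

    τ_Ca d[Ca]/dt = −0.94 µM/nA · (I_CaT + I_CaS) − [Ca] + 0.05 µM,

and the calcium reversal follows the Nernst relation
E_Ca = (RT/zF)·ln(Ca_out/Ca_in) with Ca_out = 3×10³ µM and
RT/zF = 12.2 mV by default (divalent ion near 10 °C; exposed as
`nernst_prefactor` since small changes measurably shift burst frequency
and duty cycle).  The remaining reversals are fixed: E_Na = 30,
E_K = −80, E_H = −20, E_leak = −50 mV.  The state is 13-dimensional
(V, 11 gates, Ca).  Units are mV, ms, nA, µS, nF, µM; this system is
closed under the membrane equation (nF·mV/ms = nA = µS·mV).

Inside the integrator the 18 voltage-dependent gating functions
(steady states and time constants) are evaluated from a dense lookup
table — tabulated once per kinetics configuration on a 0.01 mV grid over
[−120, 70] mV and linearly interpolated.  At this spacing the
interpolation error is below 10⁻⁶ for every function in the table, far
beneath the O(dt⁴) integration error; it buys a ~3× simulation speedup
and leaves every objective score reported here unchanged to four
decimals.  The exact closed forms remain available through
`gate_steady_state` and `derivatives`, and membrane currents are always
computed from the exact current law.

All integrations use fixed-step 4th-order Runge–Kutta, dt = 0.1 ms by
default, starting from the fixed initial condition V = −51 mV, all gates
0 (inactivation gates begin fully inactivated, taken literally), and
Ca = 5 µM.  Gates are clipped to [0, 1] after each full step; the clip
corrects only the O(dt⁵)-scale overshoot RK4 can produce at gate rails
and does not otherwise alter trajectories.  A non-finite state aborts
with an error naming the failing step; nothing is silently repaired.

## Channel kinetics and their provenance

The gating functions ship as an editable YAML table
(`stgscape/data/kinetics.yaml`) in the Liu et al. (1998) /
Prinz et al. (2003) lineage of cultured-STG-neuron kinetics.  Two
printed variants of this table exist in the literature, differing by a
factor of two in the time constants (Prinz et al. 2003 doubled the
Liu et al. 1998 values).  We validated the alternatives against the
published bursting behavior of the packaged parameter sets: with the
sodium time constants as printed in the half-scale variant
(τ_m = 1.32 − 1.26·σ ms, τ_h prefactor 0.67 ms) and all other channels'
time constants at the half (Liu-original) scale, every packaged model
cell bursts at ~0.8–1.1 Hz with duty cycles of 15–22% and membrane
potential confined to roughly (−52, 20) mV, matching the regime the
parameter sets were selected for; the doubled table slows all rhythms by
a factor of ~2 and the mixed table collapses bursts to 2–3 spikes.  The
shipped table is therefore the half-scale variant.  Residual
transcription uncertainty remains and bounds the quantitative agreement
of trace-level statistics (see Limitations).

## Trace metrics

Spikes are upward crossings of −20 mV (sample n is a crossing when
V_n ≤ T < V_{n+1}; a sample exactly on the threshold counts as "below",
the only tie-break the rule needs).  Spikes strictly closer than
δ = 100 ms share a burst.  A burst from spike s_i to s_k has duration
δ_b = s_k − s_i, period τ_b = δ_b + (s_{k+1} − s_k), frequency
f_b = 1/τ_b and duty cycle d_c = δ_b/τ_b; an isolated spike is a
zero-duration burst.

Finite windows need boundary rules.  A burst is **counted** (enters #b)
only when its end is certified by a ≥ δ spike-free interval, observed
either before the next spike or against the window edge; a burst still
in progress when the window closes is not counted — it has not yet
produced its slow-wave descent, which keeps #b in register with the
slow-wave crossing count (#sw, downward crossings summed over the
−49/−51 mV threshold pair) rather than off by one at arbitrary window
phases.  A burst contributes an (f_b, d_c) **sample** only when its
start is also certified (the first observed spike qualifies only when
the window provides δ of spike-free lead-in) and a following spike
exists to measure τ_b against.

A solution is discarded as unstable when std{f_b} ≥ 0.1·⟨f_b⟩ or
std{d_c} ≥ 0.2·⟨d_c⟩ — except that zero spread is stationary by
definition (otherwise every perfectly periodic tonic spiker, with
mean = std = 0 duty cycle, would be discarded).

Distinct ISI counting uses single-linkage clustering with a 2% relative
tolerance: wide enough to absorb discretization jitter at dt = 0.1 ms,
far narrower than the gaps between genuinely different ISI values
(doublet/quadruplet ISIs differ by tens of percent).

## Landscape functions

Burster target: E(g) = α·E_f + β·E_dc + γ·E_sw with
E_f = (f_tg − ⟨f_b⟩)², E_dc = (dc_tg − ⟨d_c⟩)², E_sw = (#sw/2 − #b)²,
weights (1, 100, 1), targets 1 Hz and 0.2, evaluated on 20 s of
simulation at dt = 0.1 ms with the first 10 s dropped.  Tonic target:
E(g) = α·E_f + β·E_dc + γ·E_mid + δ·E_sw + η·E_lag with weights
(1000, 1000, 100, 100, 1); E_mid sums squared deviations of the
downward-crossing counts at three mid thresholds (−35, −40, −45 mV —
the count of thresholds is a package choice, the band is fixed) from the
spike count, E_sw = (#sw)² (a tonic solution must never cross the
slow-wave thresholds), and E_lag is the mean lag from each spike's
upstroke through −20 mV to the next downstroke through −35 mV, with
unpaired spikes contributing the mean ISI as a cap (the aggregate is a
package choice; only the lag concept is fixed).

Discarded candidates — integration failure, fewer than 3 spikes, no
measurable burst, instability — score a fixed penalty of 10⁶: finite,
so an optimizer can rank failures below any behaving solution, and far
above any attainable score of a behaving one.  For optimization, an
optional 4 s probe (2 s transient) rejects diverging and silent
candidates before the full protocol is paid for; candidates that pass
are re-simulated from the standard initial condition, so the probe
affects cost, not scores of behaving solutions.

## Genetic algorithm

Real-coded and fully seeded.  Initialization uniform in the
search box (g_Na, g_KCa ∈ [0, 2×10³] µS; g_CaT, g_CaS, g_A, g_Kd,
g_H ∈ [0, 2×10²]; g_leak ∈ [0, 20]; τ_Ca ∈ [0, 10³] ms).  Parent
selection is linear ranking with the "elitism" parameter as the ratio of
the best rank's breeding weight to the population mean (1.0 = uniform;
production default 1.2, the validity range of linear ranking is [1, 2]).
Crossover is uniform per-gene with probability 0.5; mutation resamples a
gene uniformly in its bounds with probability 0.05.  Survivor selection
is elitist (mu+lambda): each generation's offspring compete with their
parents and the best individuals survive, so the best-so-far history is
non-increasing and the best-ever individual is always retained.
Scores are memoized by candidate bytes, and parallel evaluation
(joblib) attaches scores by candidate identity, so
results are independent of worker count.  τ_Ca = 0 sits on the box edge
and is degenerate (division by the buffering time constant); candidate
evaluation floors it at 10⁻⁶ ms.

## Currentscapes

At each time stamp the eight currents are split by sign; each sign's
magnitudes are normalized by their sum (n⁺, n⁻), giving share columns
that sum to 1 where any current of that sign flows.  Shares map to an
R-row image (R = 2000) by stacking bands in the fixed channel order
(Na, CaT, CaS, A, KCa, Kd, H, leak): band boundaries sit at the floor of
the cumulative share·R, and the final band absorbs the rounding
remainder so unit-sum columns fill exactly R pixels (each band within
±1 pixel of its exact share).  Columns with zero total current of a sign
are flagged and render as gaps.  The rendered figure stacks V (optional),
the total outward current on a log scale, the outward and inward share
images, and the total inward current on an inverted log scale, with
dotted reference lines at 5, 50 and 500 nA.

## Waveform distributions and ridge maps

The retained solution is treated as a stochastic variable: V is
histogrammed into 1001 bins over (−70, 35) mV (current shares over
[0, 1]) from 2×10⁶ random time stamps drawn uniformly with replacement
(seeded; using all samples instead is an option and differs only by
sampling noise).  Bins are half-open with the last bin closed;
out-of-range values clip into the edge bins with a warning.  Decrement
sweeps scale one conductance over levels descending 1 → 0 (row 0 =
control) and stack one histogram row per level; ridge enhancement is the
central-difference derivative of log₁₀(counts + 1) along the V axis,
which turns each probability peak (a waveform extremum) into a paired
+/− ridge.

Two simulation profiles exist for distribution runs.  The *desk* profile
(default) uses dt = 0.01 ms with a 20 s transient and 30 s retained
window — chosen so a full sweep is workable on a single desktop core
while the histograms are visually and statistically indistinguishable
from finer-step runs for this system.  The *paper-exact* profile
(dt = 0.001 ms, 120 s transient) is available through the CLI
`--profile` flag for users who want the high-resolution protocol.
Injected-current scans similarly default to 20 s per level with 10 s
dropped, with a long profile (580 s / 240 s) available.

## Perturbation drivers

Decrement sweeps, deletions (the level-0 special case) and
injected-current scans all restart every level from the fixed standard
initial condition rather than continuing from the previous level's final
state.  The model can be multistable, and fresh starts make each level's
result a well-defined function of its parameters, avoiding
hysteresis-dependent sweep artifacts; the cost is that a sweep does not
track a solution branch through a fold.

## Degenerate inputs and edge cases

Fewer than 3 spikes → statistics flagged unstable with zero bursts, not
an exception.  Empty ISI sets (silent levels) are flagged, not fatal.
Integration failure inside a sweep flags the level and continues.
Zero-total currentscape columns are flagged empty.  Calcium is floored
at 10⁻¹² µM inside the Nernst logarithm only.

## Limitations

* Quantitative trace-level agreement with published values for the
  packaged parameter sets is bounded by the kinetics-transcription
  uncertainty described above.  In the shipped table the model cells
  reproduce the intended regime (stable ~1 Hz bursters, duty cycle
  ~0.15–0.22, clean slow-wave separation), but e.g. the `fig3` cell
  fires 11 spikes per burst where 12 is the published figure, the
  model-`a` interburst interval is ~870 ms rather than ~640 ms, and
  decrement-transition points shift by tens of percent of the
  conductance scale.
* Single compartment only; no channel noise, no temperature dependence,
  no multi-compartment or network extensions.
* Fixed-step explicit integration: no stiffness control — pathological
  parameter corners fail fast (and are scored as failures) rather than
  being integrated adaptively.
* The GA is a means of producing solution pools, not a benchmark-grade
  optimizer; with the production selection pressure (elitism 1.2) it
  trades convergence speed for diversity of the solution pool.
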