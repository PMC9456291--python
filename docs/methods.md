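# Methods

## The gating model

KCNQ1 gating is described by a continuous-time Markov scheme with a
column-stochastic generator Q(V, Ca): occupancies evolve as dp/dt = Q p,
propagated segment-by-segment with the matrix exponential (ramps are
sub-stepped at ≤ 0.1 ms using the midpoint voltage).  Rates follow a
single-exponential voltage dependence k(V) = k₀·exp(zFV/RT) at 294.15 K
(21 °C, matching the chelator calculations).

The normal (Ca²⁺-sufficient) layer is a five-state scheme with two
sequentially activated voltage-sensor states, both of which can open:

```
RC ⇌ IC ⇌ AC        voltage-sensor steps (resting/intermediate/activated)
      |    |
      IO   AO        open states; IO ⇌ AO mirrors the second sensor step
```

The conducting weights are w_AO = 1 and w_IO ≈ 0.24 (calibrated); the
IO ⇌ AO rates are tied to the IC ⇌ AC step so the IC–AC–AO–IO cycle obeys
detailed balance.

The starved layer RC\*, IC\*, AC\* holds channels whose calmodulin lacks
Ca²⁺.  Starred states are non-conducting, their own activation is shallowly
voltage dependent, and the IC\* → AC\* rate is small, so depolarizations at
low Ca²⁺ accumulate channels in IC\* ("inactivated" intermediate state)
with only a limited exit towards the activated end.  Vertical transitions
X ⇌ X\* carry the Ca²⁺ dependence: entry scales with 1 − f(Ca) and exit
with f(Ca), where f is a Hill function of the free intracellular Ca²⁺
(defaults Kd = 250 nM, n = 1.3; see *Calibration*).  Two transitions of the
normal layer are additionally Ca²⁺-facilitated with a floor,
k·(floor + (1 − floor)·f): the intermediate-state opening IC → IO
(floor ≈ 0.55; the "partial block" of this pathway at low Ca²⁺) and the
sensor step IC → AC (floor = 0.16; Ca²⁺-CaM facilitates the transition to
the fully activated sensor position).  Disease variants are modelled with
the sensor pinned to f ≡ 1 (starved layer unreachable, block lifted);
V185M additionally has activation slowed (×0.7) and deactivation sped
(×2.38, solved), which right-shifts its isochronal GV to −29.0 mV.  R116L
and P369L default to WT rates; their specific kinetic nuances are exposed
through the per-variant configuration but not calibrated.

Simulations start from the algebraic stationary state at the holding
potential (−80 mV; not stated in the source experiments, typical for
KCNQ1 work) and either carry occupancy through the inter-sweep holding
interval (protocol simulations) or restart each sweep from the holding
steady state at the sweep's Ca²⁺ (quasi-static recording generation; the
Ca²⁺ wash-in time constant of 60 s is ~40× a sweep).

## Calibration

The concrete rate constants of the source model are not published in
machine-readable form, so the default set is calibrated in-repo
(`analysis/02_calibrate_gating.py`, deterministic staged solves) against
the printed anchors: WT isochronal V₀.₅ −33.2 mV (early recording) and
−39.6 mV (saturating Ca²⁺-CaM), V185M −29.0 mV, cross-over minimum at a P1
potential of −30 mV, HVA slope factor 25 mV, and the 4-min run-down/run-up
levels 62.7%, 79.6% and 112%.  Structural choices made once and frozen:
sensor-step midpoints near −33/−26 mV with charges 2.8/3.0 (forward rate
of the second step voltage-independent, its charge on the backward rate);
a starved-trap entry rate of 8×10⁻⁴ ms⁻¹ which places the cross-over
minimum; and a small open-state equilibrium (L₂ = 1/3) so the GV position
is governed by the IO pathway.

Two deliberate deviations from round-number defaults deserve note:

* **Ca²⁺ sensor.** A Hill curve with Kd = 100 nM, n = 2 puts the resting
  Ca²⁺ (100 nM) exactly at half-saturation, which makes the observed mild
  run-down between 100 nM and 20 nM (37.3%) incompatible with the strong
  run-up between 100 nM and 5 µM (112%) for any monotone gain.  The
  shipped defaults (Kd = 250 nM, n = 1.3) place resting Ca²⁺ on the lower
  limb with most of the dynamic range above it, which reconciles all
  printed amplitude anchors simultaneously.  Both parameters are plain
  configuration values.
* **Slope factors.** With the midpoints pinned by the cross-over position,
  the isochronal GV slope comes out shallower (k ≈ 11.9 mV saturated,
  ≈ 15 mV early) than the printed 6.6/9.2 mV.  The model prioritizes the
  V₀.₅ anchors, the cross-over phenomenology and the HVA slope, which are
  not jointly satisfiable with the steep main-component slopes in this
  scheme topology; treat absolute slope factors of the main component as a
  known limitation.

## Synthetic recordings

A recording is the product of three factors, per sweep:

1. the Markov current I = g_max·Σ wᵢpᵢ·(V − E_K) simulated at the sweep's
   effective Ca²⁺ (E_K = −86 mV from the solution compositions; g_max
   default 20 nS, lognormal across cohort cells, σ = 0.5);
2. an exponential **wash-out factor** p + (1 − p)e^(−t/90 s) representing
   loss of cytosolic cofactors distinct from the Ca²⁺ axis; the plateau p
   is condition-specific and solved in closed form so the run-down metric
   recovers the printed 4-min anchors exactly (0.80 standard, 0.89 +CaM,
   0.85 high-Ca²⁺, 1.0 for pre-incubated conditions);
3. for KCNE2 co-expression, a near-linear **leak conductance** with a
   single-exponential sag at positive potentials (15%, τ = 200 ms), whose
   availability tracks Ca²⁺-CaM through a separate high-demand sensor
   (Kd = 5 µM): KCNE2 raises the Ca²⁺-CaM requirement for opening, which
   is why WT Q1E2 is small at rest and rises dramatically only with CaM
   overexpression plus Ca²⁺ loading, while the disease variants are
   constitutively available (P369L fully Ca²⁺-insensitive).

Intracellular Ca²⁺ relaxes exponentially from a pre-incubation-determined
initial level (none: 100 nM, EGTA-Ringer: 30 nM, BAPTA-AM: 5 nM) to the
pipette free Ca²⁺ with τ_wash = 60 s (150 s after BAPTA loading, whose
cytosolic buffer delays the wash-in); these are assumptions exposed in
`data/condition_table.json`.  CaM overexpression is modelled as a tenfold
gain on the Ca²⁺ seen by the sensor.  Pre-incubated cells start their
first sweep from the model steady state at an unpatched resting potential
of −18 mV (CHO cells are poorly polarized), which places low-Ca²⁺ cells in
the starved/trapped states and reproduces the small initial currents and
the ≥2-fold run-up upon Ca²⁺ loading.  Gaussian noise (default 5 pA at
1 kHz sampling, motivated by the 3 kHz recording filter) is added from a
seeded NumPy PCG64 generator; identical seeds give bit-identical
recordings, and cohort seeds derive from a SeedSequence spawn.

What the generator does *not* emulate: series-resistance and capacitive
artifacts (compensated in the experiments), endogenous GH₃/B₆ Na⁺/BK/SK
currents (a voltage-independent leak stands in), KCNE1/KCNE3 heteromers,
stochastic single-channel gating, and any PIP₂ dynamics (a PIP₂ add-back
flag exists and deliberately has no effect, matching its experimental
impotence against early run-down).  Passing tests therefore demonstrate
internal consistency of model + pipeline under these idealized conditions,
not fidelity to raw recordings.

## Trace analysis

The instantaneous P2 amplitude is the mean current 2–7 ms after P2 onset
(the source does not state its window; this skips residual capacitive
settle), the late-P2 amplitude the mean over the final 50 ms of the 1-s P2,
and run-down amplitudes the final 50 ms of the 500-ms test pulse,
normalized to sweep 1.  GV curves are normalized per recording to their
maximum.  Boltzmann and biexponential fits are lmfit least squares from
fixed, documented multi-start grids (no randomness; noiseless recovery to
≤10⁻⁴ relative is tested).  Double-Boltzmann components are ordered by
V₀.₅ with the HVA slope bounded to (5, 60) mV against component collapse.
Model order is chosen by the extra-sum-of-squares F-test (α = 0.05) with
two guards: a single fit with RMS residual ≤ 1.5% of the normalized
amplitude is accepted outright ("adequately described"), and a double fit
must give the HVA component ≥ 5% of the total amplitude.  The cross-over
detector reports an interior minimum of the late-P2 profile that is lower
than both neighbours by > 2% of the profile range.

## Solution chemistry

Free Ca²⁺/Mg²⁺ are solved from stepwise proton and metal association
constants for EGTA and ATP (`data/chelator_constants.json`, NIST-style
critical values adjusted to ionic strength 0.15 M — the calculators the
recipes were designed with do not state their assumed ionic strength —
with van't Hoff enthalpy corrections to the working temperature).  The
solver is a damped fixed point on (free Ca, free Mg) with a bisection
fallback, to 10⁻¹² relative.  The shipped recipes give 15.9 nM and 4.2 µM
free Ca²⁺ at 21 °C — within the constants-set spread of the nominal
~20 nM and 5 µM.  HEPES and glucose are treated as non-chelating;
aspartate as a non-chelating monovalent anion that only contributes its
limiting conductivity (30.7 S cm²/eq) to the Henderson junction potential,
which evaluates to −12.8 mV for the pipette interior relative to the
Ringer bath (reported ≈ −13 mV); command voltages are assumed already
LJP-corrected.

## Statistics

Group comparisons follow the published decision tree: Shapiro–Wilk on
every group at α = 0.05 gates parametric (t-test; one-way ANOVA with
Bonferroni-corrected pairwise t-tests) versus rank-based tests
(Mann–Whitney; Kruskal–Wallis with Dunn's test, tie-corrected).  The full
procedure's type-I error under a Gaussian null is verified ≤ 0.07 by
simulation.  Statistics are reported with the conventional star levels.

## Numerical choices and problem sizes

Matrix exponentials use scipy's `expm`; steady states solve the bordered
linear system [Q; 1ᵀ]p = e with residual tolerance 10⁻¹⁰; output
occupancies are clipped/renormalized at the 10⁻⁹ level.  Default output
sampling is 1 ms.  The reproduction targets run 17-sweep IV families and
60-sweep (5-min) run-down recordings — the full set completes in a few
seconds on one core, and the test suite (including the Monte-Carlo
operating-characteristics checks at 40–2000 replicates) in well under a
minute.
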