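# kcnq1ca

Disease-causing KCNQ1 variants (R116L, V185M, P369L) cause a
gain-of-function of heteromeric KCNQ1-KCNE2 channels that has been traced
to an impaired Ca²⁺ sensitivity of the KCNQ1 channel itself.  This package
implements the computational core of that analysis for people studying
KCNQ1/Kv7.1 gating and Ca²⁺-calmodulin regulation:

* an **eight-state Markov gating model** of KCNQ1 — the five-state scheme
  RC ⇌ IC ⇌ AC (two sequentially activated voltage-sensor states) with the
  two open states IO and AO, extended by a Ca²⁺-CaM-starved closed layer
  RC\*, IC\*, AC\* that traps channels in a non-conducting intermediate
  ("inactivated" IC\*) state when calcified calmodulin is scarce;
* a **synthetic whole-cell recording generator** emulating CHO-cell
  patch-clamp experiments: channel variant, optional KCNE2 co-expression
  and calmodulin overexpression, pipette solutions buffered to ~20 nM or
  5 µM free Ca²⁺, pre-incubation in EGTA-Ringer or BAPTA-AM loading,
  wash-in/run-down dynamics and recording noise;
* the **trace analysis** behind the numbers: isochronal conductance–voltage
  (GV) relations from instantaneous P2 tail currents fitted with
  `y = c + d / (1 + exp(−(V − V₀.₅)/k))` (single or double Boltzmann, the
  higher-V₀.₅ component being the high-voltage-activated, HVA, component),
  biexponential activation/deactivation kinetics, run-down metrics,
  cross-over detection, current densities;
* **solution chemistry**: free Ca²⁺/Mg²⁺ of EGTA/ATP-buffered pipette
  solutions (chelator-calculator style), Nernst potentials, and Henderson
  liquid junction potentials;
* **statistics**: the Shapiro–Wilk-gated test selection used for group
  comparisons (t-test / Mann–Whitney / ANOVA+Bonferroni / Kruskal–Wallis+Dunn).

The default rate constants are calibrated in-repo so that the simulated
experiments reproduce the study's printed anchors (see below); the
calibration script and its target table ship with the repository
(`analysis/02_calibrate_gating.py`).

## Worked example

Simulate the wild-type channel under the standard 2-s double-pulse IV
protocol shortly after break-in (intracellular Ca²⁺ ≈ 100 nM), extract the
isochronal GV from the instantaneous P2 tail amplitudes, and fit a
Boltzmann:

```python
from kcnq1ca import gating, pipelines
from kcnq1ca.analysis import fit_boltzmann

wt = gating.build_default_scheme("WT")
gv = pipelines.model_gv(wt, ca=100e-9)      # molar free Ca2+
fit = fit_boltzmann(gv, n_components=1)
c = fit.components[0]
print(f"V0.5 = {c.v_half:+.1f} mV, k = {c.k:.1f} mV")
```

prints

```
V0.5 = -33.2 mV, k = 15.0 mV
```

i.e. half-maximal isochronal activation at −33.2 mV.  With the pipette
Ca²⁺ saturating the sensor (`ca=5e-6`) the midpoint shifts to −39.6 mV;
after five minutes of simulated wash-out towards the 20-nM pipette
solution the late-P2 amplitude profile develops the characteristic
cross-over minimum at a P1 potential of −30 mV and the GV needs a second,
high-voltage-activated Boltzmann component (slope factor ≈ 25 mV):

```python
from kcnq1ca import synth
from kcnq1ca.analysis import crossover_profile

ca_5min = synth.intracellular_ca_timecourse(synth.ConditionSpec(), 300.0)
rec = pipelines.model_recording(wt, "iv2s", ca=float(ca_5min))
print(crossover_profile(rec).minimum_mV)    # -30.0
```

The numbered scripts under `analysis/` run the full study pipeline
(solution chemistry, calibration, GV families, cross-over controls,
synthetic cohorts with statistics) and write their tables to `results/`.

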