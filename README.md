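# aggkinetics

Kinetic-regime analysis of thermal protein aggregation, built around the
test system of heat-stressed yeast alcohol dehydrogenase (yADH, a 150 kDa
tetramer) at 56 °C and its suppression by the chemical chaperone
2-hydroxypropyl-β-cyclodextrin (2-HP-β-CD).

Protein aggregation proceeds through distinguishable stages — irreversible
unfolding (N → I, first-order, rate constant k_den), nucleation of unfolded
intermediates, growth of aggregates by monomer attachment, and
aggregate–aggregate sticking. Which stage limits the overall rate (the
*kinetic regime*) is diagnosed from the order of aggregation with respect to
protein, n_c: the exponent of the protein-concentration dependence of a
stage's rate parameter. n_c = 1 marks an unfolding-limited pseudo-first-order
process; n_c = 2 a regime limited by the bimolecular attachment step.

The package provides, as scikit-learn-style estimators plus thin functional
wrappers:

* **Trace analysis** — segmentation of sigmoidal light-scattering traces
  into lag, nucleation and growth phases, with least-squares fits of
  `I = I₀ + K_agg (t − t₀)²` (nucleation stage) and
  `I = I₀ + v₀ (t − t*) − B (t − t*)²` (growth stage; t* is the lag cut off
  on the abscissa, v₀ the initial growth rate).
* **Regime inference** — power-law fits `K_agg = const·[P]₀ᵇ`,
  `v₀ = const·[P]₀ᵇ` across protein concentrations (n_c = round(b)); Hill
  dose–response fits `y/y₀ = 1/(1 + ([L]/[L]₀.₅)ʰ)` of chaperone
  suppression; the shape-parameterized decay of the non-aggregated fraction
  γ_non-agg(t); the second-order linearization `1/c − 1/c₀ = k_II t`; and a
  regime classifier.
* **A mass-action Smoluchowski simulator** of the full scheme
  (denaturation → cooperative nucleation → attachment growth →
  cluster–cluster sticking over a truncated size spectrum) that renders
  every observable synthetically: scattering traces, γ_non-agg decays,
  R_h populations, dose–response series, DLS autocorrelation functions and
  DSC thermograms.
* **DLS sizing** — CONTIN-style regularized inversion of g₂(τ) into decay
  rates and two hydrodynamic-radius populations via Stokes–Einstein.
* **DSC analysis** — baseline subtraction, T_max, calorimetric enthalpy
  ΔH_cal, and the denaturation rate profile
  k(T) = v·Cp_ex(T)/(ΔH_cal − Q(T)) of an irreversible two-state transition.

## Worked example

Simulate the no-chaperone and saturating-chaperone conditions at six protein
concentrations (0.1–0.6 mg/mL), fit every trace, and classify the regime:

```python
from aggkinetics.pipeline import regime_report

for preset in ("A", "B"):        # A: no chaperone, B: 100 mM 2-HP-β-CD
    rep = regime_report(preset, n_conc=6, seed=1)
    print(preset,
          "b_nuc=%.2f" % rep["order_nucleation"]["b"],
          "b_growth=%.2f" % rep["order_growth"]["b"],
          rep["regime"]["limiting_stage"])
```

prints

```
A b_nuc=2.17 b_growth=1.11 denaturation
B b_nuc=4.41 b_growth=1.84 aggregate_growth
```

i.e. without chaperone the growth-stage order rounds to n_c = 1 (the overall
rate is set by unfolding), while under the chaperone it rounds to n_c = 2
(the bimolecular attachment step becomes limiting) and the nucleation-stage
order rises from ≈2 to ≈4 — the change of kinetic regime. A single trace
analysis looks like:

```python
from aggkinetics import (make_regime_presets, simulate_trajectory,
                         trajectory_to_intensity, analyze_trace)

cfg = make_regime_presets("A", protein_conc=0.4)
trace = trajectory_to_intensity(simulate_trajectory(cfg))
a = analyze_trace(trace)
# onset 330 s, K_agg = 0.565 counts/s², inflection 510 s,
# v0 = 322 counts/s, t* = 167 s, growth r² = 0.999
```

A `aggkinetics` CLI exposes the same pipeline as subcommands
(`simulate`, `analyze-trace`, `fit-order`, `fit-dose`, `fit-nonagg`,
`fit-kii`, `invert-acf`, `analyze-dsc`, `regime-report`, `make-fixtures`);
every JSON result embeds the package version, configuration hash and seed.

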