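# bronchosynergy

Quantitative analysis of drug-combination interaction in ex vivo airway
pharmacology: does adding an inhaled corticosteroid (beclomethasone
dipropionate, BDP) to a long-acting β₂-agonist (formoterol fumarate, FF)
merely add up, or is the bronchorelaxation truly synergistic?

The package implements the full analysis chain used for organ-bath
(isometric tension of medium bronchi) and precision-cut-lung-slice
(luminal area of small airways) concentration–response studies, plus a
synthetic data generator so every stage is testable without raw tissue
recordings.

## What it computes

**Curve fitting.** Responses are normalized to the papaverine maximum
(100%) over the histamine pre-contraction plateau (0%) and fitted with the
variable-slope logistic (4PL / Hill) model

    Y = Bottom + (Top − Bottom) / (1 + 10^((logEC50 − X)·HillSlope)),

with X = log₁₀ concentration, yielding Emax (Top), pEC50 = −log₁₀ EC50 (M)
and closed-form effect inversions (e.g. EC70). Non-monotone curves fall back
to a rise–fall product-of-logistics model. Arms whose response never exceeds
20% Emax are flagged "potency not calculable" (NC).

**Bliss Independence.** The expected additive fractional effect of two
independently acting agents is E(x,y) = Ex + Ey − Ex·Ey. For a fixed-ratio
combination (100:6 BDP:FF by mass) the per-concentration delta
(observed − expected) is tested per point (Welch t) and curve-wise (two-way
ANOVA); delta > 0 with p < 0.05 is synergistic.

**Unified Theory (median-effect / Combination Index).** Each condition is
linearized by the median-effect equation fa/fu = (D/Dm)^m, and the
Combination Index at effect level fa is

    CI = D1/Dx1 + D2/Dx2,

with (D1, D2) the component doses of the mixture total reaching fa and
Dx1, Dx2 the single-agent doses reaching the same fa. CI < 1 is synergism,
CI = 1 additivity, CI > 1 antagonism; magnitude bands grade the index
(< 0.1 very strong, 0.1–0.3 strong, 0.3–0.7 synergism, …). Normalized
isobolograms (D1/Dx1 vs D2/Dx2) are produced at the standard effect levels
15/25/50/75/90% Emax.

**Synthetic studies.** `GeneratorConfig` / `generate_study` simulate whole
studies (n = 5 tissues/arm, 3% response noise, between-tissue parameter
spread, vehicle time controls at the organ-bath 1-in-7 rate, QC failures)
under a Bliss-consistent null, a dose-additive (Loewe) null, or a
potency-shift synergy alternative, and return the latent ground truth for
recovery checks.

## Worked example

```python
import bronchosynergy as bs

cfg = bs.GeneratorConfig(interaction_model="potency_shift", psi=4.0)
ds, truth = bs.generate_study(cfg, seed=20)
report = bs.run_analysis(ds)
print(bs.render_report(report))
```

prints

```
bronchosynergy analysis report (config dec2b499128e4ed9)
curves analyzed: 17 / 17 (QC excluded tissues: 0)
time controls: n=2, mean drift -0.31%/step (summary only, no correction)

== medium airways, NS ==
       FF: n=5, Emax 99.84% ± 4.06, pEC50 8.37 ± 0.12
      BDP: n=5, Emax 12.19% ± 0.62, pEC50 NC
   BDP_FF: n=5, Emax 94.34% ± 4.61, pEC50 NC
  Bliss: 6/9 points synergistic; curve-level ANOVA p = 9.7e-10
  Combination Index (fa: CI grade):
    0.15: 0.31 +++
    0.25: 0.32 +++
    0.50: 0.34 +++
    0.75: 0.37 +++
    0.90: 0.39 +++
```

Read it as: FF alone is a full agonist (Emax ~100%, pEC50 8.4); BDP alone
barely relaxes the tissue (~12%, potency not calculable); yet their 100:6
mixture relaxes more than Bliss additivity predicts at 6 of 9 tested totals,
and the Combination Index sits around 0.3–0.4 (synergism, "+++") across
effect levels — exactly the ψ = 4 potency synergy the generator injected.

The same pipeline runs from the shell:

```sh
bronchosynergy simulate --seed 20 --out sim/
bronchosynergy analyze --data sim/study.csv --out results/ --plots
bronchosynergy report --in results/report.json
```

`analyze` writes `report.json` plus CSV tables (`curve_fits.csv`,
`group_summary.csv`, `bliss_per_point.csv`, `fa_ci.csv`, `isobologram.csv`).

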