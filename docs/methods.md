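# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about
real tissue recordings.

## Normalization and data model

Raw readings are isometric tension (g, organ bath; relaxation lowers the
reading) or luminal area (mm², PCLS; relaxation raises it). Each tissue
carries two references: the histamine pre-contraction plateau and the
papaverine (100 µM) reading that defines the maximal achievable relaxation.
Normalized relaxation is the affine map

    R% = 100 · (plateau − observed) / (plateau − papaverine),

which sends plateau → 0% and papaverine → 100% for both sign conventions
and is invariant to rescaling all three raw inputs. Normalized values may
exceed 100% (observed readings can overshoot the papaverine reference);
they are stored un-clipped and only clipped where a formula demands a
fraction (see below). A tissue with plateau = papaverine has no dynamic
range and is rejected.

The canonical concentration unit is ng/ml because the fixed-dose
combination is defined by a 100:6 BDP:FF *weight* ratio; molar annotations
use molecular weights FF 840.91 g/mol (fumarate dihydrate, the form the
marketed doses refer to) and BDP 521.04 g/mol, so
pEC50 = log₁₀(MW) + 6 − log₁₀(EC50 ng/ml).

Quality control: organ-bath rings must respond to electrical field
stimulation at 25 Hz; PCLS must show ≥ 25% luminal-area reduction to
acetylcholine (0.3 µM). Failing tissues are excluded before analysis and
listed with reasons. Vehicle time controls (one ring per seven mounted) are
summarized (mean drift per addition step) but never used to correct treated
curves — no such correction is part of the analysis convention, and
inventing one would change the estimand.

## 4PL fitting

`fit_hill` minimizes least squares of the variable-slope logistic with
scipy's bounded trust-region solver from a 3×3 multistart (logEC50 at the
0.25/0.5/0.75 quantiles of the tested log-concentrations × slopes 0.5/1/2;
Bottom/Top initialized from the data extremes). Bounds: Bottom ∈ [−5, 20]%,
Top ∈ [20, 115]% (tolerance for >100% normalized readings), slope ∈
[0.1, 6], logEC50 within the tested span ± 2 log units. On exact model data
the parameters are recovered to ~1e−6; the objective has been verified
against an exhaustive profiled grid search (step 0.01 on the two nonlinear
parameters, Bottom/Top solved exactly at each node).

Potency is reported "not calculable" (NC) when the fitted Top *or* the
largest observed response is below 20% Emax — the latter condition matters
because the Top bound would otherwise let a boundary-pinned fit masquerade
as an active curve. NC arms are excluded from pEC50 summaries, and group
summaries report their observed maximum rather than the extrapolated Top.

Effect inversion is closed-form: ECp = EC50 · (p/(100−p))^(1/slope), so
EC70 = EC50 · (7/3)^(1/slope).

Non-monotone (bell-shaped) curves — rank correlation of response with log
concentration < 0.5 plus an interior peak with ≥ 10-point terminal drop —
are fitted with a product-of-logistics rise–fall model; the peak is located
on a dense grid and refined by bounded scalar minimization. The rise–fall
family is a package choice; no specific bell model is dictated by the
analysis convention.

## Bliss Independence analysis

For each combination total C the 100:6 mass split gives component
concentrations (C·100/106, C·6/106). Monotherapy fractional effects at
those components are read from each tissue's fitted Hill curve (smooth
reference, the default) or from log-linear interpolation of the raw
responses (config option); NC arms always use the raw responses, because a
Top-bounded fit systematically overstates a sub-threshold curve's plateau
and would bias the expected response upward. Fractional inputs of
E = Ex + Ey − Ex·Ey are clipped to [0, 1−1e−6] (with a warning above 1);
observed responses enter the tests un-clipped so the null stays calibrated.

Replicates: monotherapy tissue i of each arm (sorted by id) is paired to
form per-replicate expected values — the pairing is arbitrary since arms
come from different tissues, and it is documented rather than hidden.
Per-point tests are unpaired Welch t-tests without multiplicity correction
(matching per-point asterisk reporting conventions); the curve-level test
is an ordinary two-way ANOVA (response type × concentration) with the
response-type main effect reported. A repeated-measures pairing is not
assumed because the observed and expected "replicates" are physically
different tissues. Degenerate zero-variance comparisons (possible only with
synthetic noiseless data) return p = 1 when the means coincide. The SEM of
the expected response uses the delta method,
sqrt((1−Ey)²·SEMx² + (1−Ex)²·SEMy²), verified against Monte-Carlo.

Classification per point: synergistic (delta > 0, p < α), antagonistic
(delta < 0, p < α), additive otherwise; α = 0.05 by default.

## Median-effect and Combination Index

Median-effect fits are ordinary least squares of log₁₀(fa/fu) on log₁₀ D;
points with fa outside (1e−3, 1−1e−3) are excluded and counted (the logit
is undefined/explosive there). Fits are computed on the group-mean curve,
matching single-index-per-condition reporting; per-tissue fits remain
available for uncertainty work. The combination is fitted on its *total*
dose.

CI uses the two-term (mutually exclusive) theorem by default; the mutually
nonexclusive third term D1·D2/(Dx1·Dx2) is behind a flag since the analysis
convention does not state the variant. When the BDP component is
sub-threshold the default still fits its observed sub-20% range and carries
a caveat flag on the profile (mirroring how CI software requires both
component fits); an alternative mode drops the inactive term, giving an
upper-bound CI equal to D1/Dx1.

The fa grid is 0.05…0.95 (step 0.05) plus the standard tabulated levels
{0.15, 0.25, 0.50, 0.75, 0.90}. Grades follow the conventional CI bands:
(0, 0.1) very strong synergism (+++++), [0.1, 0.3) strong (++++), [0.3,
0.7) synergism (+++), [0.7, 0.85) moderate, [0.85, 0.9) slight, [0.9, 1.1]
nearly additive, then mirrored antagonism bands (1.2, 1.45, 3.3, 10).
Synergism bands are half-open on the left so CI = 0.10 grades strong, not
very strong — required for consistency of the printed magnitude table.
`overall_ci` is the arithmetic mean of CI over a set of tabulated effect
levels (optionally pooled across conditions); this is an interpretive
summary, not part of the CI theorem.

## Synthetic data generator

The generator emulates the study design: per (compartment, sensitization)
cell, monotherapy FF and BDP arms plus a 100:6 fixed-ratio combination,
n = 5 tissues per arm. Monotherapy truths default to the study's printed
group parameters (FF: Emax 97.00%/pEC50 8.26 NS-medium, 94.96%/8.89
PS-medium, 72.03%/7.13 NS-small, 105.30%/7.52 PS-small); between-tissue SDs
are back-calculated as SEM·√5 from the printed SEMs. The PS-small Emax has
no printed SEM, so the mean of the other three (2.78%) is used. Hill slopes
are not printed anywhere; 1.0 is used for FF. BDP arms are shallow
sub-threshold curves (top ~12%, drawn within [5, 18]% so the NC pathway is
exercised; slope 0.8, EC50 mid-grid) — nominal by necessity, since only
"< 20% / NC" is reported for them.

Dosing: combination totals 1.06→106 ng/ml (medium) and 1.06→1060 ng/ml
(small), log-spaced, 9 points; monotherapy grids span each agent's active
range. Noise is additive Gaussian on the normalized response (default SD
3% of Emax), truncated to [−5, 115]% — consistent with occasional >100%
readings. Raw tension/area values are back-computed from drawn plateau and
papaverine references so the I/O normalization round-trips. Organ-bath
cells include vehicle time controls at round(n_treated/6) (≈ 1 ring in 7),
with a configurable drift slope (default 0.5%/step). Tissues are
independent; any real inter-tissue correlation structure is unknown and not
modelled.

Interaction surfaces:

* `bliss_null` — the combination response is the Bliss composite of the
  component fractional effects: the type-I-error null for the delta
  analysis.
* `loewe_null` — dose-additive median-effect agents with a shared shape
  (requires equal slopes, enforced): CI is exactly 1 at every level, the
  null for CI calibration. The canonical instance (`loewe_null_config`)
  uses two fully active agents and grids bracketing each condition's Dm by
  ±1.5 log units — the standard design for median-effect work, where
  points should span fa ≈ 0.05–0.95; grids reaching far below an agent's
  active range put near-zero responses into the logit and bias Dm.
* `potency_shift` — the Bliss surface evaluated at component doses
  multiplied by ψ ≥ 1; ψ = 1 recovers the null, ψ > 1 yields positive
  deltas and CI < 1 (a controllable synergy alternative; the real
  generative mechanism is unknown).

## What the tests show — and do not

Calibration and recovery results (type-I rate ≤ ~5% per point under the
Bliss null; mean pipeline CI within ~3% of 1 under the dose-additive null;
grand-mean pEC50/Emax recovered at the preset under 3% noise with n = 5)
hold under the generator's assumptions: Gaussian noise, independent
tissues, exactly logistic truths, and noise-free concentration delivery.
Real organ-bath data add serial correlation within a cumulative curve,
drift interacting with treatment, and operator-dependent reference
readings; none of these are modelled, so passing tests validate the
*analysis machinery*, not the biology. Under the dose-additive null a small
residual tilt in mean CI (± ≲0.03 across fa 0.2–0.8) remains: group-mean
curves of heterogeneous tissues are slightly flatter than any single
median-effect line, and the combination arm (which averages two independent
potency draws per tissue) flattens less than the monotherapy arms. This is
a property of single-curve-per-condition CI reporting itself, not of the
implementation.

Simulation sizes in the test suite (e.g. 100 studies for parameter
recovery, 200 for null calibration, 50 for CI calibration) were chosen so
that Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

* Per-curve fitting with group averaging; no hierarchical/mixed-effects
  model across tissues.
* CI uncertainty is not propagated from the median-effect fits (point
  estimates per condition, as in conventional CI reporting).
* The Bliss "expected" replicates rely on an arbitrary pairing of
  monotherapy tissues across arms; only the per-point variance, not the
  mean, is sensitive to this.
* Bell-shaped fits report peak location/effect but are not used in the
  interaction analysis.
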