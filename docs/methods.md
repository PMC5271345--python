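# Methods

## Scores and variable handling

All nine calculators implement the published formulas verbatim, with the
handling rules applied in a fixed order: dialysis substitution first (where
a score defines one), then floors, then caps, then the formula, then any
rounding and score-level ceiling. For MELD the order compute → round → cap
at 40 is used; it is equivalent to cap-then-round for this formula.
"Rounded to the nearest integer" is implemented as round-half-up on the
positive axis (`floor(x + 0.5)`), matching clinical calculators; only MELD
and MELD-Na are rounded, all other scores are returned unrounded. PELD may
be negative.

Decisions worth stating explicitly:

- **Units.** Creatinine, bilirubin and albumin carry mandatory unit tags and
  are converted on demand with the standard factors 88.42 (creatinine,
  mg/dl → μmol/l), 17.104 (bilirubin) and 10 (albumin, g/dl → g/l). The
  source formulas mix unit systems (MELD-family in conventional units,
  UKELD in SI), which is why the tags are not optional.
- **Missing values** are an explicit `None` marker, never 0. A score whose
  required input is missing yields a missing result with a recorded reason;
  nothing is imputed (complete-case throughout).
- **Dialysis** substitutes creatinine = 4.0 mg/dl for MELD/MESO/MELD-Na and
  3.0 mg/dl for refitMELD/refitMELD-Na; upMELD caps creatinine at 4.0
  regardless of renal replacement and never substitutes. A patient is "on
  dialysis" when sessions/week ≥ 1 unless the flag is explicitly overridden.
- **MESO** uses the rounded integer MELD (the published "MELD as above"
  includes rounding); a flag switches to the continuous value. Neither MESO
  nor iMELD clamps sodium, because no clamp is published for them; a
  sensitivity switch can borrow the MELD-Na 125–140 mmol/l clamp.
- **refitMELD-Na** enters BiliCC (bilirubin floored at 1, capped at 20
  mg/dl) into the sodium interaction *untransformed*, exactly as published
  here even though the original derivation used a log transform. A
  consequence worth knowing: the marginal sodium effect is
  −(0.652 − 0.194·BiliCC) per mmol/l, so above bilirubin ≈ 3.36 mg/dl the
  score *increases* with sodium. The property tests assert sodium
  monotonicity only below that point.
- **PELD** computes the under-1-year indicator from age at listing alone
  (the rule that infants keep the indicator until 24 months needs listing
  and assessment dates the cohort schema does not carry) and forces the
  growth-failure indicator to 0 above 219 months. No 1.0 floors are applied
  to bilirubin or INR because the published formula states none. PELD is
  computed for all ages by default — it is validated cohort-wide as a
  covariate — with a configurable age ceiling (e.g. 12 years) for
  allocation-style use.

Each calculator optionally records every rule that actually changed an
input ("creatinine 5 capped to 4", "growth failure set to 0 …") into an
audit list; the panel driver aggregates these per patient and the pipeline
logs per-score counts per run.

## Synthetic cohort generator

The generator emulates the *marginal* structure of a real single-center
waiting list of 818 candidates; it is the test bed for every downstream
stage, not a patient-level model of liver disease.

- **Composition.** Pediatric fraction 0.284 (child ages uniform on
  0.02–16.9 years, adults uniform on 17–73.6 — crude but spanning the
  observed range; no age pyramid is published), male fraction 0.567,
  hemodialysis 0.073 (2–3 sessions/week), growth failure 18.5% among
  children under 16, high-urgency 0.203, standard-exception 0.256. The
  ten-group indication mix follows the published fractions renormalized to
  sum to 1 (as printed they sum to 1.045 because the published counts
  overlap).
- **Laboratories.** Independent truncated log-normals parameterized by the
  published medians (creatinine 70 μmol/l, bilirubin 66 μmol/l, INR 1.4,
  albumin 31 g/l, PTT 41 s) and truncated to the published ranges; sodium
  is a truncated normal (138 ± 5 mmol/l on 121–161). The log-scale sigmas
  (0.70, 1.10, 0.30, 0.25, 0.25) are chosen to give clinically plausible
  spread; sampled medians land within 15% of targets at n ≥ 500. No lab
  correlation structure is published, so marginals are independent by
  default; an exchangeable Gaussian copula (`lab_correlation=ρ`) is
  available for sensitivity analyses.
- **Mortality.** 90-day death is Bernoulli with
  P = expit(intercept + slope·driver), driver = iMELD by default. The slope
  default of 0.12 per iMELD point was calibrated once so that the driver's
  AUROC is ≈ 0.80, mirroring the headline discrimination of the
  best-performing score; the intercept is solved by root-finding so the
  cohort's mean event probability equals the 9% target (74/818).
  `calibrate_intercept` does the same on a large (n = 20 000) fixed-seed
  covariate sample. With slope 0 every score discriminates at chance — the
  generator's negative control.
- **Waiting time** is an exponential draw matched to the published median
  of 91.5 days, truncated at 2323; deaths within 90 days get at most 90
  days on the list. Post-90-day outcomes are drawn with fixed proportions
  (transplanted/died/delisted ≈ 0.76/0.10/0.14 of survivors).

What passing tests therefore show: the pipeline recovers a known
generating mechanism (slope within 2 SE, driver score selected and
top-ranked by AUROC) under realistic marginals. What they do not show:
performance on real cohorts with correlated labs, subgroup-specific case
mix, informative censoring by transplantation, or longitudinal lab drift —
none of which the generator attempts.

## ROC analysis

AUROC is the Mann–Whitney statistic with midrank tie handling (ties count
1/2; no jittering), oriented so that higher scores mean death. The curve
has one point per distinct threshold, and its trapezoidal area equals the
pairwise statistic to 1e-12 (an internal consistency the tests enforce
against a brute-force O(n²) oracle). The default 95% CI is the DeLong
structural-components normal interval, truncated to [0, 1]; a seeded
stratified percentile bootstrap is the alternative. Coverage of the DeLong
interval is verified at 93–97% over 500 binormal simulations (true AUC
0.75, n = 2000). "Clinically useful" is strictly AUROC > 0.700 — a score
at 0.699–0.700 just fails.

The sub-cohort matrix evaluates every score in: all cases,
children/adults (age < 16 by default; 12 available), first listing vs
re-transplantation, and each indication group against its complement —
complete-case per score within subgroup. Cells with fewer than 2 events or
2 non-events are flagged not-estimable rather than raising.

## Logistic modelling

`fit_logistic` is Newton–Raphson/IRLS with step-halving, converged at
score sup-norm < 1e-8 (max 100 iterations); Wald standard errors from the
observed information; CIs exp(coef ± z₀.₉₇₅·se). Perfect separation is
detected when fitted probabilities saturate and reported with the
offending covariate named. The fit agrees with closed-form 2×2 odds ratios
and standard errors to 1e-6 and with an independent ML implementation to
1e-6 on random designs.

Selection follows the classic forward likelihood-ratio procedure: start
from intercept-only, enter the candidate with the smallest LR p below 0.05,
then remove any included term whose LR removal p exceeds 0.10 (the
conventional stepwise removal default; only the 0.05 significance
convention is published). Collinearity is resolved *before* selection by
declared variable groups — {weight, height, BMI} and {age, pediatric <16,
pediatric <12} — keeping the member with the smallest univariable p
(judgment overrides supported). Score-component collinearity is handled
architecturally: model set 1 uses clinical and laboratory covariates only,
model set 2 replaces the raw score-component labs (creatinine, bilirubin,
INR, sodium, albumin) with the nine scores themselves; PTT stays in set 2
since no score uses it. A VIF table is emitted for transparency but takes
no decisions.

## Quality appraisal

Eighteen binary items in five categories; per-item means are taken across
evaluators first and the two external-validity items are then doubled
(averaging and scaling commute), giving category maxima of 4 and a total
out of 20. Fractional per-item values such as 0.33/0.67 arise only as
3-evaluator means; input sheets are strictly 0/1. The published per-item
table ships as a fixture; for several models its printed column totals do
not equal the sum of their own printed cells, so the fixture keeps a
separate `printed_total` row, and only the internally consistent columns
(UKELD = 16, MELD-Na = 14.35) are exact recomputation targets. The
cross-model report reproduces the published aggregate of 14.45 points
(72.25% of 20) from the printed totals and identifies statistical validity
(per-item mean 0.49) and model evaluation (0.67) as the weakest categories.

## Numerical and testing choices

- All randomness (generator, bootstrap, pipeline) flows from one integer
  seed through `numpy.random.default_rng`; equal seeds give byte-identical
  CSV artifacts.
- Truncated (log-)normal sampling uses inverse-CDF transforms, so the
  copula and independent paths share one code path.
- Pipeline artifacts are written to a temporary directory and moved into
  place only on success; a failed run leaves no partial outputs.
- Test problem sizes: oracle equivalence on 1000 random lab draws per
  score; AUROC oracle equality on 500 random instances (n ≤ 50); DeLong
  coverage on 500 simulations of n = 2000; slope recovery on 100 cohorts of
  n = 5000; selection consistency on 100 cohorts of n = 818. The full suite
  runs in well under a minute on one CPU.

## Known limitations

- The generator's independence assumptions (labs, indication vs age) make
  subgroup AUROC patterns unrealistic; subgroup results on synthetic data
  are structural checks only.
- The infant PELD continuation rule and growth-failure derivation from
  growth charts are out of scope; growth failure is an input flag.
- No AUROC-difference tests between correlated scores, no calibration
  metrics, no competing-risks treatment of transplantation.
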