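# Methods

## The phenotype and its operationalisation

A participant's frailty status is determined by five dichotomous
components. Two are self-reports consumed as given: *shrinking* is a
reported unintentional weight loss of more than 2–3 kg in the prior six
months (the package deliberately accepts this as a binary questionnaire
item rather than recomputing it from serial weights — the instrument
defines no weighing protocol, and the "2–3 kg" phrasing is itself
ambiguous), and *exhaustion* is a positive answer to either of two
questions about the past month. The other three are measured against
population-specific worst-quintile cut-offs:

- *weakness*: grip strength ≤ the 20th percentile of grip within the
  participant's gender × BMI band (bands < 18.5, [18.5, 25), [25, 30),
  ≥ 30 kg/m²). Grip is the mean of the per-hand maxima over two readings
  per hand; with one hand entirely missing, the other hand's maximum is
  used and flagged.
- *slowness*: 5-m walk time ≥ the 80th percentile within gender × height
  band, the bands splitting at the within-gender median height.
- *low physical activity*: mean daily activity energy expenditure (AEE,
  kcal per kg body weight per day, from a tri-axial accelerometer) ≤ the
  20th percentile within gender. A day contributes only if wear time is
  strictly greater than 600 minutes; a participant needs ≥ 3 valid days.
  The paper trail for this exposure calls it a per-day quantity without
  naming the aggregator across valid days; the arithmetic mean is used as
  the standard choice.

Status: 0 components non-frail, 1–2 pre-frail, ≥ 3 frail. All boundary
comparisons are inclusive (≤ / ≥), matching how published cut-off tables
print attained sample values.

**Percentile convention.** Cut-offs use the inverse empirical CDF (the
smallest observed value with at least the target fraction of observations
at or below it; numpy's `method="inverted_cdf"`), so every cut-off is an
attained sample value. Consequences: each stratified component flags
between 20% and 20% + 1/(stratum size) of its stratum when values are
distinct, and a stratum of ties flags everyone (documented degenerate
case). Strata with fewer than 5 members trigger a warning; empty strata
are configuration errors.

**Exclusion funnel.** Applied in fixed order, logging the first matching
rule per participant: (1) no physical tests at all; (2) history of
dementia, Parkinson's disease or stroke, or MMSE < 18; (3) accelerometer
ineligibility; (4) any remaining component input missing. Order matters
only for the log's attribution, not for the retained set.

**Prevalence.** Percentages with Wald 95% intervals
p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 100]; age bands 65–69 … 80–84, 85+.
The Wald form is used because it reproduces the published pre-frail
interval from the unrounded proportion; the published frail interval is
not symmetric about its point estimate and reproduces under no standard
interval, so it is treated as a misprint and not targeted.

## Latent class analysis

Internal construct validity is assessed by fitting latent class models
with C = 1, 2, 3 classes to the 2⁵ = 32 response patterns of the five
components. The model assumes conditional independence of items given
class; free parameters k = (C−1) + 5C = 6C − 1.

Estimation is pure EM on the weighted pattern table: E-step posterior
responsibilities per pattern, M-step closed-form updates of the mixing
proportions π and conditionals p. Defaults: 20 random starts (Dirichlet
mixing, conditionals uniform on [0.2, 0.8]), relative log-likelihood
tolerance 1e-8, max 1000 iterations; the best converged start wins. A
Newton–Raphson polish (used by some LCA software) is omitted: EM at this
tolerance reaches the same optimum on 5 binary items. Conditionals are
clamped to [1e-6, 1−1e-6] to avoid log(0) absorbing states; the
log-likelihood is asserted non-decreasing at every iteration. The 1-class
model bypasses EM — its MLE is the item-independence model with
conditionals equal to the marginal frequencies.

Label switching is resolved by sorting classes on the expected number of
positive items (ascending; ties by descending mixing weight), so class 0
is always the fittest. Model comparison reports AIC = −2ℓ + 2k and
BIC = −2ℓ + k·ln(n) at full precision and truncated (floored) to integer —
the truncation convention is the one consistent with all six published
integer values — plus a Pearson χ² over all 32 cells with df = 31 − k (no
adjustment for empty or boundary cells) and its upper-tail p. Expected
cells below 1e-12 contribute through a guarded denominator with a
sparse-cell warning. Across a class range the log-likelihood must be
non-decreasing; a decrease beyond 1e-6 marks a trapped start and triggers
one refit with triple the starts.

## Correlates models

Association screening uses the Cochran–Mantel–Haenszel nonzero-correlation
statistic with integer scores (status 0/1/2, factor level codes): in the
single-stratum case (n−1)·r², 1 df. Odds ratios come from a
generalized-logit (multinomial) model with non-frail as the reference,
giving the pre-frail and frail contrasts jointly; a paired-binary mode
(two separate logistic fits) exists behind a flag for sensitivity, since
published analyses of this design rarely state which was used. Age and
the K6 psychological-distress score enter continuously (per 1 unit); all
other covariates as coded flags or dummy-coded categories (first level
reference). Rows missing any model term are dropped and counted.

Backward elimination removes, one at a time, the removable term with the
largest likelihood-ratio p ≥ the threshold (default 0.05), each term
tested jointly across both contrasts with df = (columns of the term) × 2;
the complete-case sample is fixed at the initial term set so nested fits
stay comparable. The LR criterion is chosen over Wald as the more
defensible default. In the comorbidity-adjusted model the seven-condition
adjustment set (minor-trauma fracture, hypertension, chronic heart
disease, diabetes, chronic pulmonary disease, digestive disease,
osteoarthritis/rheumatism) is forced in and never removed. Gender
stratification reruns the identical pipeline on subset rows.

Diagnostics: VIF per design column as 1/(1−R²) from an intercept-included
auxiliary regression (≥ 2 flagged, infinite for perfect collinearity);
Hosmer–Lemeshow per binary contrast on deciles of fitted conditional risk
(ties merge groups with a warning; df = groups − 2), applied per contrast
because no published convention exists for a 3-level outcome; Nagelkerke
R² as Cox–Snell divided by its attainable maximum.

## The synthetic cohort

The generator emulates a suburban Japanese community cohort of ~1,500
adults aged 65–93: ages from a truncated normal (mean 73.3 y, SD 6.0),
38.8% male, and a two-class latent structure (baseline mixing 0.75/0.25)
whose standardized liability shift (0 / 1.1 SD) drives all five
components. Binary items use a liability-threshold model: the threshold is
solved so the population marginal matches its configured target (weight
loss 0.148, exhaustion answers 0.11/0.10, covariates at realistic
community rates), while the class shift moves per-class rates apart.
Continuous measures are gender-specific: grip normal (male 36 ± 6 kg,
female 22 ± 4 kg, shifted down by the class liability), walk time and AEE
lognormal (medians ≈ 2.95/3.35 s and 8.3/9.5 kcal/kg/day) with mild age
slopes; these distributions are invented defaults calibrated so derived
quintile cut-offs land near the published magnitudes (e.g. male AEE
cut-off ≈ 6 kcal/kg/day) — they are configuration, not claims about any
real population. With this parameterisation roughly one retained
participant in ten is frail and ~44% pre-frail, matching the magnitude of
the study population the generator emulates.

Class membership probability tilts mildly with age (logit slope 0.09/yr),
so age–frailty associations exist for the correlates stage. Realism
features deliberately included: ~1% physical-test non-participation, ~2%
accelerometer non-wearers, ~9% of days under the 600-minute wear
threshold, and 0.3% completely-at-random missingness per covariate (never
on id/gender/age or the component inputs), sized so the multivariate
complete-case loss is a few percent. Features of real data *not*
emulated: population weighting, household/geographic clustering,
measurement drift, informative missingness, longitudinal change, and any
dependence of items within class beyond the latent structure — so passing
tests demonstrate the pipeline's correctness under a known generating
model, not external validity on any real cohort. BMI is exact
(weight/height²) by construction; one global seed derives independent
substreams per block, so identical configuration reproduces bit-identical
tables.

## Problem sizes and numerics

The test suite exercises cohorts of 300–1,500 (one 20,000-participant
independence check), LCA tables of n = 200–4,000 with up to 20 starts, and
logistic simulations of n = 500–5,000; the full default pipeline (n =
1,500, three LCA fits, two eliminated multinomial models) runs in well
under a minute on one CPU. The parameter-recovery check uses a balanced,
well-separated two-class truth (mixing 0.5/0.5, conditionals ~0.1 vs
~0.7–0.8) so sampling error at n = 2,000 stays well below the 0.05
tolerance and the check isolates the estimator. The 2-item/2-class EM
check compares against a brute-force grid search at 0.05 resolution and
the saturated multinomial bound.

## Known limitations

- Cut-off derivation requires every gender × BMI stratum to be non-empty;
  very small cohorts may need the shipped constants instead.
- The CMH trend test is implemented for the single-stratum (unstratified)
  correlation form only.
- Separation in logistic fits is flagged, not penalised; no Firth
  correction.
- LCA supports at most 5 classes and complete binary data (no partial
  response patterns).
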