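# frailscreen

Screening for the frailty phenotype in community-dwelling older adults, with
the low-physical-activity component measured objectively by a tri-axial
accelerometer instead of a questionnaire.

The frailty phenotype classifies a person by five dichotomous components —
**shrinking** (self-reported unintentional weight loss), **weakness** (low
grip strength), **exhaustion** (two self-report questions), **slowness**
(slow timed 5-m walk) and **low physical activity** (low daily activity
energy expenditure, AEE, in kcal/kg/day). With 0 components a person is
*non-frail*, with 1–2 *pre-frail*, with ≥ 3 *frail*. Weakness, slowness and
low activity are defined against population-specific worst-quintile
cut-offs: the lowest 20% of grip within gender × BMI band, the slowest 20%
of walk time within gender × height band (split at the gender median), and
the lowest 20% of mean AEE within gender. A valid accelerometer day needs
strictly more than 600 minutes of wear; at least 3 valid days make a
participant analysable.

The package implements the full screening analysis as a tested pipeline:

- **`frailscreen.simulate`** — synthetic cohort generator with a known
  two-class latent frailty structure (ground truth for every later stage);
- **`frailscreen.accelerometry`** — valid-day flagging and per-participant
  mean AEE;
- **`frailscreen.phenotype`** — study exclusions, stratified quintile
  cut-off derivation (`FrailtyPhenotype` estimator: `fit` derives cut-offs,
  `transform` scores), status classification and prevalence tables with
  Wald 95% CIs. The published Sasaguri Genkimon Study cut-offs ship as a
  constant (`FrailtyCutoffs.sasaguri()`);
- **`frailscreen.lca`** — internal construct validity: a multi-start EM
  latent class model (`LatentClassModel`) over the 32 response patterns of
  the five components, compared across 1/2/3 classes by AIC, BIC and a
  Pearson χ² over all patterns. For a C-class model the pattern likelihood
  is P(x) = Σ_c π_c Π_j p_cj^{x_j}(1−p_cj)^{1−x_j} with k = 6C − 1 free
  parameters;
- **`frailscreen.correlates`** — Cochran–Mantel–Haenszel trend tests,
  univariate and mutually adjusted generalized-logit (multinomial) models
  with non-frail as reference, likelihood-ratio backward elimination, VIF,
  Hosmer–Lemeshow and Nagelkerke R² diagnostics;
- **`frailscreen.pipeline` / CLI** — the orchestrated end-to-end run with a
  reproducibility manifest.

## Worked example

```sh
$ frailscreen run --n 1500 --seed 42 --outdir out
retained n=1400; pre-frail 44.4%, frail 10.8%; BIC-preferred latent classes: 2; outputs in out
```

A 1500-person synthetic cohort loses 100 participants to the exclusion
funnel (physical-test non-participation; dementia/Parkinson/stroke history
or MMSE < 18; fewer than 3 valid accelerometer days; missing component
inputs). Of the 1400 retained, 44.4% are pre-frail and 10.8% frail. The
latent class comparison (`out/lca_comparison.csv`) shows the validity
pattern the phenotype is expected to produce:

| classes | log-lik | AIC  | BIC  | Pearson χ² | p      |
|--------:|--------:|-----:|-----:|-----------:|-------:|
| 1       | −3322.3 | 6654 | 6680 | 295.9      | <0.001 |
| 2       | −3230.3 | 6482 | 6540 | 26.5       | 0.15   |
| 3       | −3226.3 | 6486 | 6575 | 19.2       | 0.16   |

The one-class (independence) model is rejected; two classes fit adequately
and minimise both criteria — the five components aggregate into a syndrome.
`out/correlates_model1.csv` holds the backward-eliminated multinomial odds
ratios (e.g. age and psychological-distress score retained with OR > 1 for
the frail contrast), and `out/diagnostics.json` the Hosmer–Lemeshow and
Nagelkerke R² diagnostics.

The same stages run on user data from CSV files with the documented
headers: `frailscreen phenotype --cohort cohort.csv --accel accel.csv
--cutoffs {derive,sasaguri,FILE}`.

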