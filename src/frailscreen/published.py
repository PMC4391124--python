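"""Published summary values from the Sasaguri Genkimon Study baseline cohort.

These constants are printed study-level inputs (distributions, fitted
log-likelihoods, sample sizes) used to cross-check the package's arithmetic
— information criteria, status classification, Wald intervals — against the
published analysis of the real cohort, which is not itself available.
"""

from __future__ import annotations

#: Analytic sample size after exclusions.
N_ANALYTIC = 1527

#: Percentage of participants with k affected frailty components (k = 0..5),
#: whole cohort.
CRITERIA_COUNT_PCT = {0: 46.8, 1: 29.9, 2: 14.1, 3: 7.0, 4: 2.2, 5: 0.1}

#: Published prevalence of frailty statuses (percent of the cohort).
PREVALENCE_PCT = {"pre-frail": 43.9, "frail": 9.3}

#: Unrounded pre-frail proportion (the published 95% CI 41.5-46.4 identifies
#: 671/1527 among the counts consistent with the printed 43.9%).
PREFRAIL_PROPORTION = 0.4394

#: Maximised log-likelihoods of the 1/2/3-class latent class models fitted
#: to the five dichotomous frailty components of the cohort.
LCA_LOGLIK = {1: -3553.3, 2: -3432.6, 3: -3427.9}

#: Printed (integer) AIC / BIC for those models.
LCA_AIC = {1: 7116, 2: 6887, 3: 6889}
LCA_BIC = {1: 7143, 2: 6945, 3: 6980}

#: Published marginal frequencies of the five components (percent).
COMPONENT_PCT = {
    "shrinking": 14.8,
    "weakness": 18.6,
    "exhaustion": 18.3,
    "slowness": 17.1,
    "low_pa": 19.5,
}
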