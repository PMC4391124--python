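"""Synthetic community-cohort generator with a known latent frailty structure.

Emulates a Japanese suburban cohort of older adults (65–93 y) in which a
latent two-class structure (robust / frail-leaning) drives five frailty
measures — grip strength, 5-m walk time, daily activity energy expenditure,
self-reported weight loss and exhaustion — plus the questionnaire covariates
used by the correlates analysis. Every downstream stage (accelerometry
summaries, quintile cut-offs, component scoring, latent class analysis,
logistic modelling) can be tested against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SyntheticConfig",
    "LCAGroundTruth",
    "generate_binary_patterns",
    "generate_cohort",
]


def _default_marginal_rates() -> dict[str, float]:
    # (marginal probability, class-shift slope on the liability scale)
    # Slopes > 0 make the item more likely in the frail-leaning class.
    return {
        "weight_loss": 0.148,
        "exhaustion_q1": 0.11,
        "exhaustion_q2": 0.10,
        "living_alone": 0.12,
        "employed": 0.22,
        "self_health_poor": 0.30,
        "smoking": 0.10,
        "alcohol": 0.40,
        "exercise": 0.45,
        "hobby": 0.60,
        "outdoor_gt_once_week": 0.85,
        "social_activity": 0.55,
        "cm_hypertension": 0.45,
        "cm_heart": 0.12,
        "cm_hyperlipidemia": 0.25,
        "cm_diabetes": 0.15,
        "cm_fracture": 0.10,
        "cm_depression": 0.05,
        "cm_pulmonary": 0.07,
        "cm_digestive": 0.20,
        "cm_renal": 0.04,
        "cm_osteo": 0.20,
        "cm_cancer": 0.08,
        "history_dementia": 0.010,
        "history_parkinson": 0.005,
        "history_stroke": 0.030,
        "iadl_limit": 0.10,
        "intellect_limit": 0.15,
        "social_role_limit": 0.12,
    }


#: How strongly each binary item loads on the latent class (liability-scale
#: multiplier of the class shift). Frailty components load fully; lifestyle
#: covariates load moderately with signs matching their expected direction.
_ITEM_SLOPES = {
    "weight_loss": 1.0,
    "exhaustion_q1": 1.0,
    "exhaustion_q2": 1.0,
    "living_alone": 0.5,
    "employed": -0.4,
    "self_health_poor": 0.9,
    "smoking": 0.1,
    "alcohol": -0.5,
    "exercise": -0.4,
    "hobby": -0.3,
    "outdoor_gt_once_week": -0.5,
    "social_activity": -0.5,
    "cm_hypertension": 0.3,
    "cm_heart": 0.3,
    "cm_hyperlipidemia": 0.1,
    "cm_diabetes": 0.3,
    "cm_fracture": 0.4,
    "cm_depression": 0.5,
    "cm_pulmonary": 0.3,
    "cm_digestive": 0.3,
    "cm_renal": 0.2,
    "cm_osteo": 0.4,
    "cm_cancer": 0.1,
    "history_dementia": 0.5,
    "history_parkinson": 0.3,
    "history_stroke": 0.4,
    "iadl_limit": 0.8,
    "intellect_limit": 0.7,
    "social_role_limit": 0.7,
}

#: Columns to which MCAR missingness may be applied (covariates only; never
#: id / gender / age / the five component inputs).
_MISSABLE = [
    "education_years", "income", "living_alone", "employed", "housing",
    "lsns6", "self_health_poor", "k6", "smoking", "alcohol", "exercise",
    "hobby", "outdoor_gt_once_week", "social_activity", "iadl_limit",
    "intellect_limit", "social_role_limit",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the target cohort's headline demographics (mean age
    73.3 y, SD 6.0, range 65–93, 38.8% male, n≈1500) and a two-class latent
    structure whose per-item rates put frailty prevalence near one in ten.
    """

    n_participants: int = 1500
    prop_male: float = 0.388
    age_mean: float = 73.3
    age_sd: float = 6.0
    age_range: tuple[float, float] = (65.0, 93.0)
    class_mixing: tuple[float, ...] = (0.75, 0.25)
    #: Standardised liability shift of each class; class 0 is the fittest.
    class_effect_shifts: tuple[float, ...] = (0.0, 1.1)
    marginal_rates: dict[str, float] = field(default_factory=_default_marginal_rates)
    #: Mean / SD of daily accelerometer wear minutes.
    wear_minutes_model: tuple[float, float] = (820.0, 160.0)
    n_days: int = 7
    missing_rate: float = 0.003
    #: Fraction skipping all physical tests / with failed accelerometers.
    nonparticipation_rate: float = 0.01
    nonwear_rate: float = 0.02
    #: Per-year log-odds slope of membership in higher (frailer) classes.
    age_class_slope: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        mix = np.asarray(self.class_mixing, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("class_mixing must be non-negative and sum to 1")
        if len(self.class_effect_shifts) != len(self.class_mixing):
            raise ValueError("class_effect_shifts must match class_mixing in length")
        lo, hi = self.age_range
        if not (65.0 <= lo < hi <= 93.0):
            raise ValueError("age_range must lie within [65, 93]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for name, p in self.marginal_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal rate for {name!r} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class LCAGroundTruth:
    """True parameters of a latent class model over five binary items."""

    mixing: tuple[float, ...]
    conditionals: tuple[tuple[float, ...], ...]  # n_classes x 5

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing, dtype=float)
        cond = np.asarray(self.conditionals, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixing must be non-negative and sum to 1")
        if cond.ndim != 2 or cond.shape[0] != mix.size:
            raise ValueError("conditionals must be (n_classes, n_items)")
        if cond.min() < 0 or cond.max() > 1:
            raise ValueError("conditionals must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.mixing)


def generate_binary_patterns(
    truth: LCAGroundTruth, n: int, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw ``n`` binary response rows from a latent class truth.

    Returns the n x n_items 0/1 matrix and a complete pattern-frequency
    table (all 2^n_items cells, zeros retained, lexicographic order).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mix = np.asarray(truth.mixing, dtype=float)
    cond = np.asarray(truth.conditionals, dtype=float)
    n_items = cond.shape[1]
    classes = rng.choice(mix.size, size=n, p=mix)
    x = (rng.random((n, n_items)) < cond[classes]).astype(np.int64)

    weights = 1 << np.arange(n_items - 1, -1, -1)
    codes = x @ weights
    counts = np.bincount(codes, minlength=1 << n_items)
    patterns = [format(i, f"0{n_items}b") for i in range(1 << n_items)]
    table = pd.DataFrame({"pattern": patterns, "count": counts})
    return x, table


def _solve_liability_threshold(
    marginal: float, shifts: np.ndarray, mixing: np.ndarray
) -> float:
    """Threshold t with sum_c pi_c * P(N(shift_c,1) > t) = marginal."""
    if marginal <= 0.0:
        return np.inf
    if marginal >= 1.0:
        return -np.inf

    def f(t: float) -> float:
        return float(np.sum(mixing * stats.norm.sf(t - shifts)) - marginal)

    lo, hi = shifts.min() - 12.0, shifts.max() + 12.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and an accelerometer daily-record table.

    The cohort table has one row per participant (demographics, four grip
    readings, walk time, binary items, questionnaire covariates, comorbidity
    flags and the ground-truth ``latent_class`` label). The accelerometer
    table has one row per participant-day (wear minutes, kcal/kg/day).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # Independent substreams so adding a draw to one block never perturbs others.
    streams = {
        k: np.random.default_rng(s)
        for k, s in zip(
            ["demo", "class", "cont", "items", "scores", "accel", "missing"],
            rng.integers(0, 2**31 - 1, size=7),
        )
    }
    n = cfg.n_participants
    mixing = np.asarray(cfg.class_mixing, dtype=float)
    shifts = np.asarray(cfg.class_effect_shifts, dtype=float)

    demo = streams["demo"]
    male = demo.random(n) < cfg.prop_male
    age = _truncnorm(demo, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)

    # Latent class: baseline mixing tilted by age so frailty rises with age.
    logit = np.log(np.clip(mixing, 1e-12, None))[None, :] + (
        cfg.age_class_slope * (age - cfg.age_mean)[:, None] * np.arange(mixing.size)[None, :]
    )
    probs = np.exp(logit - logit.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = streams["class"].random(n)
    latent = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    s_i = shifts[latent]

    cont = streams["cont"]
    height = np.where(
        male, cont.normal(162.0, 6.0, n), cont.normal(148.7, 6.0, n)
    ).round(1)
    bmi = np.clip(cont.normal(23.2, 3.2, n), 15.0, 38.0)
    weight = (bmi * (height / 100.0) ** 2).round(1)
    bmi = weight / (height / 100.0) ** 2  # keep the identity exact after rounding

    grip_mu = np.where(male, 36.0, 22.0)
    grip_sd = np.where(male, 6.0, 4.0)
    grip_true = np.clip(grip_mu + grip_sd * (cont.normal(size=n) - s_i), 2.0, None)
    grip = grip_true[:, None] + cont.normal(0.0, 1.2, (n, 4))
    grip = np.clip(grip, 0.0, None).round(1)

    walk_base = np.where(male, 2.95, 3.35)
    mu_h = np.where(male, 162.0, 148.7)
    log_walk = (
        np.log(walk_base)
        - 0.004 * (height - mu_h)
        + 0.16 * (cont.normal(size=n) + s_i)
        + 0.008 * (age - cfg.age_mean)
    )
    walk_time = np.exp(log_walk).round(2)

    aee_base = np.where(male, 8.3, 9.5)
    log_aee = (
        np.log(aee_base)
        + 0.30 * (cont.normal(size=n) - 0.8 * s_i)
        - 0.012 * (age - cfg.age_mean)
    )
    aee_true = np.exp(log_aee)

    # Binary items: liability threshold chosen so the population marginal
    # matches the configured rate, while the class shift moves per-class rates.
    items_rng = streams["items"]
    cols: dict[str, np.ndarray] = {}
    pi_marg = mixing  # thresholds are solved at the baseline mixing
    for name, marginal in cfg.marginal_rates.items():
        slope = _ITEM_SLOPES.get(name, 0.0)
        t = _solve_liability_threshold(marginal, slope * shifts, pi_marg)
        liab = slope * s_i + items_rng.normal(size=n)
        cols[name] = (liab > t).astype(np.int64)

    sc = streams["scores"]
    k6 = np.clip(np.round(sc.gamma(1.3, 2.0, n) * (1.0 + 0.8 * s_i)), 0, 24).astype(int)
    mmse = np.clip(30 - np.round(sc.gamma(1.2, 1.6, n) * (1.0 + 0.5 * s_i)), 0, 30).astype(int)
    lsns6 = np.clip(np.round(sc.normal(16.0, 5.0, n) - 2.5 * s_i), 0, 30).astype(int)
    education = np.clip(np.round(sc.normal(11.1, 2.5, n)), 6, 18).astype(int)
    income = sc.choice(["very poor", "poor/fair", "good"], size=n, p=[0.07, 0.55, 0.38])
    housing = sc.choice(["owned/mortgaged", "rented", "other"], size=n, p=[0.80, 0.15, 0.05])

    cohort = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(1, n + 1)],
            "gender": np.where(male, "male", "female"),
            "age": age.round(1),
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "grip1_left": grip[:, 0],
            "grip2_left": grip[:, 1],
            "grip1_right": grip[:, 2],
            "grip2_right": grip[:, 3],
            "walk_time_s": walk_time,
            "mmse": mmse,
            "k6": k6,
            "lsns6": lsns6,
            "education_years": education,
            "income": income,
            "housing": housing,
            "latent_class": latent,
        }
    )
    for name, v in cols.items():
        cohort[name] = v
    # Columns that can receive NaN must be float-typed up front.
    for col in set(_MISSABLE) | {"weight_loss", "exhaustion_q1", "exhaustion_q2"}:
        if col in cohort and cohort[col].dtype.kind in "iu":
            cohort[col] = cohort[col].astype(float)

    # Physical-test non-participation: all frailty measures missing.
    nonpart = streams["missing"].random(n) < cfg.nonparticipation_rate
    phys_cols = [
        "grip1_left", "grip2_left", "grip1_right", "grip2_right", "walk_time_s",
    ]
    cohort.loc[nonpart, phys_cols] = np.nan
    cohort.loc[nonpart, ["weight_loss", "exhaustion_q1", "exhaustion_q2"]] = np.nan

    # MCAR missingness on covariates only.
    if cfg.missing_rate > 0:
        miss = streams["missing"].random((n, len(_MISSABLE))) < cfg.missing_rate
        for j, col in enumerate(_MISSABLE):
            cohort.loc[miss[:, j], col] = np.nan

    # Accelerometer daily records.
    accel_rng = streams["accel"]
    nonwear = accel_rng.random(n) < cfg.nonwear_rate
    wear_mu, wear_sd = cfg.wear_minutes_model
    rows = []
    for i in range(n):
        days = accel_rng.integers(0, 3) if nonwear[i] else cfg.n_days
        if days == 0:
            continue
        wear = np.clip(accel_rng.normal(wear_mu, wear_sd, days), 0.0, 1440.0).round(0)
        day_aee = (aee_true[i] * np.exp(accel_rng.normal(0.0, 0.08, days))).round(3)
        for d in range(days):
            rows.append((cohort.at[i, "id"], d + 1, wear[d], day_aee[d]))
    accel = pd.DataFrame(
        rows, columns=["participant_id", "day_index", "wear_minutes", "aee"]
    )
    return cohort, accel
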