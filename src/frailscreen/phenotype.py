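"""Frailty-phenotype operationalisation.

The phenotype has five dichotomous components — shrinking (self-reported
unintentional weight loss), weakness (low grip strength), exhaustion (two
self-report questions), slowness (slow timed 5-m walk) and low physical
activity (low accelerometer AEE). Weakness, slowness and low activity are
defined against population-specific quintile cut-offs: the worst 20% within
gender x BMI band (grip), gender x height band split at the gender median
(walk time) and gender (AEE). 0 components = non-frail, 1-2 = pre-frail,
>= 3 = frail.

Cut-offs may be derived from the cohort at hand (``derive_cutoffs``), loaded
from file, or taken from the shipped constants of the Sasaguri Genkimon
Study (``FrailtyCutoffs.sasaguri()``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BMI_BANDS",
    "AGE_BANDS",
    "STATUS_LABELS",
    "FrailtyCutoffs",
    "FrailtyPhenotype",
    "grip_strength",
    "apply_exclusions",
    "derive_cutoffs",
    "score_components",
    "classify_status",
    "prevalence_table",
    "wald_ci",
]

BMI_BANDS = ("bmi_lt_18.5", "bmi_18.5_25", "bmi_25_30", "bmi_ge_30")
STATUS_LABELS = ("non-frail", "pre-frail", "frail")
AGE_BANDS = ((65, 69), (70, 74), (75, 79), (80, 84), (85, None))

_GRIP_COLS = ["grip1_left", "grip2_left", "grip1_right", "grip2_right"]
_COMPONENT_INPUTS = ["walk_time_s", "weight_loss", "exhaustion_q1", "exhaustion_q2"]


def bmi_band(bmi: float) -> str:
    if bmi < 18.5:
        return BMI_BANDS[0]
    if bmi < 25.0:
        return BMI_BANDS[1]
    if bmi < 30.0:
        return BMI_BANDS[2]
    return BMI_BANDS[3]


def quintile_cutpoint(values: np.ndarray, q: float) -> float:
    """q-th quantile as an attained sample value (inverse empirical CDF).

    Returns the smallest observed value v such that at least a fraction q of
    the observations are <= v; cut-offs are therefore always attained values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty stratum")
    return float(np.quantile(v, q, method="inverted_cdf"))


@dataclass
class FrailtyCutoffs:
    """All stratified cut-off values of the phenotype.

    grip: gender -> BMI band -> kg (lowest-quintile boundary, inclusive)
    gait_time: gender -> {"short","tall"} -> seconds (highest quintile, inclusive)
    aee: gender -> kcal/kg/day (lowest quintile, inclusive)
    height_medians: gender -> cm (boundary between short and tall bands)
    """

    grip: dict
    gait_time: dict
    aee: dict
    height_medians: dict

    def __post_init__(self) -> None:
        for gender in ("male", "female"):
            if set(self.grip[gender]) != set(BMI_BANDS):
                raise ValueError(f"grip cut-offs for {gender} must cover {BMI_BANDS}")
            if set(self.gait_time[gender]) != {"short", "tall"}:
                raise ValueError("gait cut-offs need 'short' and 'tall' cells")
        values = (
            [v for g in self.grip.values() for v in g.values()]
            + [v for g in self.gait_time.values() for v in g.values()]
            + list(self.aee.values())
        )
        arr = np.asarray(values, dtype=float)
        if not (np.isfinite(arr).all() and (arr > 0).all()):
            raise ValueError("all cut-offs must be positive and finite")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FrailtyCutoffs":
        return cls(
            grip=d["grip"],
            gait_time=d["gait_time"],
            aee=d["aee"],
            height_medians=d["height_medians"],
        )

    @classmethod
    def from_json(cls, path) -> "FrailtyCutoffs":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def sasaguri(cls) -> "FrailtyCutoffs":
        """The published cut-offs of the Sasaguri Genkimon baseline cohort."""
        raw = json.loads(
            resources.files("frailscreen.data")
            .joinpath("sasaguri_cutoffs.json")
            .read_text()
        )
        return cls(
            grip=raw["grip_kg"],
            gait_time=raw["gait_time_s"],
            aee=raw["aee_kcal_kg_day"],
            height_medians=raw["height_median_cm"],
        )


def grip_strength(readings) -> tuple[float, bool]:
    """Grip strength in kg from up to two readings per hand.

    Takes (left1, left2, right1, right2); NaN marks a missing reading. The
    score is the mean of the per-hand maxima. With one hand entirely missing
    the other hand's maximum is returned with single_hand=True.

    Returns (kg, single_hand). Raises if no reading at all is present.
    """
    r = np.asarray(readings, dtype=float)
    if r.shape != (4,):
        raise ValueError("expected four readings: left x2, right x2")
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("grip readings must be non-negative")
    left, right = r[:2], r[2:]
    has_l, has_r = np.isfinite(left).any(), np.isfinite(right).any()
    if not (has_l or has_r):
        raise ValueError("no grip readings present")
    if has_l and has_r:
        return (np.nanmax(left) + np.nanmax(right)) / 2.0, False
    return float(np.nanmax(left if has_l else right)), True


def _grip_column(cohort: pd.DataFrame) -> pd.Series:
    """Vectorised grip score (NaN where no reading exists)."""
    g = cohort[_GRIP_COLS].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        left = np.nanmax(g[:, :2], axis=1)
        right = np.nanmax(g[:, 2:], axis=1)
        both = np.nanmean(np.column_stack([left, right]), axis=1)
    return pd.Series(both, index=cohort.index, name="grip_kg")


def apply_exclusions(
    cohort: pd.DataFrame, accel_summaries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study exclusion funnel; returns (retained, exclusion_log).

    Rules, in order (the log records the first matching rule per row):
      1. no_physical_tests  — every frailty measure missing
      2. neurological_or_mmse — dementia / Parkinson / stroke history, or MMSE < 18
      3. accelerometer       — fewer than 3 valid wear days (or no device data)
      4. missing_component   — any remaining component input missing

    The retained table gains ``grip_kg``, ``grip_single_hand`` and
    ``mean_aee`` columns.
    """
    if cohort["id"].duplicated().any():
        dupes = cohort.loc[cohort["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dupes[:5]}")

    df = cohort.copy()
    df["grip_kg"] = _grip_column(df)
    df["grip_single_hand"] = (
        df[_GRIP_COLS[:2]].isna().all(axis=1) ^ df[_GRIP_COLS[2:]].isna().all(axis=1)
    )
    acc = accel_summaries.set_index("participant_id")
    df["mean_aee"] = df["id"].map(acc["mean_aee"])
    df["accel_eligible"] = (
        df["id"].map(acc["eligible"]).astype("boolean").fillna(False).astype(bool)
    )

    phys_missing = (
        df["grip_kg"].isna()
        & df[_COMPONENT_INPUTS].isna().all(axis=1)
    )
    neuro = (
        (df.get("history_dementia", 0) == 1)
        | (df.get("history_parkinson", 0) == 1)
        | (df.get("history_stroke", 0) == 1)
        | (df["mmse"] < 18)
    )
    accel_out = ~df["accel_eligible"]
    component_missing = (
        df["grip_kg"].isna()
        | df[_COMPONENT_INPUTS].isna().any(axis=1)
        | df[["gender", "bmi", "height_cm"]].isna().any(axis=1)
    )

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    for rule, mask in [
        ("no_physical_tests", phys_missing),
        ("neurological_or_mmse", neuro),
        ("accelerometer", accel_out),
        ("missing_component", component_missing),
    ]:
        reason = reason.mask(reason.isna() & mask.fillna(False), rule)

    excluded = reason.notna()
    log = pd.DataFrame({"id": df.loc[excluded, "id"], "reason": reason[excluded]})
    retained = df.loc[~excluded].drop(columns=["accel_eligible"]).reset_index(drop=True)
    return retained, log.reset_index(drop=True)


def derive_cutoffs(cohort: pd.DataFrame, q: float = 0.20) -> FrailtyCutoffs:
    """Derive the stratified quintile cut-offs from a retained cohort.

    Requires gender, bmi, height_cm, walk_time_s, mean_aee and either a
    grip_kg column or the four raw grip readings. Grip and AEE use the
    lowest-q quantile; walk time uses the highest-q (1-q) quantile. Height
    bands split at the within-gender median height.
    """
    df = cohort.copy()
    if "grip_kg" not in df:
        df["grip_kg"] = _grip_column(df)

    grip: dict = {}
    gait: dict = {}
    aee: dict = {}
    medians: dict = {}
    for gender in ("male", "female"):
        sub = df[df["gender"] == gender]
        if sub.empty:
            raise ValueError(f"empty stratum: gender={gender}")
        medians[gender] = float(np.median(sub["height_cm"]))
        grip[gender] = {}
        for band in BMI_BANDS:
            cell = sub[sub["bmi"].map(bmi_band) == band]["grip_kg"].dropna()
            if cell.empty:
                raise ValueError(f"empty stratum: gender={gender}, band={band}")
            if len(cell) < 5:
                warnings.warn(
                    f"stratum gender={gender}, band={band} has only {len(cell)} members",
                    stacklevel=2,
                )
            grip[gender][band] = quintile_cutpoint(cell.to_numpy(), q)
        gait[gender] = {}
        for label, mask in [
            ("short", sub["height_cm"] < medians[gender]),
            ("tall", sub["height_cm"] >= medians[gender]),
        ]:
            cell = sub[mask]["walk_time_s"].dropna()
            if cell.empty:
                raise ValueError(f"empty stratum: gender={gender}, height={label}")
            gait[gender][label] = quintile_cutpoint(cell.to_numpy(), 1.0 - q)
        aee[gender] = quintile_cutpoint(sub["mean_aee"].dropna().to_numpy(), q)
    return FrailtyCutoffs(grip=grip, gait_time=gait, aee=aee, height_medians=medians)


def classify_status(flags) -> tuple[int, str]:
    """(n_components, status) from the five component flags."""
    flags = [bool(f) for f in flags]
    if len(flags) != 5:
        raise ValueError("exactly five component flags expected")
    n = sum(flags)
    return n, STATUS_LABELS[0] if n == 0 else (STATUS_LABELS[1] if n <= 2 else STATUS_LABELS[2])


def score_components(cohort: pd.DataFrame, cutoffs: FrailtyCutoffs) -> pd.DataFrame:
    """Score the five components against cut-offs; boundary values flag.

    Expects a retained cohort (complete component inputs, mean_aee merged).
    Returns one row per participant with the flags, n_components and status,
    carrying gender/age through for stratified prevalence tables.
    """
    df = cohort.copy()
    if "grip_kg" not in df:
        df["grip_kg"] = _grip_column(df)

    gender = df["gender"].to_numpy()
    grip_cut = np.array(
        [cutoffs.grip[g][bmi_band(b)] for g, b in zip(gender, df["bmi"].to_numpy())]
    )
    med = np.array([cutoffs.height_medians[g] for g in gender])
    band = np.where(df["height_cm"].to_numpy() < med, "short", "tall")
    gait_cut = np.array([cutoffs.gait_time[g][b] for g, b in zip(gender, band)])
    aee_cut = np.array([cutoffs.aee[g] for g in gender])

    out = pd.DataFrame({"id": df["id"].to_numpy()})
    out["shrinking"] = df["weight_loss"].to_numpy() == 1
    out["weakness"] = df["grip_kg"].to_numpy() <= grip_cut
    out["exhaustion"] = (df["exhaustion_q1"].to_numpy() == 1) | (
        df["exhaustion_q2"].to_numpy() == 1
    )
    out["slowness"] = df["walk_time_s"].to_numpy() >= gait_cut
    out["low_pa"] = df["mean_aee"].to_numpy() <= aee_cut
    out["n_components"] = out[list(COMPONENT_NAMES)].sum(axis=1).astype(int)
    out["status"] = pd.Categorical(
        np.where(
            out["n_components"] == 0,
            STATUS_LABELS[0],
            np.where(out["n_components"] <= 2, STATUS_LABELS[1], STATUS_LABELS[2]),
        ),
        categories=list(STATUS_LABELS),
        ordered=True,
    )
    for carry in ("gender", "age"):
        if carry in df:
            out[carry] = df[carry].to_numpy()
    return out


COMPONENT_NAMES = ("shrinking", "weakness", "exhaustion", "slowness", "low_pa")


def wald_ci(count: int, n: int) -> tuple[float, float, float]:
    """Percentage and 95% Wald interval, clipped to [0, 100]."""
    if n <= 0:
        return float("nan"), float("nan"), float("nan")
    p = count / n
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return 100.0 * p, max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half))


def _age_band(age: float) -> str:
    for lo, hi in AGE_BANDS:
        if hi is None:
            if age >= lo:
                return f"{lo}+"
        elif lo <= age < hi + 1:  # e.g. 79.1 still belongs to 75-79
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside supported bands")


def prevalence_table(
    assessments: pd.DataFrame, grouping: str = "overall"
) -> pd.DataFrame:
    """Prevalence of each frailty status as percentages with 95% Wald CIs.

    grouping: "overall", "gender", or "gender_age" (5-year bands 65-69 ...
    85+). Empty groups yield n=0 rows with NaN percentages.
    """
    if assessments.empty:
        raise ValueError("no assessments to tabulate")
    df = assessments.copy()
    if grouping == "overall":
        df["_group"] = "all"
        keys = ["_group"]
    elif grouping == "gender":
        keys = ["gender"]
    elif grouping == "gender_age":
        df["age_band"] = df["age"].map(_age_band)
        keys = ["gender", "age_band"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for key, grp in df.groupby(keys, observed=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        for status in STATUS_LABELS:
            count = int((grp["status"] == status).sum())
            pct, lo, hi = wald_ci(count, n)
            rows.append((*key, status, n, count, pct, lo, hi))
    cols = [k.lstrip("_") for k in keys] + [
        "status", "n", "count", "pct", "ci_low", "ci_high",
    ]
    return pd.DataFrame(rows, columns=cols)


class FrailtyPhenotype(BaseEstimator, TransformerMixin):
    """Scores frailty phenotypes against derived or fixed cut-offs.

    Parameters
    ----------
    cutoffs : "derive", "sasaguri", a FrailtyCutoffs, or a JSON path.
        "derive" recomputes population-specific quintile cut-offs from the
        cohort passed to :meth:`fit`; "sasaguri" uses the shipped published
        constants.
    quantile : float, default 0.2
        Worst-quintile fraction used when deriving.

    Attributes
    ----------
    cutoffs_ : FrailtyCutoffs
        The cut-offs used by :meth:`transform`.
    """

    def __init__(self, cutoffs: object = "derive", quantile: float = 0.20):
        self.cutoffs = cutoffs
        self.quantile = quantile

    def fit(self, X: pd.DataFrame, y=None) -> "FrailtyPhenotype":
        if isinstance(self.cutoffs, FrailtyCutoffs):
            self.cutoffs_ = self.cutoffs
        elif self.cutoffs == "derive":
            self.cutoffs_ = derive_cutoffs(X, q=self.quantile)
        elif self.cutoffs == "sasaguri":
            self.cutoffs_ = FrailtyCutoffs.sasaguri()
        else:
            self.cutoffs_ = FrailtyCutoffs.from_json(self.cutoffs)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            raise RuntimeError("FrailtyPhenotype is not fitted")
        return score_components(X, self.cutoffs_)
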