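"""Correlates of frailty status: trend tests, polytomous logistic models,
backward elimination and model diagnostics.

The 3-level frailty status (non-frail / pre-frail / frail) is the outcome.
Association screening uses the Cochran-Mantel-Haenszel nonzero-correlation
statistic with integer scores. Odds ratios come from a generalized-logit
(multinomial) model with non-frail as the reference, giving one contrast
for pre-frail and one for frail; a two-binary-fit mode exists for
sensitivity. Backward elimination removes, one at a time, the term with the
largest likelihood-ratio p at or above the threshold, testing each term
jointly across both contrasts. Diagnostics: variance inflation factors,
per-contrast Hosmer-Lemeshow tests and Nagelkerke's R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "trend_test",
    "fit_polytomous",
    "backward_eliminate",
    "vif",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "PolytomousResult",
    "build_design",
]

_STATUS_ORDER = ("non-frail", "pre-frail", "frail")


def _status_codes(status: pd.Series) -> np.ndarray:
    codes = pd.Categorical(status, categories=list(_STATUS_ORDER), ordered=True).codes
    if (codes < 0).any():
        bad = set(pd.unique(status)) - set(_STATUS_ORDER)
        raise ValueError(f"unknown status labels: {bad}")
    return codes.astype(int)


def trend_test(factor, status) -> tuple[float, float]:
    """CMH nonzero-correlation test of a factor against ordered status.

    Integer scores (0,1,2 for status; level codes for the factor); the
    single-stratum statistic is (n-1) * r^2 with 1 df, r the Pearson
    correlation of the scores. Returns (statistic, two-sided p).
    """
    f = pd.Series(factor).reset_index(drop=True)
    s = pd.Series(status).reset_index(drop=True)
    keep = f.notna() & s.notna()
    f, s = f[keep], s[keep]
    if f.dtype == object or isinstance(f.dtype, pd.CategoricalDtype):
        u = np.asarray(pd.Categorical(f).codes, dtype=float)
    else:
        u = f.to_numpy(dtype=float)
    v = _status_codes(s).astype(float)
    n = u.size
    if n < 2 or np.ptp(u) == 0 or np.ptp(v) == 0:
        warnings.warn("constant factor or status: trend statistic undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    r = np.corrcoef(u, v)[0, 1]
    statistic = (n - 1) * r * r
    return float(statistic), float(stats.chi2.sf(statistic, 1))


def build_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design matrix: numeric columns pass through, object or
    categorical columns are dummy-coded dropping the first level."""
    pieces = []
    for term in terms:
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            pieces.append(d)
        else:
            pieces.append(col.astype(float).to_frame(term))
    if not pieces:
        return pd.DataFrame(index=data.index)
    return pd.concat(pieces, axis=1)


@dataclass
class PolytomousResult:
    """Fitted polytomous (or paired-binary) logistic model.

    ``table`` has one row per (term, contrast) with coef, SE, OR, Wald CI
    and p; ``loglik``/``loglik_null`` support LR tests and Nagelkerke R^2.
    """

    table: pd.DataFrame
    loglik: float
    loglik_null: float
    n: int
    n_dropped: int
    terms: list[str]
    mode: str
    separation: bool
    diagnostics: dict = field(default_factory=dict)
    _fit: object | None = None
    _design: pd.DataFrame | None = None
    _codes: np.ndarray | None = None


def _extract_table(params, bse, design_cols, term_of_col, contrasts) -> pd.DataFrame:
    rows = []
    for j, contrast in enumerate(contrasts):
        for i, col in enumerate(design_cols):
            coef = params[i, j]
            se = bse[i, j]
            z = coef / se if se > 0 else np.nan
            rows.append(
                {
                    "term": term_of_col[col],
                    "column": col,
                    "contrast": contrast,
                    "coef": coef,
                    "se": se,
                    "or": np.exp(coef),
                    "ci_low": np.exp(coef - 1.96 * se),
                    "ci_high": np.exp(coef + 1.96 * se),
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def fit_polytomous(
    data: pd.DataFrame,
    terms: list[str],
    status_col: str = "status",
    mode: str = "multinomial",
) -> PolytomousResult:
    """Fit frailty-status logistic model(s) with non-frail as reference.

    mode="multinomial" (default) fits one generalized-logit model yielding
    both contrasts jointly; mode="binary" fits two separate binary models
    (pre-frail vs non-frail, frail vs non-frail) on the respective subsets.
    Rows with any missing term are dropped and counted (``n_dropped``).
    """
    cols = terms + [status_col]
    complete = data[cols].dropna()
    n_dropped = len(data) - len(complete)
    X = build_design(complete, terms)
    term_of_col = {}
    for term in terms:
        for col in X.columns:
            if col == term or col.startswith(term + "_"):
                term_of_col[col] = term
    y = _status_codes(complete[status_col])
    levels = sorted(pd.unique(y))
    if 0 not in levels or len(levels) < 2:
        raise ValueError("outcome needs the non-frail reference plus >=1 other level")
    _names = {1: "pre-frail vs non-frail", 2: "frail vs non-frail"}
    contrasts = [_names[lv] for lv in levels if lv != 0]

    if mode == "multinomial":
        exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        model = sm.MNLogit(y, exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=200, disp=0)
        params = np.asarray(fit.params)[1:, :]  # drop intercept row
        bse = np.asarray(fit.bse)[1:, :]
        table = _extract_table(params, bse, list(X.columns), term_of_col, contrasts)
        probs = np.asarray(fit.predict(exog))
        separation = bool(
            ((probs < 1e-8) | (probs > 1 - 1e-8)).any()
            and (np.abs(params) > 10).any()
        )
        res = PolytomousResult(
            table=table,
            loglik=float(fit.llf),
            loglik_null=float(fit.llnull),
            n=len(complete),
            n_dropped=n_dropped,
            terms=list(terms),
            mode=mode,
            separation=separation,
        )
        res._fit = fit
        res._design = X
        res._codes = y
        return res

    if mode != "binary":
        raise ValueError("mode must be 'multinomial' or 'binary'")
    rows, lls, llnulls, seps = [], [], [], []
    for level, contrast in zip([lv for lv in levels if lv != 0], contrasts):
        mask = (y == 0) | (y == level)
        yb = (y[mask] == level).astype(float)
        exog = sm.add_constant(X.to_numpy(dtype=float)[mask], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yb, exog).fit(method="newton", maxiter=200, disp=0)
        params = np.asarray(fit.params)[1:, None]
        bse = np.asarray(fit.bse)[1:, None]
        rows.append(_extract_table(params, bse, list(X.columns), term_of_col,
                                   [contrast]))
        lls.append(float(fit.llf))
        llnulls.append(float(fit.llnull))
        probs = np.asarray(fit.predict(exog))
        seps.append(bool(((probs < 1e-8) | (probs > 1 - 1e-8)).any()
                         and (np.abs(params) > 10).any()))
    res = PolytomousResult(
        table=pd.concat(rows, ignore_index=True),
        loglik=sum(lls),
        loglik_null=sum(llnulls),
        n=len(complete),
        n_dropped=n_dropped,
        terms=list(terms),
        mode=mode,
        separation=any(seps),
    )
    res._design = X
    res._codes = y
    return res


def fit_univariate(
    data: pd.DataFrame,
    terms: list[str],
    status_col: str = "status",
    mode: str = "multinomial",
) -> pd.DataFrame:
    """One single-term model per covariate; stacked OR table."""
    pieces = []
    for term in terms:
        res = fit_polytomous(data, [term], status_col=status_col, mode=mode)
        t = res.table.copy()
        t["model"] = "univariate"
        pieces.append(t)
    return pd.concat(pieces, ignore_index=True)


def _lr_term_pvalues(
    data: pd.DataFrame, terms: list[str], status_col: str, mode: str,
    full: PolytomousResult,
) -> dict[str, float]:
    """Likelihood-ratio p per term, jointly across both contrasts."""
    pvals = {}
    complete = data[terms + [status_col]].dropna()
    for term in terms:
        reduced = [t for t in terms if t != term]
        if reduced:
            red = fit_polytomous(complete, reduced, status_col=status_col, mode=mode)
            ll_red = red.loglik
        else:
            ll_red = full.loglik_null
        n_cols = len([c for c in full._design.columns
                      if c == term or c.startswith(term + "_")])
        df = full.table["contrast"].nunique() * n_cols  # joint across contrasts
        lr = 2.0 * (full.loglik - ll_red)
        pvals[term] = float(stats.chi2.sf(max(lr, 0.0), df))
    return pvals


def backward_eliminate(
    data: pd.DataFrame,
    terms: list[str],
    threshold: float = 0.05,
    forced: list[str] | None = None,
    status_col: str = "status",
    mode: str = "multinomial",
) -> tuple[PolytomousResult, pd.DataFrame]:
    """Backward elimination by likelihood-ratio tests.

    Repeatedly drops the removable term with the largest LR p >= threshold
    (tested jointly over both contrasts) until every remaining removable
    term has p < threshold. ``forced`` terms (e.g. the comorbidity
    adjustment set) are never removed. The complete-case sample is fixed at
    the initial term set so nested models stay comparable.

    Returns the final fit and a trace table (step, term, p).
    """
    forced = list(forced or [])
    current = [t for t in terms if t not in forced]
    # Fix the analysis sample once so every nested fit uses the same rows.
    sample = data[list(dict.fromkeys(current + forced + [status_col]))].dropna()
    trace = []
    step = 0
    while True:
        fit = fit_polytomous(sample, current + forced, status_col=status_col,
                             mode=mode)
        removable = [t for t in current if t not in forced]
        if not removable:
            break
        pvals = _lr_term_pvalues(sample, current + forced, status_col, mode, fit)
        worst = max(removable, key=lambda t: pvals[t])
        if pvals[worst] < threshold:
            break
        step += 1
        trace.append({"step": step, "removed": worst, "p": pvals[worst]})
        current.remove(worst)
    final = fit_polytomous(sample, current + forced, status_col=status_col,
                           mode=mode)
    final.n_dropped = len(data) - len(sample)
    return final, pd.DataFrame(trace, columns=["step", "removed", "p"])


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column: 1 / (1 - R^2_j).

    R^2_j is from the OLS regression (with intercept) of column j on the
    remaining columns. Perfect collinearity yields inf.
    """
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss <= 0:
            out[name] = float("nan")
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def hosmer_lemeshow(
    y: np.ndarray, p: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit for a binary fit.

    Groups observations by deciles of fitted risk (ties kept together;
    fewer distinct values reduce the group count with a warning);
    stat = sum (O_g - E_g)^2 / (E_g (1 - E_g/n_g)), df = groups - 2.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    try:
        bins = pd.qcut(p, groups, duplicates="drop")
    except ValueError:
        bins = pd.qcut(p, 2, duplicates="drop")
    g = pd.DataFrame({"y": y, "p": p, "bin": bins}).groupby("bin", observed=True)
    n_g = g.size().to_numpy(dtype=float)
    used = len(n_g)
    if used < groups:
        warnings.warn(
            f"tied fitted values reduced Hosmer-Lemeshow groups to {used}",
            stacklevel=2,
        )
    obs = g["y"].sum().to_numpy(dtype=float)
    exp = g["p"].sum().to_numpy(dtype=float)
    denom = exp * (1.0 - exp / n_g)
    denom = np.clip(denom, 1e-12, None)
    statistic = float((((obs - exp) ** 2) / denom).sum())
    df = max(used - 2, 1)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def hosmer_lemeshow_contrasts(
    result: PolytomousResult, groups: int = 10
) -> dict[str, tuple[float, int, float]]:
    """Hosmer-Lemeshow per binary contrast of a fitted multinomial model.

    Each contrast is evaluated on the subset of reference + that level,
    using the conditional probability p_level / (p_ref + p_level).
    """
    if result._fit is None or result._design is None:
        raise ValueError("requires a multinomial fit with retained design")
    X = result._design.to_numpy(dtype=float)
    exog = sm.add_constant(X, has_constant="add")
    probs = np.asarray(result._fit.predict(exog))
    y = result._codes
    out = {}
    for level, name in ((1, "pre-frail vs non-frail"), (2, "frail vs non-frail")):
        mask = (y == 0) | (y == level)
        cond_p = probs[mask, level] / (probs[mask, 0] + probs[mask, level])
        out[name] = hosmer_lemeshow((y[mask] == level).astype(float), cond_p,
                                    groups=groups)
    return out


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's R^2: Cox-Snell divided by its attainable maximum."""
    if loglik < loglik_null - 1e-6:
        raise ValueError("model log-likelihood below null: optimizer failure")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))
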