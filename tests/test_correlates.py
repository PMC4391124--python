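"""Trend tests, logistic odds ratios, elimination and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailscreen.correlates import (
    backward_eliminate,
    build_design,
    fit_polytomous,
    fit_univariate,
    hosmer_lemeshow,
    nagelkerke_r2,
    trend_test,
    vif,
)

STATUSES = ["non-frail", "pre-frail", "frail"]


def expand_table(counts_by_x):
    """counts_by_x: {x_value: (n_nonfrail, n_prefrail, n_frail)} -> long df."""
    rows = []
    for x, counts in counts_by_x.items():
        for status, k in zip(STATUSES, counts):
            rows += [{"x": float(x), "status": status}] * k
    return pd.DataFrame(rows)


class TestTrendTest:
    def test_hand_computed_small_table(self):
        # 2x3 table with monotone proportions; the CMH correlation
        # statistic is (n-1) r^2 = 119 * (1/6)/ ... = 119/6 exactly.
        df = expand_table({0: (30, 20, 10), 1: (10, 20, 30)})
        stat, p = trend_test(df["x"], df["status"])
        assert stat == pytest.approx(119.0 / 6.0, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(119.0 / 6.0, 1), rel=1e-12)

    def test_null_statistic_small_under_independence(self):
        rng = np.random.default_rng(0)
        n = 10000
        df = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n).astype(float),
                "status": rng.choice(STATUSES, n),
            }
        )
        stat, p = trend_test(df["x"], df["status"])
        assert stat < 6.0  # ~chi2(1) under the null
        assert p > 0.01

    def test_perfect_association_extreme(self):
        df = expand_table({0: (200, 0, 0), 1: (0, 0, 200)})
        stat, p = trend_test(df["x"], df["status"])
        assert p < 1e-6

    def test_constant_factor_flagged_undefined(self):
        df = expand_table({1: (5, 5, 5)})
        with pytest.warns(UserWarning, match="constant"):
            stat, p = trend_test(df["x"], df["status"])
        assert np.isnan(stat)


class TestOddsRatioIdentities:
    @pytest.mark.parametrize("mode", ["multinomial", "binary"])
    def test_binary_predictor_or_equals_cross_product_ratio(self, mode):
        # per contrast 2x2 (level vs non-frail): OR = ad/bc, Wald SE =
        # sqrt(1/a+1/b+1/c+1/d)
        counts = {0: (120, 60, 20), 1: (80, 90, 45)}
        df = expand_table(counts)
        res = fit_polytomous(df, ["x"], mode=mode)
        for level, contrast in [(1, "pre-frail vs non-frail"),
                                (2, "frail vs non-frail")]:
            a = counts[1][level]   # exposed cases
            b = counts[0][level]   # unexposed cases
            c = counts[1][0]       # exposed reference
            d = counts[0][0]       # unexposed reference
            or_expected = (a * d) / (b * c)
            se_expected = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            row = res.table[res.table["contrast"] == contrast].iloc[0]
            assert row["or"] == pytest.approx(or_expected, rel=1e-5)
            assert row["se"] == pytest.approx(se_expected, rel=1e-4)
            assert row["ci_low"] == pytest.approx(
                np.exp(np.log(or_expected) - 1.96 * se_expected), rel=1e-4
            )

    def test_independent_predictor_or_near_one(self):
        rng = np.random.default_rng(1)
        n = 4000
        df = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n).astype(float),
                "status": rng.choice(STATUSES, n, p=[0.47, 0.44, 0.09]),
            }
        )
        res = fit_polytomous(df, ["x"])
        assert ((res.table["ci_low"] < 1.0) & (res.table["ci_high"] > 1.0)).all()

    def test_null_loglik_is_multinomial_baseline(self):
        df = expand_table({0: (50, 30, 20), 1: (40, 35, 25)})
        res = fit_polytomous(df, ["x"])
        counts = df["status"].value_counts()
        n = counts.sum()
        ll0 = float((counts * np.log(counts / n)).sum())
        assert res.loglik_null == pytest.approx(ll0, abs=1e-6)

    def test_complete_case_counting(self):
        df = expand_table({0: (40, 30, 10), 1: (40, 30, 10)})
        df.loc[df.index[:13], "x"] = np.nan
        res = fit_polytomous(df, ["x"])
        assert res.n == len(df) - 13
        assert res.n_dropped == 13

    def test_known_age_effect_recovered(self):
        """Continuous log-odds of 0.23/yr for the frail contrast (OR 1.26)
        is recovered within 15% relative error at n=5000."""
        rng = np.random.default_rng(7)
        n = 5000
        age = rng.uniform(65, 93, n)
        z = age - 73.0
        # generalized-logit truth: eta1 = 0.09 z - 0.1, eta2 = 0.23 z - 2.2
        e1, e2 = np.exp(0.09 * z - 0.1), np.exp(0.23 * z - 2.2)
        denom = 1 + e1 + e2
        u = rng.random(n)
        p0, p1 = 1 / denom, e1 / denom
        status = np.where(u < p0, STATUSES[0], np.where(u < p0 + p1, STATUSES[1], STATUSES[2]))
        df = pd.DataFrame({"age": age, "status": status})
        res = fit_polytomous(df, ["age"])
        row = res.table[res.table["contrast"] == "frail vs non-frail"].iloc[0]
        assert abs(row["or"] - np.exp(0.23)) / np.exp(0.23) < 0.15


class TestBackwardElimination:
    @staticmethod
    def _signal_noise_data(n=3000, seed=3):
        rng = np.random.default_rng(seed)
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        e1, e2 = np.exp(0.8 * signal - 0.2), np.exp(1.2 * signal - 1.5)
        denom = 1 + e1 + e2
        u = rng.random(n)
        p0, p1 = 1 / denom, e1 / denom
        status = np.where(u < p0, STATUSES[0],
                          np.where(u < p0 + p1, STATUSES[1], STATUSES[2]))
        return pd.DataFrame({"signal": signal, "noise": noise, "status": status})

    def test_noise_term_removed_first(self):
        df = self._signal_noise_data()
        final, trace = backward_eliminate(df, ["signal", "noise"], threshold=0.05)
        assert list(trace["removed"]) == ["noise"]
        assert final.terms == ["signal"]

    def test_threshold_one_removes_nothing(self):
        df = self._signal_noise_data(n=500)
        final, trace = backward_eliminate(df, ["signal", "noise"], threshold=1.1)
        assert trace.empty
        assert set(final.terms) == {"signal", "noise"}

    def test_threshold_zero_removes_everything_removable(self):
        df = self._signal_noise_data(n=500)
        final, trace = backward_eliminate(df, ["signal", "noise"], threshold=0.0)
        assert final.terms == []
        assert len(trace) == 2

    def test_forced_terms_never_removed(self):
        df = self._signal_noise_data(n=800)
        final, trace = backward_eliminate(
            df, ["signal", "noise"], threshold=0.0, forced=["noise"]
        )
        assert "noise" in final.terms
        assert "noise" not in set(trace["removed"])


class TestVIF:
    # centered orthonormal design columns
    _u = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
    _v = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    _w = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0

    def test_orthogonal_columns_give_unity(self):
        d = pd.DataFrame({"a": self._u, "b": self._v, "c": self._w})
        assert np.allclose(vif(d), 1.0, atol=1e-10)

    def test_correlation_point_six_gives_closed_form(self):
        d = pd.DataFrame({"a": self._u, "b": 0.6 * self._u + 0.8 * self._v,
                          "c": self._w})
        out = vif(d)
        assert out["a"] == pytest.approx(1.0 / (1.0 - 0.36), rel=1e-9)
        assert out["b"] == pytest.approx(1.0 / (1.0 - 0.36), rel=1e-9)
        assert out["c"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_infinite(self):
        d = pd.DataFrame({"a": self._u, "b": self._u})
        assert np.isinf(vif(d)).all()


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 500)
        y = (rng.random(500) < p).astype(float)
        _, df, _ = hosmer_lemeshow(y, p, groups=10)
        assert df == 8

    def test_ties_reduce_groups_with_warning(self):
        p = np.repeat([0.2, 0.8], 100)
        y = (np.random.default_rng(1).random(200) < p).astype(float)
        with pytest.warns(UserWarning, match="reduced"):
            _, df, _ = hosmer_lemeshow(y, p, groups=10)
        assert df == max(2 - 2, 1)

    def test_calibrated_model_not_rejected(self):
        """Median p over seeded logistic fits of well-specified data sits in
        the central range — the test does not systematically reject."""
        import statsmodels.api as sm

        pvals = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.normal(size=n)
            p = 1.0 / (1.0 + np.exp(-(0.8 * x - 0.3)))
            y = (rng.random(n) < p).astype(float)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            phat = np.asarray(fit.predict(sm.add_constant(x)))
            pvals.append(hosmer_lemeshow(y, phat)[2])
        assert 0.2 <= np.median(pvals) <= 0.8


class TestNagelkerke:
    def test_zero_when_model_equals_null(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_formula_against_direct_evaluation(self):
        l0, l1, n = -3000.0, -2400.0, 5000
        cs = 1 - np.exp((2 / n) * (l0 - l1))
        expected = cs / (1 - np.exp((2 / n) * l0))
        assert nagelkerke_r2(l1, l0, n) == pytest.approx(expected, abs=1e-9)

    def test_perfect_prediction_limit(self):
        # loglik -> 0 while the null stays fixed drives R^2 to 1
        assert nagelkerke_r2(-1e-9, -500.0, 800) == pytest.approx(1.0, abs=1e-6)

    def test_optimizer_failure_detected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-110.0, -100.0, 50)


def test_univariate_stacks_single_term_models():
    df = expand_table({0: (50, 30, 20), 1: (40, 35, 25)})
    df["z"] = np.tile([0.0, 1.0], len(df) // 2)
    out = fit_univariate(df, ["x", "z"])
    assert set(out["term"]) == {"x", "z"}
    assert (out["model"] == "univariate").all()


def test_categorical_terms_dummy_coded():
    rng = np.random.default_rng(5)
    n = 600
    df = pd.DataFrame(
        {
            "income": rng.choice(["very poor", "poor/fair", "good"], n),
            "status": rng.choice(STATUSES, n, p=[0.5, 0.4, 0.1]),
        }
    )
    design = build_design(df, ["income"])
    assert design.shape[1] == 2  # first level dropped
    res = fit_polytomous(df, ["income"])
    assert res.table["column"].nunique() == 2
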