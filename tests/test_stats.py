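"""Descriptives, mixed model, rank tests, averaging, spline trends."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palatemap import stats as ps
from palatemap.errors import DesignError, InsufficientDataError
from palatemap.phantom import MD_ROI_EFFECTS, CohortSpec, sample_cohort


class TestDescribe:
    def test_summary_interval_cohort_md(self):
        """Printed-table convention: mean 10.44, SD 2.53, n 184 → CI low 10.07."""
        lo, hi = ps.interval_from_summary(10.44, 2.53, 184, kind="ci_mean")
        assert round(lo, 2) == 10.07
        assert round(hi, 2) == 10.81

    def test_summary_range_convention(self):
        lo, hi = ps.interval_from_summary(10.79, 3.84, kind="range")
        assert round(lo, 2) == 3.26
        assert round(hi, 2) == 18.32

    def test_more_printed_values(self):
        assert round(ps.interval_from_summary(394.36, 180.22, 184)[0], 2) == 368.32
        assert round(ps.interval_from_summary(12.25, 3.75, kind="range")[1], 2) == 19.6
        assert round(ps.interval_from_summary(3973.07, 1447.37, 184)[1], 1) == 4182.2
        assert round(ps.interval_from_summary(1116.31, 458.42, 184)[0], 2) == 1050.07

    def test_degenerate_sd(self):
        assert ps.interval_from_summary(5.0, 0.0, 10) == (5.0, 5.0)

    def test_negative_sd_raises(self):
        with pytest.raises(ValueError):
            ps.interval_from_summary(5.0, -1.0, 10)

    def test_symmetric_sample_zero_skew(self):
        d = ps.describe([-2, -1, 0, 1, 2])
        assert np.isclose(d.skewness, 0.0, atol=1e-12)
        assert d.min <= d.mean <= d.max
        # CI for the mean nests inside the individual range band
        assert d.ci_mean[0] > d.range_1_96sd[0] and d.ci_mean[1] < d.range_1_96sd[1]

    def test_exponential_asymptotic_moments(self):
        """Exponential: skewness → 2, excess kurtosis → 6."""
        sk, ku = [], []
        for seed in range(10):
            x = np.random.default_rng(seed).exponential(size=100_000)
            d = ps.describe(x)
            sk.append(d.skewness)
            ku.append(d.excess_kurtosis)
        assert abs(np.mean(sk) - 2.0) < 0.1
        assert abs(np.mean(ku) - 6.0) < 0.8

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ps.describe([1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        d1 = ps.describe(x)
        d2 = ps.describe(rng.permutation(x))
        assert np.isclose(d1.mean, d2.mean) and np.isclose(d1.skewness, d2.skewness)


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,group",
        [(4, "4-12"), (12, "4-12"), (13, "13-16"), (16, "13-16"),
         (17, "17-20"), (20, "17-20")],
    )
    def test_binning(self, age, group):
        assert ps.assign_age_group(age) == group

    @pytest.mark.parametrize("age", [3, 21, 50])
    def test_out_of_range(self, age):
        with pytest.raises(ValueError):
            ps.assign_age_group(age)


class TestLMM:
    def test_balanced_closed_form(self):
        """REML on balanced one-way data matches the ANOVA estimator."""
        rng = np.random.default_rng(42)
        g, m = 100, 6
        y = (rng.normal(0, 2.0, g)[:, None] + rng.normal(0, 1.0, (g, m))).ravel()
        df = pd.DataFrame({"response": y,
                           "patient_id": np.repeat(np.arange(g), m)})
        model = ps.RandomInterceptLMM(
            df["response"].to_numpy(),
            pd.DataFrame({"intercept": np.ones(len(df))}),
            df["patient_id"].to_numpy(),
        )
        res = model.fit()
        ybar_i = y.reshape(g, m).mean(1)
        msb = m * ((ybar_i - y.mean()) ** 2).sum() / (g - 1)
        msw = ((y.reshape(g, m) - ybar_i[:, None]) ** 2).sum() / (g * (m - 1))
        assert abs(res.sigma_e**2 - msw) < 1e-4
        assert abs(res.sigma_b**2 - (msb - msw) / m) < 1e-4

    def test_sex_effect_recovery_20_seeds(self):
        """Simulated sex effect of −1.5 mm recovered within 3 SE in ≥95%."""
        ok = 0
        for seed in range(20):
            eff = dict(MD_ROI_EFFECTS, sex_female=-1.5)
            tab = sample_cohort(CohortSpec(n_patients=200, fixed_effects=eff,
                                           seed=seed))
            fit = ps.fit_lmm(tab)
            z = abs(fit.params["sex[female]"] - (-1.5)) / fit.bse["sex[female]"]
            ok += z <= 3.0
        assert ok >= 19

    def test_sigma_b_zero_boundary(self):
        """Data with no between-group variance: σ̂_b collapses to ≈0 without
        failure (the estimate sits at or near the boundary)."""
        est = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "response": rng.normal(size=300),
                "patient_id": np.repeat(np.arange(50), 6),
            })
            res = ps.RandomInterceptLMM(
                df["response"].to_numpy(),
                pd.DataFrame({"intercept": np.ones(300)}),
                df["patient_id"].to_numpy(),
            ).fit()
            assert res.sigma_b >= 0
            est.append(res.sigma_b)
        assert np.median(est) < 0.2 and np.mean(est) < 0.25

    def test_matches_statsmodels(self):
        """Independent cross-check against statsmodels MixedLM (REML)."""
        import statsmodels.formula.api as smf

        tab = sample_cohort(CohortSpec(n_patients=80, seed=3))
        fit = ps.fit_lmm(tab)
        t2 = tab.copy()
        t2["teeth"] = t2["teeth"].astype(int)
        sm_fit = smf.mixedlm(
            "response ~ C(age_group, Treatment('4-12')) + C(sex, Treatment('male'))"
            " + teeth + C(side, Treatment('l')) + C(roi, Treatment(1))",
            t2, groups=t2["patient_id"],
        ).fit(reml=True)
        assert abs(fit.params["sex[female]"]
                   - sm_fit.params["C(sex, Treatment('male'))[T.female]"]) < 1e-4
        assert abs(fit.params["roi[2]"] - sm_fit.params["C(roi, Treatment(1))[T.2]"]) < 1e-4
        assert abs(fit.sigma_e - np.sqrt(sm_fit.scale)) < 1e-3
        assert abs(fit.sigma_b - np.sqrt(sm_fit.cov_re.iloc[0, 0])) < 1e-3

    def test_rank_deficient_design_raises(self):
        tab = sample_cohort(CohortSpec(n_patients=20, seed=0))
        tab["dup"] = tab["sex"]  # aliased term
        with pytest.raises(DesignError):
            ps.fit_lmm(tab, fixed_terms=("sex", "dup"))

    def test_reference_levels_absent_from_terms(self):
        tab = sample_cohort(CohortSpec(n_patients=20, seed=0))
        fit = ps.fit_lmm(tab)
        names = set(fit.params.index)
        assert "age_group[4-12]" not in names and "sex[male]" not in names
        assert {"age_group[13-16]", "age_group[17-20]", "sex[female]",
                "roi[2]", "roi[3]", "side[r]"} <= names

    def test_ci_contains_coefficient_and_summary_renders(self):
        tab = sample_cohort(CohortSpec(n_patients=30, seed=1))
        fit = ps.fit_lmm(tab)
        ci = fit.conf_int()
        assert ((ci["lower"] <= fit.params) & (fit.params <= ci["upper"])).all()
        assert ((fit.pvalues > 0) & (fit.pvalues <= 1)).all()
        text = fit.summary()
        assert "sigma_b" in text and "roi[3]" in text


def _brute_mann_whitney(x, y):
    """Independent enumeration oracle (midranks, symmetric two-sided tail)."""
    from scipy.stats import rankdata

    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return u_obs, hits / total


class TestRankTests:
    def test_mann_whitney_textbook_case(self):
        res = ps.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert np.isclose(res.pvalue, 1 / 3, atol=1e-9)
        assert res.method == "exact"

    def test_wilcoxon_textbook_case(self):
        res = ps.wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 6
        assert np.isclose(res.pvalue, 0.25)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = ps.mann_whitney([1, 2, 3], [1, 2, 3])
        assert np.isclose(res.pvalue, 1.0)

    def test_all_zero_diffs_undefined(self):
        with pytest.raises(ValueError):
            ps.wilcoxon_signed_rank([0.0, 0.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=4).astype(float)  # ties likely
        y = rng.integers(0, 6, size=5).astype(float)
        u_ref, p_ref = _brute_mann_whitney(x, y)
        res = ps.mann_whitney(x, y)
        assert res.statistic == u_ref
        assert np.isclose(res.pvalue, p_ref)

    def test_wilcoxon_exact_by_sign_enumeration(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=8)
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mu = ranks.sum() / 2
        hits = sum(
            abs(np.dot(s, ranks) - mu) >= abs(w_obs - mu) - 1e-12
            for s in product((0, 1), repeat=8)
        )
        res = ps.wilcoxon_signed_rank(d)
        assert np.isclose(res.pvalue, hits / 2**8)

    def test_exact_approx_agree_at_crossover(self):
        """Exact enumeration vs corrected normal approximation at n = 12."""
        from scipy.stats import mannwhitneyu, wilcoxon

        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=6)
            exact = ps.mann_whitney(x, y)
            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
            diffs.append(abs(exact.pvalue - approx.pvalue))
        assert max(diffs) < 0.02
        wdiffs = []
        for _ in range(10):
            d = rng.normal(0.3, size=12)
            exact = ps.wilcoxon_signed_rank(d)
            approx = wilcoxon(d, correction=True, method="approx")
            wdiffs.append(abs(exact.pvalue - approx.pvalue))
        assert max(wdiffs) < 0.02

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(0)
        res = ps.mann_whitney(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "asymptotic"


class TestAverageDependent:
    def test_collapses_to_one_row_per_patient(self):
        tab = sample_cohort(CohortSpec(n_patients=10, seed=0))
        out = ps.average_dependent(tab)
        assert len(out) == 10
        one = tab[tab["patient_id"] == "P0000"]
        assert np.isclose(
            out.loc[out["patient_id"] == "P0000", "response"].iloc[0],
            one["response"].mean(),
        )
        # patient-level covariates survive
        assert {"sex", "age_group", "teeth"} <= set(out.columns)

    def test_unique_rows_unchanged(self):
        tab = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "response": [1.0, 2.0, 3.0],
        })
        out = ps.average_dependent(tab)
        assert list(out["response"]) == [1.0, 2.0, 3.0]

    def test_grand_mean_preserved_when_balanced(self):
        tab = sample_cohort(CohortSpec(n_patients=15, seed=2))
        out = ps.average_dependent(tab)
        assert np.isclose(out["response"].mean(), tab["response"].mean())

    def test_condition_keys(self):
        tab = sample_cohort(CohortSpec(n_patients=6, seed=0))
        out = ps.average_dependent(tab, condition_keys=("roi",))
        assert len(out) == 6 * 3  # patient × roi


class TestSmoothAgeTrend:
    def test_linear_data_reproduced_exactly(self):
        ages = np.arange(4, 21, dtype=float)
        values = 0.3 * ages + 2.0
        grid, fitted = ps.smooth_age_trend(ages, values)
        np.testing.assert_allclose(fitted, 0.3 * grid + 2.0, atol=1e-6)

    def test_heavy_smoothing_tends_to_least_squares_line(self):
        rng = np.random.default_rng(3)
        ages = np.tile(np.arange(4, 21, dtype=float), 3)
        values = np.sin(ages) + rng.normal(0, 0.2, ages.size)
        grid, fitted = ps.smooth_age_trend(ages, values, smoothing=1e9)
        agg = pd.DataFrame({"a": ages, "v": values}).groupby("a")["v"].mean()
        coef = np.polyfit(agg.index, agg.to_numpy(), 1)
        np.testing.assert_allclose(fitted, np.polyval(coef, grid), atol=1e-3)

    def test_residuals_decrease_with_less_smoothing(self):
        rng = np.random.default_rng(5)
        ages = np.arange(4, 21, dtype=float)
        values = np.cos(ages / 3) + rng.normal(0, 0.1, ages.size)
        rss = []
        for lam in (1e4, 1e1, 1e-2, 1e-5):
            grid, fitted = ps.smooth_age_trend(ages, values, smoothing=lam,
                                               grid=ages)
            rss.append(((fitted - values) ** 2).sum())
        assert all(a >= b - 1e-12 for a, b in zip(rss, rss[1:]))

    def test_too_few_ages(self):
        with pytest.raises(InsufficientDataError):
            ps.smooth_age_trend([4, 5, 6], [1.0, 2.0, 3.0])
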