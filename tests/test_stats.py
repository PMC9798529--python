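"""Cohort statistics: ANOVA, floor-proportion test, Falconer
heritability, propensity matching, COVID ANCOVA, KS test, retest r."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromat.stats import (
    DegenerateDesignError,
    InfeasibleMatchingError,
    InsufficientDataError,
    anova_sex_age,
    assign_age_bin,
    covid_ancova,
    falconer_heritability,
    floor_proportion_test,
    pearson_retest,
    propensity_match,
    propensity_scores,
    standardized_mean_differences,
)


def balanced_2x3(values):
    """12-row balanced sex x age-bin table with given threshold values."""
    rows = []
    it = iter(values)
    for sex in ("M", "F"):
        for age_bin in ("18-37", "38-57", "58-77"):
            for _ in range(2):
                rows.append({"sex": sex, "age_bin": age_bin, "threshold": next(it)})
    return pd.DataFrame(rows)


class TestAgeBins:
    @pytest.mark.parametrize(
        "age, expected",
        [(18, "18-37"), (37, "18-37"), (38, "38-57"), (57, "38-57"),
         (58, "58-77"), (77, "58-77"), (17, None), (78, None)],
    )
    def test_closed_interval_bins(self, age, expected):
        assert assign_age_bin(age) == expected


class TestAnovaSexAge:
    def test_null_data_gives_null_f(self):
        # every cell holds {-1, +1}: cell means identical, within-cell
        # spread nonzero, so every F is exactly 0
        df = balanced_2x3([-1.0, 1.0] * 6)
        res = anova_sex_age(df)
        assert res.table.loc["C(sex)", "F"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.loc["C(age_bin)", "F"] == pytest.approx(0.0, abs=1e-9)
        assert (res.tukey_age["reject"] == False).all()  # noqa: E712

    def test_matches_hand_computed_sums_of_squares(self):
        """Balanced 2x3 design: F values from the textbook SS decomposition."""
        vals = [2.0, 4.0, 3.0, 5.0, 6.0, 8.0, 1.0, 3.0, 4.0, 6.0, 5.0, 7.0]
        df = balanced_2x3(vals)
        res = anova_sex_age(df)

        y = df["threshold"].to_numpy()
        grand = y.mean()
        cell = df.groupby(["sex", "age_bin"])["threshold"].mean()
        a_means = df.groupby("sex")["threshold"].mean()
        b_means = df.groupby("age_bin")["threshold"].mean()
        ss_a = 6 * sum((m - grand) ** 2 for m in a_means)
        ss_b = 4 * sum((m - grand) ** 2 for m in b_means)
        ss_cells = 2 * sum((m - grand) ** 2 for m in cell)
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            (row["threshold"] - cell[(row["sex"], row["age_bin"])]) ** 2
            for _, row in df.iterrows()
        )
        ms_err = ss_err / 6  # df = 12 - 6 cells
        assert res.table.loc["C(sex)", "F"] == pytest.approx((ss_a / 1) / ms_err)
        assert res.table.loc["C(age_bin)", "F"] == pytest.approx((ss_b / 2) / ms_err)
        assert res.table.loc["C(sex):C(age_bin)", "F"] == pytest.approx(
            (ss_ab / 2) / ms_err
        )

    def test_planted_effect_is_detected(self):
        rng = np.random.default_rng(1)
        rows = []
        for sex, shift in (("M", 0.0), ("F", -0.5)):
            for age_bin in ("18-37", "38-57", "58-77"):
                for _ in range(120):
                    rows.append({"sex": sex, "age_bin": age_bin,
                                 "threshold": shift + rng.normal(-2, 1)})
        res = anova_sex_age(pd.DataFrame(rows))
        assert res.table.loc["C(sex)", "PR(>F)"] < 0.01
        assert res.sex_means["F"] - res.sex_means["M"] == pytest.approx(-0.5, abs=0.25)

    def test_empty_cell_rejected(self):
        df = balanced_2x3(list(range(12)))
        df = df[~((df.sex == "F") & (df.age_bin == "58-77"))]
        with pytest.raises(DegenerateDesignError):
            anova_sex_age(df)

    def test_single_level_factor_rejected(self):
        df = balanced_2x3(list(range(12)))
        with pytest.raises(DegenerateDesignError):
            anova_sex_age(df[df.sex == "M"])


class TestFloorProportionTest:
    def test_equal_proportions_null_statistic(self):
        df = pd.DataFrame({
            "sex": ["M"] * 100 + ["F"] * 100,
            "threshold": ([-4.5] * 10 + [-2.0] * 90) * 2,
        })
        res = floor_proportion_test(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_computed_chi_squared(self):
        # 2x2 counts: males 5/95 at floor, females 20/80
        df = pd.DataFrame({
            "sex": ["M"] * 100 + ["F"] * 100,
            "threshold": [-4.5] * 5 + [-2.0] * 95 + [-4.5] * 20 + [-2.0] * 80,
        })
        res = floor_proportion_test(df)
        obs = np.array([[20, 80], [5, 95]])  # rows F, M (alphabetical)
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2_hand)
        assert res.percentages["F"] == pytest.approx(20.0)

    def test_degenerate_margin_warns_not_crashes(self):
        df = pd.DataFrame({"sex": ["M", "F"] * 5, "threshold": [-4.5] * 10})
        with pytest.warns(UserWarning):
            res = floor_proportion_test(df)
        assert np.isnan(res.statistic)


class TestFalconerHeritability:
    def test_worked_example_from_rounded_correlations(self):
        """2 x (0.46 - 0.19) = 0.54; SEs via Fisher-z propagation with the
        field-study pair counts reproduce the published +-0.07 / +-0.16 /
        +-0.36."""
        rng = np.random.default_rng(0)

        def pairs_with_r(r, n):
            cov = np.array([[1.0, r], [r, 1.0]])
            z = rng.multivariate_normal([0, 0], cov, size=n)
            # force the empirical correlation to exactly r
            from scipy import stats as sps
            z = (z - z.mean(0)) / z.std(0, ddof=0)
            u = z[:, 1] - np.corrcoef(z.T)[0, 1] * z[:, 0]
            u /= u.std(ddof=0)
            z[:, 1] = r * z[:, 0] + np.sqrt(1 - r**2) * u
            return z

        mz = pairs_with_r(0.46, 143)
        dz = pairs_with_r(0.19, 37)
        res = falconer_heritability(mz, dz)
        assert res.r_mz == pytest.approx(0.46, abs=1e-9)
        assert res.r_dz == pytest.approx(0.19, abs=1e-9)
        assert res.h2 == pytest.approx(0.54, abs=1e-9)
        assert res.se_mz == pytest.approx(0.07, abs=0.005)
        assert res.se_dz == pytest.approx(0.16, abs=0.01)
        assert res.se_h2 == pytest.approx(0.36, abs=0.01)
        # MZ-vs-DZ z-test: one-sided p ~ 0.055, two-sided ~ 0.11
        assert res.p_compare_one_sided == pytest.approx(0.055, abs=0.01)
        assert res.p_compare_two_sided == pytest.approx(2 * res.p_compare_one_sided)

    @given(seed_mz=st.integers(0, 10_000), seed_dz=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30)
    def test_h2_is_exactly_twice_the_correlation_gap(self, seed_mz, seed_dz):
        mz = np.random.default_rng(seed_mz).normal(size=(20, 2))
        dz = np.random.default_rng(seed_dz).normal(size=(15, 2))
        res = falconer_heritability(mz, dz)
        assert res.h2 == pytest.approx(2 * (res.r_mz - res.r_dz))

    def test_equal_correlations_zero_h2(self):
        rng = np.random.default_rng(5)
        pairs = rng.normal(size=(50, 2))
        res = falconer_heritability(pairs, pairs)
        assert res.h2 == 0.0

    def test_fisher_interval_coverage(self):
        """95% Fisher CIs for r cover the true correlation ~95% of the
        time (1000 replicates, n=143 pairs, rho=0.46)."""
        rng = np.random.default_rng(42)
        rho, n, covered = 0.46, 143, 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            z = np.arctanh(r)
            half = 1.959964 / np.sqrt(n - 3)
            if np.tanh(z - half) <= rho <= np.tanh(z + half):
                covered += 1
        assert covered / reps == pytest.approx(0.95, abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            falconer_heritability(np.zeros((3, 2)), np.zeros((10, 2)))


def synthetic_covid_cohort(n_cases, n_controls, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    covid = np.array([True] * n_cases + [False] * n_controls)
    age = rng.integers(18, 78, n).astype(float)
    age[covid] = np.clip(age[covid] + rng.normal(3, 5, n_cases), 18, 77)  # confounding
    sex = rng.choice(["M", "F"], n)
    race = rng.choice(["white", "black", "asian", "other"], n, p=[0.85, 0.06, 0.05, 0.04])
    thr = rng.normal(-2, 1, n) + effect * covid
    return pd.DataFrame({"covid": covid, "age": age, "sex": sex, "race": race,
                         "threshold": thr})


class TestPropensityMatch:
    def test_78_cases_give_two_groups_of_78(self):
        df = synthetic_covid_cohort(78, 400, seed=1)
        matched = propensity_match(df)
        assert len(matched) == 156
        assert matched["covid"].sum() == 78
        assert (~matched["covid"].astype(bool)).sum() == 78

    def test_covariate_clones_match_at_zero_distance(self):
        rows = []
        for i in range(6):
            for covid in (True, False):
                rows.append({"covid": covid, "age": 30.0 + 5 * i,
                             "sex": "M" if i % 2 else "F", "race": "white",
                             "threshold": -2.0})
        df = pd.DataFrame(rows)
        matched = propensity_match(df)
        for _, grp in matched.groupby("match_id"):
            assert grp["age"].nunique() == 1
            assert grp["sex"].nunique() == 1

    def test_matches_brute_force_greedy_oracle(self):
        df = synthetic_covid_cohort(3, 3, seed=2)
        scores = propensity_scores(df)
        treated = list(np.where(df["covid"])[0])
        controls = list(np.where(~df["covid"])[0])
        # independent greedy: descending treated score, nearest control
        assignment = {}
        pool = list(controls)
        for t in sorted(treated, key=lambda i: -scores[i]):
            j = min(pool, key=lambda c: (abs(scores[c] - scores[t]), pool.index(c)))
            pool.remove(j)
            assignment[t] = j
        matched = propensity_match(df)
        for _, grp in matched.groupby("match_id"):
            t_row = grp[grp["covid"].astype(bool)].iloc[0]
            c_row = grp[~grp["covid"].astype(bool)].iloc[0]
            t_ix = int(np.where((df["age"] == t_row["age"]) & df["covid"])[0][0])
            assert abs(scores[assignment[t_ix]] - c_row["propensity"]) < 1e-12

    def test_matching_improves_covariate_balance(self):
        df = synthetic_covid_cohort(100, 500, seed=3)
        before = standardized_mean_differences(df)
        after = standardized_mean_differences(propensity_match(df))
        assert after["age"] < before["age"]

    def test_more_cases_than_controls_rejected(self):
        df = synthetic_covid_cohort(10, 5, seed=4)
        with pytest.raises(InfeasibleMatchingError):
            propensity_match(df)


class TestCovidAncova:
    def test_identical_distributions_null(self):
        df = synthetic_covid_cohort(60, 60, seed=5, effect=0.0)
        df.loc[~df["covid"], "threshold"] = df.loc[df["covid"], "threshold"].values
        df.loc[~df["covid"], "age"] = df.loc[df["covid"], "age"].values
        df.loc[~df["covid"], "sex"] = df.loc[df["covid"], "sex"].values
        res = covid_ancova(df)
        assert res.ks_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.anova.loc["C(covid)", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_ks_matches_hand_computed_supremum(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.5, 2.5, 3.5, 8.0, 9.0]
        df = pd.DataFrame({
            "covid": [True] * 5 + [False] * 5,
            "threshold": a + b,
            "sex": ["M", "F"] * 5,
            "age": list(range(30, 40)),
        })
        res = covid_ancova(df)
        grid = np.sort(np.unique(a + b))
        f1 = np.searchsorted(np.sort(a), grid, side="right") / 5
        f2 = np.searchsorted(np.sort(b), grid, side="right") / 5
        assert res.ks_statistic == pytest.approx(np.max(np.abs(f1 - f2)))

    @given(shift=st.floats(0.1, 3.0), scale=st.floats(0.2, 4.0))
    @settings(derandomize=True, max_examples=20)
    def test_ks_invariant_under_monotone_transforms(self, shift, scale):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(9)
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1.2, size=25)

        def mono(x):
            return np.exp(scale * x) + shift * x

        assert ks_2samp(a, b).statistic == pytest.approx(
            ks_2samp(mono(a), mono(b)).statistic
        )


class TestPearsonRetest:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_retest(x, x) == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_retest(x, -x) == pytest.approx(-1.0)

    def test_matches_hand_computation(self):
        d1 = np.array([-2.1, -3.0, -1.5, -4.5, -2.8, -0.5, -3.3, -2.0, -1.1, -2.6])
        d2 = np.array([-2.4, -2.7, -1.9, -4.0, -3.1, -1.0, -2.9, -2.2, -0.8, -2.9])
        num = np.sum((d1 - d1.mean()) * (d2 - d2.mean()))
        den = np.sqrt(np.sum((d1 - d1.mean()) ** 2) * np.sum((d2 - d2.mean()) ** 2))
        assert pearson_retest(d1, d2) == pytest.approx(num / den)

    def test_zero_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_retest([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
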