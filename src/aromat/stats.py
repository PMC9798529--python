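"""Cohort-level statistics: ANOVA, floor-proportion test, heritability,
propensity matching, COVID ANCOVA, KS test, test-retest correlation.

All model fitting goes through statsmodels/scipy; this module owns only
the glue specific to the threshold cohort: the fixed 2 x 3 sex x
age-bin design, Falconer's broad-sense heritability with Fisher-z
variance propagation, and the greedy 1:1 propensity matching used for
the exploratory COVID comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

AGE_BIN_EDGES = ((18, 37), (38, 57), (58, 77))


class DegenerateDesignError(ValueError):
    """An ANOVA cell is empty or a factor has fewer than two levels."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class InfeasibleMatchingError(ValueError):
    """More treated participants than available controls."""


def assign_age_bin(age: int | float) -> str | None:
    """Closed-interval age bins; ages outside 18-77 are excluded (None)."""
    for lo, hi in AGE_BIN_EDGES:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


# -- sex x age ANOVA -------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame  # term, sum_sq, df, F, PR(>F)
    tukey_age: pd.DataFrame  # pairwise age-bin comparisons
    group_means: pd.DataFrame  # sex x age_bin cell means
    sex_means: pd.Series
    age_means: pd.Series


def anova_sex_age(table: pd.DataFrame, ss_type: int = 2) -> AnovaResult:
    """Two-way fixed-effects ANOVA of threshold on sex and age bin.

    Type-II sums of squares by default (cohorts are rarely balanced),
    followed by Tukey HSD on the age-bin means.
    """
    df = table.copy()
    for factor in ("sex", "age_bin"):
        levels = df[factor].unique()
        if len(levels) < 2:
            raise DegenerateDesignError(f"factor {factor!r} has fewer than 2 levels")
    cells = df.groupby(["sex", "age_bin"], observed=True).size()
    full = len(df["sex"].unique()) * len(df["age_bin"].unique())
    if len(cells) < full or (cells == 0).any():
        raise DegenerateDesignError("empty sex x age_bin cell")

    model = smf.ols("threshold ~ C(sex) * C(age_bin)", data=df).fit()
    atab = anova_lm(model, typ=ss_type)

    tukey = pairwise_tukeyhsd(df["threshold"], df["age_bin"], alpha=0.05)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    return AnovaResult(
        table=atab,
        tukey_age=tukey_df,
        group_means=df.groupby(["sex", "age_bin"], observed=True)["threshold"]
        .mean()
        .unstack(),
        sex_means=df.groupby("sex", observed=True)["threshold"].mean(),
        age_means=df.groupby("age_bin", observed=True)["threshold"].mean(),
    )


# -- floor-proportion chi-squared test ------------------------------------


@dataclass(frozen=True)
class FloorTestResult:
    counts: pd.DataFrame  # 2x2: sex x at-floor
    percentages: pd.Series  # % at floor per sex
    statistic: float
    p_value: float


def floor_proportion_test(table: pd.DataFrame, floor: float = -4.5) -> FloorTestResult:
    """Chi-squared contingency test of sex vs at-floor-threshold.

    Uses the plain Pearson statistic (no continuity correction).  A
    degenerate margin (nobody, or everybody, at floor) returns NaN with
    a warning rather than raising.
    """
    df = table.copy()
    if df["sex"].nunique() < 2:
        raise DegenerateDesignError("both sexes required")
    df["at_floor"] = np.isclose(df["threshold"], floor)
    counts = pd.crosstab(df["sex"], df["at_floor"])
    pct = df.groupby("sex")["at_floor"].mean() * 100.0
    if counts.shape != (2, 2):
        warnings.warn("degenerate margin in floor-proportion table; statistic undefined")
        return FloorTestResult(counts, pct, float("nan"), float("nan"))
    chi2, p, _, _ = sps.chi2_contingency(counts.values, correction=False)
    return FloorTestResult(counts, pct, float(chi2), float(p))


# -- Falconer heritability -------------------------------------------------


@dataclass(frozen=True)
class HeritabilityResult:
    r_mz: float
    r_dz: float
    se_mz: float
    se_dz: float
    n_mz: int
    n_dz: int
    h2: float
    se_h2: float
    z_compare: float
    p_compare_two_sided: float
    p_compare_one_sided: float


def _pair_correlation(pairs: np.ndarray) -> float:
    return float(sps.pearsonr(pairs[:, 0], pairs[:, 1]).statistic)


def falconer_heritability(pairs_mz, pairs_dz) -> HeritabilityResult:
    """Broad-sense heritability H^2 = 2 (r_MZ - r_DZ) with Fisher-z SEs.

    Each correlation's variance is taken as 1/(n_pairs - 3) on the
    Fisher-z scale and delta-method back-transformed to the r scale,
    Var(r) ~= (1 - r^2)^2 / (n - 3); these propagate to
    Var(H^2) = 4 (Var(r_MZ) + Var(r_DZ)).  The MZ-vs-DZ comparison is
    the standard z-test on the Fisher-z difference; both one- and
    two-sided p-values are reported (two-sided primary).
    """
    mz = np.asarray(pairs_mz, dtype=float)
    dz = np.asarray(pairs_dz, dtype=float)
    n_mz, n_dz = len(mz), len(dz)
    if n_mz < 4 or n_dz < 4:
        raise InsufficientDataError("need at least 4 twin pairs per zygosity")
    r_mz = _pair_correlation(mz)
    r_dz = _pair_correlation(dz)
    var_mz = (1.0 - r_mz**2) ** 2 / (n_mz - 3)
    var_dz = (1.0 - r_dz**2) ** 2 / (n_dz - 3)
    h2 = 2.0 * (r_mz - r_dz)
    se_h2 = 2.0 * float(np.sqrt(var_mz + var_dz))
    z = (np.arctanh(r_mz) - np.arctanh(r_dz)) / np.sqrt(
        1.0 / (n_mz - 3) + 1.0 / (n_dz - 3)
    )
    p_two = 2.0 * float(sps.norm.sf(abs(z)))
    p_one = float(sps.norm.sf(z))
    return HeritabilityResult(
        r_mz=r_mz,
        r_dz=r_dz,
        se_mz=float(np.sqrt(var_mz)),
        se_dz=float(np.sqrt(var_dz)),
        n_mz=n_mz,
        n_dz=n_dz,
        h2=h2,
        se_h2=se_h2,
        z_compare=float(z),
        p_compare_two_sided=p_two,
        p_compare_one_sided=p_one,
    )


def twin_pairs_from_cohort(table: pd.DataFrame, column: str = "threshold") -> tuple[np.ndarray, np.ndarray]:
    """Extract (MZ, DZ) pair arrays from a cohort with twin_id/zygosity."""
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = table[table["zygosity"] == zyg]
        pairs = [
            g[column].values[:2]
            for _, g in sub.groupby("twin_id")
            if len(g) == 2
        ]
        out[zyg] = np.array(pairs) if pairs else np.empty((0, 2))
    return out["MZ"], out["DZ"]


# -- propensity matching ---------------------------------------------------


def propensity_scores(
    table: pd.DataFrame,
    treatment: str = "covid",
    covariates: tuple[str, ...] = ("age", "sex", "race"),
) -> np.ndarray:
    """Logistic propensity P(treated | covariates); categoricals dummy-coded."""
    X = pd.get_dummies(
        table[list(covariates)], drop_first=True, dtype=float
    )
    X = sm.add_constant(X, has_constant="add")
    y = table[treatment].astype(int)
    model = sm.Logit(y, X)
    # BFGS tolerates the singular Hessians that quasi-separated small
    # samples produce; fall back to a ridge-penalized fit if even that fails
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=500, method="bfgs")
    except Exception:
        fit = model.fit_regularized(disp=0, maxiter=500, alpha=1e-4, L1_wt=0.0)
    return np.asarray(fit.predict(X))


def propensity_match(
    table: pd.DataFrame,
    treatment: str = "covid",
    covariates: tuple[str, ...] = ("age", "sex", "race"),
) -> pd.DataFrame:
    """1:1 greedy nearest-neighbor matching without replacement.

    Treated rows are processed in descending propensity-score order;
    each takes the unmatched control with the closest score (lowest row
    order on ties).  Output stacks the treated rows and their matched
    controls, tagged with a shared ``match_id``.
    """
    df = table.reset_index(drop=True)
    treated_ix = df.index[df[treatment].astype(bool)].to_numpy()
    control_ix = df.index[~df[treatment].astype(bool)].to_numpy()
    if len(treated_ix) == 0 or len(control_ix) == 0:
        raise InfeasibleMatchingError("both treatment groups must be non-empty")
    if len(treated_ix) > len(control_ix):
        raise InfeasibleMatchingError(
            f"{len(treated_ix)} treated but only {len(control_ix)} controls"
        )
    scores = propensity_scores(df, treatment, covariates)
    order = treated_ix[np.argsort(-scores[treated_ix], kind="stable")]
    available = list(control_ix)
    matches = []
    for t in order:
        dists = np.abs(scores[available] - scores[t])
        j = int(np.argmin(dists))  # argmin keeps lowest row order on ties
        matches.append((t, available.pop(j)))
    rows = []
    for mid, (t, c) in enumerate(matches):
        for ix in (t, c):
            row = df.loc[ix].copy()
            row["match_id"] = mid
            row["propensity"] = scores[ix]
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def standardized_mean_differences(
    table: pd.DataFrame,
    treatment: str = "covid",
    covariates: tuple[str, ...] = ("age", "sex", "race"),
) -> pd.Series:
    """Absolute SMDs of (dummy-coded) covariates between the two groups."""
    X = pd.get_dummies(table[list(covariates)], drop_first=True, dtype=float)
    g = table[treatment].astype(bool).values
    m1, m0 = X[g].mean(), X[~g].mean()
    s = np.sqrt((X[g].var(ddof=1) + X[~g].var(ddof=1)) / 2.0)
    return ((m1 - m0).abs() / s.replace(0.0, np.nan)).fillna(0.0)


# -- COVID ANCOVA + KS test ------------------------------------------------


@dataclass(frozen=True)
class CovidResult:
    anova: pd.DataFrame  # terms: covid, sex, age (continuous)
    group_stats: pd.DataFrame  # mean/SD/n per covid group
    ks_statistic: float
    ks_p: float


def covid_ancova(matched: pd.DataFrame) -> CovidResult:
    """threshold ~ covid + sex + age (continuous), type-II F tests, plus
    a two-sample KS test on the threshold distributions."""
    df = matched.copy()
    df["covid"] = df["covid"].astype(bool)
    model = smf.ols("threshold ~ C(covid) + C(sex) + age", data=df).fit()
    atab = anova_lm(model, typ=2)
    grp = df.groupby("covid")["threshold"].agg(["mean", "std", "count"])
    a = df.loc[df["covid"], "threshold"].values
    b = df.loc[~df["covid"], "threshold"].values
    ks = sps.ks_2samp(a, b, method="asymp")
    return CovidResult(
        anova=atab,
        group_stats=grp,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


# -- test-retest -----------------------------------------------------------


def pearson_retest(day1, day2=None) -> float:
    """Pearson correlation between day-1 and day-2 threshold estimates."""
    if day2 is None:  # accept an (n, 2) array or DataFrame with day1/day2
        arr = (
            day1[["day1", "day2"]].to_numpy()
            if isinstance(day1, pd.DataFrame)
            else np.asarray(day1, dtype=float)
        )
        day1, day2 = arr[:, 0], arr[:, 1]
    x = np.asarray(day1, dtype=float)
    y = np.asarray(day2, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("zero variance on one day; correlation undefined")
    return float(sps.pearsonr(x, y).statistic)
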