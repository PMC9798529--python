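"""Virtual observers and synthetic cohorts.

Nothing downstream of the card requires human data: a virtual observer
is a (log tau, lambda) pair answering each sniff with a Bernoulli draw
at the psychometric YES probability, and a synthetic cohort plants the
population structure the test is meant to resolve — a sex effect and
age-bin effects on the true log threshold, a twin variance-component
structure with a target broad-sense heritability, an optional COVID
effect, and test-retest sessions.

Default effect sizes mirror the field-study conditions the engine is
built for: females 0.50 log10 units more sensitive than males, the
oldest age bin 0.94 log10 units less sensitive than the youngest
(middle bin 0.33 above the youngest, i.e. 0.61 below the oldest), a
baseline young-male mean of -2.2 so the sex group means land near
-1.8 (M) and -2.3 (F), residual between-subject SD of 1.0 log10 units,
and a criterion population of lambda ~ N(1.55, 0.4^2), which yields a
~7.5% false-alarm probability on a first blank.  The twin block
defaults to 143 MZ and 37 DZ pairs with H^2 = 0.55; with 29 singletons
per sex x age-bin cell the default cohort has 534 participants.

Twin structure is the classical two-component model: true log tau =
fixed effects + F + E with familial variance sigma_F^2 shared fully by
MZ co-twins and half-shared by DZ co-twins, so Falconer's
H^2 = 2(r_MZ - r_DZ) recovers sigma_F^2 / sigma_total^2.  Twin pairs
are same-sex and share an age bin, so the shared fixed effects inflate
r_MZ and r_DZ equally and cancel in the Falconer difference; sigma_F^2
is scaled against the *total* variance (fixed-effect variance
included) so the planted H^2 is the one Falconer recovers on raw
thresholds.

All randomness flows from one root seed through named spawned
substreams (cohort, sessions, retest), so every table is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .card import CardLayout
from .policy import LookupTable, run_session
from .posterior import PriorConfig
from .psychometric import NO, YES, PsychometricParams, yes_probability
from .scoring import DEFAULT_SE_CUTOFF

AGE_BINS = ("18-37", "38-57", "58-77")
AGE_RANGES = {"18-37": (18, 37), "38-57": (38, 57), "58-77": (58, 77)}
RACE_LEVELS = ("white", "black", "asian", "other")
RACE_PROBS = (0.85, 0.06, 0.05, 0.04)


class VarianceDecompositionError(ValueError):
    """Requested heritability not achievable with the given variances."""


@dataclass(frozen=True)
class VirtualObserver:
    """One simulated participant with a private seeded response stream."""

    true_log_tau: float
    true_lambda: float
    slope: float = 0.5
    seed: int = 0

    def params(self) -> PsychometricParams:
        return PsychometricParams(self.true_log_tau, self.true_lambda, self.slope)

    def responder(self):
        """Fresh deterministic responder; replays identically per seed."""
        rng = np.random.default_rng(self.seed)

        def respond(stimulus):
            p = yes_probability(self.params(), stimulus)
            return YES if rng.random() < p else NO

        return respond


def respond(observer: VirtualObserver, stimulus) -> str:
    """Single Bernoulli response (convenience over a one-shot responder)."""
    return observer.responder()(stimulus)


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort."""

    n_per_cell: int = 29  # singletons per sex x age-bin cell
    baseline_log_tau: float = -2.2  # young-male mean
    sex_effect: float = -0.50  # female minus male, log10 units
    age_bin_effects: tuple[float, float, float] = (0.0, 0.33, 0.94)
    residual_sd: float = 1.0  # between-subject SD around fixed effects
    lambda_mean: float = 1.55
    lambda_sd: float = 0.4
    n_mz_pairs: int = 143
    n_dz_pairs: int = 37
    h2_target: float = 0.55
    covid_prevalence: float = 0.15
    covid_effect: float = 0.0  # log10 units added to true log tau
    slope: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0 or self.lambda_sd <= 0:
            raise ValueError("SDs must be positive")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if not 0.0 <= self.covid_prevalence <= 1.0:
            raise ValueError("covid_prevalence must be a probability")


def _fixed_effect_variance(config: CohortConfig) -> float:
    """Population variance contributed by sex and age-bin fixed effects."""
    sex_var = (config.sex_effect / 2.0) ** 2  # balanced sexes
    ages = np.asarray(config.age_bin_effects)
    age_var = float(np.mean(ages**2) - np.mean(ages) ** 2)  # balanced bins
    return sex_var + age_var


def _familial_variances(config: CohortConfig) -> tuple[float, float]:
    """(sigma_F^2, sigma_E^2) splitting residual_sd^2 so that Falconer on
    raw thresholds (fixed effects included) recovers h2_target."""
    resid_var = config.residual_sd**2
    total_var = resid_var + _fixed_effect_variance(config)
    var_f = config.h2_target * total_var
    var_e = resid_var - var_f
    if var_e < 0:
        raise VarianceDecompositionError(
            f"h2_target={config.h2_target} requires familial variance {var_f:.3f} "
            f"exceeding the residual variance {resid_var:.3f}"
        )
    return var_f, var_e


def generate_twin_pairs(
    n_mz: int,
    n_dz: int,
    h2: float,
    mean: float = -2.0,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pure variance-component twin pairs (no fixed effects).

    Returns (mz, dz) arrays of shape (n, 2) with total variance sd^2,
    familial variance h2*sd^2 fully shared within MZ pairs and
    half-shared within DZ pairs.
    """
    if not 0.0 <= h2 <= 1.0:
        raise VarianceDecompositionError("h2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    var_f = h2 * sd**2
    var_e = (1.0 - h2) * sd**2
    f_mz = rng.normal(0.0, np.sqrt(var_f), size=(n_mz, 1))
    mz = mean + f_mz + rng.normal(0.0, np.sqrt(var_e), size=(n_mz, 2))
    # DZ: common half + unique half of the familial variance
    c = rng.normal(0.0, np.sqrt(var_f / 2.0), size=(n_dz, 1))
    u = rng.normal(0.0, np.sqrt(var_f / 2.0), size=(n_dz, 2))
    dz = mean + c + u + rng.normal(0.0, np.sqrt(var_e), size=(n_dz, 2))
    return mz, dz


def generate_matched_groups(
    n_per_group: int,
    group_effects: dict[str, float],
    column: str = "sex",
    baseline_log_tau: float = -2.2,
    residual_sd: float = 1.0,
    lambda_mean: float = 1.55,
    lambda_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched-arms cohort for planted-contrast recovery experiments.

    Every group holds clones of the same ``n_per_group`` base observers
    (shared residual and criterion draws) shifted by its planted effect,
    so the true group-mean contrasts equal the planted effects exactly
    and any error in the recovered contrast comes from the measurement
    pipeline alone (common-random-numbers design).  Measurement seeds
    remain independent per row.
    """
    rng = np.random.default_rng(seed)
    resid = rng.normal(0.0, residual_sd, n_per_group)
    lams = rng.normal(lambda_mean, lambda_sd, n_per_group)
    rows = []
    for label, effect in group_effects.items():
        for i in range(n_per_group):
            rows.append({
                column: label,
                "true_log_tau": baseline_log_tau + effect + resid[i],
                "true_lambda": lams[i],
            })
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"m{i:05d}" for i in range(len(df))])
    return df


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Synthetic cohort of true parameters and covariates.

    Columns: id, sex, age, age_bin, twin_id, zygosity, race, covid,
    true_log_tau, true_lambda.
    """
    var_f, var_e = _familial_variances(config)
    root = np.random.SeedSequence(config.seed)
    ss_cohort, _, _ = root.spawn(3)
    rng = np.random.default_rng(ss_cohort)

    rows: list[dict] = []

    def draw_person(sex: str, age_bin: str, twin_id, zygosity: str, familial: float) -> dict:
        lo, hi = AGE_RANGES[age_bin]
        age = int(rng.integers(lo, hi + 1))
        bin_ix = AGE_BINS.index(age_bin)
        mu = (
            config.baseline_log_tau
            + (config.sex_effect if sex == "F" else 0.0)
            + config.age_bin_effects[bin_ix]
        )
        covid = bool(rng.random() < config.covid_prevalence)
        return {
            "sex": sex,
            "age": age,
            "age_bin": age_bin,
            "twin_id": twin_id,
            "zygosity": zygosity,
            "race": rng.choice(RACE_LEVELS, p=RACE_PROBS),
            "covid": covid,
            "true_log_tau": mu
            + familial
            + rng.normal(0.0, np.sqrt(var_e))
            + (config.covid_effect if covid else 0.0),
            "true_lambda": rng.normal(config.lambda_mean, config.lambda_sd),
        }

    for sex in ("M", "F"):
        for age_bin in AGE_BINS:
            for _ in range(config.n_per_cell):
                rows.append(draw_person(sex, age_bin, None, "none", rng.normal(0.0, np.sqrt(var_f))))

    pair_id = 0
    for zygosity, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            pair_id += 1
            sex = "M" if rng.random() < 0.5 else "F"  # same-sex pairs
            age_bin = AGE_BINS[rng.integers(0, 3)]
            if zygosity == "MZ":
                shared = rng.normal(0.0, np.sqrt(var_f))
                fams = (shared, shared)
            else:
                c = rng.normal(0.0, np.sqrt(var_f / 2.0))
                fams = tuple(c + rng.normal(0.0, np.sqrt(var_f / 2.0)) for _ in range(2))
            for fam in fams:
                rows.append(draw_person(sex, age_bin, f"pair{pair_id:04d}", zygosity, fam))

    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"p{i:05d}" for i in range(len(df))])
    return df


def simulate_measured_cohort(
    cohort: pd.DataFrame,
    card: CardLayout,
    config: PriorConfig | None = None,
    seed: int = 0,
    table: LookupTable | None = None,
    se_cutoff: float = DEFAULT_SE_CUTOFF,
    slope: float = 0.5,
) -> pd.DataFrame:
    """One full 8-trial session per participant; adds measurement columns.

    Adds: threshold (final, post-imputation), est_se, qc, fa_first_blank,
    fa_both_blanks.
    """
    root = np.random.SeedSequence(seed)
    _, ss_sessions, _ = root.spawn(3)
    obs_seeds = ss_sessions.generate_state(len(cohort)) % (2**31)
    out = cohort.copy()
    thresholds, ses, qcs, fa1, fa2 = [], [], [], [], []
    for (_, row), obs_seed in zip(cohort.iterrows(), obs_seeds):
        obs = VirtualObserver(
            true_log_tau=row["true_log_tau"],
            true_lambda=row["true_lambda"],
            slope=slope,
            seed=int(obs_seed),
        )
        rec = run_session(obs.responder(), card, config, table=table, se_cutoff=se_cutoff)
        thresholds.append(rec.final_threshold)
        ses.append(rec.raw_se)
        qcs.append(rec.qc)
        fa1.append(rec.fa_first_blank)
        fa2.append(rec.fa_both_blanks)
    out["threshold"] = thresholds
    out["est_se"] = ses
    out["qc"] = qcs
    out["fa_first_blank"] = fa1
    out["fa_both_blanks"] = fa2
    return out


def simulate_test_retest(
    cohort: pd.DataFrame,
    card: CardLayout,
    config: PriorConfig | None = None,
    seed: int = 0,
    table: LookupTable | None = None,
    day_jitter_sd: float = 0.0,
    slope: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Two independent sessions per observer; returns pairs and Pearson r.

    With ``day_jitter_sd = 0`` (default) any reliability below 1 comes
    purely from 8-trial measurement error.
    """
    root = np.random.SeedSequence(seed)
    _, _, ss_retest = root.spawn(3)
    state = ss_retest.generate_state(3 * len(cohort)) % (2**31)
    seeds1 = state[: len(cohort)]
    seeds2 = state[len(cohort) : 2 * len(cohort)]
    jitter_rng = np.random.default_rng(state[2 * len(cohort) :])

    day1, day2 = [], []
    for (_, row), s1, s2 in zip(cohort.iterrows(), seeds1, seeds2):
        for day, s in ((day1, s1), (day2, s2)):
            tau = row["true_log_tau"] + (
                jitter_rng.normal(0.0, day_jitter_sd) if day_jitter_sd > 0 else 0.0
            )
            obs = VirtualObserver(tau, row["true_lambda"], slope, int(s))
            rec = run_session(obs.responder(), card, config, table=table)
            day.append(rec.final_threshold)
    pairs = pd.DataFrame({"id": cohort["id"].values, "day1": day1, "day2": day2})
    r = float(np.corrcoef(pairs["day1"], pairs["day2"])[0, 1])
    return pairs, r
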