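# Methods

This note documents the models, numerical choices and known limits of
the package. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Psychometric model

The yes/no task is modeled in signal-detection style with two observer
parameters: the log10 detection threshold `log_tau` and the decision
criterion `lambda`.  The criterion maps to a false-alarm probability
`gamma = Phi(-lambda)`; the YES probability at concentration `x` is

    P(YES | x) = gamma + (1 - gamma) * Phi((x - log_tau) / s).

Rationale for this form: it has exactly the two inferred parameters the
priors describe; the blank-response rate is governed by the criterion
alone; and the curve's floor is `gamma` with ceiling 1, so the
"halfway between minimum and maximum" definition of threshold lands
exactly on `log_tau`.  Whether a deployed instrument of this design
used a probit, logistic or other link is not knowable from outside; the
package claims structural, not bit-exact, equivalence.

The slope `s` is a fixed configuration constant, default 0.5 log10
units (one card step).  It is deliberately not inferred: 8 binary
trials cannot support a third free parameter, and the adaptive policy's
behavior is insensitive to moderate slope changes.  There is no lapse
(upper-asymptote) parameter, again for parsimony.

## Priors and grid

Priors are independent normals, `log_tau ~ N(-3, 100)` and
`lambda ~ N(1, 0.5)`.  The second argument is read as a **variance**
(SD 10 for the threshold — weakly informative over the card's 3.5-log
range — and SD ~0.707 for the criterion); `PriorConfig` exposes a
switch so the standard-deviation reading can be exercised too.

The joint posterior lives on a rectangular grid: `log_tau` from -7.5 to
1.5 in steps of 0.05 (181 nodes) and `lambda` from -1 to 3 in steps of
0.1 (41 nodes).  The tau range is symmetric about the prior mean so the
truncated (nearly flat) prior keeps its stated mean of -3, and it spans
the extreme-value imputation range [-4.5, 1.0] with margin on both
sides.  Grid-resolution stability is tested: doubling (and a 10x
refinement) moves point estimates on fixed sessions by < 0.02 log
units, comfortably below the instrument's ~0.4-log single-session SD.

Point estimate = posterior mean of `log_tau`; uncertainty = posterior
SD.  The mean was preferred to the MAP because it is stable on coarse
grids and matches the "standard error" framing of the uncertainty band.
Updates are pure functions (no mutation) so the lookup-table compiler
can branch without copying state, and per-stimulus likelihood matrices
are cached and shared across branches.

## Adaptive policy

Trial 1 is fixed to label 1 (an intermediate rung, -1.5).  Trials 2-8
pick the unused label minimizing the response-probability-weighted
expected posterior SD of `log_tau`.  The objective is the tau-marginal
SD, not joint entropy, because the quantity being reported is the
threshold; reducing criterion uncertainty is valuable only insofar as
it sharpens the threshold, which the expectation captures.  Ties (the
six duplicate rungs) break to the lowest label id, making the compiled
table deterministic.  Blanks compete on equal terms and are genuinely
selected on YES-heavy paths, where distinguishing sensitivity from a
liberal criterion matters most.

The policy is myopic (one-step lookahead).  The full decision tree over
8 trials is 2^1+...+2^7 = 254 internal decisions and 2^8 = 256
terminals; the compiler enumerates it depth-first in about a quarter
second, and the serialized table is stamped with content hashes of the
card and prior configuration so stale tables are rejected rather than
silently misused.

## Scoring

ASTM E679 extreme-value rules: all-YES-to-odorants with NO on received
blanks imputes `min(ladder) - 1` (-4.5 on the default card); NO on
every trial imputes `max(ladder) + 1` (+1.0).  A YES on a received
blank voids the floor imputation (indistinguishable from pure response
bias) but is irrelevant to the ceiling rule, where NO on a blank is
correct behavior.  The imputed values are computed from the card's
ladder, not hard-coded.

"Inconsistent response pattern" has no standard operational definition;
the package classifies a non-imputed session INDETERMINATE when the
posterior SD exceeds a configurable cutoff (default 1.0 log10 unit).
This is a stand-in chosen because it is monotone in evidence quality
and directly testable; the widest of the 256 possible paths reaches an
SD of about 1.4 and is correctly flagged.

## Synthetic cohorts

The simulator emulates the population structure such a test is used to
resolve.  Defaults: baseline young-male mean -2.2; sex effect -0.50
(female minus male); age-bin effects 0 / 0.33 / 0.94 log10 units for
18-37 / 38-57 / 58-77 (so the middle-vs-old gap is 0.61); residual
between-subject SD 1.0 log10 units; criterion population
`lambda ~ N(1.55, 0.4^2)`, which gives a ~7.5% mean false-alarm
probability on a first blank; 143 MZ + 37 DZ twin pairs with planted
broad-sense heritability 0.55 and 29 singletons per sex-by-age cell
(534 participants in all); COVID prevalence 15% with a zero effect by
default.  These values were fixed once, from the published magnitudes
of sex/age/criterion effects for PEA thresholds, and are the
conditions under which all recovery tests run.

Twin structure is the classical shared/unique variance-component model:
MZ co-twins share the full familial component, DZ co-twins half its
variance, which is exactly the generative model under which Falconer's
`H^2 = 2(r_MZ - r_DZ)` is consistent.  Twin pairs are same-sex and
share an age bin; because shared fixed effects inflate both
correlations equally they cancel in the Falconer difference, and the
familial variance is scaled against the total (fixed effects included)
so the planted value is the one recovered from raw thresholds.
`generate_twin_pairs` provides the pure variance-component version with
no fixed effects for clean estimator checks.

Test-retest sessions default to zero day-to-day jitter in the true
threshold, so reliability below 1 isolates the 8-trial measurement
error; a jitter SD is available for sensitivity analyses.  All
randomness flows from one root seed through named spawned substreams.

For planted-contrast recovery experiments, `generate_matched_groups`
builds matched arms that share residual and criterion draws
(common-random-numbers design) while sessions keep independent seeds:
the true group contrast then equals the planted effect exactly, and the
recovered contrast deviates only through the measurement pipeline.  The
acceptance script uses this design for the sex (0.50, n = 500/arm) and
age (0.94, n = 300/arm) recovery targets; the acceptance test suite
additionally runs the unpaired full-cohort ANOVA route at n = 500 per
group.

What the simulator does **not** emulate: realistic demographic
sampling, longitudinal aging, odorant-specific anosmias, day-to-day
criterion drift, malingering, or physical card effects (label reuse,
cross-contamination).  Passing recovery tests therefore demonstrate
correctness of the algorithmic pipeline under the stated generative
model, not field validity.

Two known small biases of the full pipeline under the default
conditions, visible in the test suite: the extreme-value imputation
stretches the scale beyond the ladder, inflating wide group contrasts
slightly (about +0.05 on the 0.94 age contrast at large n), and
single-session estimates of interior thresholds carry ~0.1 log of
prior-and-censoring bias with a ~0.4-log SD.

## Cohort statistics

ANOVA uses statsmodels OLS with type-II sums of squares (cohorts are
unbalanced in general; the type is configurable), Tukey HSD on age-bin
means, and an explicit degenerate-design error for empty cells.  The
floor-proportion test is the plain Pearson chi-squared (no continuity
correction) on the 2x2 sex-by-at-floor table.

Falconer uncertainty: each correlation's Fisher-z variance `1/(n-3)` is
delta-method back-transformed, `Var(r) = (1-r^2)^2/(n-3)`, and
propagated as `Var(H^2) = 4*(Var(r_MZ) + Var(r_DZ))`.  With the default
pair counts (143, 37) and correlations 0.46 / 0.19 this reproduces SEs
of 0.07, 0.16 and 0.36.  The MZ-vs-DZ comparison is a z-test on the
Fisher-z difference with pair counts as sample sizes; one- and
two-sided p-values are both reported (two-sided primary) because the
directional hypothesis r_MZ > r_DZ is defensible a priori.

Propensity matching fits a logistic model of treatment on age, sex and
dummy-coded race, then matches 1:1 greedy nearest-neighbor without
replacement, treated units processed in descending score order, no
caliper.  BFGS optimization is used because small quasi-separated
samples give singular Newton Hessians; a ridge-penalized fit is the
fallback.  The COVID comparison is `threshold ~ covid + sex + age`
(age continuous, type-II F) plus an asymptotic two-sample KS test.

Age bins are the closed intervals 18-37 / 38-57 / 58-77; ages outside
18-77 are excluded from binned analyses.

## Problem sizes

The default verification sizes are: all 256 paths for table/online
equivalence; 500 per group (sex) and 500 per bin (age, acceptance-test
route) or 300 per arm (matched-arms route) for effect recovery; 2000 +
2000 twin pairs for heritability; 500 replicated studies of ~300
participants for the type-I-error check of the COVID term.  These sizes
put Monte-Carlo error comfortably inside each check's tolerance while
keeping the whole suite around a minute of compute.
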