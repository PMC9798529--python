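# aromat

An adaptive Bayesian engine for measuring odor detection thresholds
with a disposable 17-label odorant card, plus a virtual-participant
simulator and the cohort statistics used to characterize such an
instrument.

## The problem

Classic ascending-series threshold tests are accurate but slow, and
single-stimulus yes/no ("can you smell it?") tests confound true
sensitivity with the respondent's willingness to say YES.  This package
implements a fast alternative: a fixed card of phenylethyl alcohol
(PEA) labels spanning 3.5 orders of magnitude in half-log steps (eight
rungs, nominal log10 concentration 0.0 down to −3.5, plus blanks), an
adaptive algorithm that picks the most informative label to sniff next,
and a signal-detection model that separates threshold from response
bias.  A full test is 8 trials.

It is written for psychophysicists and olfaction researchers who want
to study, extend or re-deploy this class of test without collecting
human data: every stage — card, observer model, inference, adaptive
policy, scoring, cohort analysis — is simulable and unit-tested.

## The model

An observer is described by a detection threshold τ (on the nominal
log10 concentration scale) and a decision criterion λ (standard-normal
units).  The probability of YES at concentration x is a
guess-rate-floored probit:

    γ(λ)       = Φ(−λ)                      (false-alarm rate on blanks)
    P(YES | x) = γ + (1 − γ) · Φ((x − log τ) / s)

with fixed slope s = 0.5 log10 units (one card step).  The curve's
floor is γ and ceiling 1, so the concentration halfway between them is
exactly log τ — the reported threshold.

Inference is grid Bayes over (log τ, λ) with weakly informative priors
log τ ~ N(−3, 100) and λ ~ N(1, 0.5) (second argument a variance).
After each YES/NO the joint posterior is multiplied by the Bernoulli
likelihood and renormalized.  The next label is chosen greedily to
minimize the *expected* posterior SD of log τ,

    E[SE] = p_YES · SE(posterior | YES) + (1 − p_YES) · SE(posterior | NO),

over all unused labels (blanks included).  Because the whole test is a
deterministic function of the response history, the complete decision
tree (254 next-label decisions, 256 terminal estimates) is precompiled
into a JSON lookup table that runs sessions with no posterior math.

Scoring follows the ASTM E679 extreme-value convention: respondents who
said YES to every odorant label received (and NO to the blanks) are
imputed one log unit below the lowest rung (−4.5); respondents who said
NO throughout are imputed one log unit above the highest rung (+1.0).
Cohort analyses include a two-way sex × age-bin ANOVA with Tukey HSD, a
floor-proportion chi-squared test, Falconer broad-sense heritability
H² = 2(R_MZ − R_DZ) with Fisher-z error propagation from twin pairs,
logistic-propensity 1:1 matching with an ANCOVA and two-sample KS test,
and test–retest Pearson correlation.

## Worked example

Run one scripted session (Y/N answers in trial order) through the
engine:

```bash
$ aromat run --responses YNNYYNNY
{"final_threshold": -0.3856022344797615, "se": 0.7188354155158463,
 "qc": "DETERMINATE", "fa_first_blank": false, "fa_both_blanks": false,
 "labels": [1, 13, 5, 6, 3, 10, 2, 12], "responses": "YNNYYNNY"}
```

Reading the output: the test started at label 1 (rung −1.5); the YES
sent it to the weakest label 13 (−3.5); the NO there and at label 5
(−1.0) pushed it back up through the strong end (labels 6, 3 at 0.0 and
−0.5), and trial 7 spent a blank (label 2) probing the criterion.  The
posterior mean threshold is −0.39 log10 units with a posterior SD of
0.72 — a determinate, mildly hyposmic result.  No blank was answered
YES, so both false-alarm flags are clear.

The same engine drives whole synthetic studies:

```bash
aromat build-table --out table.json        # 254 decisions, 256 terminals
aromat simulate --seed 7 --out-dir study/  # cohort.csv + report.json
aromat analyze study/cohort.csv            # re-run statistics on a CSV
```

`simulate` generates a 534-person cohort (planted sex effect −0.50,
age effects 0/0.33/0.94 log10 units, 143 MZ and 37 DZ twin pairs with
H² = 0.55), runs one 8-trial session per participant through the lookup
table, and writes the full analysis report (ANOVA, Tukey, floor test,
heritability, propensity-matched COVID comparison).

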