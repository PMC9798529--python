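"""Final threshold scoring: extreme-value imputation, flags, QC.

A completed 8-trial session normally reports the posterior-mean log10
threshold.  Two response patterns fall outside the measurable range and
receive the standard ASTM E679 extreme-value treatment:

* YES to every odorant label received *and* NO to every blank received
  — the observer out-sensed the card; the threshold is imputed one log
  unit below the lowest rung (-4.5 on the default card).
* NO on every trial — the observer never detected anything; the
  threshold is imputed one log unit above the highest rung (+1.0).

Blanks answered YES void the floor imputation (the all-YES pattern is
then indistinguishable from pure response bias) but are irrelevant to
the ceiling rule, where NO on a blank is correct behavior.

Sessions with neither pattern but a wide posterior (SE above a
configurable cutoff, default 1.0 log10 units) are flagged
INDETERMINATE, operationalizing "inconsistent response patterns".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Sequence

from .card import BLANK, CardLayout
from .psychometric import NO, YES, Trial

FLOOR_OFFSET = 1.0  # log10 units below the lowest rung
CEILING_OFFSET = 1.0  # log10 units above the highest rung
DEFAULT_SE_CUTOFF = 1.0  # log10 units; above this a session is indeterminate

DETERMINATE = "DETERMINATE"
INDETERMINATE = "INDETERMINATE"
FLOOR_IMPUTED = "FLOOR_IMPUTED"
CEILING_IMPUTED = "CEILING_IMPUTED"


class IncompleteSessionError(ValueError):
    """Scoring requested on a session with the wrong number of trials."""


@dataclass(frozen=True)
class SessionRecord:
    """One completed test: trials, raw posterior summary, final score."""

    trials: tuple[Trial, ...]
    raw_point: float
    raw_se: float
    final_threshold: float | None = None
    fa_first_blank: bool = False
    fa_both_blanks: bool = False
    qc: str | None = None
    n_trials_expected: int = 8


def _check_complete(session: SessionRecord) -> None:
    if len(session.trials) != session.n_trials_expected:
        raise IncompleteSessionError(
            f"session has {len(session.trials)} trials, expected {session.n_trials_expected}"
        )


def _imputation_branch(session: SessionRecord, card: CardLayout) -> str | None:
    odorant = [t for t in session.trials if t.stimulus is not BLANK]
    blanks = [t for t in session.trials if t.stimulus is BLANK]
    if all(t.response == NO for t in session.trials):
        return CEILING_IMPUTED
    if odorant and all(t.response == YES for t in odorant) and all(
        t.response == NO for t in blanks
    ):
        return FLOOR_IMPUTED
    return None


def finalize_threshold(session: SessionRecord, card: CardLayout) -> float:
    """Final reported log10 threshold after the extreme-value rules."""
    _check_complete(session)
    branch = _imputation_branch(session, card)
    if branch == FLOOR_IMPUTED:
        return min(card.ladder) - FLOOR_OFFSET
    if branch == CEILING_IMPUTED:
        return max(card.ladder) + CEILING_OFFSET
    return session.raw_point


def false_alarm_flags(session: SessionRecord, card: CardLayout) -> tuple[bool, bool]:
    """(YES to the first blank received, YES to >= 2 blanks received)."""
    blanks = [t for t in session.trials if t.stimulus is BLANK]
    fa_first = bool(blanks) and blanks[0].response == YES
    fa_both = len(blanks) >= 2 and all(t.response == YES for t in blanks)
    return fa_first, fa_both


def qc_classify(
    session: SessionRecord, card: CardLayout, se_cutoff: float = DEFAULT_SE_CUTOFF
) -> str:
    _check_complete(session)
    branch = _imputation_branch(session, card)
    if branch is not None:
        return branch
    return INDETERMINATE if session.raw_se > se_cutoff else DETERMINATE


def score_session(
    session: SessionRecord, card: CardLayout, se_cutoff: float = DEFAULT_SE_CUTOFF
) -> SessionRecord:
    """Fill final threshold, false-alarm flags and QC label on a record."""
    fa_first, fa_both = false_alarm_flags(session, card)
    return replace(
        session,
        final_threshold=finalize_threshold(session, card),
        fa_first_blank=fa_first,
        fa_both_blanks=fa_both,
        qc=qc_classify(session, card, se_cutoff),
    )


# -- session log round-trip ------------------------------------------------

_LOG_FIELDS = ["trial_index", "label_id", "rung_or_BLANK", "response"]


def write_session_log(session: SessionRecord, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LOG_FIELDS)
        for i, t in enumerate(session.trials, start=1):
            rung = "BLANK" if t.stimulus is BLANK else t.stimulus
            w.writerow([i, t.label_id, rung, t.response])


def read_session_trials(path: str) -> tuple[Trial, ...]:
    trials = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rung = row["rung_or_BLANK"]
            stim = BLANK if rung == "BLANK" else float(rung)
            trials.append(Trial(int(row["label_id"]), stim, row["response"]))
    return tuple(trials)


def response_history(trials: Sequence[Trial]) -> str:
    """Response pattern as a 'YN...' string (lookup-table key)."""
    return "".join(t.response for t in trials)
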