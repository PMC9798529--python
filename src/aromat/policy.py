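"""Adaptive label selection, session running, lookup-table compilation.

Trial 1 is always label 1 (an intermediate concentration that most
normosmic observers can smell).  Every subsequent trial is chosen
greedily: for each still-available label the engine computes the
*expected* posterior SD of log tau after sniffing it,

    E[SE] = p_yes * SE(posterior | YES) + (1 - p_yes) * SE(posterior | NO),

where p_yes is the posterior-predictive YES probability at that label's
content, and picks the label minimizing this quantity (lowest label id
on ties, so duplicate rungs are consumed in a fixed order).  Blanks are
ordinary candidates — early on they are often informative about the
criterion.  The test always ends after 8 trials.

Because the choice depends only on the response history (the posterior
is a deterministic function of it), the full decision tree can be
compiled ahead of time: 254 next-label decisions for histories of
length 1..7 plus 256 terminal estimates for the complete histories.
The compiled table drives sessions with zero posterior computation and
is byte-serializable to JSON, version-stamped with the card and prior
hashes so a stale table is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .card import CardLayout, card_hash, concentration_of, remaining_labels
from .posterior import (
    PosteriorGrid,
    PriorConfig,
    init_prior,
    predictive_yes,
    prior_hash,
    summarize,
    update,
)
from .psychometric import NO, YES, Trial
from .scoring import (
    DEFAULT_SE_CUTOFF,
    SessionRecord,
    score_session,
)

FIRST_LABEL = 1
N_TRIALS = 8


class SessionExhaustedError(RuntimeError):
    """No labels left to select."""


class UnavailableLabelError(ValueError):
    """Expected-uncertainty query for a label that is used or absent."""


class StaleTableError(ValueError):
    """Lookup table was compiled for a different card or prior."""


@dataclass
class SessionState:
    """Running state of one test: trials so far, posterior, used labels."""

    trials: list[Trial] = field(default_factory=list)
    grid: PosteriorGrid | None = None
    used: set[int] = field(default_factory=set)


def expected_uncertainty(grid: PosteriorGrid, card: CardLayout, label_id: int) -> float:
    """Response-probability-weighted posterior SD of log tau after a label."""
    if label_id not in remaining_labels(card, set()):
        raise UnavailableLabelError(f"label {label_id} is not a selectable card label")
    stim = concentration_of(card, label_id)
    p_yes = predictive_yes(grid, stim)
    se_yes = update(grid, stim, YES).tau_sd
    se_no = update(grid, stim, NO).tau_sd
    return p_yes * se_yes + (1.0 - p_yes) * se_no


def select_next(state: SessionState, card: CardLayout) -> int:
    """Greedy argmin of expected uncertainty over available labels."""
    if not state.trials:
        raise ValueError("trial 1 is fixed to label 1 and is not selected adaptively")
    candidates = sorted(remaining_labels(card, state.used))
    if not candidates:
        raise SessionExhaustedError("no labels left on the card")
    best_id, best_val = None, None
    for lid in candidates:  # ascending id: ties keep the lowest id
        val = expected_uncertainty(state.grid, card, lid)
        if best_val is None or val < best_val:
            best_id, best_val = lid, val
    return best_id


def run_session(
    responder: Callable[[float | None], str],
    card: CardLayout,
    config: PriorConfig | None = None,
    n_trials: int = N_TRIALS,
    se_cutoff: float = DEFAULT_SE_CUTOFF,
    table: "LookupTable | None" = None,
) -> SessionRecord:
    """Run one full test against a responder callable.

    With ``table`` given, label choices and the final estimate come from
    the precompiled lookup table (no posterior computation); otherwise
    the posterior is updated online after every response.
    """
    if table is not None:
        return _run_session_table(responder, card, table, se_cutoff)
    config = config or PriorConfig()
    state = SessionState(grid=init_prior(config))
    label = FIRST_LABEL
    for _ in range(n_trials):
        stim = concentration_of(card, label)
        resp = responder(stim)
        if resp not in (YES, NO):
            raise ValueError(f"responder must return {YES!r} or {NO!r}, got {resp!r}")
        state.trials.append(Trial(label, stim, resp))
        state.used.add(label)
        state.grid = update(state.grid, stim, resp)
        if len(state.trials) < n_trials:
            label = select_next(state, card)
    est = summarize(state.grid)
    record = SessionRecord(
        trials=tuple(state.trials),
        raw_point=est.point,
        raw_se=est.se,
        n_trials_expected=n_trials,
    )
    return score_session(record, card, se_cutoff)


@dataclass(frozen=True)
class LookupTable:
    """Precompiled decision tree for the fixed 8-trial test.

    ``decisions`` maps each response history of length 1..7 ('Y'/'N'
    string) to the next label id; ``terminals`` maps each complete
    8-response history to the raw posterior summary.  The first label
    (history "") is fixed and stored separately.
    """

    card_hash: str
    prior_hash: str
    first_label: int
    decisions: dict[str, int]
    terminals: dict[str, dict]

    def next_label(self, history: str) -> int:
        return self.first_label if history == "" else self.decisions[history]

    def to_dict(self) -> dict:
        return {
            "card_hash": self.card_hash,
            "prior_hash": self.prior_hash,
            "first_label": self.first_label,
            "decisions": self.decisions,
            "terminals": self.terminals,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LookupTable":
        return cls(
            card_hash=d["card_hash"],
            prior_hash=d["prior_hash"],
            first_label=int(d["first_label"]),
            decisions={k: int(v) for k, v in d["decisions"].items()},
            terminals=d["terminals"],
        )

    def check_compatible(self, card: CardLayout, config: PriorConfig) -> None:
        if self.card_hash != card_hash(card) or self.prior_hash != prior_hash(config):
            raise StaleTableError(
                "lookup table was compiled for a different card or prior configuration"
            )


def compile_lookup(card: CardLayout, config: PriorConfig | None = None) -> LookupTable:
    """Enumerate all 2^8 response paths and freeze the decision tree."""
    config = config or PriorConfig()
    decisions: dict[str, int] = {}
    terminals: dict[str, dict] = {}

    def walk(trials: list[Trial], grid: PosteriorGrid, used: set[int], label: int) -> None:
        stim = concentration_of(card, label)
        for resp in (YES, NO):
            new_trials = trials + [Trial(label, stim, resp)]
            new_hist = "".join(t.response for t in new_trials)
            new_grid = update(grid, stim, resp)
            new_used = used | {label}
            if len(new_trials) == N_TRIALS:
                est = summarize(new_grid)
                scored = score_session(
                    SessionRecord(
                        trials=tuple(new_trials), raw_point=est.point, raw_se=est.se
                    ),
                    card,
                )
                terminals[new_hist] = {
                    "point": est.point,
                    "se": est.se,
                    "final": scored.final_threshold,
                    "qc": scored.qc,
                }
            else:
                state = SessionState(trials=new_trials, grid=new_grid, used=new_used)
                nxt = select_next(state, card)
                decisions[new_hist] = nxt
                walk(new_trials, new_grid, new_used, nxt)

    walk([], init_prior(config), set(), FIRST_LABEL)
    return LookupTable(
        card_hash=card_hash(card),
        prior_hash=prior_hash(config),
        first_label=FIRST_LABEL,
        decisions=decisions,
        terminals=terminals,
    )


def _run_session_table(
    responder: Callable[[float | None], str],
    card: CardLayout,
    table: LookupTable,
    se_cutoff: float,
) -> SessionRecord:
    history = ""
    trials: list[Trial] = []
    for _ in range(N_TRIALS):
        label = table.next_label(history)
        stim = concentration_of(card, label)
        resp = responder(stim)
        if resp not in (YES, NO):
            raise ValueError(f"responder must return {YES!r} or {NO!r}, got {resp!r}")
        trials.append(Trial(label, stim, resp))
        history += resp
    term = table.terminals[history]
    record = SessionRecord(
        trials=tuple(trials), raw_point=term["point"], raw_se=term["se"]
    )
    return score_session(record, card, se_cutoff)


def scripted_responder(responses: str) -> Callable[[float | None], str]:
    """Responder that replays a fixed 'YN...' string, ignoring stimuli."""
    it = iter(responses)

    def respond(stimulus: float | None) -> str:
        return next(it)

    return respond
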