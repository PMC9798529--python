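"""The physical odor test card: labels, concentrations, blanks.

The card carries 17 peel-and-burst labels numbered 0-16.  Label 0 is an
unscored blank used to familiarize the participant with the background
smell of the card.  Of labels 1-16, fourteen carry phenylethyl alcohol
(PEA) at one of eight nominal concentrations spaced in half-log steps,
and two are blanks.  Concentrations are expressed on a nominal log10
scale anchored at 0.0 for the strongest label; the weakest rung is
therefore -3.5 (eight rungs spanning 3.5 orders of magnitude).  The
extreme rungs appear once each; the six intermediate rungs appear twice,
which lets the test revisit a concentration and, together with the
blanks, separates response bias from sensitivity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

#: Sentinel for an odorless (blank) label.  Serialized as the string
#: "BLANK" in card spec files; in memory it is ``None`` so arithmetic on
#: concentrations fails loudly if a blank slips through.
BLANK = None

#: The top rung (nominal log10 concentration 0.0) corresponds to 30% w/w
#: PEA on the physical card.  Documentation only; all computation is on
#: the nominal log10 scale.
ANCHOR_PCT_WW = 30.0

CARD_SPEC_VERSION = "1.0"

N_LABELS = 17
N_RUNGS = 8
STEP = 0.5

# Fixed label -> rung assignment.  The physical permutation is arbitrary
# (the algorithm only sees rung values); this one is version-controlled
# so lookup tables stay valid.  Label 1 holds an intermediate rung
# (-1.5), the rung the test always starts on.
_DEFAULT_ASSIGNMENT: dict[int, float | None] = {
    0: BLANK,
    1: -1.5,
    2: BLANK,
    3: -0.5,
    4: -2.5,
    5: -1.0,
    6: 0.0,
    7: -3.0,
    8: -2.0,
    9: BLANK,
    10: -0.5,
    11: -2.0,
    12: -1.0,
    13: -3.5,
    14: -2.5,
    15: -3.0,
    16: -1.5,
}


class CardError(ValueError):
    """An invalid card layout or an invalid reference into a card."""


@dataclass(frozen=True)
class CardLayout:
    """Mapping of label ids to nominal log10 concentrations or blanks.

    Attributes
    ----------
    labels
        Ordered map ``label_id -> content`` where content is a nominal
        log10 concentration (float, highest = 0.0) or :data:`BLANK`.
    """

    labels: dict[int, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived structure -------------------------------------------------

    @property
    def ladder(self) -> list[float]:
        """Distinct odorant rungs, ascending (weakest first)."""
        return sorted({c for c in self.labels.values() if c is not BLANK})

    @property
    def step(self) -> float:
        """log10 spacing between adjacent rungs."""
        ladder = self.ladder
        return ladder[1] - ladder[0]

    @property
    def odorant_labels(self) -> list[int]:
        return [i for i, c in self.labels.items() if c is not BLANK]

    @property
    def blank_labels(self) -> list[int]:
        return [i for i, c in self.labels.items() if c is BLANK]

    def validate(self) -> None:
        ids = sorted(self.labels)
        if ids != list(range(N_LABELS)):
            raise CardError(f"card must have labels 0..16, got {ids}")
        if self.labels[0] is not BLANK:
            raise CardError("label 0 must be blank (reference label)")
        body = {i: c for i, c in self.labels.items() if i >= 1}
        odorants = [c for c in body.values() if c is not BLANK]
        blanks = [c for c in body.values() if c is BLANK]
        if len(odorants) != 14 or len(blanks) != 2:
            raise CardError(
                f"labels 1..16 must hold 14 odorants and 2 blanks, "
                f"got {len(odorants)} and {len(blanks)}"
            )
        ladder = sorted(set(odorants))
        if len(ladder) != N_RUNGS:
            raise CardError(f"expected {N_RUNGS} distinct rungs, got {len(ladder)}")
        steps = [round(b - a, 9) for a, b in zip(ladder, ladder[1:])]
        if any(s != STEP for s in steps):
            raise CardError(f"rungs must be spaced {STEP} apart, got steps {steps}")
        if ladder[-1] != 0.0:
            raise CardError("highest rung must be 0.0 (anchor)")
        counts = {r: odorants.count(r) for r in ladder}
        if counts[ladder[0]] != 1 or counts[ladder[-1]] != 1:
            raise CardError("extreme rungs must appear on exactly one label")
        if any(counts[r] != 2 for r in ladder[1:-1]):
            raise CardError("intermediate rungs must appear on exactly two labels")


def build_default_card() -> CardLayout:
    """Construct the standard 17-label card with the fixed assignment."""
    return CardLayout(labels=dict(_DEFAULT_ASSIGNMENT))


def concentration_of(card: CardLayout, label_id: int) -> float | None:
    """Content of a label: a nominal log10 concentration or :data:`BLANK`."""
    if label_id not in card.labels:
        raise CardError(f"label id {label_id} not on card (valid: 0..16)")
    return card.labels[label_id]


def remaining_labels(card: CardLayout, used: Iterable[int]) -> set[int]:
    """Label ids still available for selection.

    Labels are single-use within a session; label 0 is the unscored
    reference and is never a candidate.
    """
    used = set(used)
    if not used <= set(range(1, N_LABELS)):
        raise CardError(f"used ids must be within 1..16, got {sorted(used)}")
    return set(range(1, N_LABELS)) - used


# -- serialization ---------------------------------------------------------


def card_to_dict(card: CardLayout) -> dict:
    return {
        "version": CARD_SPEC_VERSION,
        "labels": [
            {"id": i, "rung": "BLANK" if c is BLANK else c}
            for i, c in sorted(card.labels.items())
        ],
        "step": card.step,
        "anchor_pct_ww": ANCHOR_PCT_WW,
    }


def card_from_dict(d: dict) -> CardLayout:
    labels: dict[int, float | None] = {}
    for entry in d["labels"]:
        rung = entry["rung"]
        labels[int(entry["id"])] = BLANK if rung == "BLANK" else float(rung)
    return CardLayout(labels=labels)


def save_card(card: CardLayout, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(card_to_dict(card), fh, indent=1)
        fh.write("\n")


def load_card(path: str) -> CardLayout:
    with open(path) as fh:
        return card_from_dict(json.load(fh))


def card_hash(card: CardLayout) -> str:
    """Stable content hash used to version lookup tables."""
    blob = json.dumps(card_to_dict(card), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
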