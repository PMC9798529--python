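"""Signal-detection psychometric model for the yes/no odor task.

A single-stimulus (go/no-go) detection task confounds sensitivity with
the observer's willingness to say YES.  The model therefore carries two
observer parameters:

* ``log_tau`` — the detection threshold on the nominal log10
  concentration scale: the concentration at which the psychometric
  curve sits halfway between its floor and its ceiling.
* ``lam`` — the decision criterion in standard-normal units.  It maps
  to the false-alarm probability on blanks via ``gamma = Phi(-lam)``:
  a liberal observer (low ``lam``) says YES to blanks often.

The YES probability is a guess-rate-floored probit,

    P(YES | x) = gamma + (1 - gamma) * Phi((x - log_tau) / s),

with a fixed slope ``s`` (default 0.5 log10 units, one card step) that
is a configuration constant, not an inferred parameter.  On a blank the
stimulus term vanishes and P(YES) = gamma.  Because the floor is gamma
and the ceiling 1, the halfway point of the curve falls exactly at
``log_tau``, which is the threshold definition used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

from .card import BLANK

YES = "Y"
NO = "N"

#: Default psychometric slope, log10-concentration units (one card step).
DEFAULT_SLOPE = 0.5


@dataclass(frozen=True)
class PsychometricParams:
    """One observer (or one posterior-grid hypothesis)."""

    log_tau: float
    lam: float
    slope: float = DEFAULT_SLOPE

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class Trial:
    """One scored sniff: which label, what it contained, what was said."""

    label_id: int
    stimulus: float | None  # nominal log10 concentration, or BLANK
    response: str  # YES | NO

    def __post_init__(self) -> None:
        if self.response not in (YES, NO):
            raise ValueError(f"response must be {YES!r} or {NO!r}, got {self.response!r}")


def criterion_to_false_alarm(lam: float) -> float:
    """False-alarm probability gamma = Phi(-lam) on a blank stimulus."""
    return float(ndtr(-lam))


def yes_probability(params: PsychometricParams, stimulus: float | None) -> float:
    """P(YES) at a stimulus (or blank) under one parameter hypothesis."""
    gamma = ndtr(-params.lam)
    if stimulus is BLANK:
        return float(gamma)
    z = (stimulus - params.log_tau) / params.slope
    return float(gamma + (1.0 - gamma) * ndtr(z))


def yes_probability_grid(
    log_tau: np.ndarray, lam: np.ndarray, stimulus: float | None, slope: float
) -> np.ndarray:
    """Vectorized :func:`yes_probability` over broadcastable parameter arrays."""
    gamma = ndtr(-np.asarray(lam, dtype=float))
    if stimulus is BLANK:
        return np.broadcast_arrays(np.asarray(log_tau, dtype=float), gamma)[1].copy()
    z = (stimulus - np.asarray(log_tau, dtype=float)) / slope
    return gamma + (1.0 - gamma) * ndtr(z)


def response_loglik(params: PsychometricParams, trials: Sequence[Trial] | Iterable[Trial]) -> float:
    """Log-likelihood of an ordered response sequence (order-invariant)."""
    trials = list(trials)
    if not trials:
        raise ValueError("trials must be non-empty")
    total = 0.0
    for t in trials:
        p = yes_probability(params, t.stimulus)
        total += np.log(p) if t.response == YES else np.log1p(-p)
    return float(total)


__all__ = [
    "YES",
    "NO",
    "DEFAULT_SLOPE",
    "PsychometricParams",
    "Trial",
    "criterion_to_false_alarm",
    "yes_probability",
    "yes_probability_grid",
    "response_loglik",
]
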