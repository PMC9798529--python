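"""Grid Bayesian inference over (log tau, lambda).

The joint posterior over the threshold and the criterion is maintained
on a fixed rectangular grid and updated after every trial by pointwise
multiplication with the Bernoulli likelihood of the observed response,
followed by renormalization.  All updates are pure functions (the input
grid is never mutated) so the lookup-table compiler can branch cheaply.

Priors are independent normals: log(tau) ~ N(-3, 100) and
lambda ~ N(1, 0.5), with the second argument read as a VARIANCE (SD 10
for log tau — weakly informative — and SD ~0.707 for lambda).  The
alternative standard-deviation reading is selectable via
``PriorConfig.scales_are_variances`` so both interpretations can be
exercised.

The threshold estimate reported from a grid is the posterior mean of
log tau; its uncertainty is the posterior SD (the "standard error"
band of the fitted curve).  Under the guess-rate-floored probit the
concentration where the point-estimate curve crosses halfway between
its floor and ceiling equals the posterior-mean log tau exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtri

from .card import BLANK
from .psychometric import DEFAULT_SLOPE, YES, NO, yes_probability_grid


class ConfigError(ValueError):
    """Invalid prior/grid configuration."""


class DegeneratePosteriorError(RuntimeError):
    """All posterior mass annihilated by a numerically impossible response."""


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters, grid geometry and the fixed slope.

    ``tau_scale`` and ``lambda_scale`` are variances when
    ``scales_are_variances`` is true (the default reading), otherwise
    standard deviations.
    """

    tau_mean: float = -3.0
    tau_scale: float = 100.0
    lambda_mean: float = 1.0
    lambda_scale: float = 0.5
    scales_are_variances: bool = True
    # The tau grid is symmetric about the prior mean so the (nearly
    # flat) truncated prior keeps its stated mean of -3; it spans the
    # imputation range [-4.5, 1.0] with margin on both sides.
    tau_min: float = -7.5
    tau_max: float = 1.5
    tau_step: float = 0.05
    lambda_min: float = -1.0
    lambda_max: float = 3.0
    lambda_step: float = 0.1
    slope: float = DEFAULT_SLOPE

    def __post_init__(self) -> None:
        if self.tau_scale <= 0 or self.lambda_scale <= 0:
            raise ConfigError("prior scales must be positive")
        if self.tau_step <= 0 or self.lambda_step <= 0:
            raise ConfigError("grid resolution must be positive")
        if not (self.tau_min <= self.tau_mean <= self.tau_max):
            raise ConfigError("tau grid range must contain the prior mean")
        if not (self.lambda_min <= self.lambda_mean <= self.lambda_max):
            raise ConfigError("lambda grid range must contain the prior mean")
        if self.slope <= 0:
            raise ConfigError("slope must be positive")

    @property
    def tau_sd(self) -> float:
        return float(np.sqrt(self.tau_scale)) if self.scales_are_variances else self.tau_scale

    @property
    def lambda_sd(self) -> float:
        return (
            float(np.sqrt(self.lambda_scale))
            if self.scales_are_variances
            else self.lambda_scale
        )

    def refined(self, factor: int) -> "PriorConfig":
        """Same prior on a grid ``factor`` times finer (stability checks)."""
        return replace(
            self, tau_step=self.tau_step / factor, lambda_step=self.lambda_step / factor
        )


def prior_hash(config: PriorConfig) -> str:
    """Stable content hash used to version lookup tables."""
    blob = json.dumps(
        {k: getattr(config, k) for k in config.__dataclass_fields__}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class PosteriorGrid:
    """Discretized joint posterior; ``mass`` has shape (n_tau, n_lambda)."""

    tau_axis: np.ndarray
    lambda_axis: np.ndarray
    mass: np.ndarray
    config: PriorConfig
    # YES-probability matrices keyed by stimulus; shared across the pure
    # updates of one session/compilation so they are computed once.
    _p_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def yes_prob_matrix(self, stimulus: float | None) -> np.ndarray:
        key = stimulus
        if key not in self._p_cache:
            tau = self.tau_axis[:, None]
            lam = self.lambda_axis[None, :]
            self._p_cache[key] = yes_probability_grid(tau, lam, stimulus, self.config.slope)
        return self._p_cache[key]

    # -- marginal moments of log tau --------------------------------------

    @property
    def tau_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=1)

    @property
    def tau_mean(self) -> float:
        return float(self.tau_marginal @ self.tau_axis)

    @property
    def tau_sd(self) -> float:
        m = self.tau_mean
        var = float(self.tau_marginal @ (self.tau_axis - m) ** 2)
        return float(np.sqrt(max(var, 0.0)))

    @property
    def lambda_mean(self) -> float:
        return float(self.mass.sum(axis=0) @ self.lambda_axis)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Posterior summary of one session's threshold."""

    point: float  # posterior mean of log tau
    se: float  # posterior SD of log tau
    curve_min: float  # P(YES | blank) at the point-estimate parameters
    halfway_threshold: float  # curve's floor/ceiling midpoint crossing


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def init_prior(config: PriorConfig) -> PosteriorGrid:
    """Prior mass: product of the two independent normal densities."""
    tau_axis = _axis(config.tau_min, config.tau_max, config.tau_step)
    lambda_axis = _axis(config.lambda_min, config.lambda_max, config.lambda_step)
    tau_dens = np.exp(-0.5 * ((tau_axis - config.tau_mean) / config.tau_sd) ** 2)
    lam_dens = np.exp(-0.5 * ((lambda_axis - config.lambda_mean) / config.lambda_sd) ** 2)
    mass = np.outer(tau_dens, lam_dens)
    mass /= mass.sum()
    return PosteriorGrid(tau_axis=tau_axis, lambda_axis=lambda_axis, mass=mass, config=config)


def update(grid: PosteriorGrid, stimulus: float | None, response: str) -> PosteriorGrid:
    """Bayes update for one trial; pure (returns a new grid)."""
    if response not in (YES, NO):
        raise ValueError(f"response must be {YES!r} or {NO!r}")
    p_yes = grid.yes_prob_matrix(stimulus)
    lik = p_yes if response == YES else 1.0 - p_yes
    new_mass = grid.mass * lik
    total = new_mass.sum()
    if not total > 0:
        raise DegeneratePosteriorError(
            "posterior mass vanished; response numerically impossible under every hypothesis"
        )
    return PosteriorGrid(
        tau_axis=grid.tau_axis,
        lambda_axis=grid.lambda_axis,
        mass=new_mass / total,
        config=grid.config,
        _p_cache=grid._p_cache,
    )


def summarize(grid: PosteriorGrid) -> ThresholdEstimate:
    """Point estimate (posterior mean), SE (posterior SD) and curve landmarks."""
    point = grid.tau_mean
    se = grid.tau_sd
    lam = grid.lambda_mean
    gamma = float(yes_probability_grid(np.array(point), np.array(lam), BLANK, grid.config.slope))
    # Solve gamma + (1-gamma) Phi((x-point)/s) = (gamma+1)/2  =>  Phi(.) = 1/2.
    halfway = point + grid.config.slope * float(ndtri(0.5))
    return ThresholdEstimate(point=point, se=se, curve_min=gamma, halfway_threshold=halfway)


def predictive_yes(grid: PosteriorGrid, stimulus: float | None) -> float:
    """Posterior-predictive P(YES) at a stimulus: mass-weighted mixture."""
    return float((grid.mass * grid.yes_prob_matrix(stimulus)).sum())
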