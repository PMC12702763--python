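"""Synthetic cohort generator emulating the abilities-matrix study design.

Predictors are drawn from a zero-mean, unit-variance equicorrelated
multivariate normal (common pairwise correlation ``rho``).  A binary
take-over outcome is generated through a logistic link from a single latent
combination of a small *active* predictor set, with per-predictor effects
given on the standardized scale.  The intercept is solved numerically so the
population success rate equals the configured target.

Defaults mirror the reference study's conditions: 113 participants, 15
predictors, 5 active predictors with standardized effects
(+0.45, +0.35, +0.22, -0.42, -0.36) and a success base rate of 63/113.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .ability_data import AbilitiesMatrix, AbilityVariable, SuccessVector
from .errors import ValidationError

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate", "intercept_for_rate"]

#: Standardized effects of the five active predictors (default), signs and
#: magnitudes matching the reference coefficient table.
DEFAULT_EFFECTS = (0.45, 0.35, 0.22, -0.42, -0.36)

#: Default population success rate (63 successes out of 113 participants).
DEFAULT_SUCCESS_RATE = 63.0 / 113.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_vector`` entries apply to ``active_set`` predictors in order;
    ``predictor_correlation`` is the common pairwise correlation of the
    equicorrelated Gaussian predictor block.
    """

    n_participants: int = 113
    n_predictors: int = 15
    active_set: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_vector: tuple[float, ...] = DEFAULT_EFFECTS
    target_success_rate: float = DEFAULT_SUCCESS_RATE
    predictor_correlation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.n_predictors < 1:
            raise ValidationError("n_predictors must be >= 1")
        active = tuple(int(i) for i in self.active_set)
        effects = tuple(float(b) for b in self.effect_vector)
        if len(active) != len(effects):
            raise ValidationError(
                f"{len(active)} active predictors but {len(effects)} effects"
            )
        if len(set(active)) != len(active):
            raise ValidationError("active_set has duplicate indices")
        if active and (min(active) < 0 or max(active) >= self.n_predictors):
            raise ValidationError("active_set indices out of range")
        rho = self.predictor_correlation
        # equicorrelation matrix is positive definite iff -1/(p-1) < rho < 1;
        # only the non-negative range is exposed
        if not (0.0 <= rho < 1.0):
            raise ValidationError(
                f"predictor_correlation must be in [0, 1), got {rho}"
            )
        if not (0.0 < self.target_success_rate < 1.0):
            raise ValidationError("target_success_rate must be in (0, 1)")
        object.__setattr__(self, "active_set", active)
        object.__setattr__(self, "effect_vector", effects)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its generating truth (intercept and per-row
    linear predictor), for parameter-recovery checks."""

    abilities: AbilitiesMatrix
    success: SuccessVector
    intercept: float
    linear_predictor: np.ndarray
    config: SyntheticConfig


def intercept_for_rate(
    effect_vector: Sequence[float],
    predictor_correlation: float,
    target_success_rate: float,
) -> float:
    """Intercept alpha with ``E[logistic(alpha + beta' x)] = target`` for
    equicorrelated standard-normal predictors.

    The linear combination ``s = beta' x`` is normal with variance
    ``sum(beta^2) + rho * (sum(beta)^2 - sum(beta^2))``; the expectation over
    ``s`` is evaluated by Gauss-Hermite quadrature and alpha solved by root
    bracketing.  The achieved population rate matches the target to < 1e-6.
    """
    if not (0.0 < target_success_rate < 1.0):
        raise ValidationError("target_success_rate must be in (0, 1)")
    beta = np.asarray(effect_vector, dtype=float)
    rho = float(predictor_correlation)
    s2 = float(np.sum(beta**2) + rho * (np.sum(beta) ** 2 - np.sum(beta**2)))
    if s2 < 0:
        raise ValidationError("effect/correlation combination has negative variance")
    sigma = np.sqrt(s2)
    if sigma == 0.0:
        # closed form: logit of the target rate
        return float(np.log(target_success_rate / (1.0 - target_success_rate)))

    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    weights = weights / weights.sum()

    def achieved(alpha: float) -> float:
        return float(np.sum(weights * expit(alpha + sigma * nodes)))

    lo, hi = -40.0, 40.0
    f_lo = achieved(lo) - target_success_rate
    f_hi = achieved(hi) - target_success_rate
    if f_lo > 0 or f_hi < 0:
        raise ValidationError(
            "no intercept in [-40, 40] achieves the target success rate"
        )
    return float(brentq(lambda a: achieved(a) - target_success_rate, lo, hi,
                        xtol=1e-10))


def _synthetic_catalogue(p: int) -> tuple[AbilityVariable, ...]:
    return tuple(
        AbilityVariable(name=f"x{j + 1:02d}", task="synthetic",
                        description=f"synthetic predictor {j + 1}",
                        unit="SD", orientation=1)
        for j in range(p)
    )


def generate(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the configured generating model.

    One seeded generator drives all randomness; the Gaussian predictor block
    is drawn first and the Bernoulli outcome draws consume the stream after
    it, so the predictor matrix for a given seed is independent of the
    outcome model.
    """
    n, p = config.n_participants, config.n_predictors
    rho = config.predictor_correlation
    rng = np.random.default_rng(config.seed)

    # equicorrelated MVN via a shared factor: x = sqrt(rho) g + sqrt(1-rho) e
    g = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, p))
    X = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e

    beta = np.asarray(config.effect_vector, dtype=float)
    alpha = intercept_for_rate(beta, rho, config.target_success_rate)
    eta = alpha + (X[:, list(config.active_set)] @ beta if beta.size else 0.0)
    eta = np.asarray(eta, dtype=float) + np.zeros(n)
    y = (rng.random(n) < expit(eta)).astype(int)

    ids = tuple(f"S{i + 1:04d}" for i in range(n))
    abilities = AbilitiesMatrix(ids, _synthetic_catalogue(p), X)
    success = SuccessVector(ids, y)
    return SyntheticCohort(abilities, success, alpha, eta, config)
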