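"""Posterior beliefs over latent task variables and outcome utility maps.

Two binary-choice tasks share one abstraction: every option hides a latent
``h`` — the red-ball ratio of an urn, or the half-width of a partially
occluded reach target — and the decision-maker holds a normalized belief
``q(h | D, x)`` about it. Risky options carry a degenerate (delta) belief at
a known latent; ambiguous options carry a Beta posterior (urn) or a uniform
density over the occluded size range (motor).

Every belief exposes ``nodes_weights``, a fixed-order Gaussian quadrature
rule with normalized weights, so that downstream valuation can evaluate
``E_q[f(h)]`` as a weighted sum without knowing the belief family.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np
from scipy import special

__all__ = [
    "BetaBelief",
    "UniformSizeBelief",
    "DeltaBelief",
    "UtilityMap",
    "urn_utility",
    "urn_utility_map",
    "beta_posterior",
    "DEFAULT_QUAD_ORDER",
]

DEFAULT_QUAD_ORDER = 64


@lru_cache(maxsize=4096)
def _jacobi_rule(order: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    # Gauss-Jacobi on [-1, 1] with weight (1-x)^(b-1) (1+x)^(a-1); mapped to
    # h = (1+x)/2 this is quadrature against the Beta(a, b) density itself,
    # so polynomial expectations up to degree 2*order-1 are exact.
    x, w = special.roots_jacobi(order, b - 1.0, a - 1.0)
    h = 0.5 * (x + 1.0)
    w = w / w.sum()
    return h, w


@lru_cache(maxsize=8)
def _legendre_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = special.roots_legendre(order)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclasses.dataclass(frozen=True)
class BetaBelief:
    """Beta distribution over an urn's red-ball ratio h in [0, 1].

    Parameters are pseudo-counts: ``alpha_param`` for red, ``beta_param``
    for blue. The flat Beta(1, 1) prior encodes that all compositions of
    the ambiguous urn are a priori equiprobable.
    """

    alpha_param: float
    beta_param: float

    def __post_init__(self) -> None:
        if not (self.alpha_param > 0 and self.beta_param > 0):
            raise ValueError(
                f"Beta pseudo-counts must be positive, got "
                f"({self.alpha_param}, {self.beta_param})"
            )

    @property
    def mean(self) -> float:
        return self.alpha_param / (self.alpha_param + self.beta_param)

    @property
    def var(self) -> float:
        n = self.alpha_param + self.beta_param
        return self.alpha_param * self.beta_param / (n * n * (n + 1.0))

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 1.0)

    def pdf(self, h):
        from scipy import stats

        return stats.beta.pdf(h, self.alpha_param, self.beta_param)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.alpha_param, self.beta_param, size=size)

    def nodes_weights(self, order: int = DEFAULT_QUAD_ORDER):
        return _jacobi_rule(order, float(self.alpha_param), float(self.beta_param))


@dataclasses.dataclass(frozen=True)
class UniformSizeBelief:
    """Uniform density over a hidden target half-width on [lower, upper] (cm).

    ``lower`` is the visible half-width, ``upper = lower + occluder width``.
    A degenerate interval (lower == upper) is the fully visible target.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError(
                f"need 0 <= lower <= upper, got ({self.lower}, {self.upper})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def support(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def pdf(self, h):
        h = np.asarray(h, dtype=float)
        width = self.upper - self.lower
        if width == 0.0:
            raise ValueError("degenerate interval has no density; point mass")
        return np.where((h >= self.lower) & (h <= self.upper), 1.0 / width, 0.0)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=size)

    def nodes_weights(self, order: int = DEFAULT_QUAD_ORDER):
        if self.upper == self.lower:
            return np.array([self.lower]), np.array([1.0])
        u, w = _legendre_rule(order)
        return self.lower + (self.upper - self.lower) * u, w


@dataclasses.dataclass(frozen=True)
class DeltaBelief:
    """Point mass at a known latent (the risky option's belief)."""

    location: float

    @property
    def mean(self) -> float:
        return self.location

    @property
    def support(self) -> tuple[float, float]:
        return (self.location, self.location)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.location)

    def nodes_weights(self, order: int = DEFAULT_QUAD_ORDER):
        return np.array([self.location]), np.array([1.0])


@dataclasses.dataclass(frozen=True)
class UtilityMap:
    """U(h) = sum_o p(o|h) r(o) for a binary success/failure outcome.

    Default rewards r(failure) = -1, r(success) = 0: the only payoff is a
    penalty (a viscous-force punishment in the original tasks) on the bad
    outcome, so U(h) lies in [-1, 0].
    """

    failure_probability: Callable[[np.ndarray], np.ndarray]
    outcome_rewards: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"success": 0.0, "failure": -1.0}
    )

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        pf = np.asarray(self.failure_probability(h), dtype=float)
        out = (
            self.outcome_rewards["success"] * (1.0 - pf)
            + self.outcome_rewards["failure"] * pf
        )
        return out if out.ndim else float(out)


def urn_utility(h, *, inverse: bool = False):
    """Expected payoff of drawing from an urn with red ratio ``h``.

    Normal condition: blue is penalized, U(h) = -(1 - h).
    Inverse condition (reward-swap control): red is penalized, U(h) = -h.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0.0) or np.any(h > 1.0):
        raise ValueError("urn ratio h must lie in [0, 1]")
    out = -h if inverse else -(1.0 - h)
    return out if out.ndim else float(out)


def urn_utility_map(*, inverse: bool = False) -> UtilityMap:
    if inverse:
        return UtilityMap(failure_probability=lambda h: np.asarray(h, dtype=float))
    return UtilityMap(failure_probability=lambda h: 1.0 - np.asarray(h, dtype=float))


def beta_posterior(
    n_red: int, n_blue: int, prior_a: float = 1.0, prior_b: float = 1.0
) -> BetaBelief:
    """Beta posterior after observing ``n_red`` red and ``n_blue`` blue samples.

    Sampling with replacement (Beta-Bernoulli conjugacy); the flat default
    prior Beta(1, 1) treats all urn compositions as equiprobable. For the
    probe trials that matter for model comparison (symmetric evidence) the
    posterior mean coincides with the finite-urn, without-replacement
    (beta-binomial) mean, so the with-replacement default is innocuous.
    """
    if n_red < 0 or n_blue < 0:
        raise ValueError("observed counts must be nonnegative")
    return BetaBelief(prior_a + n_red, prior_b + n_blue)
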