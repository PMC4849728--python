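"""Option valuation and choice probabilities.

Two nested hypotheses about how an option ``x`` with belief ``q(h|D,x)``
and utility ``U(h)`` is valued:

* Expected utility:      V_0(x) = E_q[U(h)]
* Free energy:           V_beta(x) = (1/beta) * log E_q[exp(beta * U(h))]

The free-energy (multiplier-preference) value is the extremum of
``E_qt[U] - (1/beta) KL(qt || q)`` over distorted beliefs ``qt``; negative
``beta`` biases toward worst-case utilities (ambiguity aversion), positive
``beta`` toward best-case (ambiguity seeking), and ``beta -> 0`` recovers
expected utility. Choices follow a KL-constrained softmax over the two
option values with precision ``alpha`` and a (default uniform) prior
choice policy.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import logsumexp

from .beliefs import DEFAULT_QUAD_ORDER

__all__ = [
    "SubjectParams",
    "ChoicePrior",
    "expected_utility_value",
    "free_energy_value",
    "choice_probability",
    "log_choice_probability",
    "free_energy_from_nodes",
    "TAYLOR_BETA_THRESHOLD",
]

# Below this |beta| the log-sum-exp form loses precision to cancellation;
# the second-order expansion E[U] + (beta/2) Var[U] has error O(beta^2) < 1e-13
# for utilities bounded in [-1, 0].
TAYLOR_BETA_THRESHOLD = 1e-6


@dataclasses.dataclass(frozen=True)
class SubjectParams:
    """Free-energy subject parameters: softmax precision and ambiguity attitude.

    ``alpha >= 0`` scales sensitivity to value differences; ``beta < 0`` is
    ambiguity-averse, ``beta > 0`` ambiguity-seeking, ``beta = 0`` recovers
    the expected-utility model (the hypotheses are nested).
    """

    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclasses.dataclass(frozen=True)
class ChoicePrior:
    """Prior choice policy; the tasks assume no prior preference (1/2)."""

    p0_risk: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p0_risk < 1.0):
            raise ValueError("p0_risk must lie strictly in (0, 1)")

    @property
    def log_odds_risk(self) -> float:
        return math.log(self.p0_risk) - math.log(1.0 - self.p0_risk)


def expected_utility_value(belief, utility, order: int = DEFAULT_QUAD_ORDER) -> float:
    """V_0 = E_q[U(h)] by the belief's Gaussian quadrature rule."""
    h, w = belief.nodes_weights(order)
    return float(np.sum(w * np.asarray(utility(h), dtype=float)))


def free_energy_from_nodes(u: np.ndarray, logw: np.ndarray, beta: float):
    """V_beta from utility samples ``u`` with normalized log-weights ``logw``.

    Vectorized over leading axes: ``u`` and ``logw`` have shape (..., k) and
    the certainty-equivalent values have shape (...,). Uses log-sum-exp, with
    the second-order expansion for |beta| below the switch threshold.
    """
    u = np.asarray(u, dtype=float)
    logw = np.asarray(logw, dtype=float)
    if abs(beta) < TAYLOR_BETA_THRESHOLD:
        w = np.exp(logw)
        mean = np.sum(w * u, axis=-1)
        var = np.sum(w * u * u, axis=-1) - mean * mean
        return mean + 0.5 * beta * var
    return logsumexp(logw + beta * u, axis=-1) / beta


def free_energy_value(
    belief, utility, beta: float, order: int = DEFAULT_QUAD_ORDER
) -> float:
    """V_beta = (1/beta) log E_q[e^{beta U(h)}], the multiplier-preference value.

    Satisfies V_beta <= V_0 for beta < 0 and V_beta >= V_0 for beta > 0
    (Jensen), converges to V_0 as beta -> 0 and to U(h*) for a point-mass
    belief regardless of beta.
    """
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    h, w = belief.nodes_weights(order)
    u = np.asarray(utility(h), dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    return float(free_energy_from_nodes(u, logw, beta))


def log_choice_probability(
    v_risk: float,
    v_amb: float,
    alpha: float,
    prior: ChoicePrior | None = None,
):
    """(log p(risk), log p(amb)) under the prior-weighted softmax, stably."""
    if not np.all(np.asarray(alpha) >= 0):
        raise ValueError("alpha must be nonnegative")
    prior = prior or ChoicePrior()
    v_risk = np.asarray(v_risk, dtype=float)
    v_amb = np.asarray(v_amb, dtype=float)
    # log p(risk) = -log(1 + exp(-(alpha dv + log-odds))), dv = v_risk - v_amb
    z = alpha * (v_risk - v_amb) + prior.log_odds_risk
    log_p_risk = -np.logaddexp(0.0, -z)
    log_p_amb = -np.logaddexp(0.0, z)
    return log_p_risk, log_p_amb


def choice_probability(
    v_risk: float,
    v_amb: float,
    alpha: float,
    prior: ChoicePrior | None = None,
):
    """Probability of choosing the risky option.

    ``alpha = 0`` returns the prior; equal values with a uniform prior give
    exact indifference (1/2); p(risk) + p(amb) = 1 by construction.
    """
    log_p_risk, _ = log_choice_probability(v_risk, v_amb, alpha, prior)
    out = np.exp(log_p_risk)
    return out if np.ndim(out) else float(out)
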