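"""Occluded-target geometry: hit probabilities and the design equations.

A reach endpoint is modeled as zero-mean Gaussian with standard deviation
``endpoint_sd`` (cm). A fully visible target of half-width ``s`` is hit with
probability

    P_hit(s) = P(|X| <= s) = 2(F(s) - F(0)) = erf(s / (sd * sqrt(2))).

An ambiguous target shows half-width ``s`` plus occluders of width ``d``
on each side hiding the true edge; with the hidden half-width uniform on
[s, s+d] the *average* hitting probability is

    P_hit(s, d) = (1/d) * integral_{s}^{s+d} P_hit(x) dx.

The experimental design inverts these relations: ``solve_full_occluder``
finds the occluder width d_f achieving a target average probability at
s = 0 (full occlusion), and ``solve_visible_half_width`` finds s for a
given occluder so every ambiguity level has the same expected probability.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, special

from .beliefs import DEFAULT_QUAD_ORDER, _legendre_rule

__all__ = [
    "hit_probability",
    "avg_hit_probability",
    "solve_full_occluder",
    "solve_visible_half_width",
    "InfeasibleGeometryError",
    "MotorGeometry",
    "motor_utility_map",
]

_SQRT2 = math.sqrt(2.0)
_ROOT_TOL = 1e-12


class InfeasibleGeometryError(ValueError):
    """Raised when no nonnegative visible half-width satisfies the design."""


def _check_sd(endpoint_sd: float) -> None:
    if not endpoint_sd > 0:
        raise ValueError(f"endpoint_sd must be positive, got {endpoint_sd}")


def hit_probability(s, endpoint_sd: float):
    """P(|endpoint| <= s) for a fully visible target of half-width ``s``."""
    _check_sd(endpoint_sd)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("half-width s must be nonnegative")
    out = special.erf(s / (endpoint_sd * _SQRT2))
    return out if out.ndim else float(out)


def avg_hit_probability(
    s: float, d: float, endpoint_sd: float, order: int = DEFAULT_QUAD_ORDER
) -> float:
    """Mean hit probability when the hidden half-width is uniform on [s, s+d].

    Evaluated by fixed-order Gauss-Legendre quadrature; ``d == 0`` is the
    continuity limit ``hit_probability(s)``. Strictly increasing in both
    ``s`` and ``d``.
    """
    _check_sd(endpoint_sd)
    if s < 0 or d < 0:
        raise ValueError("s and d must be nonnegative")
    if d == 0.0:
        return float(hit_probability(s, endpoint_sd))
    u, w = _legendre_rule(order)
    x = s + d * u
    return float(np.sum(w * hit_probability(x, endpoint_sd)))


def solve_full_occluder(
    target_phit: float, endpoint_sd: float, xtol: float = 1e-10
) -> float:
    """Occluder width d_f with ``avg_hit_probability(0, d_f, sd) == target_phit``.

    Unique by strict monotonicity of the average hit probability in d.
    """
    _check_sd(endpoint_sd)
    if not (0.0 < target_phit < 1.0):
        raise ValueError(f"target_phit must lie in (0, 1), got {target_phit}")

    def f(d: float) -> float:
        return avg_hit_probability(0.0, d, endpoint_sd) - target_phit

    hi = endpoint_sd
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * endpoint_sd:  # pragma: no cover
            raise RuntimeError("failed to bracket full-occluder width")
    return float(optimize.brentq(f, 0.0, hi, xtol=xtol))


def solve_visible_half_width(
    target_phit: float, d: float, endpoint_sd: float, xtol: float = 1e-10
) -> float:
    """Visible half-width s >= 0 with the design's average hit probability.

    Requires ``d <= d_f(target_phit)``; beyond that even a zero visible
    half-width overshoots the target probability.
    """
    _check_sd(endpoint_sd)
    if not (0.0 < target_phit < 1.0):
        raise ValueError(f"target_phit must lie in (0, 1), got {target_phit}")
    if d < 0:
        raise ValueError("occluder width d must be nonnegative")
    at_zero = avg_hit_probability(0.0, d, endpoint_sd)
    if at_zero > target_phit + 1e-9:
        d_f = solve_full_occluder(target_phit, endpoint_sd)
        raise InfeasibleGeometryError(
            f"occluder width d={d:.6g} exceeds the full-occlusion bound "
            f"d_f={d_f:.6g} for target_phit={target_phit} "
            f"(endpoint_sd={endpoint_sd})"
        )

    def f(s: float) -> float:
        return avg_hit_probability(s, d, endpoint_sd) - target_phit

    if abs(f(0.0)) <= _ROOT_TOL:
        return 0.0
    # A visible target alone achieving target_phit upper-bounds the solution.
    hi = endpoint_sd * _SQRT2 * float(special.erfinv(target_phit)) + 1e-9
    return float(optimize.brentq(f, 0.0, hi, xtol=xtol))


@dataclasses.dataclass(frozen=True)
class MotorGeometry:
    """One ambiguous-target configuration of the reaching task.

    ``occluder_width = ambiguity_index * full_occluder`` and the visible
    half-width solves the average-hit-probability equation, so all
    ambiguity indices share the same expected hitting probability.
    """

    endpoint_sd: float
    visible_half_width: float
    occluder_width: float
    full_occluder: float
    ambiguity_index: float

    def __post_init__(self) -> None:
        _check_sd(self.endpoint_sd)
        if self.visible_half_width < 0 or self.occluder_width < 0:
            raise ValueError("lengths must be nonnegative")
        if not (0.0 <= self.ambiguity_index <= 1.0):
            raise ValueError("ambiguity_index must lie in [0, 1]")
        if abs(self.occluder_width - self.ambiguity_index * self.full_occluder) > 1e-8:
            raise ValueError("occluder_width must equal ambiguity_index * full_occluder")

    @classmethod
    def from_design(
        cls, target_phit: float, ambiguity_index: float, endpoint_sd: float
    ) -> "MotorGeometry":
        d_f = solve_full_occluder(target_phit, endpoint_sd)
        d = ambiguity_index * d_f
        s = solve_visible_half_width(target_phit, d, endpoint_sd)
        return cls(
            endpoint_sd=endpoint_sd,
            visible_half_width=s,
            occluder_width=d,
            full_occluder=d_f,
            ambiguity_index=ambiguity_index,
        )

    @property
    def expected_phit(self) -> float:
        return avg_hit_probability(
            self.visible_half_width, self.occluder_width, self.endpoint_sd
        )


def motor_utility_map(endpoint_sd: float, *, inverse: bool = False):
    """Utility of a target of true half-width h: miss is penalized by -1.

    Inverse condition swaps the penalty onto the hit outcome.
    """
    from .beliefs import UtilityMap

    _check_sd(endpoint_sd)
    if inverse:
        return UtilityMap(failure_probability=lambda h: hit_probability(h, endpoint_sd))
    return UtilityMap(
        failure_probability=lambda h: 1.0 - np.asarray(hit_probability(h, endpoint_sd))
    )
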