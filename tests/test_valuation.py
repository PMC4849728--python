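"""Expected-utility and free-energy valuation, softmax choice."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, special

from ambival import (
    BetaBelief,
    ChoicePrior,
    DeltaBelief,
    MotorGeometry,
    SubjectParams,
    UniformSizeBelief,
    beta_posterior,
    choice_probability,
    expected_utility_value,
    free_energy_value,
    motor_utility_map,
    urn_utility,
)


class TestExpectedUtility:
    def test_delta_belief_returns_point_utility(self):
        assert expected_utility_value(DeltaBelief(0.3), urn_utility) == pytest.approx(
            -0.7
        )

    def test_flat_beta_urn_value(self):
        assert expected_utility_value(BetaBelief(1, 1), urn_utility) == pytest.approx(
            -0.5, abs=1e-12
        )

    @pytest.mark.parametrize("a_index", [0.2, 0.5, 1.0])
    def test_probe_motor_geometry_is_worth_minus_half(self, a_index):
        """Probe-trial geometry solved from the design equation gives an
        expected hit probability of 50%, hence expected utility -0.5."""
        geom = MotorGeometry.from_design(0.5, a_index, 1.0)
        belief = UniformSizeBelief(
            geom.visible_half_width, geom.visible_half_width + geom.occluder_width
        )
        v = expected_utility_value(belief, motor_utility_map(1.0))
        assert v == pytest.approx(-0.5, abs=1e-9)


class TestFreeEnergyValue:
    def test_beta_zero_equals_expected_utility(self):
        for belief in [BetaBelief(1, 1), BetaBelief(6, 3), UniformSizeBelief(0.2, 1.4)]:
            u = urn_utility if isinstance(belief, BetaBelief) else motor_utility_map(1.0)
            assert free_energy_value(belief, u, 0.0) == pytest.approx(
                expected_utility_value(belief, u), abs=1e-12
            )

    @pytest.mark.parametrize("beta", [-10.0, -1.0, 1e-9, 2.0, 25.0])
    def test_delta_belief_is_beta_independent(self, beta):
        assert free_energy_value(DeltaBelief(0.5), urn_utility, beta) == pytest.approx(
            -0.5, abs=1e-12
        )

    def test_monte_carlo_oracle_flat_beta(self, rng):
        beta = -2.0
        n = 10**6
        h = rng.beta(1, 1, size=n)
        samples = np.exp(beta * urn_utility(h))
        v_mc = math.log(samples.mean()) / beta
        se_logz = samples.std() / (samples.mean() * math.sqrt(n))
        v = free_energy_value(BetaBelief(1, 1), urn_utility, beta)
        assert abs(v - v_mc) < 3 * se_logz / abs(beta)

    @pytest.mark.parametrize(
        "a, b, beta", [(1, 1, -2.0), (3, 7, -8.0), (11, 11, 5.0), (51, 51, -20.0)]
    )
    def test_confluent_hypergeometric_closed_form(self, a, b, beta):
        # E_Beta(a,b)[e^{beta h}] = 1F1(a; a+b; beta)
        expected = -1.0 + math.log(special.hyp1f1(a, a + b, beta)) / beta
        assert free_energy_value(BetaBelief(a, b), urn_utility, beta) == pytest.approx(
            expected, rel=1e-10
        )

    @given(
        a=st.floats(0.5, 60.0),
        b=st.floats(0.5, 60.0),
        beta=st.floats(-20.0, 20.0).filter(lambda x: abs(x) > 1e-3),
    )
    def test_jensen_ordering(self, a, b, beta):
        belief = BetaBelief(a, b)
        gap = free_energy_value(belief, urn_utility, beta) - expected_utility_value(
            belief, urn_utility
        )
        assert math.copysign(1.0, gap) == math.copysign(1.0, beta)

    def test_nondecreasing_in_beta(self):
        belief = BetaBelief(2, 5)
        betas = np.linspace(-20, 20, 81)
        vals = [free_energy_value(belief, urn_utility, b) for b in betas]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_extreme_beta_limits_reach_support_extrema(self):
        belief = BetaBelief(1, 1)
        v_min = free_energy_value(belief, urn_utility, -500.0)
        v_max = free_energy_value(belief, urn_utility, 500.0)
        assert v_min == pytest.approx(-1.0, abs=0.05)
        assert v_max == pytest.approx(0.0, abs=0.05)

    def test_taylor_regime_is_continuous(self):
        belief = BetaBelief(3, 4)
        below = free_energy_value(belief, urn_utility, 9e-7)
        above = free_energy_value(belief, urn_utility, 1.1e-6)
        # the two betas differ by 2e-7, so V itself moves by ~Var/2 * 2e-7
        assert below == pytest.approx(above, abs=1e-8)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            free_energy_value(BetaBelief(1, 1), urn_utility, float("nan"))

    @pytest.mark.parametrize("beta", [-5.0, -1.0, 2.0])
    def test_variational_form_equivalence(self, beta):
        """The closed-form value equals the extremum of the KL-regularized
        variational objective over distorted beliefs on a 201-point grid."""
        h = np.linspace(0.0025, 0.9975, 201)
        q = h**2 * (1 - h) ** 4  # Beta(3,5) density shape on the grid
        q = q / q.sum()
        u = urn_utility(h)

        def objective(theta):
            # softmax parametrization keeps qt on the simplex
            logp = theta - special.logsumexp(theta)
            p = np.exp(logp)
            val = p @ u - (p @ (logp - np.log(q))) / beta
            return val

        def neg_or_pos(theta):
            return objective(theta) if beta < 0 else -objective(theta)

        def grad(theta):
            logp = theta - special.logsumexp(theta)
            p = np.exp(logp)
            g = u - (logp - np.log(q) + 1.0) / beta
            full = p * (g - p @ g)
            return full if beta < 0 else -full

        res = optimize.minimize(
            neg_or_pos, np.log(q), jac=grad, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        v_optimizer = objective(res.x)
        # closed-form distorted belief qt proportional to q e^{beta U}
        logz = special.logsumexp(np.log(q) + beta * u)
        v_closed_solution = logz / beta
        p_star = np.exp(np.log(q) + beta * u - logz)
        v_at_solution = p_star @ u - (p_star @ np.log(p_star / q)) / beta
        assert v_at_solution == pytest.approx(v_closed_solution, abs=1e-10)
        assert v_optimizer == pytest.approx(v_closed_solution, abs=1e-6)


class TestChoiceProbability:
    def test_indifference(self):
        assert choice_probability(-0.5, -0.5, 12.0) == pytest.approx(0.5, abs=1e-15)

    def test_zero_precision_returns_prior(self):
        prior = ChoicePrior(p0_risk=0.73)
        assert choice_probability(-0.2, -0.9, 0.0, prior) == pytest.approx(0.73)

    def test_hand_computed_softmax(self):
        assert choice_probability(-0.4, -0.6, 10.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12
        )

    def test_probabilities_sum_to_one(self):
        p_risk = choice_probability(-0.3, -0.7, 5.0)
        p_amb = 1.0 - choice_probability(-0.3, -0.7, 5.0)
        assert p_risk + p_amb == pytest.approx(1.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(-0.4, -0.6, -1.0)

    def test_extreme_values_do_not_overflow(self):
        assert choice_probability(0.0, -1.0, 100.0) == pytest.approx(1.0, abs=1e-12)
        assert choice_probability(-1.0, 0.0, 100.0) == pytest.approx(0.0, abs=1e-12)


class TestInformationModulation:
    """Probe-trial predictions: value and choice curves vs information."""

    pairs = [0, 1, 2, 5, 25, 50]

    def _values(self, beta):
        return [
            free_energy_value(beta_posterior(n, n), urn_utility, beta)
            for n in self.pairs
        ]

    def test_averse_value_increases_toward_indifference(self):
        vals = self._values(-4.0)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(-0.5, abs=0.01)
        assert all(v < -0.5 for v in vals)

    def test_seeking_value_decreases_toward_indifference(self):
        vals = self._values(4.0)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] == pytest.approx(-0.5, abs=0.01)
        assert all(v > -0.5 for v in vals)

    def test_choice_probability_monotone_toward_half(self):
        for beta, sign in [(-4.0, 1), (4.0, -1)]:
            p = [
                choice_probability(-0.5, v, 15.0)
                for v in self._values(beta)
            ]
            assert np.all(sign * np.diff(p) < 0)
            assert p[-1] == pytest.approx(0.5, abs=0.05)

    def test_expected_utility_probe_indifference_is_exact(self):
        for n in self.pairs:
            v_amb = expected_utility_value(beta_posterior(n, n), urn_utility)
            assert choice_probability(-0.5, v_amb, 30.0) == pytest.approx(
                0.5, abs=1e-12
            )


def test_subject_params_validation():
    with pytest.raises(ValueError):
        SubjectParams(alpha=-1.0)
    with pytest.raises(ValueError):
        SubjectParams(alpha=1.0, beta=float("inf"))
    with pytest.raises(ValueError):
        ChoicePrior(p0_risk=1.0)
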