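"""Maximum-likelihood fitting and comparison of the choice models.

Three per-subject models of binary risk-vs-ambiguity choice:

* ``eu`` — expected utility with softmax precision alpha (1 parameter);
* ``fe`` — free-energy / multiplier preferences with (alpha, beta);
* ``gs`` — dynamic Gilboa-Schmeidler: a single fitted Beta prior whose
  asymmetry realizes worst-/best-case belief selection, updated with the
  observed urn samples, plus softmax alpha (3 parameters; urn data only).

``eu`` is nested in ``fe`` at beta = 0, so a likelihood-ratio test applies;
non-nested comparisons use BIC. The public surface follows the
Model-and-Results convention: build an :class:`AmbiguityChoiceModel` from a
canonical trial table, call :meth:`~AmbiguityChoiceModel.fit`, and read
estimates, log-likelihood, BIC and a ``summary()`` off the results object.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as _io
from .beliefs import DEFAULT_QUAD_ORDER, _jacobi_rule, _legendre_rule, urn_utility
from .geometry import avg_hit_probability, hit_probability
from .valuation import ChoicePrior, SubjectParams, free_energy_from_nodes

__all__ = [
    "GSParams",
    "TrialValueTerms",
    "trial_value_terms",
    "option_values",
    "negative_log_likelihood",
    "AmbiguityChoiceModel",
    "AmbiguityChoiceResults",
    "FitResult",
    "fit_subject",
    "likelihood_ratio_test",
    "gs_value",
    "compare_models",
    "ModelComparison",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("eu", "fe", "gs")

_PARAM_NAMES = {"eu": ("alpha",), "fe": ("alpha", "beta"), "gs": ("alpha", "prior_a", "prior_b")}
_BOUNDS = {
    "alpha": (0.0, 100.0),
    "beta": (-50.0, 50.0),
    "prior_a": (0.01, 100.0),
    "prior_b": (0.01, 100.0),
}
# Coarse multistart grids: alpha log-spaced, beta signed-log-spaced.
_GRIDS = {
    "alpha": tuple(np.logspace(-1, 2, 8)),
    "beta": (-50.0, -10.0, -3.0, -1.0, 0.0, 1.0, 3.0, 10.0, 50.0),
    "prior_a": tuple(np.logspace(-1.5, 1.5, 5)),
    "prior_b": tuple(np.logspace(-1.5, 1.5, 5)),
}
_RESTART_AGREE_TOL = 1e-4


@dataclasses.dataclass(frozen=True)
class GSParams:
    """Gilboa-Schmeidler parameters: softmax alpha and the selected Beta prior.

    A pessimistic prior (prior_a < prior_b under default rewards) plays the
    role of the worst-case belief in the multiple-priors model.
    """

    alpha: float
    prior_a: float
    prior_b: float

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValueError("alpha must be nonnegative")
        if not (self.prior_a > 0 and self.prior_b > 0):
            raise ValueError("Beta prior parameters must be positive")


@dataclasses.dataclass(frozen=True)
class TrialValueTerms:
    """Precomputed per-trial quadrature terms for fast likelihood evaluation."""

    v_risk: np.ndarray  # (n,) risky-option value (beta-independent: delta belief)
    utilities: np.ndarray  # (n, k) U(h) at the ambiguous belief's nodes
    log_weights: np.ndarray  # (n, k) normalized log-weights
    chose_risk: np.ndarray | None  # (n,) bool, None if choices absent
    is_urn: np.ndarray  # (n,) bool: urn-type belief rows
    n_red: np.ndarray  # (n,) observed red (urn rows; 0 elsewhere)
    n_blue: np.ndarray  # (n,)
    inverse: np.ndarray  # (n,) bool utility_condition == inverse

    @property
    def n_trials(self) -> int:
        return len(self.v_risk)


def trial_value_terms(
    frame: pd.DataFrame, order: int = DEFAULT_QUAD_ORDER
) -> TrialValueTerms:
    """Build quadrature utilities/weights for every trial of a canonical table.

    Urn rows get Gauss-Jacobi nodes of the Beta(1 + n_red, 1 + n_blue)
    posterior; motor rows get Gauss-Legendre nodes of the uniform belief on
    [s, s + d] (a zero-width occluder degenerates to the point mass at s).
    The risky option always carries a delta belief, so its value is a
    single number per trial.
    """
    if len(frame) == 0:
        raise ValueError("empty dataset")
    n = len(frame)
    task = frame["task"].to_numpy()
    is_urn = np.isin(task, list(_io.URN_TASKS))
    inverse = (frame["utility_condition"].to_numpy() == "inverse")

    utilities = np.zeros((n, order))
    log_weights = np.full((n, order), -math.log(order))
    v_risk = np.zeros(n)
    n_red = np.zeros(n, dtype=int)
    n_blue = np.zeros(n, dtype=int)

    urn_idx = np.flatnonzero(is_urn)
    if urn_idx.size:
        nr = frame["n_red_obs"].to_numpy()[urn_idx].astype(int)
        nb = frame["n_blue_obs"].to_numpy()[urn_idx].astype(int)
        n_red[urn_idx], n_blue[urn_idx] = nr, nb
        for a, b in set(zip(1 + nr, 1 + nb)):
            h, w = _jacobi_rule(order, float(a), float(b))
            rows = urn_idx[(1 + nr == a) & (1 + nb == b)]
            u = np.where(inverse[rows, None], -h[None, :], h[None, :] - 1.0)
            utilities[rows] = u
            log_weights[rows] = np.log(w)[None, :]
        v_risk[urn_idx] = -0.5  # delta belief at the 50:50 risky urn

    mot_idx = np.flatnonzero(~is_urn)
    if mot_idx.size:
        s = frame["visible_half_width"].to_numpy(float)[mot_idx]
        d = frame["occluder_width"].to_numpy(float)[mot_idx]
        sd = frame["endpoint_sd"].to_numpy(float)[mot_idx]
        u01, w01 = _legendre_rule(order)
        x = s[:, None] + d[:, None] * u01[None, :]
        # hit_probability scales as x/sd: evaluate at x/sd with unit sd
        phit = np.asarray(hit_probability((x / sd[:, None]).ravel(), 1.0)).reshape(
            x.shape
        )
        utilities[mot_idx] = np.where(inverse[mot_idx, None], -phit, phit - 1.0)
        log_weights[mot_idx] = np.log(w01)[None, :]  # weights already sum to 1
        # Risky target matches the trial's expected hit probability.
        target_phit = np.array(
            [
                avg_hit_probability(si, di, sdi, order=order)
                for si, di, sdi in zip(s, d, sd)
            ]
        )
        v_risk[mot_idx] = np.where(
            inverse[mot_idx], -target_phit, target_phit - 1.0
        )

    chose_risk = None
    if "choice" in frame.columns and not frame["choice"].isna().any():
        chose_risk = frame["choice"].to_numpy() == "risk"

    return TrialValueTerms(
        v_risk=v_risk,
        utilities=utilities,
        log_weights=log_weights,
        chose_risk=chose_risk,
        is_urn=is_urn,
        n_red=n_red,
        n_blue=n_blue,
        inverse=inverse,
    )


def option_values(terms: TrialValueTerms, model: str, params) -> tuple[np.ndarray, np.ndarray]:
    """(v_risk, v_amb) arrays for every trial under the named model."""
    model = model.lower()
    if model == "eu":
        v_amb = free_energy_from_nodes(terms.utilities, terms.log_weights, 0.0)
    elif model == "fe":
        beta = params.beta if hasattr(params, "beta") else params[1]
        v_amb = free_energy_from_nodes(terms.utilities, terms.log_weights, beta)
    elif model == "gs":
        if not terms.is_urn.all():
            raise ValueError("the Gilboa-Schmeidler model applies to urn-type trials only")
        a0 = params.prior_a if hasattr(params, "prior_a") else params[1]
        b0 = params.prior_b if hasattr(params, "prior_b") else params[2]
        mean = (a0 + terms.n_red) / (a0 + b0 + terms.n_red + terms.n_blue)
        v_amb = np.where(terms.inverse, -mean, mean - 1.0)
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_FAMILIES}")
    return terms.v_risk, v_amb


def _nll_from_values(v_risk, v_amb, alpha, chose_risk, prior: ChoicePrior) -> float:
    z = alpha * (v_risk - v_amb) + prior.log_odds_risk
    # -log p(chosen) in the log domain; never floors probabilities.
    nll = np.where(chose_risk, np.logaddexp(0.0, -z), np.logaddexp(0.0, z))
    return float(nll.sum())


def negative_log_likelihood(
    data: pd.DataFrame | TrialValueTerms,
    params,
    model: str,
    prior: ChoicePrior | None = None,
) -> float:
    """-sum_t log p(choice_t) under the named model."""
    terms = data if isinstance(data, TrialValueTerms) else trial_value_terms(data)
    if terms.chose_risk is None:
        raise ValueError("dataset has no recorded choices")
    prior = prior or ChoicePrior()
    alpha = params.alpha if hasattr(params, "alpha") else params[0]
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    v_risk, v_amb = option_values(terms, model, params)
    return _nll_from_values(v_risk, v_amb, alpha, terms.chose_risk, prior)


class AmbiguityChoiceModel:
    """A per-subject binary-choice model over a canonical trial table.

    Parameters
    ----------
    data : pandas.DataFrame
        Canonical trial/choice rows (one subject's trials, typically).
    family : {"eu", "fe", "gs"}
        Valuation family; "gs" requires urn-type trials only.
    prior : ChoicePrior, optional
        Prior choice policy (default: uniform).
    quad_order : int
        Fixed Gaussian-quadrature order for the ambiguous-belief values.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        family: str = "fe",
        prior: ChoicePrior | None = None,
        quad_order: int = DEFAULT_QUAD_ORDER,
    ):
        family = family.lower()
        if family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if len(data) == 0:
            raise ValueError("empty dataset")
        self.family = family
        self.prior = prior or ChoicePrior()
        self.data = data
        self.terms = trial_value_terms(data, order=quad_order)
        if self.terms.chose_risk is None:
            raise ValueError("dataset has no recorded choices")
        if family == "gs" and not self.terms.is_urn.all():
            raise ValueError("the Gilboa-Schmeidler model applies to urn-type trials only")
        self.param_names = _PARAM_NAMES[family]
        self.nobs = len(data)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, subject: str | None = None, family: str = "fe", **kw
    ) -> "AmbiguityChoiceModel":
        if subject is not None:
            frame = frame[frame["subject_id"] == subject].reset_index(drop=True)
        return cls(frame, family=family, **kw)

    def _as_vector(self, params) -> np.ndarray:
        if hasattr(params, "alpha"):
            return np.array([getattr(params, n) for n in self.param_names])
        return np.asarray(params, dtype=float)

    def nloglike(self, params) -> float:
        vec = self._as_vector(params)
        v_risk, v_amb = option_values(self.terms, self.family, vec)
        return _nll_from_values(v_risk, v_amb, vec[0], self.terms.chose_risk, self.prior)

    def loglike(self, params) -> float:
        return -self.nloglike(params)

    def fit(
        self,
        fixed: Mapping[str, float] | None = None,
        n_refine: int = 3,
        xtol: float = 1e-8,
    ) -> "AmbiguityChoiceResults":
        """Multistart MLE: coarse grid, then bounded Powell refinement.

        ``fixed`` pins named parameters (e.g. ``{"beta": 0.0}`` turns the
        free-energy family into its expected-utility special case).
        """
        fixed = dict(fixed or {})
        free = [n for n in self.param_names if n not in fixed]
        if not free:
            raise ValueError("at least one parameter must be free")

        def full(vec_free: np.ndarray) -> np.ndarray:
            it = iter(vec_free)
            return np.array(
                [fixed[n] if n in fixed else next(it) for n in self.param_names]
            )

        def objective(vec_free: np.ndarray) -> float:
            vec = full(np.asarray(vec_free, dtype=float))
            if vec[0] < 0:
                return np.inf
            return self.nloglike(vec)

        grid_pts = list(itertools.product(*[_GRIDS[n] for n in free]))
        grid_vals = [objective(np.array(p)) for p in grid_pts]
        order = np.argsort(grid_vals)
        bounds = [_BOUNDS[n] for n in free]

        best = None
        optima = []
        any_converged = False
        for k in order[:n_refine]:
            res = optimize.minimize(
                objective,
                np.array(grid_pts[k], dtype=float),
                method="Powell",
                bounds=bounds,
                options={"xtol": xtol, "ftol": xtol, "maxiter": 5000},
            )
            any_converged = any_converged or bool(res.success)
            optima.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        nll = float(best.fun)
        n_agree = int(sum(abs(v - nll) <= _RESTART_AGREE_TOL for v in optima))
        params = full(np.asarray(best.x, dtype=float))
        return AmbiguityChoiceResults(
            model=self,
            params=params,
            log_likelihood=-nll,
            converged=any_converged,
            n_restarts_agreeing=n_agree,
        )


class AmbiguityChoiceResults:
    """Fit results: estimates, log-likelihood, BIC, convergence diagnostics."""

    def __init__(self, model, params, log_likelihood, converged, n_restarts_agreeing):
        self.model = model
        self.model_name = model.family
        self.params = np.asarray(params, dtype=float)
        self.param_names = model.param_names
        self.log_likelihood = float(log_likelihood)
        self.n_trials = int(model.nobs)
        self.n_params = len(model.param_names)
        self.converged = bool(converged)
        self.n_restarts_agreeing = int(n_restarts_agreeing)

    @property
    def llf(self) -> float:
        return self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_trials) - 2.0 * self.log_likelihood

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    def __getattr__(self, name):
        try:
            idx = object.__getattribute__(self, "param_names").index(name)
        except (ValueError, AttributeError):
            raise AttributeError(name) from None
        return float(object.__getattribute__(self, "params")[idx])

    def subject_params(self):
        if self.model_name == "gs":
            return GSParams(*self.params)
        if self.model_name == "fe":
            return SubjectParams(alpha=self.params[0], beta=self.params[1])
        return SubjectParams(alpha=self.params[0], beta=0.0)

    def lr_test(self, null: "AmbiguityChoiceResults") -> tuple[float, float]:
        """(statistic, p) for this fit against a nested null fit."""
        df = self.n_params - null.n_params
        p = likelihood_ratio_test(null.log_likelihood, self.log_likelihood, df)
        stat = max(0.0, 2.0 * (self.log_likelihood - null.log_likelihood))
        return stat, p

    def summary(self) -> str:
        lines = [
            f"Ambiguity choice model ({self.model_name.upper()})",
            "=" * 44,
            f"{'n trials':<22}{self.n_trials:>12d}",
            f"{'log-likelihood':<22}{self.log_likelihood:>12.3f}",
            f"{'BIC':<22}{self.bic:>12.3f}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'restarts agreeing':<22}{self.n_restarts_agreeing:>12d}",
            "-" * 44,
        ]
        for name, value in zip(self.param_names, self.params):
            lines.append(f"{name:<22}{value:>12.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        pars = ", ".join(
            f"{n}={v:.3g}" for n, v in zip(self.param_names, self.params)
        )
        return (
            f"<AmbiguityChoiceResults {self.model_name} [{pars}] "
            f"llf={self.log_likelihood:.2f} bic={self.bic:.2f}>"
        )


# Backwards-compatible alias: the results object carries exactly the
# fields of a fit record (model, params, log_likelihood, n_trials,
# n_params, bic, converged, n_restarts_agreeing).
FitResult = AmbiguityChoiceResults


def fit_subject(
    data: pd.DataFrame, model: str = "fe", prior: ChoicePrior | None = None, **kw
) -> AmbiguityChoiceResults:
    """Fit one model family to one subject's trials by multistart MLE."""
    return AmbiguityChoiceModel(data, family=model, prior=prior).fit(**kw)


def likelihood_ratio_test(ll_null: float, ll_alt: float, df: int) -> float:
    """Upper-tail chi-square p-value for 2*(ll_alt - ll_null) on ``df`` dof."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if ll_alt < ll_null - 1e-6:
        raise ValueError(
            f"nesting violated: alternative log-likelihood {ll_alt} below null "
            f"{ll_null} (optimizer failure?)"
        )
    statistic = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(stats.chi2.sf(statistic, df))


def gs_value(n_red: int, n_blue: int, gs: GSParams, utility=None) -> float:
    """Ambiguous-option value under the dynamic Gilboa-Schmeidler model.

    The fitted Beta prior is updated with the observed counts and the
    option is valued at the posterior-mean utility; an asymmetric prior
    realizes the selected extreme (worst- or best-case) belief.
    """
    if n_red < 0 or n_blue < 0:
        raise ValueError("observed counts must be nonnegative")
    mean = (gs.prior_a + n_red) / (gs.prior_a + gs.prior_b + n_red + n_blue)
    u = utility if utility is not None else urn_utility
    return float(u(mean))


@dataclasses.dataclass
class ModelComparison:
    """Per-subject fits plus pooled log-likelihood/BIC/LRT comparisons."""

    table: pd.DataFrame
    pooled: dict
    best_model: str

    def to_dict(self) -> dict:
        return {
            "best_model": self.best_model,
            "pooled": self.pooled,
            "per_subject": self.table.to_dict(orient="records"),
        }


def compare_models(
    data: pd.DataFrame | Mapping[str, pd.DataFrame],
    models: Sequence[str] = ("eu", "fe"),
    prior: ChoicePrior | None = None,
) -> ModelComparison:
    """Fit every model to every subject; pool log-likelihoods and BICs.

    Pooled BIC uses k = (params per subject) x (number of subjects) and
    n = total trials. When both "eu" and "fe" are fitted, reports the
    pooled likelihood-ratio test (df = number of subjects, one extra beta
    each) and per-subject df = 1 tests.
    """
    datasets = data if isinstance(data, Mapping) else _io.split_by_subject(data)
    models = [m.lower() for m in models]
    rows = []
    fits: dict[str, dict[str, AmbiguityChoiceResults]] = {m: {} for m in models}
    for sid, sub in datasets.items():
        for m in models:
            res = fit_subject(sub, model=m, prior=prior)
            fits[m][sid] = res
            row = {
                "subject_id": sid,
                "model": m,
                "log_likelihood": res.log_likelihood,
                "n_trials": res.n_trials,
                "n_params": res.n_params,
                "bic": res.bic,
                "converged": res.converged,
                "n_restarts_agreeing": res.n_restarts_agreeing,
            }
            row.update(dict(zip(res.param_names, res.params)))
            rows.append(row)
    table = pd.DataFrame(rows)

    n_subjects = len(datasets)
    total_trials = int(sum(len(s) for s in datasets.values()))
    pooled: dict = {"models": {}, "n_subjects": n_subjects, "n_trials": total_trials}
    for m in models:
        ll = float(sum(r.log_likelihood for r in fits[m].values()))
        k = len(_PARAM_NAMES[m]) * n_subjects
        pooled["models"][m] = {
            "log_likelihood": ll,
            "k": k,
            "bic": k * math.log(total_trials) - 2.0 * ll,
        }
    best_model = min(pooled["models"], key=lambda m: pooled["models"][m]["bic"])
    pooled["delta_bic"] = {
        f"{a}-{b}": pooled["models"][a]["bic"] - pooled["models"][b]["bic"]
        for a in models
        for b in models
        if a < b
    }
    if "eu" in models and "fe" in models:
        ll0 = pooled["models"]["eu"]["log_likelihood"]
        ll1 = pooled["models"]["fe"]["log_likelihood"]
        pooled["lrt"] = {
            "statistic": max(0.0, 2.0 * (ll1 - ll0)),
            "df": n_subjects,
            "p_value": likelihood_ratio_test(ll0, ll1, n_subjects),
            "per_subject_p": {
                sid: likelihood_ratio_test(
                    fits["eu"][sid].log_likelihood, fits["fe"][sid].log_likelihood, 1
                )
                for sid in datasets
            },
        }
    return ModelComparison(table=table, pooled=pooled, best_model=best_model)
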