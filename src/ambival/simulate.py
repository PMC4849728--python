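"""Synthetic trial generation and cohort simulation.

Reproduces the generative structure of the two experiments so that every
downstream stage (valuation, fitting, statistics) can be exercised on data
with known ground truth:

* Urn trials: the ambiguous urn's composition is drawn uniformly from the
  eleven compositions {(0,100), (10,90), ..., (100,0)} per 100 balls, the
  number of displayed samples uniformly from {0, 2, 4, 10, 50, 100}, and
  half of all trials are symmetric *probe* trials (equal red and blue
  samples shown; feedback drawn from a 50:50 urn) in which both options
  have identical expected utility.
* Motor trials: a target hitting probability from {0.3, ..., 0.7} (probe
  trials fix it at 0.5), an ambiguity index from {0, 0.1, ..., 1}, occluder
  width d = a * d_f with d_f the full-occlusion width, and the visible
  half-width solved so every ambiguity level shares the trial's expected
  hit probability. The hidden half-width is uniform over the occluded
  range, and reach endpoints are zero-mean Gaussian with a fixed per-subject
  standard deviation.

Choices are Bernoulli draws from the designated model's choice rule;
outcomes are Bernoulli penalties with the true latent's failure
probability.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .fitting import GSParams, option_values, trial_value_terms
from .geometry import MotorGeometry, hit_probability
from .valuation import ChoicePrior, SubjectParams, log_choice_probability

__all__ = [
    "URN_SAMPLE_SIZES",
    "URN_COMPOSITIONS",
    "MOTOR_PHIT_SET",
    "AMBIGUITY_INDICES",
    "UrnTrial",
    "MotorTrial",
    "SimulatedCohort",
    "generate_urn_trials",
    "generate_motor_trials",
    "trials_to_frame",
    "simulate_choices",
    "simulate_outcome",
    "simulate_cohort",
]

URN_SAMPLE_SIZES = (0, 2, 4, 10, 50, 100)
URN_COMPOSITIONS = tuple(range(0, 101, 10))  # red balls per 100
MOTOR_PHIT_SET = (0.3, 0.4, 0.5, 0.6, 0.7)
AMBIGUITY_INDICES = tuple(round(0.1 * i, 1) for i in range(11))
URN_TOTAL_BALLS = 100
DEFAULT_ENDPOINT_SD = 1.0  # cm
DEFAULT_N_URN_TRIALS = 600
DEFAULT_N_MOTOR_TRIALS = 750


@dataclasses.dataclass(frozen=True)
class UrnTrial:
    """One urn-task decision problem with its true latent composition."""

    true_red_count: int
    shown_samples: int
    observed_red: int
    observed_blue: int
    is_probe: bool

    def __post_init__(self) -> None:
        if self.observed_red + self.observed_blue != self.shown_samples:
            raise ValueError("observed counts must sum to shown_samples")
        if not (0 <= self.true_red_count <= URN_TOTAL_BALLS):
            raise ValueError("true_red_count must lie in [0, 100]")
        if self.is_probe and self.observed_red != self.observed_blue:
            raise ValueError("probe trials must show symmetric samples")

    @property
    def info_level(self) -> float:
        return self.shown_samples / URN_TOTAL_BALLS

    @property
    def true_ratio(self) -> float:
        return self.true_red_count / URN_TOTAL_BALLS


@dataclasses.dataclass(frozen=True)
class MotorTrial:
    """One motor-task decision problem with its true hidden target size."""

    target_phit: float
    ambiguity_index: float
    visible_half_width: float
    occluder_width: float
    true_half_width: float
    endpoint_sd: float
    is_probe: bool

    def __post_init__(self) -> None:
        lo = self.visible_half_width
        hi = lo + self.occluder_width
        if not (lo - 1e-9 <= self.true_half_width <= hi + 1e-9):
            raise ValueError("true_half_width must lie in [visible, visible+occluder]")
        if not (0.0 <= self.ambiguity_index <= 1.0):
            raise ValueError("ambiguity_index must lie in [0, 1]")
        if self.endpoint_sd <= 0:
            raise ValueError("endpoint_sd must be positive")

    @property
    def info_level(self) -> float:
        return 1.0 - self.ambiguity_index


@lru_cache(maxsize=512)
def _design_geometry(target_phit: float, ambiguity_index: float, endpoint_sd: float):
    return MotorGeometry.from_design(target_phit, ambiguity_index, endpoint_sd)


def generate_urn_trials(
    n_trials: int,
    probe_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
    sample_sizes: Sequence[int] = URN_SAMPLE_SIZES,
    compositions: Sequence[int] = URN_COMPOSITIONS,
) -> list[UrnTrial]:
    """Draw urn trials per the experimental design.

    Probe trials (fraction ``probe_fraction``) show symmetric samples and
    the feedback urn is 50:50; other trials draw a composition uniformly,
    then sample the displayed colors with replacement from it.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not (0.0 <= probe_fraction <= 1.0):
        raise ValueError("probe_fraction must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    trials = []
    for _ in range(n_trials):
        is_probe = rng.random() < probe_fraction
        shown = int(rng.choice(sample_sizes))
        if is_probe:
            trials.append(
                UrnTrial(
                    true_red_count=URN_TOTAL_BALLS // 2,
                    shown_samples=shown,
                    observed_red=shown // 2,
                    observed_blue=shown // 2,
                    is_probe=True,
                )
            )
        else:
            comp = int(rng.choice(compositions))
            n_red = int(rng.binomial(shown, comp / URN_TOTAL_BALLS)) if shown else 0
            trials.append(
                UrnTrial(
                    true_red_count=comp,
                    shown_samples=shown,
                    observed_red=n_red,
                    observed_blue=shown - n_red,
                    is_probe=False,
                )
            )
    return trials


def generate_motor_trials(
    n_trials: int,
    probe_fraction: float = 0.5,
    endpoint_sd: float = DEFAULT_ENDPOINT_SD,
    rng: np.random.Generator | None = None,
) -> list[MotorTrial]:
    """Draw motor trials per the experimental design (see module docstring)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not (0.0 <= probe_fraction <= 1.0):
        raise ValueError("probe_fraction must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    trials = []
    for _ in range(n_trials):
        is_probe = rng.random() < probe_fraction
        phit = 0.5 if is_probe else float(rng.choice(MOTOR_PHIT_SET))
        a = float(rng.choice(AMBIGUITY_INDICES))
        geom = _design_geometry(phit, a, endpoint_sd)
        s, d = geom.visible_half_width, geom.occluder_width
        true_hw = float(rng.uniform(s, s + d)) if d > 0 else s
        trials.append(
            MotorTrial(
                target_phit=phit,
                ambiguity_index=a,
                visible_half_width=s,
                occluder_width=d,
                true_half_width=true_hw,
                endpoint_sd=endpoint_sd,
                is_probe=is_probe,
            )
        )
    return trials


def trials_to_frame(
    trials: Sequence[UrnTrial | MotorTrial],
    subject_id: str = "s00",
    utility_condition: str = "normal",
    task: str | None = None,
) -> pd.DataFrame:
    """Serialize trials into the canonical table (choice/payoff unfilled)."""
    rows = []
    for i, t in enumerate(trials):
        row = {c: np.nan for c in _io.COLUMNS}
        row.update(
            subject_id=subject_id,
            trial_index=i,
            is_probe=int(t.is_probe),
            info_level=t.info_level,
            utility_condition=utility_condition,
            choice=None,
            payoff=np.nan,
        )
        if isinstance(t, UrnTrial):
            row.update(
                task=task or "urn",
                n_red_obs=t.observed_red,
                n_blue_obs=t.observed_blue,
                true_red_count=t.true_red_count,
            )
        else:
            row.update(
                task=task or "motor",
                visible_half_width=t.visible_half_width,
                occluder_width=t.occluder_width,
                endpoint_sd=t.endpoint_sd,
                true_half_width=t.true_half_width,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=_io.COLUMNS)


def _failure_probability(frame: pd.DataFrame, chose_risk: np.ndarray) -> np.ndarray:
    """Per-trial probability of the penalized outcome for the chosen option."""
    is_urn = np.isin(frame["task"].to_numpy(), list(_io.URN_TASKS))
    inverse = frame["utility_condition"].to_numpy() == "inverse"
    p_fail = np.empty(len(frame))

    if is_urn.any():
        h_true = frame["true_red_count"].to_numpy(float)[is_urn] / URN_TOTAL_BALLS
        h = np.where(chose_risk[is_urn], 0.5, h_true)
        p_fail[is_urn] = np.where(inverse[is_urn], h, 1.0 - h)
    mot = ~is_urn
    if mot.any():
        sd = frame["endpoint_sd"].to_numpy(float)[mot]
        true_hw = frame["true_half_width"].to_numpy(float)[mot]
        p_hit_amb = np.asarray(hit_probability(true_hw / sd, 1.0))
        # risky target half-width reproduces the trial's expected P_hit
        s = frame["visible_half_width"].to_numpy(float)[mot]
        d = frame["occluder_width"].to_numpy(float)[mot]
        from .geometry import avg_hit_probability

        p_hit_risk = np.array(
            [avg_hit_probability(si, di, sdi) for si, di, sdi in zip(s, d, sd)]
        )
        p_hit = np.where(chose_risk[mot], p_hit_risk, p_hit_amb)
        p_fail[mot] = np.where(inverse[mot], p_hit, 1.0 - p_hit)
    return p_fail


def simulate_choices(
    trials: Sequence[UrnTrial | MotorTrial] | pd.DataFrame,
    params: SubjectParams | GSParams,
    model: str = "fe",
    rng: np.random.Generator | None = None,
    prior: ChoicePrior | None = None,
    subject_id: str = "s00",
    utility_condition: str = "normal",
) -> pd.DataFrame:
    """Fill choices and payoffs by forward-simulating the designated model."""
    model = model.lower()
    rng = rng if rng is not None else np.random.default_rng()
    prior = prior or ChoicePrior()
    frame = (
        trials.copy()
        if isinstance(trials, pd.DataFrame)
        else trials_to_frame(trials, subject_id, utility_condition)
    )
    terms = trial_value_terms(frame)
    v_risk, v_amb = option_values(terms, model, params)
    log_p_risk, _ = log_choice_probability(v_risk, v_amb, params.alpha, prior)
    chose_risk = rng.random(len(frame)) < np.exp(log_p_risk)
    frame["choice"] = np.where(chose_risk, "risk", "amb")
    p_fail = _failure_probability(frame, chose_risk)
    frame["payoff"] = np.where(rng.random(len(frame)) < p_fail, -1, 0)
    return frame


def simulate_outcome(
    trial: UrnTrial | MotorTrial,
    chosen_option: str,
    rng: np.random.Generator | None = None,
    utility_condition: str = "normal",
) -> int:
    """Payoff (0 or -1) of one trial given the chosen option's true latent."""
    if chosen_option not in ("risk", "amb"):
        raise ValueError("chosen_option must be 'risk' or 'amb'")
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(trial, UrnTrial):
        h = 0.5 if chosen_option == "risk" else trial.true_ratio
        p_good = h  # red is the safe outcome in the normal condition
    else:
        if chosen_option == "risk":
            p_good = trial.target_phit
        else:
            p_good = float(
                hit_probability(trial.true_half_width, trial.endpoint_sd)
            )
    p_fail = p_good if utility_condition == "inverse" else 1.0 - p_good
    return -1 if rng.random() < p_fail else 0


@dataclasses.dataclass
class SimulatedCohort:
    """A reproducible synthetic cohort: trials, choices and ground truth."""

    frame: pd.DataFrame
    subjects: list[tuple[str, SubjectParams | GSParams]]
    rng_seed: int
    model: str

    def truth(self) -> dict:
        return {
            sid: dataclasses.asdict(params) for sid, params in self.subjects
        }


def simulate_cohort(
    n_subjects: int = 16,
    task: str = "urn",
    n_trials: int | None = None,
    model: str = "fe",
    alpha_range: tuple[float, float] = (5.0, 30.0),
    beta_range: tuple[float, float] = (-6.0, 6.0),
    subject_params: Sequence[SubjectParams | GSParams] | None = None,
    probe_fraction: float = 0.5,
    endpoint_sd: float = DEFAULT_ENDPOINT_SD,
    utility_condition: str = "normal",
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a cohort mirroring the study groups (16 subjects by default).

    Per-subject parameters are drawn uniformly from the given ranges unless
    supplied explicitly; choices come from the designated model family.
    """
    if task not in _io.TASKS:
        raise ValueError(f"unknown task {task!r}")
    model = model.lower()
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = (
            DEFAULT_N_URN_TRIALS if task in _io.URN_TASKS else DEFAULT_N_MOTOR_TRIALS
        )
    subjects: list[tuple[str, SubjectParams | GSParams]] = []
    frames = []
    for j in range(n_subjects):
        sid = f"s{j:02d}"
        if subject_params is not None:
            params = subject_params[j]
        elif model == "gs":
            params = GSParams(
                alpha=float(rng.uniform(*alpha_range)),
                prior_a=float(rng.uniform(0.5, 5.0)),
                prior_b=float(rng.uniform(0.5, 5.0)),
            )
        else:
            beta = 0.0 if model == "eu" else float(rng.uniform(*beta_range))
            params = SubjectParams(alpha=float(rng.uniform(*alpha_range)), beta=beta)
        subjects.append((sid, params))
        if task in _io.URN_TASKS:
            trials = generate_urn_trials(n_trials, probe_fraction, rng)
        else:
            trials = generate_motor_trials(n_trials, probe_fraction, endpoint_sd, rng)
        frame = trials_to_frame(trials, sid, utility_condition, task=task)
        frames.append(
            simulate_choices(
                frame, params, model=model, rng=rng, subject_id=sid,
                utility_condition=utility_condition,
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    return SimulatedCohort(frame=cohort, subjects=subjects, rng_seed=seed, model=model)
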