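"""Descriptive and inferential statistics on probe-trial choice frequencies.

Per-condition aggregation of risky-choice rates by information level, the
exact binomial test of indifference against 50:50, the population-level
Wilcoxon signed-rank test of per-subject rates, and the Cochran-Armitage
trend test with linear scores (the information levels themselves).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_by_information",
    "pooled_by_information",
    "binomial_indifference_test",
    "wilcoxon_population_test",
    "trend_test",
    "statistics_table",
]


def aggregate_by_information(
    frame: pd.DataFrame, probe_only: bool = True
) -> pd.DataFrame:
    """Per-subject risky-choice rates by information level.

    Returns one row per (subject_id, info_level) with columns n_trials,
    n_risky_choices, risky_rate. By default restricted to probe trials,
    where expected utility predicts exact indifference.
    """
    if probe_only:
        frame = frame[frame["is_probe"] == 1]
        if len(frame) == 0:
            raise ValueError("dataset contains no probe trials")
    grouped = (
        frame.assign(risky=(frame["choice"] == "risk").astype(int))
        .groupby(["subject_id", "info_level"], sort=True)["risky"]
        .agg(n_trials="count", n_risky_choices="sum")
        .reset_index()
    )
    grouped["risky_rate"] = grouped["n_risky_choices"] / grouped["n_trials"]
    return grouped


def pooled_by_information(frame: pd.DataFrame, probe_only: bool = True) -> pd.DataFrame:
    """Risky-choice rates by information level pooled over subjects."""
    per = aggregate_by_information(frame, probe_only=probe_only)
    pooled = (
        per.groupby("info_level", sort=True)[["n_trials", "n_risky_choices"]]
        .sum()
        .reset_index()
    )
    pooled["risky_rate"] = pooled["n_risky_choices"] / pooled["n_trials"]
    return pooled


def binomial_indifference_test(k: int, n: int) -> float:
    """Exact two-sided binomial test of k successes in n against p = 1/2.

    Two-sidedness by the minimum-likelihood convention: sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(sps.binomtest(k, n, p=0.5, alternative="two-sided").pvalue)


def wilcoxon_population_test(per_subject_rates) -> float:
    """Wilcoxon signed-rank test of per-subject risky rates against 1/2.

    Zeros (rates exactly 1/2) are dropped (the 'wilcox' convention); the
    exact null distribution is used for n <= 25 when the nonzero absolute
    deviations are untied, otherwise the normal approximation.
    """
    rates = np.asarray(per_subject_rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 subjects")
    diffs = rates - 0.5
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        return 1.0
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return float(res.pvalue)


def trend_test(summaries: pd.DataFrame) -> tuple[float, float]:
    """Cochran-Armitage trend test with linear scores over information levels.

    ``summaries`` needs columns info_level, n_trials, n_risky_choices (one
    row per ordered level). Scores are the information levels themselves.
    Returns (z statistic, two-sided normal p-value); the statistic's sign
    gives the direction of the trend in risky choice with information.
    """
    required = {"info_level", "n_trials", "n_risky_choices"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    if len(summaries) < 3:
        raise ValueError("need at least 3 ordered information levels")
    s = summaries.sort_values("info_level")
    n = s["n_trials"].to_numpy(float)
    if np.any(n == 0):
        raise ValueError("every information level must have at least one trial")
    k = s["n_risky_choices"].to_numpy(float)
    w = s["info_level"].to_numpy(float)
    total = n.sum()
    pbar = k.sum() / total
    num = float(np.sum(w * (k - n * pbar)))
    var = pbar * (1.0 - pbar) * (np.sum(n * w**2) - np.sum(n * w) ** 2 / total)
    if var <= 0.0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def statistics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject test table over probe trials.

    One binomial-indifference row per (subject, information level) and one
    trend-test row per subject (statistic = z, condition = 'trend').
    """
    per = aggregate_by_information(frame, probe_only=True)
    rows = []
    for _, r in per.iterrows():
        rows.append(
            {
                "subject_id": r["subject_id"],
                "condition": r["info_level"],
                "n": int(r["n_trials"]),
                "k": int(r["n_risky_choices"]),
                "test": "binomial_indifference",
                "statistic": r["risky_rate"],
                "p_value": binomial_indifference_test(
                    int(r["n_risky_choices"]), int(r["n_trials"])
                ),
            }
        )
    for sid, sub in per.groupby("subject_id", sort=True):
        if len(sub) >= 3:
            z, p = trend_test(sub)
            rows.append(
                {
                    "subject_id": sid,
                    "condition": "trend",
                    "n": int(sub["n_trials"].sum()),
                    "k": int(sub["n_risky_choices"].sum()),
                    "test": "cochran_armitage",
                    "statistic": z,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
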