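"""Skaggs-style information scores with shuffle-based significance.

Selectivity of a unit's rate code for a task dimension (port position, odor
identity, or their conjunction) is quantified in bits per spike,

    I = sum_i P_i (F_i / F) log2(F_i / F),

where P_i is the occupancy probability of condition i, F_i the mean firing
rate in that condition, and F the overall mean rate. Scores are computed
from correct trials only, over one of four intervals of the trial: the
whole 1.5 s poke, a 500 ms *before* window (-0.75 to -0.25 s from poke
onset), a 500 ms *odor* window starting at odor onset (+0.25 s), and the
last 500 ms of the poke (*end*).

Significance is assessed against a condition-shuffle null: trial labels are
permuted (whole trials, preserving within-trial spike structure) and the
score recomputed; the observed score is significant if it strictly exceeds
the 95th percentile of the null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .session import POKE_DURATION

log = logging.getLogger("spikerhythm")

INTERVALS: dict[str, tuple[float, float]] = {
    "whole_poke": (0.0, POKE_DURATION),
    "before": (-0.75, -0.25),
    "odor": (0.25, 0.75),
    "end": (1.0, 1.5),
}

DIMENSIONS = ("position", "odor", "odor_position")


def information_score(P: np.ndarray, F_i: np.ndarray, F: float) -> float:
    """I = sum_i P_i (F_i/F) log2(F_i/F) in bits/spike; F_i = 0 terms are 0."""
    P = np.asarray(P, float)
    F_i = np.asarray(F_i, float)
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancy probabilities must sum to 1, got {P.sum()}")
    if F <= 0:
        raise ValueError("overall mean rate must be > 0 (unit fired no spikes)")
    if np.any(F_i < 0):
        raise ValueError("condition rates must be >= 0")
    ratio = F_i / F
    terms = np.zeros_like(ratio)
    pos = ratio > 0
    terms[pos] = P[pos] * ratio[pos] * np.log2(ratio[pos])
    return float(terms.sum())


def _condition_labels(trials: pd.DataFrame, dimension: str) -> np.ndarray:
    if dimension == "position":
        return trials["position"].to_numpy()
    if dimension == "odor":
        return trials["odor"].to_numpy()
    if dimension == "odor_position":
        return np.array([f"{o}{p}" for o, p in
                         zip(trials["odor"], trials["position"])])
    raise ValueError(f"unknown dimension {dimension!r}")


def _trial_counts(spike_times: np.ndarray, trials: pd.DataFrame,
                  interval: str) -> tuple[np.ndarray, float]:
    """Spike count per correct trial in the interval window; window length."""
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval {interval!r}")
    t0, t1 = INTERVALS[interval]
    st = np.asarray(spike_times, float)
    onsets = trials["onset"].to_numpy(float)
    counts = np.array([np.count_nonzero((st >= on + t0) & (st < on + t1))
                       for on in onsets])
    return counts, t1 - t0


def _score_from_counts(counts: np.ndarray, labels: np.ndarray,
                       win: float) -> float:
    """Information from per-trial counts; occupancy is the time share per
    condition (trial counts x fixed window length)."""
    cond, inv = np.unique(labels, return_inverse=True)
    n_per = np.bincount(inv, minlength=len(cond))
    spk_per = np.bincount(inv, weights=counts, minlength=len(cond))
    time_per = n_per * win
    P = time_per / time_per.sum()
    F_i = spk_per / time_per
    F = counts.sum() / time_per.sum()
    return information_score(P, F_i, F)


def condition_tables(spike_times: np.ndarray, trials: pd.DataFrame,
                     dimension: str, interval: str):
    """Occupancy probabilities, per-condition rates and overall rate from
    correct trials. Returns ``(P, F_i, F, condition_labels)``."""
    correct = trials[trials["outcome"] == "correct"]
    if len(correct) == 0:
        raise ValueError("no correct trials")
    counts, win = _trial_counts(spike_times, correct, interval)
    labels = _condition_labels(correct, dimension)
    cond, inv = np.unique(labels, return_inverse=True)
    n_per = np.bincount(inv, minlength=len(cond))
    spk_per = np.bincount(inv, weights=counts, minlength=len(cond))
    time_per = n_per * win
    P = time_per / time_per.sum()
    F_i = spk_per / time_per
    F = counts.sum() / time_per.sum()
    return P, F_i, float(F), cond


def shuffle_significance(spike_times: np.ndarray, trials: pd.DataFrame,
                         dimension: str, interval: str,
                         n_shuffles: int = 1000,
                         rng: np.random.Generator | int | None = None):
    """Observed score, 95th percentile of the condition-shuffled null, and
    the significance flag (strictly greater than the null 95th percentile).

    Whole-trial condition labels are permuted, preserving each trial's spike
    count; the shuffle stream is seeded and bit-reproducible.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be > 0")
    rng = np.random.default_rng(rng)
    correct = trials[trials["outcome"] == "correct"]
    labels = _condition_labels(correct, dimension)
    n_cond = len(np.unique(labels))
    if n_cond < 2:
        raise ValueError("need at least 2 conditions with occupancy")
    if len(correct) < n_cond:
        raise ValueError("fewer trials than conditions")
    counts, win = _trial_counts(spike_times, correct, interval)
    if counts.sum() == 0:
        raise ValueError("unit fired no spikes in the interval")
    I_obs = _score_from_counts(counts, labels, win)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = _score_from_counts(counts, rng.permutation(labels), win)
    p95 = float(np.percentile(null, 95))
    return float(I_obs), p95, bool(I_obs > p95)


def unit_information_table(session, dimensions=DIMENSIONS,
                           intervals=("whole_poke", "before", "odor", "end"),
                           n_shuffles: int = 1000,
                           rng: np.random.Generator | int | None = None
                           ) -> pd.DataFrame:
    """InfoRecord rows (unit x dimension x interval) for one session. Units
    with no spikes in a window are skipped with a log entry."""
    rng = np.random.default_rng(rng)
    rows = []
    for uid, st in session.spikes.items():
        for dim in dimensions:
            for iv in intervals:
                try:
                    I, p95, sig = shuffle_significance(
                        st, session.trials, dim, iv, n_shuffles, rng)
                except ValueError as err:
                    log.info("unit %s %s/%s skipped: %s", uid, dim, iv, err)
                    continue
                rows.append({"unit_id": uid, "dimension": dim, "interval": iv,
                             "bits_per_spike": I, "null_p95": p95,
                             "significant": sig})
    return pd.DataFrame(rows)


def interval_comparison(scores: pd.DataFrame) -> dict:
    """Friedman test plus Tukey HSD post hocs across the before/odor/end
    interval scores of a preselected population.

    ``scores`` must have one row per unit and columns ``before``, ``odor``,
    ``end``. Returns the Friedman chi-square (d.f. = 2), its p-value, and a
    post hoc p-value per interval pair.
    """
    for col in ("before", "odor", "end"):
        if col not in scores.columns:
            raise ValueError(f"missing interval column {col!r}")
    if len(scores) < 3:
        raise ValueError("need at least 3 units for the interval comparison")
    cols = [scores[c].to_numpy(float) for c in ("before", "odor", "end")]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sstats.friedmanchisquare(*cols)
    hsd = sstats.tukey_hsd(*cols)
    names = ("before", "odor", "end")
    posthoc = {(names[i], names[j]): float(hsd.pvalue[i, j])
               for i in range(3) for j in range(i + 1, 3)}
    return {"statistic": float(stat), "df": 2, "pvalue": float(p),
            "posthoc": posthoc}
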