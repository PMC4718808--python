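"""Population-level statistics for coherence categories, phases and amplitudes.

Covers the battery of tests applied across units and sessions: chi-square
goodness-of-fit of performance-category counts against a uniform split (with
Bonferroni-corrected pairwise post hocs), r x c contingency comparisons of
category distributions between rhythms, circular-circular correlations of
preferred phases (Jammalamadaka-SenGupta), Wilcoxon signed-rank comparisons
of rate-corrected coherence magnitudes and firing rates, amplitude
co-modulation with a circular-jitter surrogate null, and one- and two-factor
repeated-measures ANOVAs for amplitude/coherence dynamics. No continuity
correction is applied in the chi-square tests.

Category counts (correct-only, incorrect-only, all-trials) reported only as
a total N plus pairwise Ns can be recovered exactly: with N = c + i + a,
the pairwise totals give c = N - N_{i,a}, i = N - N_{c,a}, a = N - N_{c,i}.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

BONFERRONI_FAMILY = 3  # three pairwise post hocs per omnibus test


# ------------------------------------------------------------ chi-square

def chisq_uniform(counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of k category counts vs an equal split.

    Returns ``(chi2, df, p)`` with df = k - 1.
    """
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("category counts sum to zero")
    expected = np.full_like(counts, counts.sum() / len(counts))
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    df = len(counts) - 1
    return chi2, df, float(sstats.chi2.sf(chi2, df))


def chisq_pairwise_posthoc(counts, alpha: float = 0.05) -> list[dict]:
    """2-category goodness-of-fit on each pair of categories vs an equal
    split, judged at the Bonferroni-adjusted level alpha / 3."""
    counts = np.asarray(counts, float)
    adj_alpha = alpha / BONFERRONI_FAMILY
    out = []
    for i, j in combinations(range(len(counts)), 2):
        pair = counts[[i, j]]
        if pair.sum() == 0:
            raise ValueError(f"empty category pair ({i}, {j})")
        chi2, df, p = chisq_uniform(pair)
        out.append({"pair": (i, j), "n": float(pair.sum()), "chi2": chi2,
                    "df": df, "p": p, "significant": p < adj_alpha,
                    "adjusted_alpha": adj_alpha})
    return out


def chisq_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction); df = (r-1)(c-1)."""
    table = np.asarray(table, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = sstats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def solve_category_counts(n_total: int, n_corr_incorr: int,
                          n_corr_all: int, n_incorr_all: int
                          ) -> tuple[int, int, int]:
    """Recover (correct_only, incorrect_only, all_trials) counts from the
    total N and the three pairwise Ns; raises if they are inconsistent."""
    c = n_total - n_incorr_all
    i = n_total - n_corr_all
    a = n_total - n_corr_incorr
    if c < 0 or i < 0 or a < 0 or c + i + a != n_total:
        raise ValueError(
            f"inconsistent pairwise Ns: solved counts ({c}, {i}, {a}) "
            f"do not sum to N={n_total}")
    return c, i, a


# --------------------------------------------------- circular correlation

def circular_correlation(angles_a, angles_b) -> tuple[float, float]:
    """Jammalamadaka-SenGupta circular-circular correlation with its
    asymptotic normal p-value.

    r = sum sin(a - abar) sin(b - bbar) /
        sqrt(sum sin^2(a - abar) sum sin^2(b - bbar)).
    """
    a = np.asarray(angles_a, float)
    b = np.asarray(angles_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("angle vectors must be paired 1-d arrays")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 paired angles")
    abar = np.angle(np.mean(np.exp(1j * a)))
    bbar = np.angle(np.mean(np.exp(1j * b)))
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    den = np.sqrt(np.sum(sa ** 2) * np.sum(sb ** 2))
    if den == 0:
        raise ValueError("degenerate (constant) angle vector")
    r = float(np.sum(sa * sb) / den)
    l20 = np.mean(sa ** 2)
    l02 = np.mean(sb ** 2)
    l22 = np.mean(sa ** 2 * sb ** 2)
    if l22 == 0:
        return r, float("nan")
    z = np.sqrt(n * l20 * l02 / l22) * r
    p = 2.0 * sstats.norm.sf(abs(z))
    return r, float(p)


# ------------------------------------------------------ paired comparisons

def paired_magnitude_tests(correct, incorrect) -> dict:
    """Two-sided Wilcoxon signed-rank (normal approximation with tie
    correction) on paired correct/incorrect values; reports Z, p and the
    per-condition medians. All-zero differences give Z = 0, p = 1."""
    x = np.asarray(correct, float)
    y = np.asarray(incorrect, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d arrays")
    if len(x) < 6:
        raise ValueError("need at least 6 pairs for the signed-rank test")
    out = {"median_correct": float(np.median(x)),
           "median_incorrect": float(np.median(y)), "n": len(x)}
    if np.all(x == y):
        out.update(z=0.0, p=1.0)
        return out
    res = sstats.wilcoxon(x, y, zero_method="wilcox", method="approx")
    out.update(z=float(res.zstatistic), p=float(res.pvalue))
    return out


# ------------------------------------------------- amplitude co-modulation

def amplitude_comodulation(amplitudes: dict[str, np.ndarray], fs: float,
                           trials: pd.DataFrame, n_jitters: int = 1000,
                           rng: np.random.Generator | int | None = None,
                           margin_s: float = 30.0,
                           poke_duration: float = 1.5) -> pd.DataFrame:
    """Pairwise amplitude correlations over correct-poke samples with a
    circular-jitter surrogate null.

    For the null, each band's whole-session amplitude trace is circularly
    shifted by an independent uniform offset in [margin, duration - margin]
    before the correct-poke samples are extracted; this destroys alignment
    while preserving every band's amplitude marginal exactly. A pair is
    flagged if the observed r falls outside the central 95% of its null.
    """
    rng = np.random.default_rng(rng)
    names = list(amplitudes)
    n = len(amplitudes[names[0]])
    if any(len(a) != n for a in amplitudes.values()):
        raise ValueError("amplitude traces must share a common time base")
    correct = trials[trials["outcome"] == "correct"]
    if len(correct) == 0:
        raise ValueError("no correct trials")
    idx = np.concatenate([
        np.arange(int(round(on * fs)),
                  int(round(on * fs)) + int(round(poke_duration * fs)))
        for on in correct["onset"]])
    if idx.max() >= n:
        raise ValueError("poke window exceeds the amplitude trace")
    lo_shift = int(margin_s * fs)
    hi_shift = n - lo_shift
    if hi_shift <= lo_shift:
        raise ValueError("session too short for the requested jitter margin")
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = amplitudes[a], amplitudes[b]
        r_obs = float(np.corrcoef(xa[idx], xb[idx])[0, 1])
        null = np.empty(n_jitters)
        for k in range(n_jitters):
            sa, sb = rng.integers(lo_shift, hi_shift, size=2)
            null[k] = np.corrcoef(xa[(idx + sa) % n], xb[(idx + sb) % n])[0, 1]
        lo, hi = np.percentile(null, [2.5, 97.5])
        rows.append({"band_a": a, "band_b": b, "r": r_obs,
                     "null_lo": float(lo), "null_hi": float(hi),
                     "outside_null": bool(r_obs < lo or r_obs > hi)})
    return pd.DataFrame(rows)


# --------------------------------------------------- repeated-measures ANOVA

def _f_or_zero(ss_eff: float, df_eff: int, ss_err: float, df_err: int
               ) -> tuple[float, float]:
    """F statistic with the convention 0/0 -> 0 for perfectly flat data."""
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 1e-300:
        f = 0.0 if ms_eff <= 1e-300 else float("inf")
    else:
        f = ms_eff / ms_err
    p = float(sstats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return float(f), p


def rm_anova_two_factor(data: np.ndarray) -> dict:
    """Two-factor within-subject ANOVA on a complete balanced design.

    ``data`` has shape (subjects, levels_A, levels_B) — e.g. sessions x six
    time bins x two outcomes. Each effect is tested against its own
    effect-by-subject interaction. Returns F, d.f. and p for the A and B
    main effects and the A x B interaction.
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, levels_A, levels_B)")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells in the repeated-measures design")
    n, a, b = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for within-subject error")
    gm = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)
    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (data - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - gm)
    ss_abs = np.sum(resid ** 2)
    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
            ("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            ("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            ("AxB", ss_ab, (a - 1) * (b - 1), ss_abs,
             (a - 1) * (b - 1) * (n - 1))):
        f, p = _f_or_zero(ss_eff, df_eff, ss_err, df_err)
        out[name] = {"F": f, "df": (df_eff, df_err), "p": p}
    return out


def rm_anova_one_factor(data: np.ndarray) -> dict:
    """One-way within-subject ANOVA on (subjects, levels) data — e.g. units
    x six band-pair correlations. Tested against the treatment-by-subject
    interaction."""
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be (subjects, levels)")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells in the repeated-measures design")
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for within-subject error")
    gm = data.mean()
    m_s = data.mean(axis=1)
    m_t = data.mean(axis=0)
    ss_t = n * np.sum((m_t - gm) ** 2)
    resid = data - m_s[:, None] - m_t[None, :] + gm
    ss_err = np.sum(resid ** 2)
    f, p = _f_or_zero(ss_t, k - 1, ss_err, (k - 1) * (n - 1))
    return {"F": f, "df": (k - 1, (k - 1) * (n - 1)), "p": p}
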