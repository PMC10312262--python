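"""Questionnaire scoring and univariate/bivariate behavioral statistics.

Covers the behavioral side of the study design: scoring of the loneliness
and empathy instruments (reverse-keyed items, sum or item-mean totals,
percent-correct for the eyes task), two-sample t tests and Cohen's d from
group summary statistics, and (partial) correlation tables with
significance stars.

Instrument conventions:

* UCLA loneliness scale: 20 items on a 1-4 scale, reverse-keyed items
  mapped x -> 5 - x, summed (range 20-80).
* Eyes-task emotion recognition: 36 items scored 0/1, summed (max 36);
  reported by default on the percent scale (0-100).
* Toronto empathy questionnaire: 16 items on 0-4, reverse-keyed, summed.
* Perspective-taking / empathic-concern subscales: 7 items each on 1-5,
  reverse-keyed, reported as item means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "score_questionnaire",
    "rmie_percent",
    "pooled_t",
    "welch_t",
    "cohens_d",
    "correlation_table",
    "partial_correlation_table",
]


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p: float
    d: float  # Cohen's d magnitude
    variant: str  # "pooled" | "welch"


def score_questionnaire(
    responses: np.ndarray,
    reverse_items: set[int] | frozenset[int] | tuple[int, ...] = (),
    bounds: tuple[float, float] = (1, 4),
    aggregation: str = "sum",
) -> np.ndarray:
    """Score item responses into totals.

    ``responses`` is participants-by-items; ``reverse_items`` are 0-based
    item indices mapped x -> (min + max - x); ``aggregation`` is "sum" or
    "item-mean".  Out-of-bounds responses raise.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    lo, hi = bounds
    if np.any((R < lo) | (R > hi)):
        bad = np.argwhere((R < lo) | (R > hi))[0]
        raise ValueError(
            f"response out of bounds [{lo}, {hi}] at (participant, item) "
            f"{tuple(bad.tolist())}"
        )
    R = R.copy()
    rev = sorted(set(reverse_items))
    if rev:
        R[:, rev] = lo + hi - R[:, rev]
    if aggregation == "sum":
        out = R.sum(axis=1)
    elif aggregation == "item-mean":
        out = R.mean(axis=1)
    else:
        raise ValueError("aggregation must be 'sum' or 'item-mean'")
    return out if out.size > 1 else out.reshape(-1)


def rmie_percent(raw_correct: np.ndarray, n_items: int = 36) -> np.ndarray:
    """Eyes-task raw correct (0..n_items) -> percent scale (0..100)."""
    raw = np.asarray(raw_correct, dtype=float)
    if np.any((raw < 0) | (raw > n_items)):
        raise ValueError(f"raw scores must lie in [0, {n_items}]")
    return 100.0 * raw / n_items


def _pooled_sd(s1: float, n1: int, s2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))


def pooled_t(m1, s1, n1, m2, s2, n2) -> GroupComparison:
    """Independent-samples t test from summary statistics, pooled variance."""
    _check_two_sample(s1, n1, s2, n2)
    sp = _pooled_sd(s1, n1, s2, n2)
    df = n1 + n2 - 2
    t = (m1 - m2) / (sp * np.sqrt(1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return GroupComparison(
        t=float(t), df=float(df), p=float(p),
        d=abs(cohens_d(m1, s1, n1, m2, s2, n2)), variant="pooled",
    )


def welch_t(m1, s1, n1, m2, s2, n2) -> GroupComparison:
    """Welch's t test (unequal variances) with Welch-Satterthwaite df."""
    _check_two_sample(s1, n1, s2, n2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return GroupComparison(
        t=float(t), df=float(df), p=float(p),
        d=abs(cohens_d(m1, s1, n1, m2, s2, n2)), variant="welch",
    )


def cohens_d(m1, s1, n1, m2, s2, n2) -> float:
    """Standardized mean difference (pooled SD); signed."""
    _check_two_sample(s1, n1, s2, n2)
    return float((m1 - m2) / _pooled_sd(s1, n1, s2, n2))


def _check_two_sample(s1, n1, s2, n2) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("group SDs must be positive in at least one group")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    measures: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise product-moment correlations with two-sided p and stars.

    Missing data are handled pairwise-complete; each cell needs >= 3
    complete pairs.  Returns (r, p, stars) frames; r has a unit diagonal.
    """
    cols = list(measures.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = measures[cols[i]].to_numpy(dtype=float)
            y = measures[cols[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({cols[i]}, {cols[j]})"
                )
            rr, pp = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(_stars)
    np.fill_diagonal(sdf.values, "")
    return rdf, pdf, sdf


def partial_correlation_table(
    measures: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise partial correlations controlling the covariates.

    Rows with missing data in any covariate or in either member of a pair
    are dropped listwise for that pair.  With no covariates this reduces to
    :func:`correlation_table`.
    """
    if covariates is None or covariates.shape[1] == 0:
        return correlation_table(measures)
    from .pls import partial_corr_brainscores

    cols = list(measures.columns)
    C = covariates.to_numpy(dtype=float)
    cov_ok = np.all(np.isfinite(C), axis=1)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = measures[cols[i]].to_numpy(dtype=float)
            y = measures[cols[j]].to_numpy(dtype=float)
            ok = cov_ok & np.isfinite(x) & np.isfinite(y)
            rr, pp = partial_corr_brainscores(x[ok], y[ok], C[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(_stars)
    np.fill_diagonal(sdf.values, "")
    return rdf, pdf, sdf
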