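"""Permutation significance and bootstrap reliability for PLS latent variables.

Permutation: rows of X are reordered (default: across the whole sample,
leaving Y and the group labels in place), the grouped cross-correlation is
rebuilt and re-decomposed, and each observed singular value is compared with
the same-rank permuted singular values; p is the plain proportion of
permuted values >= observed (no +1 correction, selectable).

Bootstrap: participants are resampled with replacement within group
(preserving group sizes), the decomposition re-run, and each resampled
singular-vector pair sign-aligned (optionally Procrustes-aligned) to the
original.  The bootstrap ratio salience / SE is a z-like reliability score,
conventionally thresholded at +/-1.96 (the two-sided 95% normal critical
value).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats

from .pls import cross_correlation, standardize

__all__ = [
    "PermutationResult",
    "BootstrapOutput",
    "bootstrap_ratio_threshold",
    "permutation_test",
    "exhaustive_permutation_test",
    "bootstrap",
    "align_svd",
    "procrustes_align",
]


def bootstrap_ratio_threshold(level: float = 0.95) -> float:
    """Two-sided standard-normal critical value (1.96 at the 95% level)."""
    return float(stats.norm.ppf(0.5 + level / 2))


@dataclass
class PermutationResult:
    n_perm: int
    observed_s: np.ndarray  # observed singular values, descending
    null_s: np.ndarray  # (n_perm, n_lv) permuted singular values, sorted desc
    p_perm: np.ndarray  # per-LV p

    def __post_init__(self) -> None:
        assert np.all((self.p_perm >= 0) & (self.p_perm <= 1))


@dataclass
class BootstrapOutput:
    n_boot: int
    threshold: float
    v_se: np.ndarray  # (n_lv, E) bootstrap SEs of edge saliences
    bootstrap_ratio: np.ndarray  # (n_lv, E); NaN where SE == 0
    u_se: np.ndarray  # (n_lv, G*B)
    behavior_corr: np.ndarray  # (n_lv, G*B) observed behavior-score correlations
    behavior_corr_ci: np.ndarray  # (n_lv, G*B, 2) percentile 95% CI
    n_skipped: int = 0  # resamples dropped for constant columns

    def zero_se_edges(self, lv: int) -> np.ndarray:
        return np.flatnonzero(self.v_se[lv] == 0)


def _grouped_svd(X, Y, groups, group_order):
    R = cross_correlation(X, Y, groups, group_order)
    return np.linalg.svd(R, full_matrices=False)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    group_order=("young", "old"),
    within_group: bool = False,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation null for the LV singular values.

    Each iteration permutes the rows of X (Y and group labels fixed),
    re-standardizes within group, rebuilds R and takes its singular values.
    The l-th observed singular value is compared against the l-th largest
    permuted values; p_l = #{s_perm_l >= s_obs_l} / n_perm (or the
    (k+1)/(n+1) estimator when ``plus_one``).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to permute")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    s_obs = _grouped_svd(X, Y, groups, group_order)[1]
    null = np.empty((n_perm, s_obs.size))
    group_idx = [np.flatnonzero(groups == g) for g in group_order if np.any(groups == g)]
    for it in range(n_perm):
        if within_group:
            perm = np.arange(n)
            for idx in group_idx:
                perm[idx] = idx[rng.permutation(idx.size)]
        else:
            perm = rng.permutation(n)
        s_p = _grouped_svd(X[perm], Y, groups, group_order)[1]
        null[it] = -np.sort(-s_p)
    count = (null >= s_obs[None, :]).sum(axis=0)
    if plus_one:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    return PermutationResult(
        n_perm=n_perm, observed_s=s_obs, null_s=null, p_perm=p
    )


def exhaustive_permutation_test(
    X: np.ndarray, Y: np.ndarray, groups: np.ndarray, group_order=("young", "old")
) -> PermutationResult:
    """Enumerate every row permutation of X (oracle for tiny n)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    s_obs = _grouped_svd(X, Y, groups, group_order)[1]
    null = []
    for perm in _iter_permutations(range(n)):
        s_p = _grouped_svd(X[list(perm)], Y, groups, group_order)[1]
        null.append(-np.sort(-s_p))
    null = np.asarray(null)
    p = (null >= s_obs[None, :]).mean(axis=0)
    return PermutationResult(
        n_perm=null.shape[0], observed_s=s_obs, null_s=null, p_perm=p
    )


def align_svd(reference: np.ndarray, candidate: np.ndarray) -> tuple[np.ndarray, float]:
    """Sign-align one vector to a reference (flip to maximize dot product)."""
    reference = np.asarray(reference, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    if reference.shape != candidate.shape:
        raise ValueError("dimension mismatch")
    if not np.any(candidate) or not np.any(reference):
        raise ValueError("cannot align zero vectors")
    sign = 1.0 if float(reference @ candidate) >= 0 else -1.0
    return sign * candidate, sign


def procrustes_align(
    reference: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal (Procrustes) alignment of a singular-vector block.

    Returns (aligned candidate, rotation Q) with Q the orthogonal matrix
    minimizing ||reference - candidate @ Q||_F; handles swapped or mixed
    near-degenerate LVs, unlike per-column sign flips.
    """
    A = np.asarray(candidate, dtype=float)
    B = np.asarray(reference, dtype=float)
    U, _, Vt = np.linalg.svd(A.T @ B)
    Q = U @ Vt
    return A @ Q, Q


def bootstrap(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator | None = None,
    group_order=("young", "old"),
    threshold: float = 1.96,
    procrustes: bool = False,
    n_lv: int | None = None,
) -> BootstrapOutput:
    """Bootstrap SEs, bootstrap ratios, and behavior-correlation CIs.

    Participants are resampled with replacement within each group (group
    sizes preserved); the full standardize -> cross-correlation -> SVD
    pipeline is re-run per resample and aligned to the original solution.
    Resamples in which any column becomes constant within a group are
    skipped and counted.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)

    group_idx = [np.flatnonzero(groups == g) for g in group_order if np.any(groups == g)]
    for idx in group_idx:
        if idx.size < 2:
            raise ValueError("every group needs >= 2 members to resample")

    U0, s0, Vt0 = _grouped_svd(X, Y, groups, group_order)
    L = s0.size if n_lv is None else min(n_lv, s0.size)
    V0 = Vt0[:L].T  # E x L
    U0 = U0[:, :L]  # GB x L

    # observed per-(group, behavior) correlation between behavior and brain score
    Zx = standardize(X, groups, group_order)
    obs_corr = _behavior_score_corrs(Zx, Y, groups, group_order, V0)

    v_draws = np.empty((n_boot, L, V0.shape[0]))
    u_draws = np.empty((n_boot, L, U0.shape[0]))
    corr_draws = np.empty((n_boot, L, U0.shape[0]))
    skipped = 0
    it = 0
    while it < n_boot:
        rows = np.concatenate([idx[rng.integers(0, idx.size, idx.size)] for idx in group_idx])
        Xb, Yb, gb = X[rows], Y[rows], groups[rows]
        try:
            Ub, sb, Vtb = _grouped_svd(Xb, Yb, gb, group_order)
        except ValueError:
            skipped += 1
            if skipped > 100 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        Vb = Vtb[:L].T
        Ub = Ub[:, :L]
        if procrustes:
            _, Q = procrustes_align(U0, Ub)
            Ub = Ub @ Q
            Vb = Vb @ Q
        else:
            for l in range(L):
                _, sign = align_svd(U0[:, l], Ub[:, l])
                Ub[:, l] *= sign
                Vb[:, l] *= sign
        Zxb = standardize(Xb, gb, group_order)
        corr_draws[it] = _behavior_score_corrs(Zxb, Yb, gb, group_order, Vb)
        v_draws[it] = Vb.T
        u_draws[it] = Ub.T
        it += 1

    v_se = v_draws.std(axis=0, ddof=1)
    u_se = u_draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(v_se > 0, V0.T / np.where(v_se > 0, v_se, 1.0), np.nan)
    ci = np.stack(
        [
            np.percentile(corr_draws, 2.5, axis=0),
            np.percentile(corr_draws, 97.5, axis=0),
        ],
        axis=-1,
    )
    return BootstrapOutput(
        n_boot=n_boot,
        threshold=threshold,
        v_se=v_se,
        bootstrap_ratio=ratio,
        u_se=u_se,
        behavior_corr=obs_corr,
        behavior_corr_ci=ci,
        n_skipped=skipped,
    )


def _behavior_score_corrs(Zx, Y, groups, group_order, V):
    """corr(behavior b, X z-scores @ v_l) within group, group-major rows."""
    scores = Zx @ V  # n x L
    out = []
    for g in group_order:
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            continue
        Yg = Y[idx]
        Sg = scores[idx]
        Yz = (Yg - Yg.mean(0)) / Yg.std(0, ddof=1)
        Sz = (Sg - Sg.mean(0)) / np.where(Sg.std(0, ddof=1) > 0, Sg.std(0, ddof=1), 1.0)
        out.append(Yz.T @ Sz / (idx.size - 1))  # B x L
    return np.vstack(out).T  # L x (G*B)
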