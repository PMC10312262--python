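"""Grouped behavioral PLS: cross-correlation SVD of brain and behavior.

The method relates a participant-by-edge connectivity matrix X to a
participant-by-behavior matrix Y.  Both are z-scored within each group, the
within-group behavior-edge correlation blocks are stacked (young block on
top of old), and the stacked matrix R is decomposed by SVD,

    R = U S V',

yielding latent variables (LVs): paired behavioral profiles (columns of U,
one salience per group x behavior) and edge patterns (columns of V) that
maximally covary.  Squared singular values, normalized to their sum, give
the fraction of brain-behavior covariance each LV explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LatentVariable",
    "standardize",
    "group_standardize_params",
    "apply_standardize_params",
    "cross_correlation",
    "decompose",
    "brain_scores",
    "residualize",
    "partial_corr_brainscores",
    "fit_pls",
]


@dataclass
class LatentVariable:
    """One SVD component of the stacked brain-behavior correlation matrix."""

    index: int
    s: float
    cov_explained: float
    u: np.ndarray  # behavior saliences, length G*B (group-major)
    v: np.ndarray  # edge saliences, length E
    brain_scores: np.ndarray | None = None
    p_perm: float | None = None


def _group_blocks(groups: np.ndarray, group_order) -> list[tuple[str, np.ndarray]]:
    groups = np.asarray(groups, dtype=object)
    return [
        (g, np.flatnonzero(groups == g))
        for g in group_order
        if np.any(groups == g)
    ]


def group_standardize_params(
    M: np.ndarray, groups: np.ndarray, group_order=("young", "old")
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group column means and SDs (ddof=1), for train/test reuse."""
    M = np.asarray(M, dtype=float)
    params = {}
    for g, idx in _group_blocks(groups, group_order):
        block = M[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) {zero.tolist()} within group '{g}'"
            )
        params[g] = (mu, sd)
    return params


def apply_standardize_params(
    M: np.ndarray, groups: np.ndarray, params, group_order=("young", "old")
) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    Z = np.empty_like(M)
    for g, idx in _group_blocks(groups, group_order):
        mu, sd = params[g]
        Z[idx] = (M[idx] - mu) / sd
    return Z


def standardize(
    M: np.ndarray, groups: np.ndarray, group_order=("young", "old")
) -> np.ndarray:
    """Z-score each column within each group block (mean 0, unit SD)."""
    return apply_standardize_params(
        M, groups, group_standardize_params(M, groups, group_order), group_order
    )


def cross_correlation(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    group_order=("young", "old"),
    standardized: bool = False,
) -> np.ndarray:
    """Stacked within-group behavior-edge correlation matrix R.

    Row block for group g holds, for each behavior b (rows) and edge e
    (columns), the within-group Pearson correlation corr_g(Y[:, b], X[:, e]).
    Blocks are stacked in group order (young then old), so R is (G*B) x E.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    blocks = []
    for g, idx in _group_blocks(groups, group_order):
        if idx.size < 3:
            raise ValueError(f"group '{g}' has {idx.size} members; need >= 3")
        if standardized:
            Zx, Zy = X[idx], Y[idx]
        else:
            Zx = standardize(X[idx], np.repeat(g, idx.size), (g,))
            Zy = standardize(Y[idx], np.repeat(g, idx.size), (g,))
        blocks.append(Zy.T @ Zx / (idx.size - 1))
    return np.vstack(blocks)


def decompose(R: np.ndarray) -> list[LatentVariable]:
    """Full SVD of R into latent variables, sorted by singular value.

    Sign convention: each LV is flipped so the largest-|u| entry is positive
    (v flipped consistently).  cov_explained_l = s_l^2 / sum_k s_k^2.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("R contains non-finite entries")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    total = float(np.sum(s**2))
    lvs = []
    for l in range(s.size):
        u, v = U[:, l].copy(), Vt[l].copy()
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        lvs.append(
            LatentVariable(
                index=l,
                s=float(s[l]),
                cov_explained=float(s[l] ** 2 / total) if total > 0 else 0.0,
                u=u,
                v=v,
            )
        )
    return lvs


def singular_values(R: np.ndarray) -> np.ndarray:
    return np.linalg.svd(np.asarray(R, dtype=float), compute_uv=False)


def brain_scores(X: np.ndarray, lv: LatentVariable) -> np.ndarray:
    """Participant projections onto the LV's edge saliences: X @ v."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != lv.v.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} edges but v has {lv.v.shape[0]} saliences"
        )
    return X @ lv.v


def residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Replace each column by its least-squares residual on [1, covariates]."""
    M = np.atleast_2d(np.asarray(M, dtype=float).T).T
    C = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
    if C.shape[0] != M.shape[0]:
        raise ValueError("covariate rows do not align with data rows")
    D = np.column_stack([np.ones(C.shape[0]), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ beta


def partial_corr_brainscores(
    scores: np.ndarray, behavior: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial correlation of brain scores with one behavioral measure.

    Both vectors are residualized on the covariates; the product-moment
    correlation of the residuals is tested against t with n - 2 - c df.
    """
    scores = np.asarray(scores, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if covariates is None:
        c = 0
        rs, rb = scores - scores.mean(), behavior - behavior.mean()
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        c = C.shape[1]
        if scores.shape[0] < c + 3:
            raise ValueError(f"need at least {c + 3} complete rows, have {scores.shape[0]}")
        rs = residualize(scores, C)[:, 0]
        rb = residualize(behavior, C)[:, 0]
    n = scores.shape[0]
    r = float(rs @ rb / np.sqrt((rs @ rs) * (rb @ rb)))
    df = n - 2 - c
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    group_order=("young", "old"),
    compute_scores: bool = True,
) -> list[LatentVariable]:
    """standardize -> cross_correlation -> decompose, with brain scores.

    Brain scores are projections of the within-group standardized X onto
    each LV's edge saliences.
    """
    Zx = standardize(X, groups, group_order)
    R = cross_correlation(Zx, Y, groups, group_order, standardized=False)
    lvs = decompose(R)
    if compute_scores:
        for lv in lvs:
            lv.brain_scores = brain_scores(Zx, lv)
    return lvs
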