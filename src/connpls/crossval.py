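"""Train/test validation of the PLS solution by projection onto held-out data.

Participants are split into k group-stratified folds.  Per fold, PLS is fit
on the training participants only (including the within-group
standardization parameters), and each test participant is projected onto
the training singular vectors: a brain-side score X_test . v_train and a
behavior-side score Y_test . u_train, where u_train is the block of the
behavior saliences matching the participant's group.  The per-fold Pearson
correlation between the two score vectors measures how well the latent
pairing generalizes; significance comes from re-running the whole procedure
with behavior rows permuted within group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import (
    apply_standardize_params,
    cross_correlation,
    decompose,
    group_standardize_params,
)

__all__ = ["CVResult", "stratified_folds", "cv_pls", "cv_permutation_p"]


@dataclass
class CVResult:
    k: int
    lv_indices: tuple[int, ...]
    fold_assignments: np.ndarray  # per-participant fold id
    fold_corr: np.ndarray  # (k, n_lv) per-fold test correlations
    mean_corr: np.ndarray  # (n_lv,) mean over folds
    pooled_corr: np.ndarray  # (n_lv,) correlation pooling all test participants
    p_perm: np.ndarray | None = None
    seed: int | None = None


def stratified_folds(
    groups: np.ndarray,
    k: int,
    seed: int | np.random.Generator | None = None,
    group_order=("young", "old"),
) -> np.ndarray:
    """Assign each participant to one of k folds, stratified by group.

    Within each group the participants are shuffled and dealt into k
    near-equal folds; every participant tests exactly once.
    """
    groups = np.asarray(groups, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.full(groups.shape[0], -1, dtype=int)
    for g in group_order:
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            continue
        if idx.size < k:
            raise ValueError(f"group '{g}' has {idx.size} members < k={k}")
        perm = idx[rng.permutation(idx.size)]
        folds[perm] = np.arange(perm.size) % k
    return folds


def _group_u_expander(groups, group_order, B):
    """Map each participant row to the slice of u holding their group block."""
    present = [g for g in group_order if np.any(groups == g)]
    offset = {g: i * B for i, g in enumerate(present)}
    return np.asarray([offset[g] for g in groups]), len(present)


def cv_pls(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    folds: np.ndarray,
    lv_indices=(0, 1),
    group_order=("young", "old"),
    per_group: bool = False,
) -> CVResult:
    """k-fold train/test projection of the PLS latent variables.

    Test rows are standardized with training means/SDs (no leakage), then
    projected: brain score = X_test . v_train, behavior score = Y_test .
    u_train (group-matched block).  Correlations pool both groups' test
    participants per fold; ``mean_corr`` averages folds, ``pooled_corr``
    correlates all test participants' scores at once.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    folds = np.asarray(folds, dtype=int)
    k = int(folds.max()) + 1
    B = Y.shape[1]
    lv_indices = tuple(lv_indices)
    u_offset, _ = _group_u_expander(groups, group_order, B)

    fold_corr = np.full((k, len(lv_indices)), np.nan)
    all_brain = np.full((X.shape[0], len(lv_indices)), np.nan)
    all_behav = np.full((X.shape[0], len(lv_indices)), np.nan)

    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        gtr, gte = groups[train], groups[test]

        px = group_standardize_params(X[train], gtr, group_order)
        py = group_standardize_params(Y[train], gtr, group_order)
        Zx_tr = apply_standardize_params(X[train], gtr, px, group_order)
        R = cross_correlation(Zx_tr, Y[train], gtr, group_order)
        lvs = decompose(R)

        Zx_te = apply_standardize_params(X[test], gte, px, group_order)
        Zy_te = apply_standardize_params(Y[test], gte, py, group_order)

        for c, l in enumerate(lv_indices):
            v = lvs[l].v
            u = lvs[l].u
            brain = Zx_te @ v
            behav = np.array(
                [Zy_te[i] @ u[u_offset[t] : u_offset[t] + B]
                 for i, t in enumerate(test)]
            )
            all_brain[test, c] = brain
            all_behav[test, c] = behav
            if test.size >= 3 and brain.std() > 0 and behav.std() > 0:
                fold_corr[f, c] = float(np.corrcoef(brain, behav)[0, 1])

    mean_corr = np.nanmean(fold_corr, axis=0)
    pooled = np.array(
        [float(np.corrcoef(all_brain[:, c], all_behav[:, c])[0, 1])
         for c in range(len(lv_indices))]
    )
    return CVResult(
        k=k,
        lv_indices=lv_indices,
        fold_assignments=folds,
        fold_corr=fold_corr,
        mean_corr=mean_corr,
        pooled_corr=pooled,
    )


def cv_permutation_p(
    X: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray,
    folds: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    lv_indices=(0, 1),
    group_order=("young", "old"),
) -> tuple[np.ndarray, CVResult]:
    """Permutation p for the mean test correlation per LV.

    The null permutes behavior rows within each group and re-runs the full
    cross-validation; p = proportion of null mean correlations >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = np.asarray(groups, dtype=object)
    rng = np.random.default_rng(seed)
    observed = cv_pls(X, Y, groups, folds, lv_indices, group_order)
    group_idx = [np.flatnonzero(groups == g) for g in group_order if np.any(groups == g)]
    null = np.empty((n_perm, len(lv_indices)))
    n = groups.shape[0]
    Y = np.asarray(Y, dtype=float)
    for it in range(n_perm):
        perm = np.arange(n)
        for idx in group_idx:
            perm[idx] = idx[rng.permutation(idx.size)]
        res = cv_pls(X, Y[perm], groups, folds, lv_indices, group_order)
        null[it] = res.mean_corr
    p = (null >= observed.mean_corr[None, :]).mean(axis=0)
    return p, observed
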