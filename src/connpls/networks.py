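"""Network-level summaries of edge saliences and bootstrap-ratio maps.

Edge-level PLS output is hard to read at 50k edges; this module aggregates
it into N x N network-block matrices (N networks): mean squared salience per
block split into positive and negative maps, and a permutation test that
re-assigns parcel network labels (preserving network sizes) to ask whether a
block's mean thresholded bootstrap ratio exceeds what label-exchangeable
parcels would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .connectome import ParcelAtlas, _lower_indices

__all__ = [
    "NetworkContribution",
    "edge_network_labels",
    "mean_squared_salience",
    "threshold_bootstrap_ratios",
    "network_permutation_test",
]


@dataclass
class NetworkContribution:
    """Block summaries over network pairs (symmetric, diagonal = within)."""

    networks: tuple[str, ...]
    pos: np.ndarray
    neg: np.ndarray
    pos_counts: np.ndarray | None = None
    neg_counts: np.ndarray | None = None
    z_pos: np.ndarray | None = None
    z_neg: np.ndarray | None = None
    p_pos: np.ndarray | None = None
    p_neg: np.ndarray | None = None
    n_perm: int = 0


def edge_network_labels(atlas: ParcelAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge endpoint network labels, in edge-vector order."""
    labels = atlas.labels_array()
    rows, cols = _lower_indices(atlas.n_parcels)
    return labels[rows], labels[cols]


def _block_ids(atlas: ParcelAtlas, networks: tuple[str, ...]) -> np.ndarray:
    """Per-edge flat block id over unordered network pairs."""
    index = {nm: i for i, nm in enumerate(networks)}
    labels = np.asarray([index[l] for l in atlas.networks])
    rows, cols = _lower_indices(atlas.n_parcels)
    a = np.minimum(labels[rows], labels[cols])
    b = np.maximum(labels[rows], labels[cols])
    N = len(networks)
    return a * N + b  # a <= b


def _block_mean(
    values: np.ndarray, retained: np.ndarray, block_ids: np.ndarray, N: int,
    denominator: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of `values` over retained edges per block; empty blocks -> 0."""
    flat_sum = np.bincount(
        block_ids[retained], weights=values[retained], minlength=N * N
    )
    flat_cnt = np.bincount(block_ids[retained], minlength=N * N)
    if denominator == "retained":
        denom = flat_cnt
    elif denominator == "all":
        denom = np.bincount(block_ids, minlength=N * N)
    else:
        raise ValueError("denominator must be 'retained' or 'all'")
    with np.errstate(invalid="ignore"):
        flat_mean = np.where(denom > 0, flat_sum / np.maximum(denom, 1), 0.0)
    mean = flat_mean.reshape(N, N)
    cnt = flat_cnt.reshape(N, N)
    # stored in the upper triangle (a <= b); mirror for symmetry
    mean = mean + np.triu(mean, 1).T
    cnt = cnt + np.triu(cnt, 1).T
    return mean, cnt


def mean_squared_salience(
    v: np.ndarray,
    atlas: ParcelAtlas,
    denominator: str = "retained",
) -> NetworkContribution:
    """Positive/negative block matrices of mean squared edge saliences.

    Edges with v > 0 enter the positive map, v < 0 the negative map; each
    retained edge contributes v^2.  Block (A, B) averages over retained
    edges with one endpoint in A and one in B (unordered pairs inside A on
    the diagonal).  Empty blocks are 0 with a count of 0.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != atlas.n_parcels * (atlas.n_parcels - 1) // 2:
        raise ValueError(
            f"edge vector length {v.shape[0]} does not match "
            f"{atlas.n_parcels}-parcel atlas"
        )
    networks = atlas.network_names
    N = len(networks)
    bid = _block_ids(atlas, networks)
    pos, pos_cnt = _block_mean(v**2, v > 0, bid, N, denominator)
    neg, neg_cnt = _block_mean(v**2, v < 0, bid, N, denominator)
    return NetworkContribution(
        networks=networks, pos=pos, neg=neg, pos_counts=pos_cnt, neg_counts=neg_cnt
    )


def threshold_bootstrap_ratios(
    bsr: np.ndarray, threshold: float = 1.96
) -> tuple[np.ndarray, np.ndarray]:
    """Split a bootstrap-ratio edge map at +/-threshold.

    Returns (positive retained mask, negative retained mask); NaN ratios
    (zero bootstrap SE) are never retained.
    """
    bsr = np.asarray(bsr, dtype=float)
    with np.errstate(invalid="ignore"):
        return bsr > threshold, bsr < -threshold


def network_permutation_test(
    bsr: np.ndarray,
    atlas: ParcelAtlas,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    threshold: float = 1.96,
    denominator: str = "all",
    exhaustive: bool = False,
) -> NetworkContribution:
    """Block means of thresholded bootstrap ratios vs a label-permutation null.

    The observed statistic per block is the mean supra-threshold bootstrap
    ratio (positive map: ratios > +threshold; negative map: magnitudes of
    ratios < -threshold), averaged by default over all edges of the block
    with sub-threshold edges contributing zero.  Averaging over retained
    edges only (``denominator="retained"``) is also available, but under a
    label permutation that statistic is insensitive whenever the retained
    ratios are homogeneous: wherever a retained edge lands, the block mean
    is the same.  The null permutes parcel -> network labels,
    preserving network sizes, and recomputes the block means; z is the
    observed mean standardized by the null, p the proportion of null values
    >= observed.  ``exhaustive=True`` enumerates all distinct labelings
    (small atlases only).
    """
    bsr = np.asarray(bsr, dtype=float)
    networks = atlas.network_names
    N = len(networks)
    P = atlas.n_parcels
    labels = atlas.labels_array()

    pos_mask, neg_mask = threshold_bootstrap_ratios(bsr, threshold)
    vals_pos = np.where(np.isfinite(bsr), bsr, 0.0)
    vals_neg = np.where(np.isfinite(bsr), np.abs(bsr), 0.0)

    def stats_for(atl: ParcelAtlas) -> tuple[np.ndarray, np.ndarray]:
        bid = _block_ids(atl, networks)
        pos, _ = _block_mean(vals_pos, pos_mask, bid, N, denominator)
        neg, _ = _block_mean(vals_neg, neg_mask, bid, N, denominator)
        return pos, neg

    obs_pos, obs_neg = stats_for(atlas)

    if exhaustive:
        seen = set()
        null_pos, null_neg = [], []
        for perm in permutations(range(P)):
            lab = tuple(labels[list(perm)])
            if lab in seen:
                continue
            seen.add(lab)
            p_, n_ = stats_for(ParcelAtlas(lab))
            null_pos.append(p_)
            null_neg.append(n_)
        n_used = len(null_pos)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null_pos, null_neg = [], []
        for _ in range(n_perm):
            lab = tuple(labels[rng.permutation(P)])
            p_, n_ = stats_for(ParcelAtlas(lab))
            null_pos.append(p_)
            null_neg.append(n_)
        n_used = n_perm

    null_pos = np.stack(null_pos)
    null_neg = np.stack(null_neg)

    def z_and_p(obs, null):
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1) if null.shape[0] > 1 else np.zeros_like(mu)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        p = (null >= obs[None, :, :]).mean(axis=0)
        return z, p

    z_pos, p_pos = z_and_p(obs_pos, null_pos)
    z_neg, p_neg = z_and_p(obs_neg, null_neg)

    base = mean_squared_salience_safe(bsr, atlas, denominator)
    return NetworkContribution(
        networks=networks,
        pos=obs_pos,
        neg=obs_neg,
        pos_counts=base.pos_counts,
        neg_counts=base.neg_counts,
        z_pos=z_pos,
        z_neg=z_neg,
        p_pos=p_pos,
        p_neg=p_neg,
        n_perm=n_used,
    )


def mean_squared_salience_safe(
    bsr: np.ndarray, atlas: ParcelAtlas, denominator: str
) -> NetworkContribution:
    """mean_squared_salience with NaN ratios (zero SE) treated as zero."""
    clean = np.where(np.isfinite(bsr), bsr, 0.0)
    return mean_squared_salience(clean, atlas, denominator)
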