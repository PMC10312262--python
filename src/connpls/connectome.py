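"""Functional-connectome construction and bookkeeping.

Participant resting-state data enter the pipeline either as parcel-by-time
series or as ready-made parcel-by-parcel correlation matrices.  This module
turns them into the flat per-participant edge vectors (strict lower triangle,
column-major) that the PLS stage consumes, restricts atlases to networks of
interest, and stacks participants into the group-ordered data matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("connpls")

__all__ = [
    "ParcelAtlas",
    "GroupedDataset",
    "build_connectivity",
    "subset_atlas",
    "vectorize_lower",
    "devectorize_lower",
    "edge_index",
    "edge_index_inverse",
    "n_edges",
    "assemble",
]

#: canonical cortical network labels (7-network scheme)
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "fronto-parietal control",
    "default",
)

GROUP_ORDER = ("young", "old")


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel -> network assignment.

    Parcel ids are 0-based and contiguous internally; file formats use
    1-based ids (see :mod:`connpls.io`).
    """

    networks: tuple[str, ...]  # one label per parcel, index = parcel id

    def __post_init__(self) -> None:
        if len(self.networks) == 0:
            raise ValueError("atlas has no parcels")

    @property
    def n_parcels(self) -> int:
        return len(self.networks)

    @property
    def network_names(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.networks:
            seen.setdefault(lab)
        return tuple(seen)

    def parcels_in(self, network: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.networks, dtype=object) == network)

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.networks, dtype=object)


@dataclass
class GroupedDataset:
    """Row-aligned participant-by-edge X and participant-by-behavior Y.

    Rows are arranged in contiguous group blocks (young block first, then
    old), matching the stacked block layout of the cross-correlation matrix.
    """

    X: np.ndarray
    Y: np.ndarray
    groups: np.ndarray  # per-row group label
    participant_ids: np.ndarray
    behavior_names: tuple[str, ...] = ()
    group_order: tuple[str, ...] = GROUP_ORDER

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.X.shape[0] != self.groups.shape[0]:
            raise ValueError("group labels do not match row count")
        if not self.behavior_names:
            self.behavior_names = tuple(f"b{j}" for j in range(self.Y.shape[1]))
        # group blocks must be contiguous and follow group_order
        present = [g for g in self.group_order if g in set(self.groups)]
        expected = np.concatenate(
            [np.repeat(g, np.sum(self.groups == g)) for g in present]
        ) if present else np.empty(0, dtype=object)
        if not np.array_equal(self.groups, expected):
            raise ValueError("rows must be sorted into contiguous group blocks")

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    def group_indices(self) -> list[tuple[str, np.ndarray]]:
        """(label, row-index array) per group, in block order."""
        return [
            (g, np.flatnonzero(self.groups == g))
            for g in self.group_order
            if np.any(self.groups == g)
        ]


def build_connectivity(timeseries: np.ndarray) -> np.ndarray:
    """Pairwise product-moment correlation of parcel time series.

    Parameters
    ----------
    timeseries
        Parcel-by-time array (each row one parcel's series).

    Returns
    -------
    Symmetric parcel-by-parcel correlation matrix with unit diagonal.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("need a parcel-by-time array with >= 2 time points")
    sd = ts.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant time series for parcel(s) {flat.tolist()}: "
            "correlation undefined"
        )
    C = np.corrcoef(ts)
    np.fill_diagonal(C, 1.0)
    return C


def subset_atlas(
    atlas: ParcelAtlas, keep: set[str] | frozenset[str] | list[str] | tuple[str, ...]
) -> tuple[ParcelAtlas, np.ndarray]:
    """Restrict an atlas to the given networks.

    Returns the restricted atlas and the index mask mapping new parcel
    positions back to original parcel ids.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep must name at least one network")
    unknown = keep_set - set(atlas.networks)
    if unknown:
        raise ValueError(f"unknown network label(s): {sorted(unknown)}")
    mask = np.flatnonzero(np.isin(atlas.labels_array(), list(keep_set)))
    return ParcelAtlas(tuple(atlas.networks[i] for i in mask)), mask


def n_edges(P: int) -> int:
    """Edge count of the strict lower triangle of a P-parcel matrix."""
    return P * (P - 1) // 2


def _lower_indices(P: int) -> tuple[np.ndarray, np.ndarray]:
    # column-major over the strict lower triangle: (1,0),(2,0),...,(P-1,0),(2,1),...
    cols, rows = np.triu_indices(P, k=1)  # row-major upper == column-major lower
    return rows, cols


def edge_index(i: int, j: int, P: int) -> int:
    """Flat edge index of matrix entry (i, j) under the documented ordering.

    Ordering is column-major over the strict lower triangle:
    (1,0),(2,0),...,(P-1,0),(2,1),... ; requires 0 <= j < i < P.
    """
    if not (0 <= j < i < P):
        raise ValueError(f"need 0 <= j < i < P, got (i={i}, j={j}, P={P})")
    # columns 0..j-1 hold P-1-c edges each, then offset within column j
    return j * (P - 1) - j * (j - 1) // 2 + (i - j - 1)


def edge_index_inverse(k: int, P: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: flat index k -> (i, j)."""
    if not (0 <= k < n_edges(P)):
        raise ValueError(f"edge index {k} out of range for P={P}")
    rows, cols = _lower_indices(P)
    return int(rows[k]), int(cols[k])


def vectorize_lower(C: np.ndarray) -> np.ndarray:
    """Vectorize the strict lower triangle of a square symmetric matrix."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectivity matrix must be square")
    rows, cols = _lower_indices(C.shape[0])
    return C[rows, cols]


def devectorize_lower(v: np.ndarray, P: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector (inverse round trip)."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != n_edges(P):
        raise ValueError(f"edge vector length {v.shape[0]} != P(P-1)/2 = {n_edges(P)}")
    C = np.full((P, P), diagonal, dtype=float)
    rows, cols = _lower_indices(P)
    C[rows, cols] = v
    C[cols, rows] = v
    return C


def assemble(
    edge_vectors: dict[object, np.ndarray] | pd.DataFrame,
    behavior: pd.DataFrame,
    behavior_columns: list[str] | tuple[str, ...],
    group_column: str = "group",
    id_column: str = "participant_id",
    group_order: tuple[str, ...] = GROUP_ORDER,
) -> GroupedDataset:
    """Align edge vectors with a behavior table into a GroupedDataset.

    Rows are sorted young block then old block, stable by participant id
    within block.  Input order is irrelevant; mismatched or duplicated
    participant ids raise.
    """
    if isinstance(edge_vectors, pd.DataFrame):
        ev = {pid: np.asarray(row, dtype=float) for pid, row in edge_vectors.iterrows()}
    else:
        ev = {pid: np.asarray(v, dtype=float) for pid, v in edge_vectors.items()}

    ids = behavior[id_column].tolist()
    dup = behavior[id_column][behavior[id_column].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated participant id(s) in behavior table: {dup}")
    missing = [pid for pid in ids if pid not in ev]
    if missing:
        raise ValueError(f"participant(s) missing an edge vector: {missing}")
    extra = [pid for pid in ev if pid not in set(ids)]
    if extra:
        raise ValueError(f"edge vector(s) without a behavior row: {extra}")

    lens = {len(v) for v in ev.values()}
    if len(lens) != 1:
        raise ValueError(f"inconsistent edge-vector lengths: {sorted(lens)}")

    tbl = behavior.copy()
    bad = set(tbl[group_column]) - set(group_order)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    tbl["_grank"] = tbl[group_column].map({g: i for i, g in enumerate(group_order)})
    tbl = tbl.sort_values(["_grank", id_column], kind="stable")

    X = np.vstack([ev[pid] for pid in tbl[id_column]])
    Y = tbl[list(behavior_columns)].to_numpy(dtype=float)
    counts = tbl[group_column].value_counts().to_dict()
    log.info(
        "assembled %d participants (%s) x %d edges, %d behaviors; "
        "rows ordered %s", len(tbl), counts, X.shape[1], Y.shape[1],
        "/".join(g for g in group_order if g in counts),
    )
    return GroupedDataset(
        X=X,
        Y=Y,
        groups=tbl[group_column].to_numpy(dtype=object),
        participant_ids=tbl[id_column].to_numpy(dtype=object),
        behavior_names=tuple(behavior_columns),
        group_order=group_order,
    )
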