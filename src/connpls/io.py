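"""Delimited-text IO for behavior tables, connectivity, atlases and results.

All on-disk formats are plain text: CSV for the behavior table, TSV for
atlases and matrices, JSON for scalar results and the run manifest.  Parcel
ids are 1-based in files (common atlas convention) and 0-based in memory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ParcelAtlas, n_edges, vectorize_lower

__all__ = [
    "read_behavior_table",
    "write_behavior_table",
    "read_atlas",
    "write_atlas",
    "read_connectivity_matrix",
    "read_connectivity_long",
    "read_edge_vectors",
    "write_edge_vectors",
    "write_json",
    "file_checksum",
]


def read_behavior_table(
    path: str | Path, id_column: str = "participant_id", group_column: str = "group"
) -> pd.DataFrame:
    """Read the participant behavior table (CSV), validating ids and groups."""
    path = Path(path)
    tbl = pd.read_csv(path)
    for col in (id_column, group_column):
        if col not in tbl.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    dup = tbl[id_column][tbl[id_column].duplicated()]
    if not dup.empty:
        lines = (dup.index + 2).tolist()  # header is line 1
        raise ValueError(
            f"{path}: duplicated participant id(s) {dup.tolist()} at line(s) {lines}"
        )
    return tbl


def write_behavior_table(tbl: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tbl.to_csv(path, index=False)


def read_atlas(path: str | Path) -> ParcelAtlas:
    """Read a parcel atlas TSV with columns parcel_id (1-based), network."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t")
    for col in ("parcel_id", "network"):
        if col not in tbl.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    ids = tbl["parcel_id"].to_numpy()
    expected = np.arange(1, len(ids) + 1)
    if not np.array_equal(np.sort(ids), expected):
        raise ValueError(
            f"{path}: parcel ids must be 1..{len(ids)} without gaps or repeats"
        )
    tbl = tbl.sort_values("parcel_id")
    return ParcelAtlas(tuple(tbl["network"].astype(str)))


def write_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"parcel_id": np.arange(1, atlas.n_parcels + 1), "network": atlas.networks}
    ).to_csv(path, sep="\t", index=False)


def read_connectivity_matrix(path: str | Path) -> np.ndarray:
    """Square connectivity TSV with a header row/column of 1-based parcel ids."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    M = tbl.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is {M.shape[0]}x{M.shape[1]}, not square")
    if not np.allclose(M, M.T, atol=1e-12, equal_nan=False):
        raise ValueError(f"{path}: matrix is not symmetric")
    return M


def read_connectivity_long(path: str | Path, n_parcels: int) -> np.ndarray:
    """Long-format edge table (i, j, value; 1-based ids) -> edge vector."""
    from .connectome import edge_index

    path = Path(path)
    tbl = pd.read_csv(path, sep="\t")
    for col in ("i", "j", "value"):
        if col not in tbl.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    v = np.full(n_edges(n_parcels), np.nan)
    for line, row in enumerate(tbl.itertuples(index=False), start=2):
        i, j = int(row.i) - 1, int(row.j) - 1
        if i < j:
            i, j = j, i
        try:
            k = edge_index(i, j, n_parcels)
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from exc
        v[k] = float(row.value)
    if np.any(np.isnan(v)):
        raise ValueError(f"{path}: {int(np.isnan(v).sum())} edge(s) missing")
    return v


def read_edge_vectors(path: str | Path) -> pd.DataFrame:
    """Participant-by-edge TSV (first column participant_id)."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    dup = tbl.index[tbl.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated participant id(s) {list(dup)}")
    return tbl


def write_edge_vectors(
    edge_vectors: dict | pd.DataFrame, path: str | Path
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if not isinstance(edge_vectors, pd.DataFrame):
        edge_vectors = pd.DataFrame(
            {pid: np.asarray(v, dtype=float) for pid, v in edge_vectors.items()}
        ).T
    edge_vectors.index.name = "participant_id"
    edge_vectors.to_csv(path, sep="\t")


def connectivity_to_edge_vector(C: np.ndarray) -> np.ndarray:
    return vectorize_lower(C)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
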