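"""Readers, writers and in-memory containers for the problem instance.

A problem instance consists of three pieces tied together by a shared node
ordering:

* an undirected, unweighted interaction network (:class:`Network`),
* a per-node attribute matrix (:class:`FeatureMatrix`),
* a partially observed multi-label assignment (:class:`LabelTable`).

All on-disk formats are plain UTF-8 TSV (plus MatrixMarket for sparse
features).  Node identifiers are free-form strings externally; internally
every structure uses dense 0-based indices aligned to ``Network.node_ids``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "FeatureMatrix",
    "LabelTable",
    "read_network",
    "read_features",
    "read_labels",
    "write_network",
    "write_features",
    "write_labels",
]


@dataclass(frozen=True)
class Network:
    """Undirected graph over ``m`` nodes with deduplicated edges.

    Edges are stored as index pairs ``(i, j)`` with ``i < j``; self-loops
    are disallowed.  ``node_ids`` fixes the external-id <-> index mapping.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        m = len(self.node_ids)
        if len(set(self.node_ids)) != m:
            raise ValueError("duplicate node identifiers")
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError(f"edge ({i},{j}) endpoint outside [0,{m})")
            if i > j:
                raise ValueError("edges must be stored with i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))

    @property
    def m(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def has_edge(self, i: int, j: int) -> bool:
        a, b = (i, j) if i < j else (j, i)
        return (a, b) in set(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR form."""
        m = self.m
        if not self.edges:
            return sp.csr_matrix((m, m))
        e = np.asarray(self.edges)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(rows.shape[0])
        return sp.csr_matrix((data, (rows, cols)), shape=(m, m))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.m, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass(frozen=True)
class FeatureMatrix:
    """Dense ``m x p`` real attribute matrix aligned to a node ordering."""

    values: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", v)
        if self.feature_names is not None and len(self.feature_names) != v.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabelTable:
    """``m x c`` binary multi-label matrix with an observed-node mask.

    Rows where ``known_mask`` is true are the labeled set; every such row
    must carry at least one label.  Unknown rows are typically all-zero but
    may hold current hard predictions during collective inference.
    """

    Y: np.ndarray
    known_mask: np.ndarray

    def __post_init__(self):
        Y = np.asarray(self.Y)
        mask = np.asarray(self.known_mask, dtype=bool)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-dimensional")
        if Y.shape[1] < 2:
            raise ValueError("need at least 2 classes")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("Y entries must be 0/1")
        if mask.shape != (Y.shape[0],):
            raise ValueError("known_mask length mismatch")
        empty_known = mask & (Y.sum(axis=1) == 0)
        if empty_known.any():
            bad = np.flatnonzero(empty_known)[:5].tolist()
            raise ValueError(f"known nodes with empty label sets: {bad}")
        object.__setattr__(self, "Y", Y.astype(np.int8))
        object.__setattr__(self, "known_mask", mask)

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def c(self) -> int:
        return self.Y.shape[1]

    @property
    def n_known(self) -> int:
        return int(self.known_mask.sum())

    def class_counts(self) -> np.ndarray:
        """Number of labeled instances per class (the l_d of the label prior)."""
        return self.Y[self.known_mask].sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# readers


def _parse_tsv_pairs(path: Path) -> list[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    return out


def read_network(edge_list_path, node_list_path=None) -> Network:
    """Read an undirected network from a 2-column TSV edge list.

    Parameters
    ----------
    edge_list_path
        TSV with two identifier columns; ``#`` comment lines allowed.
    node_list_path
        Optional one-id-per-line file fixing the node ordering and allowing
        isolated nodes.  Without it, ordering is first appearance in the
        edge list.

    Symmetric duplicates are merged and self-loops dropped with a warning.
    """
    edge_list_path = Path(edge_list_path)
    if node_list_path is not None:
        ids: list[str] = []
        with open(node_list_path, encoding="utf-8") as fh:
            for raw in fh:
                s = raw.strip()
                if s and not s.startswith("#"):
                    ids.append(s)
        index = {nid: k for k, nid in enumerate(ids)}
        fixed_order = True
    else:
        ids, index = [], {}
        fixed_order = False

    edges: set[tuple[int, int]] = set()
    n_loops = 0
    for lineno, fields in _parse_tsv_pairs(edge_list_path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(
                f"{edge_list_path}:{lineno}: malformed edge line (need 2 columns)"
            )
        u, v = fields[0].strip(), fields[1].strip()
        for nid in (u, v):
            if nid not in index:
                if fixed_order:
                    raise ValueError(
                        f"{edge_list_path}:{lineno}: unknown node id {nid!r} "
                        "not present in node list"
                    )
                index[nid] = len(ids)
                ids.append(nid)
        i, j = index[u], index[v]
        if i == j:
            n_loops += 1
            continue
        edges.add((min(i, j), max(i, j)))
    if n_loops:
        logger.warning("dropped %d self-loop(s) from %s", n_loops, edge_list_path)
    return Network(node_ids=tuple(ids), edges=tuple(sorted(edges)))


def read_features(path, network: Network, fmt: str = "tsv", row_ids_path=None) -> FeatureMatrix:
    """Read an attribute matrix and align rows to the network node order.

    ``tsv``: header row of feature names, first column the node id.
    ``mtx``: MatrixMarket coordinate file plus a one-id-per-line row-id
    sidecar (``row_ids_path``).
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        id_col = df.columns[0]
        df = df.set_index(id_col)
        try:
            vals = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric feature cell ({exc})") from exc
        names = tuple(df.columns)
        row_index = {nid: k for k, nid in enumerate(df.index)}
    elif fmt == "mtx":
        if row_ids_path is None:
            raise ValueError("mtx format requires a row-id sidecar file")
        mat = scipy.io.mmread(path)
        vals = np.asarray(sp.csr_matrix(mat).todense(), dtype=float)
        with open(row_ids_path, encoding="utf-8") as fh:
            rids = [s.strip() for s in fh if s.strip()]
        if len(rids) != vals.shape[0]:
            raise ValueError("row-id sidecar length does not match matrix rows")
        names = None
        row_index = {nid: k for k, nid in enumerate(rids)}
    else:
        raise ValueError(f"unknown feature format {fmt!r}")

    if len(row_index) != network.m:
        raise ValueError(
            f"feature rows ({len(row_index)}) do not match network nodes ({network.m})"
        )
    order = np.empty(network.m, dtype=int)
    for k, nid in enumerate(network.node_ids):
        if nid not in row_index:
            raise ValueError(f"node {nid!r} missing from feature file {path}")
        order[k] = row_index[nid]
    return FeatureMatrix(values=vals[order], feature_names=names)


def read_labels(path, network: Network, c: int) -> LabelTable:
    """Read known labels from a (node_id, class_index) pair TSV.

    Nodes that appear at least once become the known set; duplicates are
    idempotent.  Class indices live in ``[0, c)``.
    """
    path = Path(path)
    Y = np.zeros((network.m, c), dtype=np.int8)
    mask = np.zeros(network.m, dtype=bool)
    index = {nid: k for k, nid in enumerate(network.node_ids)}
    for lineno, fields in _parse_tsv_pairs(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: malformed label line")
        nid, lab = fields[0].strip(), fields[1].strip()
        if nid not in index:
            raise ValueError(f"{path}:{lineno}: node id {nid!r} not in network")
        try:
            d = int(lab)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer class index {lab!r}") from exc
        if not 0 <= d < c:
            raise ValueError(f"{path}:{lineno}: class index {d} outside [0,{c})")
        i = index[nid]
        Y[i, d] = 1
        mask[i] = True
    return LabelTable(Y=Y, known_mask=mask)


# ---------------------------------------------------------------------------
# writers


def write_network(network: Network, edge_list_path, node_list_path=None) -> None:
    with open(edge_list_path, "w", encoding="utf-8") as fh:
        for i, j in network.edges:
            fh.write(f"{network.node_ids[i]}\t{network.node_ids[j]}\n")
    if node_list_path is not None:
        with open(node_list_path, "w", encoding="utf-8") as fh:
            for nid in network.node_ids:
                fh.write(nid + "\n")


def write_features(features: FeatureMatrix, network: Network, path) -> None:
    names = features.feature_names or tuple(f"f{k}" for k in range(features.p))
    df = pd.DataFrame(features.values, columns=list(names))
    df.insert(0, "node_id", list(network.node_ids))
    df.to_csv(path, sep="\t", index=False)


def write_labels(labels: LabelTable, network: Network, path) -> None:
    """Write (node_id, class_index) pairs for the known nodes only."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in np.flatnonzero(labels.known_mask):
            for d in np.flatnonzero(labels.Y[i]):
                fh.write(f"{network.node_ids[i]}\t{d}\n")
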