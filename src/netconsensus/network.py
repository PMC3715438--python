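"""Core network representation, derived stochastic matrices, and file I/O.

The universal input is a node-labelled non-negative interaction matrix ``A``
with ``A[i, j]`` = the count (or weight) of interactions sent *from* node
``i`` *to* node ``j``.  Consensus about a node accumulates in its column:
every "in" quantity in this package is a column sum.  Self-interactions are
forbidden (the systems this models — signalling, collaboration, functional
linkage — have none), so the diagonal is identically zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .scores import ScoreVector

logger = logging.getLogger(__name__)

Format = Literal["edgelist", "adjacency", "graphml"]
DanglingPolicy = Literal["self_loop", "uniform"]

_SYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class InteractionNetwork:
    """A node-labelled interaction matrix with directedness/weightedness flags.

    Parameters
    ----------
    node_ids : tuple of str
        Unique node labels, in a fixed order; every output vector is aligned
        to this order so the order itself never carries meaning.
    weights : ndarray of shape (n, n)
        Non-negative matrix, ``weights[i, j]`` = interactions from node ``i``
        to node ``j``.  Zero diagonal.  Symmetric when ``directed`` is False;
        binary (0/1) when ``weighted`` is False.
    """

    node_ids: tuple[str, ...]
    weights: np.ndarray
    directed: bool = True
    weighted: bool = True

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.node_ids)
        object.__setattr__(self, "node_ids", ids)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(ids)
        if len(set(ids)) != n:
            raise FormatError("node ids must be unique")
        if w.shape != (n, n):
            raise FormatError(
                f"weight matrix shape {w.shape} does not match {n} node ids"
            )
        if not np.all(np.isfinite(w)):
            raise FormatError("weights must be finite")
        if np.any(w < 0):
            raise FormatError("negative interaction weights are not allowed")
        if np.any(np.diag(w) != 0):
            bad = ids[int(np.argmax(np.diag(w) != 0))]
            raise FormatError(f"self-interaction on node {bad!r} is not allowed")
        if not self.directed and not np.allclose(w, w.T, rtol=_SYMMETRY_RTOL, atol=0):
            raise FormatError("undirected network requires a symmetric matrix")
        if not self.weighted and not np.all(np.isin(w, (0.0, 1.0))):
            raise FormatError("unweighted network requires binary entries")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node: str) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def in_strength(self) -> np.ndarray:
        """Weighted in-degree vector R (column sums)."""
        return self.weights.sum(axis=0)

    def out_strength(self) -> np.ndarray:
        """Weighted out-degree vector (row sums)."""
        return self.weights.sum(axis=1)

    def with_weights(self, weights: np.ndarray, *, weighted: bool | None = None,
                     directed: bool | None = None) -> "InteractionNetwork":
        return InteractionNetwork(
            self.node_ids,
            weights,
            directed=self.directed if directed is None else directed,
            weighted=self.weighted if weighted is None else weighted,
        )

    def to_graph(self) -> nx.DiGraph | nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.node_ids)
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows, cols):
            if not self.directed and i > j:
                continue
            g.add_edge(self.node_ids[i], self.node_ids[j],
                       weight=float(self.weights[i, j]))
        return g


@dataclass(frozen=True)
class ReceivingDistribution:
    """Column-stochastic matrix N: ``N[i, j] = A[i, j] / R[j]``.

    Column j describes where node j's incoming interactions come from; the
    column of a node that receives nothing is all-zero.
    """

    matrix: np.ndarray


@dataclass(frozen=True)
class SendingDistribution:
    """Row-stochastic matrix M: ``M[i, j] = A[i, j] / out_i``.

    Rows of non-senders ("dangling" nodes) are patched per policy so every
    row sums to one exactly.
    """

    matrix: np.ndarray
    dangling_policy: DanglingPolicy = "self_loop"


def to_binary(net: InteractionNetwork) -> InteractionNetwork:
    """Binary matrix B: 1 where A > 0, else 0.  Directedness is preserved."""
    return net.with_weights((net.weights > 0).astype(float), weighted=False)


def weighted_in_degree(net: InteractionNetwork) -> ScoreVector:
    """Weighted in-degree R: total interaction weight received per node."""
    return ScoreVector(net.node_ids, net.in_strength(), algorithm="R")


def receiving_distribution(net: InteractionNetwork) -> ReceivingDistribution:
    r = net.in_strength()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(r > 0, net.weights / r, 0.0)
    return ReceivingDistribution(m)


def sending_distribution(
    net: InteractionNetwork, dangling_policy: DanglingPolicy = "self_loop"
) -> SendingDistribution:
    if dangling_policy not in ("self_loop", "uniform"):
        raise FormatError(f"unknown dangling policy {dangling_policy!r}")
    out = net.out_strength()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(out[:, None] > 0, net.weights / out[:, None], 0.0)
    dangling = out == 0
    if np.any(dangling):
        if dangling_policy == "self_loop":
            m[dangling, :] = 0.0
            m[np.nonzero(dangling)[0], np.nonzero(dangling)[0]] = 1.0
        else:
            m[dangling, :] = 1.0 / net.n
    return SendingDistribution(m, dangling_policy)


# ---------------------------------------------------------------------------
# File I/O
#
# Edge list: TSV `source<TAB>target[<TAB>weight]`, '#' comments allowed,
# weight defaults to 1, duplicate rows are summed (warned).
# Adjacency: CSV with node ids as first row and first column.
# GraphML: standard, edge attribute `weight`.
# ---------------------------------------------------------------------------


def load_network(
    path: str | Path,
    format: Format = "edgelist",
    *,
    directed: bool = True,
    weighted: bool = True,
    nodes: Sequence[str] | None = None,
) -> InteractionNetwork:
    """Read an interaction network from a file.

    ``nodes`` optionally declares the node set (and order); nodes appearing
    in the file but not declared are an error, and declared isolated nodes
    are kept.  Without it, node order is order of first appearance.
    """
    path = Path(path)
    if format == "edgelist":
        return _load_edgelist(path, directed=directed, weighted=weighted, nodes=nodes)
    if format == "adjacency":
        return _load_adjacency(path, directed=directed, weighted=weighted)
    if format == "graphml":
        return _load_graphml(path, directed=directed, weighted=weighted)
    raise FormatError(f"unknown format {format!r}")


def _load_edgelist(path: Path, *, directed: bool, weighted: bool,
                   nodes: Sequence[str] | None) -> InteractionNetwork:
    edges: list[tuple[str, str, float]] = []
    order: list[str] = list(dict.fromkeys(str(x) for x in nodes)) if nodes else []
    declared = set(order) if nodes else None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
        src, tgt = parts[0], parts[1]
        try:
            w = float(parts[2]) if len(parts) == 3 else 1.0
        except ValueError:
            raise FormatError(f"{path}:{lineno}: weight {parts[2]!r} is not a number")
        if w < 0:
            raise FormatError(f"{path}:{lineno}: negative weight {w}")
        if src == tgt:
            raise FormatError(f"{path}:{lineno}: self-loop on node {src!r}")
        for node in (src, tgt):
            if declared is not None:
                if node not in declared:
                    raise FormatError(f"{path}:{lineno}: undeclared node {node!r}")
            elif node not in order:
                order.append(node)
        edges.append((src, tgt, w))

    idx = {node: i for i, node in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    seen: set[tuple[str, str]] = set()
    for src, tgt, w in edges:
        key = (src, tgt) if directed else (min(src, tgt), max(src, tgt))
        if key in seen:
            logger.warning("duplicate edge %s -> %s in %s: weights summed", src, tgt, path)
        seen.add(key)
        a[idx[src], idx[tgt]] += w
        if not directed:
            a[idx[tgt], idx[src]] += w
    if not weighted:
        a = (a > 0).astype(float)
    return InteractionNetwork(tuple(order), a, directed=directed, weighted=weighted)


def _load_adjacency(path: Path, *, directed: bool, weighted: bool) -> InteractionNetwork:
    df = pd.read_csv(path, index_col=0)
    cols = tuple(str(c) for c in df.columns)
    rows = tuple(str(r) for r in df.index)
    if cols != rows:
        raise FormatError(f"{path}: adjacency row and column labels differ")
    a = df.to_numpy(dtype=float)
    if not directed and not np.allclose(a, a.T, rtol=_SYMMETRY_RTOL, atol=0):
        raise FormatError(f"{path}: asymmetric adjacency declared undirected")
    if not weighted:
        a = (a > 0).astype(float)
    return InteractionNetwork(cols, a, directed=directed, weighted=weighted)


def _load_graphml(path: Path, *, directed: bool, weighted: bool) -> InteractionNetwork:
    g = nx.read_graphml(path)
    if directed and not g.is_directed():
        g = g.to_directed()
    if not directed and g.is_directed():
        g = g.to_undirected()
    order = tuple(str(v) for v in g.nodes())
    idx = {v: i for i, v in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise FormatError(f"{path}: negative weight on edge {u}->{v}")
        if u == v:
            raise FormatError(f"{path}: self-loop on node {u!r}")
        a[idx[u], idx[v]] += w
        if not directed:
            a[idx[v], idx[u]] += w
    if not weighted:
        a = (a > 0).astype(float)
    return InteractionNetwork(order, a, directed=directed, weighted=weighted)


def save_network(net: InteractionNetwork, path: str | Path,
                 format: Format = "edgelist") -> None:
    """Write a network to a file in one of the supported formats."""
    path = Path(path)
    if format == "edgelist":
        lines = []
        rows, cols = np.nonzero(net.weights)
        for i, j in zip(rows, cols):
            if not net.directed and i > j:
                continue
            w = net.weights[i, j]
            wtxt = str(int(w)) if float(w).is_integer() else repr(float(w))
            lines.append(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{wtxt}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "adjacency":
        df = pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)
        df.to_csv(path)
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise FormatError(f"unknown format {format!r}")
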