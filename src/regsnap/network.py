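"""Directed weighted regulatory networks and their random-walk matrices.

The regulatory network is a directed graph ``N = (V, E)`` whose vertices
are regulators and target genes and whose edges are documented regulatory
associations, optionally weighted.  The regulator set ``R`` is derived,
not supplied: any vertex with at least one outgoing edge regulates
something.  Diffusion uses the transition probability matrix ``W`` of a
random walk on ``N``, each row normalized by the vertex's total outgoing
weight; vertices without outgoing edges get all-zero rows, so mass
reaching them decays rather than teleporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """A directed weighted graph with a fixed vertex ordering.

    The vertex order (first appearance in the edge list, by default) fixes
    the coordinates of every matrix and vector derived from the network.
    """

    graph: nx.DiGraph
    vertex_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.vertex_order:
            self.vertex_order = list(self.graph.nodes)
        if set(self.vertex_order) != set(self.graph.nodes):
            raise ValueError("vertex_order must list exactly the graph's vertices")
        self._index = {v: i for i, v in enumerate(self.vertex_order)}

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def regulators(self) -> list[str]:
        """Vertices with outgoing edges, in vertex order."""
        return [v for v in self.vertex_order if self.graph.out_degree(v) > 0]

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def adjacency(self) -> sp.csr_matrix:
        """Sparse adjacency A in vertex order; A[u, v] = w(u, v)."""
        return nx.to_scipy_sparse_array(
            self.graph, nodelist=self.vertex_order, weight="weight", format="csr"
        )

    def out_weight_diagonal(self) -> np.ndarray:
        """Diagonal of D: total outgoing weight per vertex, in vertex order."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    """Read `regulator<TAB>target[<TAB>weight]` lines; '#' starts a comment.

    A missing weight defaults to 1 (edges need not be differentiated by
    evidence).  Duplicate ordered pairs are merged keeping the maximum
    weight, with a warning; non-positive weights are an error.
    """
    path = Path(path)
    g = nx.DiGraph()
    order: list[str] = []
    seen: set[str] = set()
    n_dups = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"found {len(cells)}"
                )
            u, v = cells[0], cells[1]
            if len(cells) == 3:
                try:
                    w = float(cells[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: weight is not a number: {cells[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: weight must be positive, got {w}")
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    order.append(x)
            if g.has_edge(u, v):
                n_dups += 1
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
    if n_dups:
        logger.warning("read_edge_list: merged %d duplicate edge(s) by max weight", n_dups)
    net = RegulatoryNetwork(graph=g, vertex_order=order)
    logger.info(
        "read_edge_list: |V|=%d |E|=%d |R|=%d",
        net.n_vertices, net.n_edges, len(net.regulators),
    )
    return net


def write_edge_list(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the TSV dialect that :func:`read_edge_list` consumes."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for u in net.vertex_order:
            for v in sorted(net.graph.successors(u), key=net.index_of):
                w = net.graph[u][v]["weight"]
                fh.write(f"{u}\t{v}\t{w:g}\n")


def transpose(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Reverse every edge, keeping weights and the vertex ordering.

    On the transposed graph mass flows from targets back to their
    regulators, which is how regulator relevance accumulates.
    """
    return RegulatoryNetwork(
        graph=net.graph.reverse(copy=True), vertex_order=list(net.vertex_order)
    )


def transition_matrix(net: RegulatoryNetwork) -> sp.csr_matrix:
    """Row-stochastic-or-zero random-walk matrix W = D^-1 A.

    W[u, v] = w(u, v) / (total out-weight of u); rows of vertices without
    outgoing edges are all zero.
    """
    a = net.adjacency().astype(float)
    out = np.asarray(a.sum(axis=1)).ravel()
    inv = np.divide(1.0, out, out=np.zeros_like(out), where=out > 0)
    return (sp.diags(inv) @ a).tocsr()
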