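"""Clique projections and dyadic (graph) maximum-likelihood Louvain.

These are the comparison methods for the hypergraph algorithms: a hypergraph
is flattened to a weighted graph by replacing each size-k hyperedge with a
k-clique — either unnormalized (every pair gets the edge's weight) or
normalized by ``1/(k-1)``, in which case the weighted dyadic degree of every
node equals its hypergraph degree exactly — and the two-cluster planted
partition machinery is then run on the projection.

Graph maximum-likelihood Louvain (GMLL) is implemented as the size-2
specialization of the all-or-nothing coordinate ascent, with real-valued
projected weights flowing through the cut and volume formulas unchanged
(a quasi-likelihood, since projected weights are no longer Poisson counts).
A single resolution parameter is estimated per alternation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hypergraph import Hypergraph, relabel
from .inference import InferenceResult, coordinate_ascent

__all__ = ["WeightedGraph", "clique_project", "gmll", "graph_modularity"]


class _RealWeightedHypergraph(Hypergraph):
    """Internal: a hypergraph whose edge weights may be positive reals.

    Used to push projected graphs through the hypergraph likelihood
    machinery; the data-facing :class:`Hypergraph` keeps integer weights.
    """

    def add_edge(self, nodes, weight=1.0) -> None:
        key = tuple(sorted(nodes))
        if len(set(key)) != len(key) or not key:
            raise ValueError(f"invalid hyperedge {key}")
        if any(v < 0 or v >= self.n for v in key):
            raise ValueError(f"node index out of range in hyperedge {key}")
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        self._edges[key] = self._edges.get(key, 0.0) + float(weight)


@dataclass
class WeightedGraph:
    """Symmetric non-negative weighted graph stored as an upper-triangle map."""

    n: int
    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    names: list[str] | None = None

    def __post_init__(self):
        if self.names is None:
            self.names = [str(i + 1) for i in range(self.n)]
        for (i, j), w in self.weights.items():
            if not (0 <= i < j < self.n):
                raise ValueError(f"invalid edge key {(i, j)}: need 0 <= i < j < n")
            if w < 0:
                raise ValueError("edge weights must be non-negative")

    def add(self, i: int, j: int, w: float) -> None:
        if i == j:
            raise ValueError("self-loops are not supported")
        key = (i, j) if i < j else (j, i)
        self.weights[key] = self.weights.get(key, 0.0) + w

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n)
        for (i, j), w in self.weights.items():
            d[i] += w
            d[j] += w
        return d

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def to_edge_list(self) -> str:
        lines = ["# nodes: " + ",".join(self.names)]
        for (i, j), w in sorted(self.weights.items()):
            lines.append(f"{self.names[i]} {self.names[j]} {w:.10g}")
        return "\n".join(lines) + "\n"

    def _as_hypergraph(self) -> _RealWeightedHypergraph:
        G = _RealWeightedHypergraph(n=self.n, names=self.names)
        for (i, j), w in self.weights.items():
            if w > 0:
                G.add_edge((i, j), w)
        return G


def clique_project(H: Hypergraph, normalized: bool = True) -> WeightedGraph:
    """Replace each size-k hyperedge by a weighted k-clique.

    Unnormalized: every one of the ``k choose 2`` pairs receives the edge's
    weight.  Normalized: pair weights are divided by ``k - 1``, which makes
    the weighted dyadic degree of every node equal to its hypergraph degree.
    Contributions from different hyperedges accumulate by summation.
    """
    G = WeightedGraph(n=H.n, names=list(H.names))
    for nodes, w in H.edges.items():
        k = len(nodes)
        if k < 2:
            raise ValueError("clique projection requires edges of size >= 2")
        pair_w = w / (k - 1) if normalized else float(w)
        for ai in range(k):
            for bi in range(ai + 1, k):
                G.add(nodes[ai], nodes[bi], pair_w)
    return G


def graph_modularity(G: WeightedGraph, labels) -> float:
    """Classical Newman-Girvan modularity of a partition of a weighted graph."""
    z = np.asarray(labels, dtype=int)
    W = G.total_weight
    if W <= 0:
        raise ValueError("graph has no edge weight")
    d = G.degrees()
    ncl = int(z.max()) + 1
    win = np.zeros(ncl)
    for (i, j), w in G.weights.items():
        if z[i] == z[j]:
            win[z[i]] += w
    vol = np.bincount(z, weights=d, minlength=ncl)
    return float(np.sum(win / W - (vol / (2 * W)) ** 2))


def gmll(G: WeightedGraph | Hypergraph, n_alternations: int = 20, seed=None,
         regularize: bool = False, z0=None, warm_start: bool = False,
         smoothing: float = 1e-10, select: str = "likelihood") -> InferenceResult:
    """Graph maximum-likelihood Louvain on a weighted graph.

    Alternates dyadic Louvain with closed-form estimation of the planted
    partition rates (hence a single resolution parameter) and returns the
    alternation with the highest quasi-log-likelihood.  With
    ``select="modularity"`` the returned partition instead maximizes the
    classical dyadic modularity over the alternations (the plain graph
    Louvain convention).  A :class:`Hypergraph` input must be 2-uniform.
    """
    if isinstance(G, Hypergraph):
        if set(G.m_k) - {2}:
            raise ValueError("gmll on a hypergraph requires all edges of size 2")
        graph = clique_project(G, normalized=True)  # identity on 2-uniform input
    else:
        graph = G
    if not graph.weights:
        raise ValueError("cannot cluster an empty graph")
    H2 = graph._as_hypergraph()
    result = coordinate_ascent(
        H2, family="aon", n_alternations=n_alternations, seed=seed,
        regularize=regularize, z0=z0, warm_start=warm_start,
        smoothing=smoothing, k_max=2, sizes=(2,),
        keep_partitions=(select == "modularity"),
    )
    if select == "modularity":
        scores = [graph_modularity(graph, e["z"]) for e in result.trace]
        idx = int(np.argmax(scores))
        result.best_index = idx
        result.z = relabel(result.trace[idx]["z"])
        result.best_ll = result.trace[idx]["L"]
        for e, s in zip(result.trace, scores):
            e["modularity"] = s
    elif select != "likelihood":
        raise ValueError("select must be 'likelihood' or 'modularity'")
    result.settings["method"] = "gmll"
    result.settings["select"] = select
    return result
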