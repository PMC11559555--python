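"""Hypergraph container, text I/O, and degree-based filters.

A hypergraph is a set of ``n`` nodes together with a multiset of hyperedges.
Each hyperedge is an unordered set of distinct nodes carrying a positive
integer weight (its multiplicity).  Nodes are identified externally by
arbitrary string tokens and internally by contiguous 0-based indices; the
token-to-index map is preserved so that clusterings and filtered hypergraphs
can be written back out with the original identifiers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "Hypergraph",
    "Clustering",
    "read_hyperedge_list",
    "write_hyperedge_list",
    "read_bipartite_edge_list",
    "read_labels",
    "write_labels",
    "c_core",
    "max_edge_size_filter",
]


class Hypergraph:
    """An integer-weighted hypergraph on ``n`` nodes.

    Parameters
    ----------
    n:
        Number of nodes.  Node indices are ``0 .. n-1``.
    edges:
        Mapping (or iterable of pairs) from hyperedges — iterables of
        distinct node indices — to positive integer weights.  Duplicate
        edges accumulate weight.
    names:
        Optional external node identifiers, one per node.  Defaults to the
        stringified indices ``"1" .. "n"``.
    """

    def __init__(
        self,
        n: int,
        edges: Mapping[tuple, int] | Iterable[tuple] = (),
        names: Sequence[str] | None = None,
    ):
        if n < 0:
            raise ValueError("node count must be non-negative")
        self.n = int(n)
        self._edges: dict[tuple[int, ...], int] = {}
        items = edges.items() if isinstance(edges, Mapping) else edges
        for nodes, weight in items:
            self.add_edge(nodes, weight)
        if names is None:
            names = [str(i + 1) for i in range(self.n)]
        if len(names) != self.n:
            raise ValueError("one name per node required")
        self.names = list(names)

    def add_edge(self, nodes: Iterable[int], weight: int = 1) -> None:
        key = tuple(sorted(nodes))
        if len(set(key)) != len(key):
            raise ValueError(f"repeated node in hyperedge {key}")
        if not key:
            raise ValueError("empty hyperedge")
        if any(v < 0 or v >= self.n for v in key):
            raise ValueError(f"node index out of range in hyperedge {key}")
        w = int(weight)
        if w < 1 or w != weight:
            raise ValueError(f"hyperedge weight must be a positive integer, got {weight}")
        self._edges[key] = self._edges.get(key, 0) + w

    # -- basic views ---------------------------------------------------

    @property
    def edges(self) -> dict[tuple[int, ...], int]:
        """Mapping from sorted node tuples to integer weights."""
        return self._edges

    def __len__(self) -> int:
        return len(self._edges)

    @property
    def m(self) -> int:
        """Total weighted hyperedge count."""
        return sum(self._edges.values())

    @property
    def m_k(self) -> dict[int, int]:
        """Weighted hyperedge count per edge size."""
        out: dict[int, int] = {}
        for nodes, w in self._edges.items():
            out[len(nodes)] = out.get(len(nodes), 0) + w
        return out

    @property
    def k_max(self) -> int:
        """Largest observed edge size (0 for an edgeless hypergraph)."""
        return max((len(e) for e in self._edges), default=0)

    def degrees(self) -> np.ndarray:
        """Weighted degree of every node: hyperedge incidences counted with weight."""
        d = np.zeros(self.n)
        for nodes, w in self._edges.items():
            for i in nodes:
                d[i] += w
        return d

    def volume(self) -> float:
        """vol(H) = sum of all node degrees = sum over edges of weight * size."""
        return float(sum(w * len(e) for e, w in self._edges.items()))

    def incidence(self) -> list[list[int]]:
        """Per-node list of indices into ``edge_list()`` (unweighted incidence)."""
        inc: list[list[int]] = [[] for _ in range(self.n)]
        for j, (nodes, _) in enumerate(self._edges.items()):
            for i in nodes:
                inc[i].append(j)
        return inc

    def edge_list(self) -> list[tuple[tuple[int, ...], int]]:
        return list(self._edges.items())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypergraph)
            and self.n == other.n
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return f"Hypergraph(n={self.n}, edges={len(self._edges)}, m={self.m})"


@dataclass
class Clustering:
    """A hard partition of the nodes of a hypergraph.

    ``z`` holds one 0-based cluster label per node; labels are contiguous
    ``0 .. n_clusters-1`` with no empty cluster.  ``vol`` holds the degree
    volume of each cluster, so ``vol.sum() == vol(H)``.
    """

    z: np.ndarray
    vol: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_labels(cls, labels: Sequence[int], H: Hypergraph) -> "Clustering":
        z = relabel(np.asarray(labels))
        if len(z) != H.n:
            raise ValueError("one label per node required")
        d = H.degrees()
        ncl = int(z.max()) + 1 if len(z) else 0
        vol = np.bincount(z, weights=d, minlength=ncl)
        return cls(z=z, vol=vol)

    @property
    def n_clusters(self) -> int:
        return len(self.vol)


def relabel(z: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 0-based ids, ordered by first appearance."""
    z = np.asarray(z)
    _, inv = np.unique(z, return_inverse=True)
    # np.unique sorts; reorder by first appearance for stable, input-independent ids
    order = {}
    out = np.empty(len(z), dtype=int)
    for i, lab in enumerate(inv):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def volumes(H: Hypergraph, labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """Per-cluster degree volumes and the total volume vol(H).

    ``labels`` must already be contiguous 0-based cluster ids covering all nodes.
    """
    z = np.asarray(labels, dtype=int)
    if len(z) != H.n:
        raise ValueError("one label per node required")
    if len(z) and (z.min() < 0):
        raise ValueError("labels must be non-negative")
    d = H.degrees()
    ncl = int(z.max()) + 1 if len(z) else 0
    vol = np.bincount(z, weights=d, minlength=ncl)
    return vol, float(d.sum())


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def _tokens(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None or delimiter.isspace():
        return line.split()
    return [t.strip() for t in line.split(delimiter) if t.strip()]


def read_hyperedge_list(
    source: str | TextIO,
    delimiter: str | None = None,
    weighted: bool = False,
    node_order: Sequence[str] | None = None,
) -> Hypergraph:
    """Read a hypergraph from a hyperedge-list text source.

    One hyperedge per line: node tokens separated by whitespace (or by
    ``delimiter``), with an optional trailing integer weight column enabled by
    ``weighted=True``.  Lines starting with ``#`` are comments; duplicate
    hyperedges accumulate weight.  Node tokens are mapped to indices in order
    of first appearance unless ``node_order`` fixes the universe up front.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    index: dict[str, int] = {}
    if node_order is not None:
        for name in node_order:
            index.setdefault(str(name), len(index))
    raw_edges: list[tuple[tuple[str, ...], int]] = []
    saw_content = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        saw_content = True
        toks = _tokens(line, delimiter)
        weight = 1
        if weighted:
            if len(toks) < 2:
                raise ValueError(f"line {lineno}: need node tokens and a weight")
            try:
                weight = int(toks[-1])
            except ValueError as err:
                raise ValueError(f"line {lineno}: malformed weight {toks[-1]!r}") from err
            toks = toks[:-1]
        if weight <= 0:
            raise ValueError(f"line {lineno}: non-positive weight {weight}")
        if not toks:
            raise ValueError(f"line {lineno}: empty hyperedge")
        if len(set(toks)) != len(toks):
            raise ValueError(f"line {lineno}: repeated node token in hyperedge")
        for t in toks:
            index.setdefault(t, len(index))
        raw_edges.append((tuple(toks), weight))
    if not saw_content:
        raise ValueError("empty hyperedge-list input")
    names = [None] * len(index)
    for name, i in index.items():
        names[i] = name
    H = Hypergraph(n=len(index), names=names)  # type: ignore[arg-type]
    for toks, w in raw_edges:
        H.add_edge((index[t] for t in toks), w)
    return H


def write_hyperedge_list(H: Hypergraph, delimiter: str = " ") -> str:
    """Serialize to the hyperedge-list format with a trailing weight column.

    The node-name map is recorded in a header comment so that
    ``read(write(H))`` reproduces ``(n, m_k, degrees)`` exactly, including
    isolated nodes.
    """
    lines = ["# nodes: " + ",".join(H.names)]
    for nodes, w in sorted(H.edges.items()):
        lines.append(delimiter.join(H.names[i] for i in nodes) + delimiter + str(w))
    return "\n".join(lines) + "\n"


def read_written_hyperedge_list(text: str, delimiter: str = " ") -> Hypergraph:
    """Round-trip reader for :func:`write_hyperedge_list` output.

    Recovers the node universe (including isolated nodes) from the header
    comment before parsing the weighted edge lines.
    """
    node_order = None
    for line in text.splitlines():
        if line.startswith("# nodes: "):
            node_order = line[len("# nodes: "):].split(",")
            break
    return read_hyperedge_list(
        text, delimiter=None if delimiter.isspace() else delimiter,
        weighted=True, node_order=node_order,
    )


def read_bipartite_edge_list(source: str | TextIO, delimiter: str | None = None) -> Hypergraph:
    """Read a hypergraph from (node-id, edge-id) incidence pairs, one per line."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    members: dict[str, set[str]] = {}
    index: dict[str, int] = {}
    saw = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        saw = True
        toks = _tokens(line, delimiter)
        if len(toks) != 2:
            raise ValueError(f"line {lineno}: expected 'node edge' pair")
        node, edge = toks
        index.setdefault(node, len(index))
        members.setdefault(edge, set()).add(node)
    if not saw:
        raise ValueError("empty bipartite edge-list input")
    names = [None] * len(index)
    for name, i in index.items():
        names[i] = name
    H = Hypergraph(n=len(index), names=names)  # type: ignore[arg-type]
    for edge_nodes in members.values():
        H.add_edge(sorted(index[t] for t in edge_nodes))
    return H


def read_labels(source: str | TextIO, H: Hypergraph) -> np.ndarray:
    """Read a two-column TSV (node-id <TAB> label) into a contiguous label vector."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    name_to_idx = {name: i for i, name in enumerate(H.names)}
    raw = [None] * H.n
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'node<TAB>label'")
        node, label = parts
        if node not in name_to_idx:
            raise ValueError(f"line {lineno}: unknown node {node!r}")
        raw[name_to_idx[node]] = label
    if any(v is None for v in raw):
        missing = [H.names[i] for i, v in enumerate(raw) if v is None]
        raise ValueError(f"missing labels for nodes {missing[:5]}")
    return relabel(np.asarray(raw))


def write_labels(H: Hypergraph, labels: Sequence[int]) -> str:
    return "\n".join(f"{H.names[i]}\t{labels[i]}" for i in range(H.n)) + "\n"


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _subhypergraph(H: Hypergraph, keep_nodes: Sequence[int],
                   keep_edges: Iterable[tuple[tuple[int, ...], int]]) -> Hypergraph:
    remap = {old: new for new, old in enumerate(keep_nodes)}
    sub = Hypergraph(n=len(keep_nodes), names=[H.names[i] for i in keep_nodes])
    for nodes, w in keep_edges:
        sub.add_edge((remap[i] for i in nodes), w)
    return sub


def c_core(H: Hypergraph, c: float) -> Hypergraph:
    """Largest subhypergraph in which every node has weighted degree >= c.

    Nodes of degree below ``c`` are removed together with every hyperedge
    incident to them; removal repeats until a fixed point.  The result is
    independent of removal order and the operation is idempotent.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    alive_nodes = set(range(H.n))
    edges = list(H.edges.items())
    alive_edges = set(range(len(edges)))
    while True:
        deg = Counter()
        for j in alive_edges:
            nodes, w = edges[j]
            for i in nodes:
                deg[i] += w
        drop = {i for i in alive_nodes if deg[i] < c}
        if not drop:
            break
        alive_nodes -= drop
        alive_edges = {j for j in alive_edges if not drop.intersection(edges[j][0])}
        if not alive_nodes:
            break
    keep = sorted(alive_nodes)
    return _subhypergraph(H, keep, (edges[j] for j in sorted(alive_edges)))


def max_edge_size_filter(H: Hypergraph, k_max: int) -> Hypergraph:
    """Retain only hyperedges of size at most ``k_max`` (node set unchanged)."""
    if k_max < 2:
        raise ValueError("maximum edge size must be at least 2")
    return _subhypergraph(
        H, list(range(H.n)),
        ((nodes, w) for nodes, w in H.edges.items() if len(nodes) <= k_max),
    )
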