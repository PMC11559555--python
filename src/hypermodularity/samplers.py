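"""Generative samplers for clustered hypergraphs.

Three generators are provided:

* :func:`sample_dchsbm` — the exact degree-corrected hypergraph
  stochastic blockmodel: independent Poisson edge counts at every unordered
  node tuple, sampled by size and affinity class so that the cost scales
  with the number of realized edges rather than with ``n^k``.
* :func:`sample_runtime_testbed` — an equal-cluster benchmark with a fixed
  number of edges (10 per node) of sizes 2-4, each placed inside a random
  cluster with a size-dependent probability and uniformly at random
  otherwise.
* :func:`sample_two_block` — two equal communities with tunable
  within-community fractions of 2-edges and 3-edges, the standard setting
  for detectability experiments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._comb import partitions_of, power_sums, vol_p_from_power_sums
from .affinities import AffinityFunction
from .hypergraph import Hypergraph

__all__ = [
    "DCHSBMModel",
    "TwoBlockConfig",
    "planted_aon_model",
    "sample_dchsbm",
    "sample_runtime_testbed",
    "sample_two_block",
    "detectability_threshold",
]


@dataclass
class DCHSBMModel:
    """Generative triple (labels, degree parameters, affinity) on ``n`` nodes."""

    n: int
    z: np.ndarray
    theta: np.ndarray
    Omega: AffinityFunction

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=int)
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.z) != self.n or len(self.theta) != self.n:
            raise ValueError("z and theta must have one entry per node")
        if np.any(self.theta < 0):
            raise ValueError("theta must be non-negative")

    def expected_edge_count(self) -> float:
        """Closed-form total Poisson rate, summed by size and profile."""
        ncl = int(self.z.max()) + 1
        volt = np.bincount(self.z, weights=self.theta, minlength=ncl)
        S = power_sums(volt, max(self.Omega.sizes, default=0))
        total = 0.0
        for k in self.Omega.sizes:
            for p in partitions_of(k):
                w = self.Omega.value(p)
                if w:
                    total += vol_p_from_power_sums(p, S) * w
        return total


def planted_aon_model(
    n: int,
    n_groups: int,
    mean_degree: dict[int, float],
    within_fraction: dict[int, float],
) -> DCHSBMModel:
    """An equal-cluster, unit-degree-parameter all-or-nothing DCHSBM.

    ``mean_degree[k]`` is the target expected number of size-k edges per
    node and ``within_fraction[k]`` the expected fraction of size-k edges
    contained in one cluster.  Affinity values are solved from the
    closed-form expected within/cross edge masses.
    """
    if n % n_groups:
        raise ValueError("n must be divisible by n_groups")
    z = np.repeat(np.arange(n_groups), n // n_groups)
    theta = np.ones(n)
    gvol = n / n_groups
    volH = float(n)
    omega: dict = {}
    sizes = tuple(sorted(mean_degree))
    for k in sizes:
        ck, pk = float(mean_degree[k]), float(within_fraction[k])
        if not 0 <= pk <= 1:
            raise ValueError("within fractions must lie in [0, 1]")
        total_k = n * ck / k
        within_mass = n_groups * gvol**k
        cross_mass = volH**k - within_mass
        omega[(k, 1)] = pk * total_k / within_mass
        omega[(k, 0)] = (1 - pk) * total_k / cross_mass if cross_mass > 0 else 0.0
    Omega = AffinityFunction("aon", k_max=max(sizes), omega=omega, sizes=sizes)
    return DCHSBMModel(n=n, z=z, theta=theta, Omega=Omega)


# ---------------------------------------------------------------------------
# Exact DCHSBM sampling
# ---------------------------------------------------------------------------

def _sample_injective_assignment(parts, weights_by_part, rng):
    """Draw distinct clusters (c_1..c_t) with prob proportional to
    prod_j w[c_j]^{p_j}, where ``weights_by_part[j]`` is the per-cluster
    weight vector ``vol^{p_j}``.  Enumerates when the permutation space is
    small, otherwise rejection-samples from independent draws."""
    t = len(parts)
    ncl = len(weights_by_part[0])
    n_perm = math.perm(ncl, t) if ncl >= t else 0
    if n_perm == 0:
        return None
    if n_perm <= 5000:
        assignments = list(itertools.permutations(range(ncl), t))
        probs = np.array([
            math.prod(weights_by_part[j][c] for j, c in enumerate(a))
            for a in assignments
        ])
        total = probs.sum()
        if total <= 0:
            return None
        return assignments[rng.choice(len(assignments), p=probs / total)]
    norm = [w / w.sum() for w in weights_by_part]
    while True:
        draw = tuple(rng.choice(ncl, p=norm[j]) for j in range(t))
        if len(set(draw)) == t:
            return draw


def sample_dchsbm(model: DCHSBMModel, seed=None, return_raw: bool = False):
    """Sample a hypergraph from the DCHSBM.

    Edge counts at each unordered node tuple (repeated nodes allowed, as in
    the model) are Poisson with rate ``b_R * prod(theta_R) * Omega(z_R)``.
    Sampling is grouped by (size, affinity class): a Poisson total is drawn
    from the closed-form class rate, and each edge is then placed by
    choosing a label profile, an assignment of profile parts to distinct
    clusters, and finally i.i.d. theta-proportional node draws within each
    chosen cluster.

    Tuples that realize repeated nodes are excluded from the returned
    :class:`Hypergraph`, whose edges are node sets; pass ``return_raw=True``
    to additionally obtain the full multiset counts, including
    repeated-node tuples.
    """
    rng = np.random.default_rng(seed)
    z, theta, Omega = model.z, model.theta, model.Omega
    ncl = int(z.max()) + 1
    volt = np.bincount(z, weights=theta, minlength=ncl)
    S = power_sums(volt, max(Omega.sizes, default=0))

    members = [np.flatnonzero(z == c) for c in range(ncl)]
    theta_in = [theta[idx] for idx in members]
    theta_norm = []
    for c in range(ncl):
        tot = theta_in[c].sum()
        theta_norm.append(theta_in[c] / tot if tot > 0 else None)

    counts: dict[tuple[int, ...], int] = {}
    for k in Omega.sizes:
        for cls, patterns in Omega.classes(k).items():
            w = float(Omega.omega.get(cls, 0.0))
            if w <= 0:
                continue
            rates = np.array([vol_p_from_power_sums(p, S) for p in patterns])
            total = w * rates.sum()
            if total <= 0:
                continue
            n_edges = rng.poisson(total)
            if n_edges == 0:
                continue
            probs = rates / rates.sum()
            pick = rng.choice(len(patterns), size=n_edges, p=probs)
            for idx in pick:
                p = patterns[idx]
                wparts = [volt**part for part in p]
                assign = _sample_injective_assignment(p, wparts, rng)
                if assign is None:
                    continue
                nodes: list[int] = []
                for part, c in zip(p, assign):
                    if theta_norm[c] is None:
                        nodes = []
                        break
                    pickn = rng.choice(len(members[c]), size=part, p=theta_norm[c])
                    nodes.extend(int(members[c][j]) for j in pickn)
                if not nodes:
                    continue
                key = tuple(sorted(nodes))
                counts[key] = counts.get(key, 0) + 1

    H = Hypergraph(n=model.n)
    for key, c in counts.items():
        if len(set(key)) == len(key):
            H.add_edge(key, c)
    if return_raw:
        return H, counts
    return H


# ---------------------------------------------------------------------------
# Benchmark generators
# ---------------------------------------------------------------------------

def sample_runtime_testbed(n: int, p2: float, p3: float, p4: float, seed=None,
                           nodes_per_cluster: int = 200, edges_per_node: int = 10):
    """Equal-cluster testbed: ``n / nodes_per_cluster`` clusters and exactly
    ``edges_per_node * n`` hyperedges with sizes uniform on {2, 3, 4}.

    A size-k edge is placed on k distinct nodes inside one uniformly chosen
    cluster with probability ``p_k`` and on k distinct nodes drawn uniformly
    from the whole node set otherwise.  Returns ``(H, z_true)``.
    """
    if n < nodes_per_cluster or n % nodes_per_cluster:
        raise ValueError(f"n must be a positive multiple of {nodes_per_cluster}")
    for name, p in (("p2", p2), ("p3", p3), ("p4", p4)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_clusters = n // nodes_per_cluster
    z = np.repeat(np.arange(n_clusters), nodes_per_cluster)
    p_within = {2: p2, 3: p3, 4: p4}
    H = Hypergraph(n=n)
    m = edges_per_node * n
    sizes = rng.integers(2, 5, size=m)
    for k in sizes:
        k = int(k)
        if rng.random() < p_within[k]:
            c = rng.integers(n_clusters)
            pool = np.arange(c * nodes_per_cluster, (c + 1) * nodes_per_cluster)
            nodes = rng.choice(pool, size=k, replace=False)
        else:
            nodes = rng.choice(n, size=k, replace=False)
        H.add_edge(nodes)
    return H, z


def fig1_regime(n: int) -> tuple[float, float, float]:
    """Within-cluster placement probabilities ``(3/5, 1/n^3, 1/n^4)`` under
    which larger edges are almost never within-cluster."""
    return 0.6, 1.0 / n**3, 1.0 / n**4


@dataclass
class TwoBlockConfig:
    """Two equal communities with per-size mean degrees and within fractions.

    Defaults: 500 nodes in communities of 250, each node incident on average
    to five 2-edges and five 3-edges; ``p2``/``p3`` set the expected
    fraction of size-2/size-3 edges falling inside a single community.
    """

    n: int = 500
    c2: float = 5.0
    c3: float = 5.0
    p2: float = 0.5
    p3: float = 0.5

    def __post_init__(self):
        if self.n % 2:
            raise ValueError("n must be even")
        if not (0 <= self.p2 <= 1 and 0 <= self.p3 <= 1):
            raise ValueError("within fractions must lie in [0, 1]")

    @property
    def c_in(self) -> float:
        """Expected within-community dyadic degree implied by the 2-edges."""
        return self.c2 * self.p2

    @property
    def c_out(self) -> float:
        """Expected between-community dyadic degree implied by the 2-edges."""
        return self.c2 * (1 - self.p2)


def sample_two_block(config: TwoBlockConfig, seed=None):
    """Sample the two-community detectability benchmark; returns ``(H, z_true)``.

    The number of size-k edges is Poisson with mean ``n * c_k / k``.  Each
    edge is within-community with probability ``p_k`` (k distinct nodes from
    one uniformly chosen community) and otherwise spans both communities
    (uniform over spanning k-node sets, by rejection).
    """
    rng = np.random.default_rng(seed)
    n = config.n
    half = n // 2
    z = np.repeat([0, 1], half)
    if half < 3:
        raise ValueError("communities must contain at least 3 nodes")
    H = Hypergraph(n=n)
    for k, ck, pk in ((2, config.c2, config.p2), (3, config.c3, config.p3)):
        m_k = rng.poisson(n * ck / k)
        for _ in range(m_k):
            if rng.random() < pk:
                c = rng.integers(2)
                pool = np.arange(c * half, (c + 1) * half)
                nodes = rng.choice(pool, size=k, replace=False)
            else:
                while True:
                    nodes = rng.choice(n, size=k, replace=False)
                    labs = z[nodes]
                    if labs.min() != labs.max():
                        break
            H.add_edge(nodes)
    return H, z


def detectability_threshold(c_in: float, c_out: float) -> float:
    """Signal strength ``(c_in - c_out)^2 / (2 (c_in + c_out))`` of a
    two-community planted partition; detection is impossible in the
    large-graph limit when the value is below 1."""
    if c_in < 0 or c_out < 0:
        raise ValueError("mean degrees must be non-negative")
    if c_in + c_out == 0:
        raise ValueError("at least one of c_in, c_out must be positive")
    return (c_in - c_out) ** 2 / (2 * (c_in + c_out))
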