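"""Likelihood decomposition and modularity objectives for the DCHSBM.

The degree-corrected hypergraph stochastic blockmodel places an independent
Poisson number of hyperedges at every unordered node tuple ``R`` (repeated
nodes allowed) with rate ``b_R * prod(theta_R) * Omega(z_R)``, where ``b_R``
is the number of distinct orderings of ``R``.  The log-likelihood of a
weighted hyperedge set splits as ``L = Q + K + C``:

* ``Q`` — the only term depending on labels and affinity: observed
  log-affinity mass minus the expected edge mass,
* ``K`` — the degree-parameter term ``sum_R a_R log prod(theta_R)``,
* ``C`` — a data-only constant.

For symmetric affinities ``Q`` reduces to a sum over partition vectors of
``cut_p * log Omega(p) - vol_p * Omega(p)`` — the symmetric hypergraph
modularity.  The expectation sums over all tuples, including repeated-node
tuples; that is precisely what makes the generalized volumes exact power
sums of cluster volumes.  Under the all-or-nothing affinity the objective
collapses further to per-size cut and volume terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from ._comb import (partition_vector, partitions_of, power_sums,
                    vol_p_from_power_sums)
from .affinities import AffinityFunction, AONParameters
from .hypergraph import Hypergraph

__all__ = [
    "LikelihoodDecomposition",
    "log_likelihood",
    "cut_p",
    "cut_patterns",
    "vol_p",
    "vol_p_update",
    "symmetric_modularity",
    "cut_k",
    "aon_modularity",
]


@dataclass
class LikelihoodDecomposition:
    """The ``L = Q + K + C`` split of the DCHSBM log-likelihood."""

    L: float
    Q: float
    K: float
    C: float

    def as_dict(self) -> dict[str, float]:
        return {"L": self.L, "Q": self.Q, "K": self.K, "C": self.C}


# ---------------------------------------------------------------------------
# Generalized cuts and volumes
# ---------------------------------------------------------------------------

def cut_patterns(H: Hypergraph, labels: Sequence[int]) -> dict[tuple[int, ...], float]:
    """Weighted count of observed edges per partition vector."""
    z = np.asarray(labels, dtype=int)
    out: dict[tuple[int, ...], float] = {}
    for nodes, w in H.edges.items():
        p = partition_vector(z[list(nodes)])
        out[p] = out.get(p, 0.0) + w
    return out


def cut_p(H: Hypergraph, labels: Sequence[int], p: Sequence[int]) -> float:
    """Weighted number of edges whose label profile equals ``p``."""
    p = tuple(sorted(p, reverse=True))
    return cut_patterns(H, labels).get(p, 0.0)


def vol_p(volumes: Sequence[float], p: Sequence[int]) -> float:
    """Generalized volume: sum over ordered label tuples with profile ``p``
    of the product of cluster volumes, evaluated from power sums rather than
    by ``l^k`` enumeration."""
    p = tuple(sorted(p, reverse=True))
    S = power_sums(np.asarray(volumes, dtype=float), sum(p))
    return vol_p_from_power_sums(p, S)


def vol_p_update(volumes: Sequence[float], p: Sequence[int], degree: float,
                 source: int, target: int) -> float:
    """Generalized volume of ``p`` after moving ``degree`` units of volume
    from cluster ``source`` to cluster ``target``.

    Only the two affected power-sum entries change, so the cost is
    independent of the number of nodes and clusters.
    """
    p = tuple(sorted(p, reverse=True))
    k = sum(p)
    vol = np.asarray(volumes, dtype=float)
    S = power_sums(vol, k)
    for q in range(1, k + 1):
        S[q] += ((vol[source] - degree) ** q - vol[source] ** q
                 + (vol[target] + degree) ** q - vol[target] ** q)
    return vol_p_from_power_sums(p, S)


def cut_k(H: Hypergraph, labels: Sequence[int], k: int) -> float:
    """Weighted number of size-k edges spanning two or more clusters."""
    z = np.asarray(labels, dtype=int)
    within = 0.0
    total = 0.0
    for nodes, w in H.edges.items():
        if len(nodes) != k:
            continue
        total += w
        labs = z[list(nodes)]
        if np.all(labs == labs[0]):
            within += w
    return total - within


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def _theta_volumes(H: Hypergraph, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    ncl = int(z.max()) + 1 if len(z) else 0
    return np.bincount(z, weights=theta, minlength=ncl)


def _expected_mass(vol: np.ndarray, Omega: AffinityFunction) -> float:
    """sum over sizes and profiles of vol_p * Omega(p) (the expected edge count)."""
    if not Omega.sizes:
        return 0.0
    S = power_sums(vol, max(Omega.sizes))
    total = 0.0
    for k in Omega.sizes:
        for p in partitions_of(k):
            w = Omega.value(p)
            if w:
                total += vol_p_from_power_sums(p, S) * w
    return total


def symmetric_modularity(H: Hypergraph, labels: Sequence[int],
                         Omega: AffinityFunction,
                         theta: np.ndarray | None = None) -> float:
    """Q = sum_p [cut_p log Omega(p) - vol_p Omega(p)].

    Returns ``-inf`` when an observed edge falls in a zero-affinity class
    (its Poisson rate is zero but its count is positive); a profile with
    zero affinity and zero observed count contributes nothing.
    """
    z = np.asarray(labels, dtype=int)
    theta = H.degrees() if theta is None else np.asarray(theta, dtype=float)
    vol = _theta_volumes(H, z, theta)
    q = 0.0
    for p, c in cut_patterns(H, z).items():
        lw = Omega.log_value(p)
        if lw == -math.inf:
            return -math.inf
        q += c * lw
    return q - _expected_mass(vol, Omega)


def log_likelihood(H: Hypergraph, labels: Sequence[int], Omega: AffinityFunction,
                   theta: np.ndarray | None = None) -> LikelihoodDecomposition:
    """Full DCHSBM log-likelihood split into modularity, degree and constant terms.

    ``theta`` defaults to the conditional ML estimate (the degree vector).
    Observed edges must have sizes covered by ``Omega.sizes``.
    """
    z = np.asarray(labels, dtype=int)
    if len(z) != H.n:
        raise ValueError("one label per node required")
    theta = H.degrees() if theta is None else np.asarray(theta, dtype=float)
    if len(theta) != H.n:
        raise ValueError("one theta per node required")
    if np.any(theta < 0):
        raise ValueError("theta must be non-negative")
    observed_sizes = set(H.m_k)
    if observed_sizes - set(Omega.sizes):
        raise ValueError(f"affinity does not cover edge sizes "
                         f"{sorted(observed_sizes - set(Omega.sizes))}")

    Q = symmetric_modularity(H, z, Omega, theta=theta)

    d = H.degrees()
    with np.errstate(divide="ignore", invalid="ignore"):
        lt = np.where(d > 0, np.log(np.where(theta > 0, theta, 1.0)), 0.0)
    if np.any((d > 0) & (theta == 0)):
        K = -math.inf
    else:
        K = float(np.dot(d, lt))

    C = 0.0
    for nodes, w in H.edges.items():
        # observed edges have distinct nodes, so b_R = k!
        C += w * float(gammaln(len(nodes) + 1)) - float(gammaln(w + 1))

    return LikelihoodDecomposition(L=Q + K + C, Q=Q, K=K, C=C)


def aon_modularity(H: Hypergraph, labels: Sequence[int],
                   params: AONParameters | None = None,
                   beta: Mapping[int, float] | None = None,
                   gamma: Mapping[int, float] | None = None) -> float:
    """All-or-nothing modularity: ``-sum_k beta_k [cut_k + gamma_k sum_l vol_l^k]``.

    Equal to the symmetric modularity under the corresponding AON affinity up
    to a label-independent constant, so objective *differences* between
    partitions agree exactly.  Supply either ``params`` or explicit
    ``beta``/``gamma`` maps covering every observed edge size.
    """
    if params is not None:
        beta, gamma = params.beta, params.gamma
    if beta is None or gamma is None:
        raise ValueError("need AON parameters (beta, gamma)")
    missing = set(H.m_k) - set(beta)
    if missing:
        raise ValueError(f"missing beta/gamma for edge sizes {sorted(missing)}")
    z = np.asarray(labels, dtype=int)
    d = H.degrees()
    ncl = int(z.max()) + 1 if len(z) else 0
    vol = np.bincount(z, weights=d, minlength=ncl)

    m_k = H.m_k
    within: dict[int, float] = {}
    for nodes, w in H.edges.items():
        labs = z[list(nodes)]
        if np.all(labs == labs[0]):
            within[len(nodes)] = within.get(len(nodes), 0.0) + w

    total = 0.0
    for k, b in beta.items():
        cut = m_k.get(k, 0) - within.get(k, 0.0)
        total -= b * (cut + gamma[k] * float(np.sum(vol**k)))
    return total
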