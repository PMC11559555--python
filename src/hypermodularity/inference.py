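"""Louvain-style maximum-likelihood inference for hypergraph blockmodels.

Two greedy ascent engines optimize the modularity term of the DCHSBM
log-likelihood over hard partitions:

* :func:`symmetric_hmll` handles any symmetric affinity.  It tracks the
  full label profile of every hyperedge and therefore operates on the
  original adjacency data in every round, moving previously formed clusters
  as units without collapsing them.
* :func:`aon_hmll` is the specialized all-or-nothing variant.  Because the
  objective only asks whether an edge is contained in one cluster, clusters
  can be collapsed into consolidated supernodes between rounds and only
  edge sizes and spanning patterns are retained, which makes this path fast
  and memory-light.

Both engines visit units in a seeded random order, accept only strictly
improving moves, and terminate at a partition that no single unit move can
improve.  :func:`coordinate_ascent` embeds either engine in the alternating
scheme that re-estimates the degree and affinity parameters in closed form
after every partition update and returns the alternation with the highest
model log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._comb import partitions_of, power_sums, vol_p_from_power_sums
from .affinities import (AffinityFunction, AONParameters, aon_params,
                         estimate_omega, strict_modularity_params)
from .hypergraph import Hypergraph, relabel
from .objectives import log_likelihood

__all__ = [
    "InferenceResult",
    "symmetric_hmll",
    "aon_hmll",
    "coordinate_ascent",
    "refine",
    "regularized_objective",
]

# absolute guard against accepting moves driven by floating-point noise
_MOVE_GUARD = 1e-12


def regularized_objective(Q: float, n: int, n_clusters: int) -> float:
    """Objective with the flat-prior cluster-count penalty ``-n log(n_clusters)``."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    return Q - n * math.log(n_clusters)


# ---------------------------------------------------------------------------
# Shared driver
# ---------------------------------------------------------------------------

def _louvain(state, rng, max_passes: int = 100_000) -> None:
    """Greedy rounds of unit moves.

    Round 1 treats every node (or supernode) as its own unit; each later
    round re-forms units from the clusters of the previous round.  Within a
    round, passes over a seeded random permutation of the units repeat until
    a full pass accepts no move; the algorithm stops after a round with no
    accepted move.
    """
    while True:
        moved_in_round = False
        for _ in range(max_passes):
            order = rng.permutation(state.n_units())
            moved = False
            for ui in order:
                a = state.unit_label(ui)
                best_gain, best_b = _MOVE_GUARD, None
                for b in state.candidates(ui, a):
                    gain = state.delta_q(ui, a, b)
                    if gain > best_gain:
                        best_gain, best_b = gain, b
                if best_b is not None:
                    state.apply(ui, a, best_b)
                    moved = True
                    moved_in_round = True
            if not moved:
                break
        if not moved_in_round:
            break
        if not state.regroup():
            break


# ---------------------------------------------------------------------------
# Symmetric engine (full adjacency data, no collapse)
# ---------------------------------------------------------------------------

class _SymmetricState:
    def __init__(self, H: Hypergraph, Omega: AffinityFunction,
                 z0: np.ndarray, regularize: bool):
        self.n = H.n
        self.regularize = regularize
        self.d = H.degrees()
        self.k_sizes = tuple(sorted(Omega.sizes))
        self.k_max = max(self.k_sizes, default=0)
        # pattern -> (omega, log omega) over all profiles of the supported sizes
        self.om: dict[tuple[int, ...], float] = {}
        self.logom: dict[tuple[int, ...], float] = {}
        for k in self.k_sizes:
            for p, v in Omega.pattern_table(k).items():
                self.om[p] = v
                self.logom[p] = math.log(v) if v > 0 else -math.inf
        self.patterns = [p for p in self.om if self.om[p] > 0]

        self.edges = [(nodes, float(w)) for nodes, w in H.edges.items()]
        self.incidence: list[list[int]] = [[] for _ in range(self.n)]
        for j, (nodes, _) in enumerate(self.edges):
            for i in nodes:
                self.incidence[i].append(j)

        self.z = np.array(z0, dtype=int)
        ncl = int(self.z.max()) + 1 if self.n else 0
        self.vol = np.bincount(self.z, weights=self.d, minlength=ncl).astype(float)
        self.csize = np.bincount(self.z, minlength=ncl)
        self.n_nonempty = int(np.count_nonzero(self.csize))
        self.S = power_sums(self.vol, self.k_max)
        self.expected = self._expected_mass(self.S)
        self.counters: list[dict[int, int]] = []
        for nodes, _ in self.edges:
            c: dict[int, int] = {}
            for i in nodes:
                c[self.z[i]] = c.get(self.z[i], 0) + 1
            self.counters.append(c)
        self.units: list[list[int]] = [[i] for i in range(self.n)]

    # -- unit interface -------------------------------------------------

    def n_units(self) -> int:
        return len(self.units)

    def unit_label(self, ui: int) -> int:
        return int(self.z[self.units[ui][0]])

    def candidates(self, ui: int, a: int):
        labs: set[int] = set()
        for i in self.units[ui]:
            for j in self.incidence[i]:
                labs.update(self.counters[j])
        labs.discard(a)
        return sorted(labs)

    def _expected_mass(self, S) -> float:
        total = 0.0
        for p in self.patterns:
            total += vol_p_from_power_sums(p, S) * self.om[p]
        return total

    def _unit_edges(self, ui: int) -> dict[int, int]:
        """Incident edge id -> number of unit nodes inside it."""
        touched: dict[int, int] = {}
        for i in self.units[ui]:
            for j in self.incidence[i]:
                touched[j] = touched.get(j, 0) + 1
        return touched

    def _moved_power_sums(self, v: float, a: int, b: int) -> np.ndarray:
        S = self.S.copy()
        va, vb = self.vol[a], self.vol[b]
        for q in range(1, self.k_max + 1):
            S[q] += (va - v) ** q - va**q + (vb + v) ** q - vb**q
        return S

    def delta_q(self, ui: int, a: int, b: int) -> float:
        v = float(sum(self.d[i] for i in self.units[ui]))
        dq = self.expected - self._expected_mass(self._moved_power_sums(v, a, b))
        for j, cnt in self._unit_edges(ui).items():
            c = self.counters[j]
            old_p = tuple(sorted(c.values(), reverse=True))
            new_c = dict(c)
            if new_c[a] == cnt:
                del new_c[a]
            else:
                new_c[a] -= cnt
            new_c[b] = new_c.get(b, 0) + cnt
            new_p = tuple(sorted(new_c.values(), reverse=True))
            lw_new = self.logom.get(new_p, -math.inf)
            if lw_new == -math.inf:
                return -math.inf
            dq += self.edges[j][1] * (lw_new - self.logom[old_p])
        if self.regularize and self.csize[a] == len(self.units[ui]):
            dq += self.n * math.log(self.n_nonempty / (self.n_nonempty - 1))
        return dq

    def apply(self, ui: int, a: int, b: int) -> None:
        unit = self.units[ui]
        v = float(sum(self.d[i] for i in unit))
        self.S = self._moved_power_sums(v, a, b)
        self.expected = self._expected_mass(self.S)
        for j, cnt in self._unit_edges(ui).items():
            c = self.counters[j]
            if c[a] == cnt:
                del c[a]
            else:
                c[a] -= cnt
            c[b] = c.get(b, 0) + cnt
        self.vol[a] -= v
        self.vol[b] += v
        emptied = self.csize[a] == len(unit)
        self.csize[a] -= len(unit)
        self.csize[b] += len(unit)
        if emptied:
            self.n_nonempty -= 1
        for i in unit:
            self.z[i] = b

    def regroup(self) -> bool:
        clusters: dict[int, list[int]] = {}
        for i in range(self.n):
            clusters.setdefault(int(self.z[i]), []).append(i)
        new_units = [clusters[lab] for lab in sorted(clusters)]
        self.units = new_units
        return True

    def labels(self) -> np.ndarray:
        return relabel(self.z)


def symmetric_hmll(H: Hypergraph, Omega: AffinityFunction,
                   z0: Sequence[int] | None = None,
                   regularize: bool = False, seed=None) -> np.ndarray:
    """Greedy symmetric-modularity ascent; returns contiguous 0-based labels.

    Starts from singleton clusters (or ``z0``), moves nodes and then whole
    previous-round clusters to adjacent clusters while any move strictly
    improves the objective, and returns a partition that is locally optimal
    under single-unit moves.  ``regularize`` adds the ``-n log(n_clusters)``
    prior penalty to every move evaluation.
    """
    if H.n == 0:
        return np.array([], dtype=int)
    z0 = np.arange(H.n) if z0 is None else relabel(np.asarray(z0))
    state = _SymmetricState(H, Omega, z0, regularize)
    _louvain(state, np.random.default_rng(seed))
    return state.labels()


# ---------------------------------------------------------------------------
# All-or-nothing engine (supernode collapse)
# ---------------------------------------------------------------------------

class _AONState:
    def __init__(self, n: int, edge_items, d: np.ndarray,
                 beta: Mapping[int, float], gamma: Mapping[int, float],
                 z0: np.ndarray, regularize: bool):
        self.n = n
        self.regularize = regularize
        self.beta = dict(beta)
        self.gamma = dict(gamma)
        self.k_sizes = tuple(sorted(self.beta))
        edge_items = list(edge_items)
        missing = {len(nodes) for nodes, _ in edge_items} - set(self.k_sizes)
        if missing:
            raise ValueError(f"missing beta/gamma for edge sizes {sorted(missing)}")
        # supernode state: initially one supernode per node
        self.svol = d.astype(float).copy()
        self.slabel = np.array(z0, dtype=int)
        self.membership = np.arange(self.n)  # original node -> supernode
        ncl = int(self.slabel.max()) + 1 if self.n else 0
        self.vol = np.bincount(self.slabel, weights=self.svol, minlength=ncl).astype(float)
        self.sn_per_label = np.bincount(self.slabel, minlength=ncl)
        self.n_nonempty = int(np.count_nonzero(self.sn_per_label))
        # edges over supernodes: (supernode tuple, size, weight)
        self.edges: list[tuple[tuple[int, ...], int, float]] = [
            (tuple(nodes), len(nodes), float(w)) for nodes, w in edge_items
        ]
        self._build_edge_index()

    def _build_edge_index(self) -> None:
        self.counters: list[dict[int, int]] = []
        self.incidence: list[list[int]] = [[] for _ in range(len(self.svol))]
        for j, (sns, _, _) in enumerate(self.edges):
            c: dict[int, int] = {}
            for s in sns:
                c[self.slabel[s]] = c.get(self.slabel[s], 0) + 1
                self.incidence[s].append(j)
            self.counters.append(c)

    def n_units(self) -> int:
        return len(self.svol)

    def unit_label(self, s: int) -> int:
        return int(self.slabel[s])

    def candidates(self, s: int, a: int):
        labs: set[int] = set()
        for j in self.incidence[s]:
            labs.update(self.counters[j])
        labs.discard(a)
        return sorted(labs)

    def _volume_term(self, v: float, a: int, b: int) -> float:
        va, vb = self.vol[a], self.vol[b]
        total = 0.0
        for k in self.k_sizes:
            bg = self.beta[k] * self.gamma[k]
            if bg:
                total -= bg * ((va - v) ** k - va**k + (vb + v) ** k - vb**k)
        return total

    def delta_q(self, s: int, a: int, b: int) -> float:
        dq = self._volume_term(self.svol[s], a, b)
        for j in self.incidence[s]:
            sns, k, w = self.edges[j]
            c = self.counters[j]
            uncut_before = len(c) == 1
            if c[a] > 1:
                uncut_after = False  # other a-labeled supernodes stay behind
            else:
                # labels after the move are (keys - {a}) + {b}
                uncut_after = len(c) == 1 or (len(c) == 2 and b in c)
            if uncut_after != uncut_before:
                dq += self.beta[k] * w * (1.0 if uncut_after else -1.0)
        if self.regularize and self.sn_per_label[a] == 1:
            dq += self.n * math.log(self.n_nonempty / (self.n_nonempty - 1))
        return dq

    def apply(self, s: int, a: int, b: int) -> None:
        v = self.svol[s]
        for j in self.incidence[s]:
            c = self.counters[j]
            if c[a] == 1:
                del c[a]
            else:
                c[a] -= 1
            c[b] = c.get(b, 0) + 1
        self.vol[a] -= v
        self.vol[b] += v
        emptied = self.sn_per_label[a] == 1
        self.sn_per_label[a] -= 1
        self.sn_per_label[b] += 1
        if emptied:
            self.n_nonempty -= 1
        self.slabel[s] = b

    def regroup(self) -> bool:
        """Collapse each cluster into one supernode and re-key the edges."""
        labs = sorted({int(l) for l in self.slabel})
        lab_to_new = {lab: i for i, lab in enumerate(labs)}
        old_to_new = np.array([lab_to_new[int(l)] for l in self.slabel])
        nsn = len(labs)
        new_svol = np.bincount(old_to_new, weights=self.svol, minlength=nsn)
        self.membership = old_to_new[self.membership]
        merged: dict[tuple[tuple[int, ...], int], float] = {}
        for sns, k, w in self.edges:
            new_sns = tuple(sorted({int(old_to_new[s]) for s in sns}))
            if len(new_sns) == 1:
                continue  # contained edges can never be cut again
            merged[(new_sns, k)] = merged.get((new_sns, k), 0.0) + w
        self.edges = [(sns, k, w) for (sns, k), w in merged.items()]
        self.svol = new_svol.astype(float)
        self.slabel = np.arange(nsn)
        self.vol = new_svol.astype(float).copy()
        self.sn_per_label = np.ones(nsn, dtype=int)
        self.n_nonempty = nsn
        self._build_edge_index()
        return True

    def labels(self) -> np.ndarray:
        return relabel(self.slabel[self.membership])


def aon_hmll(H: Hypergraph, params: AONParameters | None = None,
             beta: Mapping[int, float] | None = None,
             gamma: Mapping[int, float] | None = None,
             z0: Sequence[int] | None = None,
             regularize: bool = False, seed=None) -> np.ndarray:
    """Fast all-or-nothing Louvain ascent; returns contiguous 0-based labels.

    Optimizes the all-or-nothing modularity for the given per-size cut
    weights ``beta`` and resolutions ``gamma``.  Clusters are collapsed into
    supernodes between rounds; only edge sizes and the supernodes each edge
    spans are retained, so later rounds run on a much smaller structure.
    Produces the same local ascent as :func:`symmetric_hmll` under the
    corresponding all-or-nothing affinity.
    """
    if params is not None:
        beta, gamma = params.beta, params.gamma
    if beta is None or gamma is None:
        raise ValueError("need AON parameters (beta, gamma)")
    if H.n == 0:
        return np.array([], dtype=int)
    z0 = np.arange(H.n) if z0 is None else relabel(np.asarray(z0))
    state = _AONState(H.n, H.edges.items(), H.degrees(), beta, gamma, z0, regularize)
    _louvain(state, np.random.default_rng(seed))
    return state.labels()


# ---------------------------------------------------------------------------
# Coordinate ascent
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    """Output of alternating partition/parameter maximum-likelihood inference."""

    z: np.ndarray
    omega: AffinityFunction
    aon: AONParameters | None
    trace: list[dict] = field(default_factory=list)
    best_index: int = 0
    best_ll: float = -math.inf
    seed: object = None
    settings: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.z.max()) + 1 if len(self.z) else 0


def _positive_aon(Omega: AffinityFunction, volH: float, floor_scale: float) -> AONParameters:
    """AON (beta, gamma) from an estimated affinity, flooring non-positive
    class values (empty classes, or zero cross-volume when one cluster
    remains) at a negligible positive rate so the logs stay finite."""
    omega = dict(Omega.omega)
    for (k, branch), v in list(omega.items()):
        if v <= 0:
            omega[(k, branch)] = floor_scale / max(volH, 1.0) ** k
    return aon_params(AffinityFunction("aon", Omega.k_max, omega, sizes=Omega.sizes))


def coordinate_ascent(
    H: Hypergraph,
    family: str = "aon",
    n_alternations: int = 20,
    seed=None,
    z0: Sequence[int] | None = None,
    regularize: bool = False,
    k_max: int | None = None,
    sizes: Sequence[int] | None = None,
    smoothing: float = 1e-10,
    warm_start: bool = False,
    optimizer: str | None = None,
    keep_partitions: bool = False,
) -> InferenceResult:
    """Alternating maximization of the DCHSBM likelihood.

    Each alternation updates the partition with the Louvain engine matching
    the affinity family (the fast supernode path for ``aon``, the full
    symmetric engine otherwise), then re-estimates the degree and affinity
    parameters in closed form.  The first alternation, lacking parameter
    estimates, uses strict-modularity parameters (``beta_k = 1``,
    ``gamma_k = m_k / vol(H)^k``).  The returned result is the alternation
    with the highest model log-likelihood (penalized by ``-n log(n_clusters)``
    when ``regularize`` is on, matching the objective being ascended).

    Greedy agglomeration has a blind spot: an all-or-nothing size-k edge
    contributes no move gradient until k - 1 of its nodes are already
    co-clustered, so a singleton start cannot exploit large-edge signal when
    the dyadic signal is weak.  The alternations therefore mix three kinds
    of Louvain starts: the first runs from singletons (or ``z0``, which then
    also supplies the initial parameter estimates); odd alternations are
    seeded restarts cycling through random balanced partitions with a small
    number of clusters (interleaved with singleton starts), every other one
    masking the all-or-nothing objective to a single edge size so each
    size's signal is probed on its own — including sizes the current
    parameter estimates mis-weight; even alternations polish the best
    partition found so far.  Parameters feeding each update are the
    estimates from the most likely partition with at least two clusters, so
    weak correlation found by a coarse restart is amplified over later
    alternations.  ``warm_start=True`` instead seeds every run at the
    previous partition (useful for refining an external partition, but
    coarse partitions are absorbing — Louvain moves merge and never split).
    """
    family = family.lower()
    if optimizer is None:
        optimizer = "aon" if family == "aon" else "symmetric"
    if optimizer == "aon" and family != "aon":
        raise ValueError("the fast supernode path supports only the AON family")
    if H.m == 0:
        raise ValueError("cannot infer clusters in an edgeless hypergraph")
    rng = np.random.default_rng(seed)
    if k_max is None:
        k_max = max(H.k_max, 2)

    volH = H.volume()
    params: AONParameters | None = None
    Omega: AffinityFunction | None = None
    z_prev = None if z0 is None else relabel(np.asarray(z0))
    if z_prev is not None and z_prev.max() > 0:
        # a non-trivial initial partition also supplies initial parameters
        Omega = estimate_omega(H, z_prev, family=family, k_max=k_max,
                               sizes=sizes, smoothing=smoothing)
        if family == "aon":
            params = _positive_aon(Omega, volH, max(smoothing, 1e-300))

    # restart scales: random balanced partitions at small cluster counts
    # (where partial containment of large edges is most likely), interleaved
    # with singleton starts; the cycle repeats across alternations
    scales: list[int | None] = [k for k in (2, 3, 4, None, 2, 6, 8, None)
                                if k is None or k <= max(2, H.n // 4)]

    trace: list[dict] = []
    best = None  # (score, index, z, Omega, params) — selection criterion
    anchor = None  # (L, z) — best multi-cluster partition, drives estimation
    n_restarts = 0
    for t in range(n_alternations):
        sub_seed = int(rng.integers(2**31 - 1))
        if warm_start or t == 0:
            z_start = z_prev
        elif t % 2 == 0 and anchor is not None:
            z_start = anchor[1]  # polish the estimation anchor
        else:
            k_init = scales[n_restarts % len(scales)]
            n_restarts += 1
            z_start = None if k_init is None else rng.integers(0, k_init, size=H.n)
        use_params = params if params is not None else strict_modularity_params(H)
        if (optimizer == "aon" and z_start is not None and t % 2 == 1
                and n_restarts % 2 == 0 and len(use_params.beta) > 1):
            # single-size probe: zero out every other size's contribution
            probe = sorted(use_params.beta)[(n_restarts // 2) % len(use_params.beta)]
            strict = strict_modularity_params(H)
            use_params = AONParameters(
                beta={k: (max(abs(use_params.beta[k]), strict.beta[k])
                          if k == probe else 0.0)
                      for k in use_params.beta},
                gamma=dict(use_params.gamma))
        if optimizer == "aon" or Omega is None:
            z = aon_hmll(H, params=use_params, z0=z_start, regularize=regularize,
                         seed=sub_seed)
        else:
            z = symmetric_hmll(H, Omega, z0=z_start, regularize=regularize,
                               seed=sub_seed)
        Om_t = estimate_omega(H, z, family=family, k_max=k_max, sizes=sizes,
                              smoothing=smoothing)
        ncl = int(z.max()) + 1
        dec = log_likelihood(H, z, Om_t)
        score = dec.L if not regularize else regularized_objective(dec.L, H.n, ncl)
        entry = {"L": dec.L, "Q": dec.Q, "score": score, "n_clusters": ncl}
        if keep_partitions:
            entry["z"] = z.copy()
        trace.append(entry)
        pars_t = None
        if family == "aon":
            pars_t = (strict_modularity_params(H) if ncl == 1
                      else _positive_aon(Om_t, volH, max(smoothing, 1e-300)))
        if best is None or score > best[0]:
            best = (score, t, z.copy(), Om_t, pars_t)
        # parameters driving subsequent updates come from the most likely
        # partition that actually splits the nodes: a single-cluster
        # partition is uninformative about the affinity, and under the
        # cluster-count penalty it can dominate the selection score while a
        # weakly-correlated split still carries estimable signal worth
        # amplifying over the remaining alternations
        if ncl > 1 and (anchor is None or dec.L > anchor[0]):
            anchor = (dec.L, z.copy())
            Omega = Om_t
            if family == "aon":
                params = pars_t
        z_prev = z

    score, idx, z_best, Omega_best, params_best = best
    return InferenceResult(
        z=relabel(z_best), omega=Omega_best,
        aon=params_best if family == "aon" else None,
        trace=trace, best_index=idx, best_ll=trace[idx]["L"], seed=seed,
        settings={"family": family, "n_alternations": n_alternations,
                  "regularize": regularize, "warm_start": warm_start,
                  "k_max": k_max, "smoothing": smoothing},
    )


def refine(H: Hypergraph, z_init: Sequence[int], family: str = "aon",
           n_alternations: int = 20, **kwargs) -> InferenceResult:
    """Coordinate ascent warm-started at ``z_init`` (e.g. a dyadic baseline
    partition); the fitted objective can only improve on the initializer."""
    return coordinate_ascent(H, family=family, n_alternations=n_alternations,
                             z0=z_init, **kwargs)
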