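"""Symmetric affinity functions and closed-form conditional ML estimation.

A symmetric affinity function maps the cluster-label composition of a node
tuple — summarized by its partition vector ``p`` (sorted label
multiplicities) — to a non-negative Poisson rate factor.  Four standard
families are supported:

* **AON** (all-or-nothing): distinguishes only whether the tuple lies
  entirely inside one cluster (``len(p) == 1``).
* **GN** (group number): depends on the number of distinct clusters in the
  tuple.
* **RP** (relative plurality): distinguishes whether the gap between the two
  largest groups in the tuple is below ``k/4``.
* **Pairwise**: distinguishes whether the number of ordered cross-cluster
  node pairs in the tuple is below ``k(k-1)/4``.

Arbitrary per-pattern tables are supported as the ``table`` family.

Given a label vector ``z``, the degree parameters and the per-class affinity
values have closed-form conditional maximum-likelihood estimates:
``theta_hat = d`` (the degree vector), and for each class the ratio of the
observed weighted edge count to the class's generalized volume.  These
estimates are exact when all clusters have equal volumes and are otherwise
the standard approximation used by modularity-type objectives.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._comb import partition_vector, partitions_of, power_sums, vol_p_from_power_sums
from .hypergraph import Hypergraph

__all__ = [
    "partition_vector",
    "AffinityFunction",
    "AONParameters",
    "affinity_class",
    "enumerate_classes",
    "estimate_theta",
    "estimate_omega",
    "aon_params",
    "strict_modularity_params",
    "count_parameters",
]

FAMILIES = ("aon", "gn", "rp", "pairwise", "table")


def affinity_class(family: str, p: Sequence[int], k_max: int | None = None):
    """Equivalence class of partition vector ``p`` under an affinity family.

    Classes are hashable ids; the affinity is constant on each class.  For
    the two-value families the second component is 1 for the ``omega_k1``
    branch and 0 for ``omega_k0``.
    """
    p = tuple(sorted(p, reverse=True))
    if not p or any(x < 1 for x in p):
        raise ValueError(f"invalid partition vector {p}")
    k = sum(p)
    if k_max is not None and k > k_max:
        raise ValueError(f"edge size {k} exceeds maximum size {k_max}")
    family = family.lower()
    if family == "aon":
        return (k, 1 if len(p) == 1 else 0)
    if family == "gn":
        return (k, len(p))
    if family == "rp":
        p2 = p[1] if len(p) > 1 else 0
        return (k, 1 if (p[0] - p2) < k / 4 else 0)
    if family == "pairwise":
        # ordered cross-pairs: sum_{i != j} p_i p_j = k^2 - sum p_i^2
        cross = k * k - sum(x * x for x in p)
        return (k, 1 if cross < k * (k - 1) / 4 else 0)
    if family == "table":
        return p
    raise ValueError(f"unknown affinity family {family!r}")


def enumerate_classes(family: str, k: int, k_max: int | None = None) -> dict:
    """Group the partition vectors of size ``k`` by affinity class."""
    out: dict = {}
    for p in partitions_of(k):
        out.setdefault(affinity_class(family, p, k_max), []).append(p)
    return out


@dataclass
class AffinityFunction:
    """A symmetric affinity: per-class non-negative rates over partition vectors.

    ``omega`` maps class ids (as produced by :func:`affinity_class`) to
    values; ``sizes`` lists the edge sizes on which the affinity (and hence
    the model) is defined.
    """

    family: str
    k_max: int
    omega: dict = field(default_factory=dict)
    sizes: tuple[int, ...] = ()

    def __post_init__(self):
        self.family = self.family.lower()
        if self.family not in FAMILIES:
            raise ValueError(f"unknown affinity family {self.family!r}")
        if not self.sizes:
            self.sizes = tuple(sorted({k for k, *_ in map(self._key_size, self.omega)})) \
                if self.family != "table" else tuple(sorted({sum(p) for p in self.omega}))
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("affinity values must be non-negative")

    @staticmethod
    def _key_size(key):
        return key if isinstance(key, tuple) else (key,)

    def class_of(self, p: Sequence[int]):
        return affinity_class(self.family, p, self.k_max)

    def value(self, p: Sequence[int]) -> float:
        """Omega(p); zero if the class has no entry."""
        return float(self.omega.get(self.class_of(p), 0.0))

    def log_value(self, p: Sequence[int]) -> float:
        v = self.value(p)
        return math.log(v) if v > 0 else -math.inf

    def classes(self, k: int) -> dict:
        """Map class-id -> list of partition vectors of size ``k`` in that class."""
        return enumerate_classes(self.family, k, self.k_max)

    def pattern_table(self, k: int) -> dict[tuple[int, ...], float]:
        """Explicit pattern -> value table for edges of size ``k``."""
        return {p: float(self.omega.get(self.class_of(p), 0.0)) for p in partitions_of(k)}

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "k_max": self.k_max,
            "sizes": list(self.sizes),
            "omega": [[list(k) if isinstance(k, tuple) else k, v]
                      for k, v in self.omega.items()],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AffinityFunction":
        payload = json.loads(text)
        omega = {tuple(k) if isinstance(k, list) else k: v for k, v in payload["omega"]}
        return cls(family=payload["family"], k_max=payload["k_max"],
                   omega=omega, sizes=tuple(payload["sizes"]))


@dataclass
class AONParameters:
    """Derived all-or-nothing objective parameters per edge size.

    ``beta[k] = log(omega_k1) - log(omega_k0)`` weights the size-k cut and
    ``gamma[k] = (omega_k1 - omega_k0) / beta[k]`` is the size-k resolution.
    """

    beta: dict[int, float]
    gamma: dict[int, float]
    omega: AffinityFunction | None = None

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.beta))


def estimate_theta(H: Hypergraph) -> np.ndarray:
    """Conditional ML degree parameters under the volume normalization.

    With cluster volumes used as the identifiability constraint the estimate
    is exactly the degree vector, independent of the label vector.
    """
    return H.degrees()


def estimate_omega(
    H: Hypergraph,
    labels: Sequence[int],
    family: str = "aon",
    k_max: int | None = None,
    sizes: Sequence[int] | None = None,
    smoothing: float = 1e-10,
) -> AffinityFunction:
    """Closed-form conditional ML estimate of a symmetric affinity function.

    For each class ``Y`` of partition vectors, ``omega_hat = (weighted count
    of observed edges whose profile lies in Y) / (sum over Y of generalized
    volumes)``.  A pseudocount ``smoothing`` is added to numerators of
    classes with positive volume so that log-affinities stay finite;
    pass ``smoothing=0`` to disable.

    ``sizes`` fixes the edge sizes the affinity covers (default: all sizes
    from 2, or the smallest observed size, up to ``k_max``).
    """
    z = np.asarray(labels, dtype=int)
    if len(z) != H.n:
        raise ValueError("one label per node required")
    if k_max is None:
        k_max = max(H.k_max, 2)
    if sizes is None:
        lo = min([min(H.m_k, default=2), 2])
        sizes = tuple(range(lo, k_max + 1))
    sizes = tuple(sorted(sizes))

    d = H.degrees()
    ncl = int(z.max()) + 1 if len(z) else 0
    vol = np.bincount(z, weights=d, minlength=ncl)
    S = power_sums(vol, k_max)

    # observed weighted edge count per pattern
    cut: dict[tuple[int, ...], float] = {}
    for nodes, w in H.edges.items():
        p = partition_vector(z[list(nodes)])
        cut[p] = cut.get(p, 0.0) + w

    omega: dict = {}
    for k in sizes:
        for cls, patterns in enumerate_classes(family, k, k_max).items():
            num = sum(cut.get(p, 0.0) for p in patterns)
            den = sum(vol_p_from_power_sums(p, S) for p in patterns)
            if den > 0:
                omega[cls] = (num + smoothing) / den
            else:
                omega[cls] = 0.0
    return AffinityFunction(family=family, k_max=k_max, omega=omega, sizes=sizes)


def aon_params(omega: AffinityFunction | Mapping) -> AONParameters:
    """Convert per-size (omega_k0, omega_k1) all-or-nothing values to (beta, gamma).

    Accepts an AON :class:`AffinityFunction` or a mapping ``{k: (omega_k0,
    omega_k1)}``.  When ``omega_k1 == omega_k0`` the cut weight ``beta_k``
    vanishes; ``gamma_k`` is then reported as the continuity limit (the
    common value) with a warning, and the size contributes nothing to the
    objective.
    """
    if isinstance(omega, AffinityFunction):
        if omega.family != "aon":
            raise ValueError("aon_params requires an AON affinity")
        pairs = {}
        for (k, branch), v in omega.omega.items():
            pairs.setdefault(k, [None, None])[branch] = v
        aff = omega
    else:
        pairs = {k: [v[0], v[1]] for k, v in omega.items()}
        aff = None
    beta: dict[int, float] = {}
    gamma: dict[int, float] = {}
    for k, (w0, w1) in sorted(pairs.items()):
        if w0 is None or w1 is None:
            raise ValueError(f"size {k}: need both omega_k0 and omega_k1")
        if w0 <= 0 or w1 <= 0:
            raise ValueError(f"size {k}: affinity values must be positive (got {w0}, {w1})")
        if w1 == w0:
            warnings.warn(f"size {k}: omega_k1 == omega_k0; beta_k = 0 and "
                          "gamma_k taken as the limiting common value")
            beta[k] = 0.0
            gamma[k] = float(w0)
        else:
            beta[k] = math.log(w1) - math.log(w0)
            gamma[k] = (w1 - w0) / beta[k]
    return AONParameters(beta=beta, gamma=gamma, omega=aff)


def strict_modularity_params(H: Hypergraph, sizes: Sequence[int] | None = None) -> AONParameters:
    """All-or-nothing parameters of the strict hypergraph modularity.

    ``beta_k = 1`` and ``gamma_k = m_k / vol(H)^k``: every size-k cut costs
    one unit and the resolution matches the density of size-k edges.
    """
    volH = H.volume()
    m_k = H.m_k
    if sizes is None:
        sizes = sorted(m_k)
    if volH <= 0:
        raise ValueError("strict modularity parameters need a non-empty hypergraph")
    beta = {k: 1.0 for k in sizes}
    gamma = {k: m_k.get(k, 0) / volH**k for k in sizes}
    return AONParameters(beta=beta, gamma=gamma)


def count_parameters(family: str, k_max: int, n_groups: int | None = None,
                     restrict_groups: bool = True) -> int:
    """Number of free affinity parameters used in BIC comparisons.

    AON, RP and Pairwise have two values per size, ``2 * k_max`` in total.
    GN has one value per (size, number of groups) pair; with the default
    restriction the group count for size ``k`` is capped at the number of
    distinct labels ``n_groups`` in the clustering at hand, giving
    ``sum_{k=2..k_max} min(k, n_groups)``.  Pass ``restrict_groups=False``
    to drop the cap (``k`` parameters per size).
    """
    family = family.lower()
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if family in ("aon", "rp", "pairwise"):
        return 2 * k_max
    if family == "gn":
        if restrict_groups:
            if n_groups is None:
                raise ValueError("GN parameter count needs the number of groups")
            return sum(min(k, n_groups) for k in range(2, k_max + 1))
        return sum(range(2, k_max + 1))
    raise ValueError(f"unknown affinity family {family!r}")
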