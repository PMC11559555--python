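"""Combinatorics shared by the affinity and objective modules.

The central primitive is the generalized volume of a partition vector
``p = (p_1, ..., p_t)`` with respect to per-cluster volumes ``v``:

    vol_p = sum over ordered label tuples y with profile p of prod_j v[y_j]

Direct enumeration costs ``l^k`` for ``l`` clusters and tuples of size ``k``.
Instead we evaluate it from the power sums ``S_q = sum_l v_l^q`` via an
inclusion-exclusion recursion over injective assignments of the parts of
``p`` to distinct clusters, which costs a function of the number of parts
only — independent of both ``n`` and ``l``.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np

__all__ = ["partitions_of", "partition_vector", "power_sums", "injective_power_sum",
           "vol_p_from_power_sums", "multinomial"]


@lru_cache(maxsize=None)
def partitions_of(k: int) -> tuple[tuple[int, ...], ...]:
    """All integer partitions of ``k`` as non-increasing tuples."""
    if k == 0:
        return ((),)
    out: list[tuple[int, ...]] = []

    def rec(remaining: int, cap: int, prefix: tuple[int, ...]):
        if remaining == 0:
            out.append(prefix)
            return
        for part in range(min(cap, remaining), 0, -1):
            rec(remaining - part, part, prefix + (part,))

    rec(k, k, ())
    return tuple(out)


def partition_vector(labels) -> tuple[int, ...]:
    """Profile of a label tuple: non-increasing multiplicities of its labels."""
    labels = tuple(labels)
    if not labels:
        raise ValueError("empty label sequence has no partition vector")
    counts: dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return tuple(sorted(counts.values(), reverse=True))


def power_sums(vol: np.ndarray, k_max: int) -> np.ndarray:
    """``S[q] = sum_l vol_l**q`` for q = 0 .. k_max (S[0] = number of clusters)."""
    vol = np.asarray(vol, dtype=float)
    return np.array([np.sum(vol**q) for q in range(k_max + 1)])


def injective_power_sum(p: tuple[int, ...], S) -> float:
    """Sum over ordered tuples of *distinct* clusters (c_1..c_t) of prod_j vol_{c_j}^{p_j}.

    Inclusion-exclusion: fix the cluster receiving part p_1; it either is free
    (factor S[p_1]) minus the terms where it collides with one of the other
    parts (merge exponents).
    """
    return _inj(tuple(sorted(p, reverse=True)), S)


def _inj(p: tuple[int, ...], S) -> float:
    # recursion over at most len(p)! terms; len(p) <= edge size, so this is cheap
    if not p:
        return 1.0
    head, rest = p[0], list(p[1:])
    total = S[head] * _inj(tuple(rest), S)
    for j in range(len(rest)):
        merged = rest[:j] + [rest[j] + head] + rest[j + 1:]
        total -= _inj(tuple(merged), S)
    return total


def multinomial(p: tuple[int, ...]) -> int:
    """k! / (p_1! ... p_t!) for k = sum(p)."""
    num = factorial(sum(p))
    for part in p:
        num //= factorial(part)
    return num


def _part_multiplicity_factor(p: tuple[int, ...]) -> int:
    mult: dict[int, int] = {}
    for part in p:
        mult[part] = mult.get(part, 0) + 1
    out = 1
    for c in mult.values():
        out *= factorial(c)
    return out


def vol_p_from_power_sums(p: tuple[int, ...], S) -> float:
    """Generalized volume of profile ``p`` from cluster-volume power sums ``S``.

    Equals the brute-force sum over all ``l^k`` ordered label tuples whose
    profile is ``p`` of the product of cluster volumes.
    """
    p = tuple(sorted(p, reverse=True))
    return multinomial(p) * injective_power_sum(p, S) / _part_multiplicity_factor(p)
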