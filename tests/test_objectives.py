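import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from hypermodularity import (AffinityFunction, Hypergraph, aon_modularity,
                             aon_params, cut_k, cut_p, estimate_omega,
                             log_likelihood, symmetric_modularity, vol_p,
                             vol_p_update)
from hypermodularity._comb import partition_vector, partitions_of
from hypermodularity.hypergraph import relabel

from conftest import random_hypergraph, set_partitions


def brute_vol_p(vols, p):
    total = 0.0
    k = sum(p)
    for y in itertools.product(range(len(vols)), repeat=k):
        if partition_vector(y) == tuple(sorted(p, reverse=True)):
            total += math.prod(vols[c] for c in y)
    return total


def brute_log_likelihood(H, z, Om, theta):
    """Direct sum of Poisson log-probabilities over every unordered tuple
    (with repeated nodes) of the supported sizes."""
    L = 0.0
    for k in Om.sizes:
        for R in itertools.combinations_with_replacement(range(H.n), k):
            mult = {}
            for i in R:
                mult[i] = mult.get(i, 0) + 1
            b_R = math.factorial(k)
            for m in mult.values():
                b_R //= math.factorial(m)
            rate = b_R * math.prod(theta[i] for i in R) \
                * Om.value(partition_vector([z[i] for i in R]))
            a_R = H.edges.get(tuple(sorted(R)), 0) if len(mult) == k else 0
            if rate == 0:
                L += 0.0 if a_R == 0 else -math.inf
            else:
                L += a_R * math.log(rate) - rate - float(gammaln(a_R + 1))
    return L


class TestGeneralizedVolumes:
    def test_worked_values(self):
        assert vol_p([7, 1], (3,)) == pytest.approx(344)
        assert vol_p([7, 1], (2, 1)) == pytest.approx(168)
        assert 344 + 168 == 8**3

    def test_matches_brute_force_exhaustively(self):
        """Fast power-sum evaluation equals l^k enumeration for all profiles
        with k <= 5 and up to 5 clusters."""
        rng = np.random.default_rng(0)
        for n_cl in range(1, 6):
            vols = rng.uniform(0.5, 10, size=n_cl)
            for k in range(1, 6):
                for p in partitions_of(k):
                    # abs tolerance covers cancellation residue on exact zeros
                    assert vol_p(vols, p) == pytest.approx(
                        brute_vol_p(vols, p), rel=1e-9, abs=1e-6)

    def test_conservation_sum_over_profiles(self):
        rng = np.random.default_rng(1)
        vols = rng.uniform(0, 5, size=4)
        for k in range(1, 6):
            total = sum(vol_p(vols, p) for p in partitions_of(k))
            assert total == pytest.approx(vols.sum() ** k)

    def test_update_equals_recomputation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            vols = rng.uniform(1, 10, size=4)
            a, b = rng.choice(4, size=2, replace=False)
            d = float(rng.uniform(0, vols[a]))
            for k in range(2, 5):
                for p in partitions_of(k):
                    moved = vols.copy()
                    moved[a] -= d
                    moved[b] += d
                    assert vol_p_update(vols, p, d, a, b) == pytest.approx(
                        vol_p(moved, p), rel=1e-9, abs=1e-9)

    def test_zero_degree_move_is_noop(self):
        vols = [7.0, 1.0]
        assert vol_p_update(vols, (2,), 0.0, 0, 1) == pytest.approx(vol_p(vols, (2,)))

    def test_power_sum_worked_update(self):
        # moving one unit of volume from cluster 0 to 1: 6^2 + 2^2 = 40
        assert vol_p_update([7.0, 1.0], (2,), 1.0, 0, 1) == pytest.approx(40)


class TestCuts:
    def test_toy_pattern_cuts(self, toy):
        z = [0, 0, 0, 1]
        assert cut_p(toy, z, (2, 1)) == 1  # edge {2,3,4}
        assert cut_p(toy, z, (3,)) == 1    # edge {1,2,3}
        assert cut_p(toy, z, (2,)) == 1    # edge {1,2}

    def test_cut_patterns_sum_to_edge_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            H = random_hypergraph(rng)
            z = relabel(rng.integers(0, 3, size=H.n))
            for k, m_k in H.m_k.items():
                total = sum(cut_p(H, z, p) for p in partitions_of(k))
                assert total == m_k

    def test_cut_k_counts_split_edges(self, toy):
        z = [0, 0, 0, 1]
        assert cut_k(toy, z, 2) == 0
        assert cut_k(toy, z, 3) == 1
        assert cut_k(toy, [0, 0, 0, 0], 3) == 0
        assert cut_k(toy, [0, 1, 2, 3], 3) == 2


class TestLikelihoodDecomposition:
    def test_single_edge_brute_force(self):
        H = Hypergraph(2)
        H.add_edge((0, 1))
        Om = AffinityFunction("aon", 2, {(2, 1): 0.3, (2, 0): 0.1}, sizes=(2,))
        theta = np.array([1.0, 1.0])
        z = np.array([0, 0])
        dec = log_likelihood(H, z, Om, theta=theta)
        assert dec.L == pytest.approx(brute_log_likelihood(H, z, Om, theta), rel=1e-12)

    def test_decomposition_identity_random_instances(self):
        """L from closed-form Q + K + C equals brute-force tuple summation
        on 100 random instances with n <= 6 and edges of size <= 3."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            H = random_hypergraph(rng, n_min=3, n_max=6, k_max=3, m_max=8)
            z = relabel(rng.integers(0, 3, size=H.n))
            theta = rng.uniform(0.2, 2.0, size=H.n)
            family = rng.choice(["aon", "gn", "rp", "pairwise"])
            Om = estimate_omega(H, z, family=family, k_max=3, sizes=(2, 3))
            dec = log_likelihood(H, z, Om, theta=theta)
            brute = brute_log_likelihood(H, z, Om, theta)
            assert dec.L == pytest.approx(brute, rel=1e-9)
            assert dec.L == pytest.approx(dec.Q + dec.K + dec.C, rel=1e-9)

    def test_zero_affinity_on_observed_edge_gives_minus_inf(self, toy):
        Om = AffinityFunction("aon", 3,
                              {(2, 1): 0.5, (2, 0): 0.5, (3, 1): 0.5, (3, 0): 0.0},
                              sizes=(2, 3))
        dec = log_likelihood(toy, [0, 0, 0, 1], Om)
        assert dec.L == -math.inf

    def test_empty_hypergraph_reduces_to_expected_mass(self):
        H = Hypergraph(3)
        Om = AffinityFunction("aon", 2, {(2, 1): 0.2, (2, 0): 0.1}, sizes=(2,))
        theta = np.ones(3)
        dec = log_likelihood(H, [0, 0, 1], Om, theta=theta)
        assert dec.K == 0 and dec.C == 0
        # - sum_p vol_p(theta) Omega(p): within mass (2^2 + 1) * .2, cross 4 * .1
        assert dec.Q == pytest.approx(-(5 * 0.2 + 4 * 0.1))

    def test_negative_theta_rejected(self, toy):
        Om = estimate_omega(toy, [0, 0, 0, 1], "aon")
        with pytest.raises(ValueError):
            log_likelihood(toy, [0, 0, 0, 1], Om, theta=np.array([1, 1, -1, 1.0]))


class TestModularityEquivalences:
    def test_symmetric_modularity_equals_Q(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            H = random_hypergraph(rng)
            z = relabel(rng.integers(0, 3, size=H.n))
            Om = estimate_omega(H, z, family="gn")
            assert symmetric_modularity(H, z, Om) == pytest.approx(
                log_likelihood(H, z, Om).Q, rel=1e-12)

    def test_uniform_affinity_reduces_to_volume_mass(self, toy):
        Om = AffinityFunction("table", 3,
                              {p: 1.0 for k in (2, 3) for p in partitions_of(k)},
                              sizes=(2, 3))
        q = symmetric_modularity(toy, [0, 0, 0, 1], Om)
        volH = toy.volume()
        assert q == pytest.approx(-(volH**2 + volH**3))

    def test_empty_cluster_label_leaves_q_unchanged(self, toy):
        Om = estimate_omega(toy, [0, 0, 0, 1], "aon")
        q1 = symmetric_modularity(toy, np.array([0, 0, 0, 1]), Om)
        # same partition with an unused high label id collapsed away
        q2 = symmetric_modularity(toy, relabel(np.array([0, 0, 0, 5])), Om)
        assert q1 == pytest.approx(q2)

    def test_aon_plugin_value(self, toy):
        beta = {2: 1.0, 3: 1.0}
        gamma = {2: 0.0, 3: 0.0}
        assert aon_modularity(toy, [0, 0, 0, 1], beta=beta, gamma=gamma) == -1.0

    def test_aon_differences_match_symmetric_differences_exhaustively(self):
        """On every partition of a 5-node hypergraph the AON objective and
        the symmetric objective under the matching AON affinity differ by
        the same label-independent constant."""
        rng = np.random.default_rng(7)
        H = random_hypergraph(rng, n_min=5, n_max=5, m_min=4, m_max=10, k_max=3)
        sizes = tuple(sorted(H.m_k))
        omega = {}
        for k in sizes:
            omega[(k, 1)] = float(rng.uniform(0.5, 2.0))
            omega[(k, 0)] = float(rng.uniform(0.01, 0.4))
        Om = AffinityFunction("aon", max(sizes), omega, sizes=sizes)
        pars = aon_params(Om)
        gaps = []
        for z in set_partitions(H.n):
            z = np.asarray(z)
            gaps.append(symmetric_modularity(H, z, Om)
                        - aon_modularity(H, z, params=pars))
        assert max(gaps) - min(gaps) < 1e-8

    def test_k2_restriction_matches_dyadic_modularity_differences(self):
        """With beta_2 = 1 the AON objective difference between partitions
        equals the difference of the dyadic modularity-with-resolution
        objective -(cut + gamma sum vol^2)."""
        rng = np.random.default_rng(8)
        H = random_hypergraph(rng, n_min=5, n_max=6, k_max=2)
        gamma2 = 0.01

        def dyadic(z):
            z = np.asarray(z)
            cut = cut_k(H, z, 2)
            vol = np.bincount(z, weights=H.degrees())
            return -(cut + gamma2 * np.sum(vol**2))

        zs = [np.asarray(z) for z in set_partitions(H.n)]
        ref = [aon_modularity(H, z, beta={2: 1.0}, gamma={2: gamma2}) for z in zs]
        dy = [dyadic(z) for z in zs]
        gaps = np.array(ref) - np.array(dy)
        assert np.ptp(gaps) < 1e-10
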