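"""Partition scoring, affinity-family model comparison, and experiment harnesses.

Partitions are scored against reference labels with the adjusted Rand index
(permutation-model chance correction).  Affinity families are compared with
the Bayesian Information Criterion ``BIC = kappa * log(m) - 2 * L_hat``,
where ``kappa`` counts the free affinity parameters (the ``n`` degree
parameters are identical across families and excluded), ``m`` is the total
weighted hyperedge count — the number of Poisson observations — and
``L_hat`` is the log-likelihood at the closed-form conditional parameter
estimates for the given labels.  Lower BIC indicates a more plausible
affinity family.

The harnesses reproduce the two standard synthetic designs: the
two-community detectability sweep over within-cluster edge fractions, and
the equal-cluster runtime benchmark with ground-truth-estimated parameters.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .affinities import count_parameters, estimate_omega, aon_params
from .dyadic import clique_project, gmll
from .hypergraph import Hypergraph
from .inference import aon_hmll, coordinate_ascent, refine
from .objectives import log_likelihood
from .samplers import TwoBlockConfig, sample_runtime_testbed, sample_two_block

__all__ = [
    "ari",
    "bic",
    "ModelComparisonReport",
    "compare_affinity_families",
    "run_detectability_sweep",
    "run_runtime_benchmark",
]


def ari(z_a, z_b) -> float:
    """Adjusted Rand index between two partitions (1 = identical up to
    relabeling, ~0 = chance agreement)."""
    z_a = np.asarray(z_a)
    z_b = np.asarray(z_b)
    if len(z_a) != len(z_b):
        raise ValueError("partitions must label the same node set")
    return float(adjusted_rand_score(z_a, z_b))


def bic(H: Hypergraph, labels, family: str, k_max: int | None = None,
        sample_size: str = "edges", smoothing: float = 1e-10,
        restrict_groups: bool = True) -> float:
    """BIC of the DCHSBM with the given affinity family at the given labels.

    ``sample_size`` chooses the observation count in the penalty:
    ``"edges"`` (total weighted hyperedge count, the default — edges are the
    Poisson observations) or ``"nodes"``.
    """
    z = np.asarray(labels, dtype=int)
    if k_max is None:
        k_max = max(H.k_max, 2)
    Omega = estimate_omega(H, z, family=family, k_max=k_max, smoothing=smoothing)
    L = log_likelihood(H, z, Omega).L
    n_groups = int(z.max()) + 1
    kappa = count_parameters(family, k_max, n_groups=n_groups,
                             restrict_groups=restrict_groups)
    m = H.m if sample_size == "edges" else H.n
    return kappa * np.log(m) - 2.0 * L


@dataclass
class ModelComparisonReport:
    """Per-family fit summary; ``table`` rows are sorted ascending by BIC."""

    table: pd.DataFrame

    @property
    def best_family(self) -> str:
        return str(self.table.iloc[0]["family"])

    def selected(self, family: str, tol: float = 0.0) -> bool:
        """True when ``family`` attains the minimal BIC (within ``tol``);
        families whose class structures coincide can tie exactly."""
        best = self.table["bic"].min()
        row = self.table[self.table["family"] == family]
        return bool(len(row)) and float(row["bic"].iloc[0]) <= best + tol


def compare_affinity_families(H: Hypergraph, labels,
                              families=("aon", "gn", "rp", "pairwise"),
                              k_max: int | None = None,
                              sample_size: str = "edges",
                              smoothing: float = 1e-10) -> ModelComparisonReport:
    """Fit each affinity family at the given labels and rank by BIC."""
    z = np.asarray(labels, dtype=int)
    if k_max is None:
        k_max = max(H.k_max, 2)
    n_groups = int(z.max()) + 1
    rows = []
    for family in families:
        Omega = estimate_omega(H, z, family=family, k_max=k_max, smoothing=smoothing)
        L = log_likelihood(H, z, Omega).L
        kappa = count_parameters(family, k_max, n_groups=n_groups)
        m = H.m if sample_size == "edges" else H.n
        rows.append({"family": family, "log_likelihood": L, "kappa": kappa,
                     "bic": kappa * np.log(m) - 2.0 * L})
    table = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ModelComparisonReport(table=table)


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------

def _seed_list(seed, n_seeds: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31 - 1, size=n_seeds)]


def run_detectability_sweep(
    p2_grid, p3_grid, n_seeds: int = 20, seed=0,
    methods=("hmll", "gmll"), config: TwoBlockConfig | None = None,
    n_alternations: int = 20, regularize: bool = True,
    normalized_projection: bool = False,
) -> pd.DataFrame:
    """Mean ARI per (p2, p3) cell of the two-community design, per method.

    For every cell, ``n_seeds`` hypergraphs are sampled; each method returns
    the highest-likelihood partition over ``n_alternations`` alternations,
    run with the cluster-count regularizer by default (the convention for
    these detectability experiments).  The dyadic baseline runs on the
    unnormalized clique projection unless ``normalized_projection`` is set.
    Columns: p2, p3, method, mean_ari, threshold_2 (the dyadic signal
    strength implied by the 2-edges).
    """
    base = config or TwoBlockConfig()
    seeds = _seed_list(seed, n_seeds)
    rows = []
    for p2 in p2_grid:
        for p3 in p3_grid:
            cfg = TwoBlockConfig(n=base.n, c2=base.c2, c3=base.c3,
                                 p2=float(p2), p3=float(p3))
            scores = {m: [] for m in methods}
            for s in seeds:
                H, z_true = sample_two_block(cfg, seed=s)
                for method in methods:
                    if method == "hmll":
                        res = coordinate_ascent(
                            H, family="aon", n_alternations=n_alternations,
                            seed=s, regularize=regularize)
                        z_hat = res.z
                    elif method == "gmll":
                        G = clique_project(H, normalized=normalized_projection)
                        z_hat = gmll(G, n_alternations=n_alternations, seed=s,
                                     regularize=regularize).z
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    scores[method].append(ari(z_true, z_hat))
            from .samplers import detectability_threshold
            thr2 = detectability_threshold(cfg.c_in, cfg.c_out) \
                if cfg.c_in + cfg.c_out > 0 else np.nan
            for method in methods:
                rows.append({"p2": float(p2), "p3": float(p3), "method": method,
                             "mean_ari": float(np.mean(scores[method])),
                             "threshold_2": thr2})
    return pd.DataFrame(rows)


def run_runtime_benchmark(
    n_list, n_seeds: int = 5, seed=0, p2: float | None = None,
    p3: float | None = None, p4: float | None = None,
    n_alternations: int = 20, methods=("hmll", "gmll", "refine"),
) -> pd.DataFrame:
    """Runtime/ARI/cluster-count table on the equal-cluster testbed.

    By default each size uses the benchmark regime ``p2 = 3/5,
    p3 = 1/n^3, p4 = 1/n^4`` (large edges almost never within-cluster).
    The all-or-nothing parameters are estimated from the ground-truth
    labels, so the comparison isolates runtime and optimization quality.
    Runtimes are reported, never asserted.
    """
    seeds = _seed_list(seed, n_seeds)
    rows = []
    for n in n_list:
        q2 = 0.6 if p2 is None else p2
        q3 = 1.0 / n**3 if p3 is None else p3
        q4 = 1.0 / n**4 if p4 is None else p4
        for s in seeds:
            H, z_true = sample_runtime_testbed(int(n), q2, q3, q4, seed=s)
            params = aon_params(
                _floor_positive(estimate_omega(H, z_true, family="aon")))
            z_gmll = None
            for method in methods:
                t0 = time.perf_counter()
                if method == "hmll":
                    z_hat = aon_hmll(H, params=params, seed=s)
                elif method == "gmll":
                    G = clique_project(H, normalized=True)
                    z_hat = gmll(G, n_alternations=n_alternations, seed=s).z
                    z_gmll = z_hat
                elif method == "refine":
                    if z_gmll is None:
                        G = clique_project(H, normalized=True)
                        z_gmll = gmll(G, n_alternations=n_alternations, seed=s).z
                    z_hat = refine(H, z_gmll, family="aon",
                                   n_alternations=n_alternations, seed=s).z
                else:
                    raise ValueError(f"unknown method {method!r}")
                elapsed = time.perf_counter() - t0
                rows.append({
                    "n": int(n), "seed": s, "method": method,
                    "runtime_s": elapsed, "ari": ari(z_true, z_hat),
                    "n_clusters": int(np.asarray(z_hat).max()) + 1,
                })
    return pd.DataFrame(rows)


def _floor_positive(Omega, floor: float = 1e-12):
    """Replace non-positive estimated class values so beta/gamma stay finite."""
    from .affinities import AffinityFunction
    omega = {k: (v if v > 0 else floor) for k, v in Omega.omega.items()}
    return AffinityFunction(Omega.family, Omega.k_max, omega, sizes=Omega.sizes)
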