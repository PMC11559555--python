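# hypermodularity

Generative clustering of hypergraphs — networks whose edges connect any
number of nodes at once (protein complexes, multi-way contacts,
co-purchases, committee memberships).  Standard practice flattens such data
to a graph by clique expansion and clusters the graph, destroying exactly
the higher-order structure one cares about.  This package instead fits a
**degree-corrected hypergraph stochastic blockmodel (DCHSBM)**: every node
tuple `R` receives an independent Poisson number of hyperedges with rate

```
b_R · Π_{i∈R} θ_i · Ω(z_R)
```

where `θ_i` are node degree propensities, `z_i` cluster labels, `b_R` the
number of orderings of `R`, and the affinity `Ω` controls how much an edge
"wants" its nodes' labels to look a certain way.  For affinities that are
symmetric in the labels, `Ω` depends only on the **partition vector**
`p = ϕ(z_R)` — the sorted multiplicities of labels in the edge, e.g.
`ϕ(1,1,4,1,2,3,2) = (3,2,1,1)` — and maximum-likelihood estimation of `z`
reduces to maximizing a **hypergraph modularity**

```
Q(z) = Σ_p [ cut_p(z) · log Ω(p) − vol_p(z) · Ω(p) ]
```

with generalized cuts and volumes in place of the familiar dyadic ones.
Under the **all-or-nothing (AON)** affinity (only "edge inside one cluster
or not" matters) this collapses to per-size cut and volume terms with
interpretable weights `β_k` (how much a size-k cut costs) and resolutions
`γ_k`, recovering classical graph modularity at `k = 2`.

The package provides, as library + `hypermod` CLI:

- the `Hypergraph` container with plain-text hyperedge-list / bipartite /
  label-TSV I/O, c-core extraction and edge-size filtering;
- partition vectors, the AON / group-number / relative-plurality / pairwise
  affinity families, and closed-form conditional ML estimation of `θ` and
  `Ω`;
- exact likelihood decomposition, fast generalized-volume evaluation via
  power sums, symmetric and AON modularities;
- two Louvain-style optimizers (a general symmetric engine, and a fast
  supernode-collapsing AON engine) inside an alternating
  partition/parameter maximum-likelihood loop with seeded restarts;
- exact DCHSBM samplers and the standard synthetic benchmarks (equal-cluster
  runtime testbed, two-community detectability design);
- dyadic baselines (normalized/unnormalized clique projection + graph ML
  Louvain) and evaluation tools (ARI, BIC comparison of affinity families,
  sweep/benchmark harnesses).

See `docs/methods.md` for the model, estimators, optimizer design and
limitations.

## Worked example

Two planted communities of 250 nodes; each node averages five 2-edges and
five 3-edges.  The 2-edges are pure noise (`p2 = 0.5`: a coin flip whether
an edge stays within a community) while 95% of 3-edges are within-community
— higher-order structure a dyadic method can only see diluted.

```python
import numpy as np
from hypermodularity import (TwoBlockConfig, sample_two_block, coordinate_ascent,
                             ari, clique_project, gmll)

H, z_true = sample_two_block(TwoBlockConfig(n=500, p2=0.5, p3=0.95), seed=1)
print(f"sampled: n={H.n}, m={H.m} (m_2={H.m_k[2]}, m_3={H.m_k[3]})")

res = coordinate_ascent(H, family="aon", n_alternations=20, seed=1, regularize=True)
print(f"AON HMLL: {res.n_clusters} clusters, best log-likelihood {res.best_ll:.1f}, "
      f"ARI vs truth = {ari(z_true, res.z):.3f}")
print("fitted beta:", {k: round(v, 3) for k, v in res.aon.beta.items()})

G = clique_project(H, normalized=False)
res_g = gmll(G, n_alternations=20, seed=1, regularize=True)
print(f"dyadic GMLL on the clique projection: ARI = {ari(z_true, res_g.z):.3f}")
```

prints

```
sampled: n=500, m=2043 (m_2=1251, m_3=792)
AON HMLL: 2 clusters, best log-likelihood -14728.7, ARI vs truth = 0.984
fitted beta: {2: 0.034, 3: 4.109}
dyadic GMLL on the clique projection: ARI = 0.891
```

The fitted size weights tell the story: `β_2 ≈ 0.03` — the model has
learned that 2-edge cuts carry almost no information — while `β_3 ≈ 4.1`
makes cutting a 3-edge expensive.  The hypergraph method recovers the
planted partition nearly perfectly (ARI 0.984); the dyadic baseline, which
pools both sizes into one weighted graph, does visibly worse (0.891).  The
`−n log ℓ̄` regularizer (`regularize=True`) is the convention for these
detectability experiments, where the true number of clusters is small.

The same from the shell:

```bash
hypermod sample --design two-block --n 500 --p2 0.5 --p3 0.95 --seed 1 -o h.txt
hypermod cluster -i h.txt --weighted --family aon --regularize --seed 1 -o labels.tsv
hypermod compare -i h.txt --weighted --labels h.txt.labels.tsv
```

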