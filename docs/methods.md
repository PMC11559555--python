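# Methods

## Model

`hypermodularity` clusters hypergraphs by approximate maximum-likelihood
inference in a degree-corrected hypergraph stochastic blockmodel (DCHSBM).
Every node `i` carries a cluster label `z_i ∈ {1..ℓ̄}` and a degree
parameter `θ_i ≥ 0`; every unordered node tuple `R` (repeated nodes
allowed) receives an independent Poisson number of hyperedges with rate

    a_R ~ Poisson( b_R · Π_{i∈R} θ_i · Ω(z_R) ),

where `b_R` is the number of distinct orderings of `R` and the affinity
`Ω` is a non-negative function of the tuple's label composition.  We work
throughout with *symmetric* affinities: `Ω` depends on `z_R` only through
the partition vector `p = ϕ(z_R)`, the non-increasing multiplicities of the
labels in the tuple.  Four parametric families are built in — all-or-nothing
(AON; within-cluster vs. not), group number (GN; number of distinct
clusters), relative plurality (RP; gap between the two largest groups,
threshold `k/4`), and pairwise (ordered cross-cluster pair count, threshold
`k(k−1)/4`) — plus arbitrary per-profile tables.

The log-likelihood of a weighted hyperedge set splits as `L = Q + K + C`
where only

    Q(z, Ω) = Σ_p [ cut_p(z) · log Ω(p) − vol_p(z) · Ω(p) ]

depends on the labels: `cut_p` is the weighted count of observed edges with
profile `p` and `vol_p` is the generalized volume, the sum over all ordered
label tuples with profile `p` of the product of cluster volumes
`vol(ℓ) = Σ_i d_i δ(z_i,ℓ)`.  `Q` is the symmetric hypergraph modularity;
maximizing it over `z` is the partition stage of inference.

Identifiability is fixed by constraining `θ` to sum to the cluster volume
within each cluster, under which the conditional maximum-likelihood
estimates are closed-form: `θ̂ = d` (the degree vector, independent of `z`)
and, for each class `Y` on which `Ω` is constant,
`ω̂ = (observed weighted edge count in Y) / (Σ_{p∈Y} vol_p)`.  These
closed forms are exact when all clusters have equal volumes and are
otherwise the standard modularity-style approximation; no correction is
attempted, and results inherit the familiar bias of modularity methods
toward balanced clusters.

Under the AON affinity the objective collapses to

    Q(z) = −Σ_k β_k [ cut_k(z) + γ_k Σ_ℓ vol(ℓ)^k ] + const,

with `β_k = log ω_k1 − log ω_k0` (how much a size-k cut costs) and
`γ_k = (ω_k1 − ω_k0)/β_k` (the size-k resolution).  `β_k = 1`,
`γ_k = m_k / vol(H)^k` reproduces the strict hypergraph modularity
(`strict_modularity_params`).  When `ω_k1 = ω_k0`, `β_k = 0` and `γ_k` is
reported as the common value (the continuity limit); the size then
contributes nothing to the objective and a warning is raised.

## Generalized volumes without enumeration

Direct evaluation of `vol_p` sums `ℓ̄^k` terms.  We instead evaluate it
from the power sums `S_q = Σ_ℓ vol(ℓ)^q` by inclusion–exclusion over
injective assignments of the parts of `p` to distinct clusters:

    vol_p = (k! / Π_j p_j!) · (1 / Π_r μ_r!) · I(p),
    I(p_1,…,p_t) = S_{p_1}·I(p_2,…,p_t) − Σ_{j≥2} I(p_2,…,p_j+p_1,…,p_t),

where `μ_r` are the multiplicities of repeated part values.  The recursion
touches at most `t!` terms (`t ≤ k` parts), independent of `n` and `ℓ̄`,
and a node move changes only two clusters' volumes, hence two entries of
every `S_q` — so move evaluations cost O(#profiles) regardless of problem
size.  The implementation is validated exhaustively against the brute-force
definition for all profiles with `k ≤ 5` over up to 5 clusters.  A caveat:
the expectation term deliberately sums over tuples with repeated nodes
(matching the model's tuple space); this is exactly what makes the power
sums exact even though observed edges never repeat nodes.

## Louvain engines

Two greedy ascent engines optimize `Q` over hard partitions; both accept
only strictly improving moves (absolute guard `1e-12` against float noise),
visit units in a seeded random order, and terminate at a partition no
single-unit move to an *adjacent* cluster (one sharing a hyperedge)
improves.

* **Symmetric engine** — for arbitrary symmetric `Ω`.  Each hyperedge's
  label profile is tracked as a counter and updated incrementally; because
  profiles must be known exactly, clusters from earlier rounds are moved as
  units over the full adjacency data rather than collapsed.
* **AON engine** — only "is the edge within one cluster?" matters, so after
  each round clusters are collapsed into consolidated supernodes, edges
  keyed by their supernode sets and sizes are merged, and fully interior
  edges are dropped.  This path is the scalable one.

Both paths implement the same ascent; given the same seed they produce the
same partition under matching AON parameters (checked exhaustively on small
instances).  Incremental ΔQ equals full objective recomputation to 1e-8 on
randomized move sequences.

An optional flat-prior penalty `−n log ℓ̄` (from a uniform label prior)
discourages extra clusters; it enters every move evaluation through the
`Δℓ̄` of cluster-emptying moves.  It is off by default and switched on in
the synthetic detectability experiments, where the true cluster count is
small.  Note one consequence: with the penalty on, merging an isolated
low-degree cluster into a *non-adjacent* cluster could pay, but such moves
are outside the adjacency move set; local optimality is with respect to the
algorithm's own neighborhood.

## Coordinate ascent and restarts

`coordinate_ascent` alternates (i) a Louvain partition update at the current
parameters with (ii) closed-form re-estimation of `(θ, Ω)`, for
`n_alternations` rounds (default 20), and returns the alternation with the
highest model log-likelihood (penalized when the regularizer is on, since
that is the objective being ascended).  The first alternation, lacking
estimates, uses strict-modularity parameters; a supplied initial partition
also supplies initial estimates.

Plain restarts from singletons are provably blind to higher-order signal:
an AON size-k edge contributes no move gradient until `k−1` of its nodes
are already co-clustered, so when dyadic signal is weak the ascent starts
on a plateau and agglomerates along noise.  Three design choices address
this, and together they constitute the package's restart policy:

1. **Coarse random restarts.**  Odd alternations start from random balanced
   partitions with a small number of clusters (cycling 2, 3, 4, 6, 8,
   interleaved with singleton starts).  In a coarse partition most large
   edges already have `k−1` nodes together, so their signal is visible.
2. **Single-size probes.**  Every other restart masks the objective to one
   edge size (`β` zeroed elsewhere, cycling sizes).  This probes each
   size's signal on its own — crucial when the current estimates mis-weight
   a size (e.g. a disassortative size-2 signal estimated with the wrong
   sign from an earlier assortative local optimum).
3. **Anchored estimation.**  The estimates that drive subsequent updates
   come from the most likely partition *with at least two clusters* seen so
   far, and even alternations re-polish that anchor.  A single-cluster
   partition is uninformative about `Ω` (its cross-cluster volumes vanish),
   and under the cluster-count penalty it can dominate the selection score
   while a weakly correlated split still carries estimable signal; anchoring
   lets that weak correlation be amplified over later alternations.

Warm-starting every alternation from the previous partition is available
(`warm_start=True`, used by `refine` for polishing an external partition)
but is not the default: Louvain moves merge and never split, so coarse
partitions — in particular the single-cluster state the regularizer
favors early — are absorbing under warm starts.

Degenerate estimates are floored: estimated class values that are zero
with positive denominator receive a pseudocount `ε = 1e-10` (disable with
`smoothing=0`); classes with zero denominator (e.g. cross-cluster classes
of a one-cluster partition) would otherwise produce infinite `β`, so
parameter estimation then falls back to strict-modularity values.

## Samplers

* `sample_dchsbm` draws from the exact model, grouped by (size, affinity
  class): a Poisson total at the closed-form class rate, then per edge a
  profile (∝ its generalized θ-volume), an injective assignment of profile
  parts to clusters (enumerated when the permutation space is small,
  rejection-sampled otherwise), and i.i.d. θ-proportional node draws within
  each cluster.  This reproduces the per-tuple Poisson law without ever
  enumerating `n^k` tuples; per-tuple goodness-of-fit is tested.  Realized
  repeated-node tuples are excluded from the returned `Hypergraph` (whose
  edges are node sets) and available via `return_raw=True`.
* `sample_runtime_testbed`: `n/200` equal clusters, exactly `10n` edges of
  sizes uniform on {2,3,4}; a size-k edge lies within one uniformly chosen
  cluster with probability `p_k`, else on k uniform distinct nodes.
* `sample_two_block`: two communities of `n/2`; Poisson(`n·c_k/k`) edges of
  size k (defaults `c_2 = c_3 = 5`, i.e. mean per-node size-k degree 5);
  within-community with probability `p_k`, otherwise uniform over spanning
  k-sets (by rejection).  `detectability_threshold` exposes the two-block
  signal strength `(c_i − c_o)² / (2(c_i + c_o))` whose unit value marks
  the dyadic detectability boundary.

What these generators emulate — planted equal-size communities,
homogeneous degrees, independent edges — is deliberately simpler than real
data (no degree heterogeneity within the testbeds, no overlapping or
hierarchical structure, no size–cluster correlation).  Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the model's own assumptions, not performance on empirical hypergraphs.

## Dyadic baselines

`clique_project` replaces each size-k edge by a weighted k-clique;
normalized weights `w = a_e/(|e|−1)` make every node's weighted dyadic
degree equal its hypergraph degree exactly (tested on random hypergraphs).
`gmll` is graph maximum-likelihood Louvain: the size-2 specialization of
the AON coordinate ascent run on the projection, with real-valued projected
weights flowing through the cut/volume formulas unchanged — a
quasi-likelihood, since projected weights are not Poisson counts — and a
single estimated resolution.  `select="modularity"` instead returns the
alternation maximizing the classical Newman–Girvan modularity.

## Model comparison

`bic(H, z, family) = κ·log m − 2·L̂`, with `L̂` the log-likelihood at the
closed-form estimates for the given labels, `κ` the number of free affinity
parameters (AON/RP/Pairwise: `2k̄`; GN: `Σ_{k=2..k̄} min(k, ℓ̄)`, the
group count capped at the labels present, removable via
`restrict_groups=False`), and `m` the total weighted hyperedge count — the
edges are the Poisson observations (`sample_size="nodes"` is available).
The `n` degree parameters are identical across families and excluded.
A structural fact worth knowing: for edges of size ≤ 8 the Pairwise
thresholds reproduce the AON classes exactly, so the two families tie;
`ModelComparisonReport.selected` treats exact ties as selection.

## Numerical choices and limitations

- Ties among equal-gain move targets: candidates are scanned in ascending
  cluster-label order and only strictly better gains replace the incumbent,
  so the lowest-labeled target wins and staying put beats any tie.
- `0 · log 0 := 0` for profiles with zero affinity and zero observed count;
  an observed edge in a zero-affinity class makes the objective `−∞`.
- Edge weights are positive integers in the data container; the projection
  path uses an internal real-weighted variant.
- Units within a round are never split; a set moved as a unit stays a unit
  until the next round re-forms units from clusters.
- Greedy ascent offers no global-optimality guarantee; on hard instances
  different seeds can land in different local optima, which is why the
  alternation returns the best of many seeded restarts.
- Runtime: the AON path handles the `n = 1000`, `m = 10^4` testbed in
  seconds per run; the symmetric engine is for small-to-moderate instances
  (it re-scans full adjacency every round).  Test and harness problem sizes
  (n = 100–1000, 5–20 seeds) were chosen so the full suite runs on a
  laptop-class single core in minutes.
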