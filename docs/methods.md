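# Methods

## Model

A weighted graph `G = (V, E)` with nonnegative weight matrix `W` is read
as a Markov chain: the transition probability from node `i` to node `j`
is `p_ij = w_ij / deg(i)` with `deg(i) = Σ_k w_ik`.  The information hop
distance `ihd(i, j) = -log2 p_ij` is the self-information, in bits, of
the one-step transition; the information distance `id(i, j)` is the
shortest-path distance under these hop lengths (computed with SciPy's
multi-source Dijkstra on a sparse matrix that preserves genuine
zero-length hops, i.e. deterministic transitions with `p = 1`).

All logarithms are base 2.  The equal-length encoding threshold
`T = log2 |V|` is the cost of naming any node when the graph is assumed
to carry no structure; `idt = min(id, T)` caps every distance there.  A
pair at `idt = T` — including every unreachable pair — is "connected no
better than random" and is never admitted by the extension cutoff
(strict `score < T`; a score exactly at `T` encodes no better than the
null model).

Row normalization makes transitions asymmetric even for undirected
input; `id` is computed on the directed transition structure and never
symmetrized.  Distances are invariant to a global rescaling of the
weights (only weight *ratios* at each node matter), which is exercised
by a property test.

### Extension

For a seed set `S`, one distance bundle with sources = `S` supplies both
the pairwise within-`S` distances and the `S`-to-all distances; paths
may leave `S` freely.  Key points are either

* the **inner boundary** — members of `S` with at least one neighbor
  outside `S` (default; it is the natural frontier for growth and is
  empty only when `S` is a union of whole components, which is reported
  as "no extension possible"); or
* the **center** (radial metric) — members of minimal eccentricity,
  where eccentricity is the maximum *thresholded* distance to the other
  members; ties are all kept.

Each candidate's score is the minimum `idt` from any key point.  Ties in
ranking and in center selection break lexicographically by node label,
so outputs are bit-reproducible.  The two metrics coincide for singleton
seed sets.

### Conductance

`Φ(S) = Cut(S, S̄) / min(Vol(S), Vol(S̄))`, with `Cut` the total weight
crossing the boundary and `Vol` the total outgoing weight of a side.
`Φ` is defined as 0 when the smaller volume is 0 (an edgeless side cuts
nothing).  Low conductance means a well-isolated module and therefore a
trustworthy guilt-by-association extension.

### Baselines

RWR and PPR share one power-iteration engine:
`v ← (1-r)(Pᵀ v + (dangling mass)·e_S) + r·e_S` with teleport vector
`e_S` uniform over the seeds.  Mass on dangling (zero out-degree) nodes
is redistributed to the teleport vector — the standard PageRank
convention — so probability is conserved at every step; under this
convention PPR with damping `d` equals RWR with restart `r = 1 - d`, and
a test pins the power iteration to a dense linear solve.  Defaults:
restart 0.15, L1 tolerance 1e-10, at most 10 000 iterations; the
evaluation harness sweeps restart over {0.15, 0.3, 0.5} so the baselines
are not strawmanned by a single arbitrary setting.

### Evaluation protocol

A known cluster is split into 80% seed / 20% held-out (train size =
`round(0.8·|C|)`, sampled without replacement from a seeded generator),
10 splits by default.  Every method ranks *all* non-seed nodes; NDCG
with binary relevance (`DCG = Σ 1/log2(p+1)` over relevant positions,
normalized by the ideal ranking) scores the held-out recovery.  ID-GBA's
automatic cutoff is deliberately **not** used to truncate the ranking —
that keeps NDCG comparable with methods that lack a cutoff — and is
instead scored separately as precision/recall of the below-threshold set
against the held-out members.  Summaries report per-method mean, sample
SD, and a t-distribution 95% CI (n-1 df; at 10 splits the normal
approximation would be anti-conservative), plus paired t-tests between
methods.

## Graph construction

### Differential co-expression

Expression (genes × samples, case/control labels) is reduced to the top
2000 most-variable genes by default — variance is ranked on the raw
values, since post-z-score variance is 1 for every gene — then each gene
is z-scored across samples (constant genes dropped with a warning).
Precision matrices are estimated for the control samples and for the
pooled case+control samples; the graph weight is
`|sym(Prec_pooled - Prec_control)|` with zero diagonal.  Negative
differential entries would violate the nonnegativity the walker model
requires, so the magnitude is taken after symmetrization: the weight
measures the *change* in conditional dependence, whichever direction.

**Precision estimation.**  With more genes than samples the empirical
covariance is singular, and a plain or weakly ridged inverse amplifies
sampling noise in the null space by `1/λ` — the resulting "graph" is
uniform noise with no module contrast.  The default estimator is
therefore the graphical lasso with a single **shared** penalty for both
fits, `α = sqrt(log p / n_pooled)` (the standard sparsistency rate of
the larger sample).  Sharing one penalty matters: the lasso's shrinkage
bias then cancels in the difference, whereas per-matrix rates leave a
bias mismatch that swamps the differential signal, and the rate of the
smaller sample over-shrinks the pooled fit and erases the module block.
`estimator="ridge"` (add `1e-3·mean(diag)·I` when the condition number
exceeds 1e12, then invert) remains available and is adequate when
samples comfortably outnumber genes.

Spectral clustering (scikit-learn, precomputed affinity, k-means label
assignment, seeded) partitions the graph — `k = 40` by default, matching
the scale of biological pathways (~43 genes on average) so that clusters
stay small enough to interpret — and the cluster of minimum conductance
becomes the starting module.

### Disease/disease graph

From a genes × diseases association-score matrix (scores in [0, 1]),
each disease pair's edge is the Pearson correlation of their score
vectors over the genes where at least one of the pair is nonzero,
clipped below at zero (cosine similarity available behind a flag; the
estimator choice is a genuinely open design point and Pearson over the
union support is the least surprising reading of "correlation over
shared genes").  Only the top 5% of positive edges by weight survive
pruning (`ceil` of the fraction; ties at the boundary all kept).
All-zero diseases are excluded with a warning.

## Synthetic generators

* `planted_cluster_graph` — a planted-partition graph: edge probability
  `p_in = 0.3` inside a 30-node cluster, `p_out = 0.01` elsewhere,
  300 nodes, edge weights U[0.5, 1.5] (uniform rather than unit so row
  normalization is nontrivial and transition asymmetry is exercised),
  no self-loops.  Disconnected samples are repaired by bridging each
  extra component to the growing core with one `weight_low` edge; the
  repair can be disabled so the `idt = T` unreachable path is testable.
* `planted_expression` — controls are i.i.d. standard normal; in case
  samples a 40-gene module (of 500; 100 case + 100 control samples)
  shares a latent factor: `sqrt(ρ)·f + sqrt(1-ρ)·σ·ε` with `ρ = 0.8`,
  giving pairwise case correlation `ρ/(ρ + (1-ρ)σ²)` — exactly `ρ` at
  the default `σ = 1`.

Both are bit-reproducible under a fixed seed.  What they deliberately do
**not** emulate: RNA-seq count distributions (library size, negative
binomial overdispersion — the pipeline consumes z-scores, so Gaussian
fixtures exercise every code path), hub-dominated degree distributions,
overlapping modules, or correlated background structure.  Passing tests
on these fixtures demonstrate algorithmic correctness and end-to-end
recovery of clean planted signal, not performance on real expression
compendia.

### A regime note on the planted-partition graph

The planted graph draws edge weights i.i.d. from the same distribution
inside and outside the cluster, so its only planted signal is edge
*multiplicity*.  A single-shortest-path score is invariant to how many
parallel paths support a candidate, whereas propagation methods
accumulate mass across them; on this generator RWR/PPR therefore reach
near-perfect NDCG (≈ 1.0) while the information-distance ranking
measures ≈ 0.70 — a background node with one lucky heavy edge from a
seed scores in the same band (`-log2(w/deg)` ≈ 2.5–4.5 bits) as a true
member.  When the module instead carries *weight* contrast — as
differential co-expression graphs do, where within-module weights are
systematically heavier — the information-distance ranking is exact
(NDCG 1.0 with within-cluster weights scaled 5×).  The two regimes are
both covered by tests so the trade-off is measured rather than assumed.

## Numerical choices

* Threshold comparisons are strict (`score < T`); capped values equal
  `T` exactly by construction, so no epsilon is needed.
* Transition rows of isolated nodes are all-zero and reported via a
  warning, not an error; their distance rows are `+inf` off-diagonal.
* Shortest paths run on `csgraph_from_dense(·, null_value=inf)` so that
  0-bit hops survive sparsification.
* Spectral clustering and splits take explicit seeds; CLI floats are
  serialized at 6 decimals, making repeated runs byte-identical.
* Problem sizes in tests and the acceptance script (300-node graphs,
  500-gene expression matrices, 10 generator seeds × 10 splits) were
  chosen to exercise every pipeline stage at the scale where the
  planted-signal analyses above are stable.

## Known limitations

* The extension is a single ranking pass; accepted candidates are not
  fed back into `S` for iterative growth.
* `id` is asymmetric; consumers wanting a metric must symmetrize
  externally.
* The dense weight-matrix representation is comfortable to a few
  thousand nodes (the scale of co-expression graphs here); very large
  sparse networks would need a sparse storage path.
* Graphical-lasso precision estimation is the default for the
  differential graph; on very large gene panels it is the pipeline's
  dominant cost.
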