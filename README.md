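# idgba — information-distance guilt-by-association subgraph extension

`idgba` expands a known set of nodes (a *seed set* or *starting module*) in
a weighted network by ranking all other nodes on their **thresholded
information distance** from the set's key points, with a built-in,
data-driven cutoff that says where the extension should stop.  It is aimed
at network biology — extending disease modules in disease/disease
association graphs, or recovering disease genes in gene co-expression
networks — but works on any nonnegatively weighted graph.

## The method

Model information flow with a Markov walker on the row-normalized
adjacency matrix, `p_ij = w_ij / deg(i)`.  The *information hop distance*
between neighbors is the self-information of the one-step transition,

```
ihd(i, j) = -log2 p_ij        [bits]
```

and the *information distance* `id(i, j)` is the minimum total hop
distance over all paths from `i` to `j` — a shortest path in information
space.  Under a null model with no structural connectivity, naming any of
the `|V|` nodes costs exactly `log2 |V|` bits (equal-length encoding), so
distances at or above

```
T = log2 |V|
```

signal connections no better than random.  The *thresholded information
distance* caps everything there: `idt(i, j) = min(id(i, j), T)`.

To extend a seed set `S`, candidates are ranked by their minimum `idt`
from the key points of `S` — either the **inner boundary** (members with a
neighbor outside `S`; the default) or the **center** (members of minimal
eccentricity, the *radial* metric).  Candidates whose score reaches `T`
encode no better than the null model and fall below the automatic cutoff:
no top-*k* parameter is needed.  Subgraph **conductance**
`Φ(S) = Cut(S, S̄) / min(Vol(S), Vol(S̄))` quantifies how well isolated the
seed module is, i.e. how much trust a guilt-by-association extension
deserves.

The package also ships random walk with restart (RWR) and personalized
PageRank (PPR) baselines, an NDCG hold-out evaluation harness, builders
for differential co-expression graphs (case/control precision-matrix
difference + spectral cluster selection) and disease/disease association
graphs (score-vector correlation with top-edge pruning), and synthetic
generators with planted structure.

## Worked example

Generate a 60-node graph with a planted 10-node module, seed the method
with 8 of the 10 members, and ask for an extension:

```sh
idgba synth graph --n-nodes 60 --cluster-size 10 --seed 0 \
    --out G.tsv --truth truth.txt
head -8 truth.txt > S.txt
idgba extend --graph G.tsv --seeds S.txt --out ranked.csv
# ranked 52 candidates; 35 below threshold T=5.906891 bits
head -6 ranked.csv
# rank,node,score_bits,below_threshold
# 1,v08,0.454087,True
# 2,v19,1.138203,True
# 3,v44,1.749526,True
# 4,v50,1.888819,True
# 5,v12,1.955129,True
```

The threshold is `T = log2 60 ≈ 5.907` bits.  The two held-out planted
members are recovered near the top: `v08` at rank 1 (0.45 bits — reachable
from a key point far more cheaply than naming a random node) and `v09` at
rank 6 (2.01 bits).  Everything at `score_bits = T` is connected no better
than chance and sits below the cutoff.  The module itself is well
isolated:

```sh
idgba conductance --graph G.tsv --seeds truth.txt
# phi=0.275820
# cut=8.174514
# vol_s=29.637149
# vol_complement=61.689622
```

Comparing methods over ten 80/20 hold-out splits:

```sh
idgba evaluate --graph G.tsv --cluster truth.txt --splits 10 --seed 0 \
    --methods idgba-boundary,rwr,ppr --out report.csv
# idgba-boundary: mean NDCG 0.646393
# ppr: mean NDCG 0.877733
# rwr: mean NDCG 0.877733
```

NDCG is 1.0 when every held-out member outranks every background node.
On this generator — equal edge-weight distributions inside and outside
the module, so the planted signal is edge *density* only — the
propagation baselines, which accumulate mass over parallel edges, hold an
edge over the single-shortest-path information distance; see
`docs/methods.md` for the analysis of when each regime favors which
method.

As a library:

```python
from idgba import read_graph, read_seed_set, extend

g = read_graph("G.tsv")
seeds = read_seed_set("S.txt", g)
result = extend(g, seeds, metric="boundary")
result.accepted          # candidates admitted by the automatic cutoff
result.to_dataframe()    # full ranking with scores in bits
```

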