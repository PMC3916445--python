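# ncis — network-assisted co-clustering for cancer subtype identification

`ncis` identifies cancer subtypes from a gene expression matrix while using a
directed gene-interaction network to decide *which genes matter*. It is aimed
at computational biologists clustering bulk (or pseudo-bulk) tumor expression
profiles who want network context folded into the clustering itself rather
than bolted on as a post-hoc gene filter.

## Method

Given an expression matrix **X** (d genes × n samples) and a directed network
in which an edge *j → i* means gene *j* regulates gene *i*:

1. **Gene weighting.** Each gene's expression variability is summarized by its
   median absolute deviation, normalized to NMAD ∈ [0, 1], and propagated over
   the network by a modified PageRank in which a regulator inherits weight
   from its targets:

       w = (1 − α) (I − α E D⁻¹)⁻¹ NMAD,        α = 0.85 by default,

   where E is the adjacency matrix (E_ji = 1 iff j regulates i) and D the
   diagonal matrix of regulator counts. A gene scores highly if it varies
   across samples *and* sits upstream of other high-scoring genes. Weights are
   max-normalized to 1.

2. **Weighted co-clustering.** Samples are grouped into c subtypes and genes
   into m co-expression groups by semi-nonnegative matrix tri-factorization,
   minimizing the row-weighted reconstruction error

       J = ‖X − G S Fᵀ‖²_W = Σᵢ wᵢ ‖Xᵢ· − (G S Fᵀ)ᵢ·‖²,

   with nonnegative partition matrices G (d × m), F (n × c) and an
   unconstrained centroid matrix S (m × c). Optimization alternates the
   closed-form S update with multiplicative updates of F and G; the objective
   is non-increasing at every sweep.

3. **Consensus.** Because different random starts reach different local
   minima, the fit is repeated (50 runs by default), same-cluster indicator
   matrices are averaged into consensus matrices, and final sample/gene labels
   come from average-linkage hierarchical clustering of 1 − consensus.
   Cluster numbers (m, c) are chosen where the average cophenetic correlation
   of the consensus matrices starts to decrease.

A simulator (`ncis.simulate`) generates subtype-structured expression on a
known random network — subtype-marker genes propagate their signal along
edges — and injects "noisy" genes by permuting the rows of the
lowest-network-weight genes, for benchmarking exactly this pipeline.

## Worked example

Simulate a desk-scale study (300 genes, 90 samples, 3 subtypes, 30 permuted
low-weight genes), train weights, co-cluster, and score against the known
labels:

```bash
ncis simulate --n-genes 300 --n-samples 90 --subtypes 3 \
     --noisy-genes 30 --seed 7 --out-prefix demo
ncis weights demo.expression.tsv demo.network.tsv --alpha 0.85 --out demo.weights.tsv
ncis cluster demo.expression.tsv demo.network.tsv --m 8 --c 3 --seed 1 --out-prefix demo.run
ncis evaluate demo.run.samples.tsv demo.labels.tsv \
     --expression demo.expression.tsv --weights-file demo.weights.tsv --top-k 5
```

which prints

```
simulated 300 genes x 90 samples (3 subtypes, 30 permuted genes) -> demo.*
wrote weights for 300 genes to demo.weights.tsv (alpha=0.85)
final objective 1617.87 after 336 sweeps (converged=True)
accuracy 1.0000 under mapping 1->3, 2->2, 3->1
top shared genes: g173, g068, g131, g183, g101
```

The final objective is the weighted reconstruction error J of the best single
fit; the accuracy line reports optimal-matching agreement between predicted
and true subtypes (here perfect, with predicted cluster 1 corresponding to
true subtype 3). The "top shared genes" are the genes ranked high by *both*
the per-gene ANOVA p-value across subtypes and the network weight — the
package's candidate subtype-defining genes.

Cluster-number selection over a grid writes the full coefficient table so the
"starts to decrease" suggestion can be overridden:

```bash
ncis select demo.expression.tsv demo.network.tsv --m-grid 8 --c-grid 2:4 \
     --runs 10 --out demo.rho.tsv
```

```
m   c   rho_samples  rho_genes  rho_average
8   2   0.997282     0.842726   0.920004
8   3   0.990193     0.793465   0.891829
8   4   0.977477     0.790826   0.884151
```

(Consensus stability is highest at c = 2 — merging two of the three subtypes
is also very reproducible, a classic conservatism of stability-based
selection; the sample coefficient at the true c = 3 is 0.99, and the table is
there so you can judge.)

The same functionality is available as a library (`ncis.weights`,
`ncis.cocluster.fit`, `ncis.selection.consensus`, ...); see the module
docstrings and `docs/methods.md`.

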