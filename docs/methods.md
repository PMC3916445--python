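# Methods

This note records the model, the numerical choices, and the reasoning behind
the design decisions that were genuinely open. Notation: X is the d × n
expression matrix (genes × samples), E the directed adjacency with E_ji = 1
iff gene j regulates gene i, deg_i the number of regulators of gene i, W =
diag(w) the gene-weight matrix, G (d × m) and F (n × c) the relaxed partition
matrices, S (m × c) the block-centroid matrix.

## Gene weighting

Weights solve the fixed point

    w_j = (1 − α) NMAD_j + α Σ_i E_ji w_i / deg_i ,

with NMAD_i = MAD_i / max(MAD) and MAD the per-gene median absolute deviation
across samples. Expression values are used as-is (no log transform is applied
by the loader; callers working with raw counts should transform first, since
MAD on raw scale is dominated by highly expressed genes). The closed form
w = (1 − α)(I − α E D⁻¹)⁻¹ NMAD is solved by a sparse direct solver; the
fixed-point iteration is kept as an independent cross-check and for very
large networks. Genes without regulators get (D⁻¹)_ii = 0; their column of E
is zero, so the convention changes nothing while keeping the system matrix
well defined. α E D⁻¹ has column sums ≤ α < 1, so the system matrix is
nonsingular and the iteration contracts the 1-norm error by at least α per
sweep (the *max-norm* error need not contract monotonically, which is why the
contraction test is stated in the 1-norm). Resolvent entries are nonnegative
(Neumann series of a nonnegative matrix), so raising any gene's NMAD can only
raise weights — tested as a property. Weights are max-normalized once, after
solving, and the normalized weights are what the co-clustering consumes;
normalization only rescales the objective, and the F/G/S updates are
invariant to a global weight scale (also tested).

Defaults: α = 0.85 (weights lean on network structure), iterative tol 1e-10,
max 1000 sweeps. All MADs equal to zero is an error at the weighting stage:
every gene would be uninformative and the weighted objective degenerate.

## Weighted SNMTF co-clustering

The objective is the row-weighted squared Frobenius error
J = Σ_i w_i ‖X_i· − (G S Fᵀ)_i·‖², minimized under G, F ≥ 0 with rows of G
and F summing to 1 (relaxed partition matrices). One sweep is

    S ← (Gᵀ W G)⁻¹ Gᵀ W X F (Fᵀ F)⁻¹          (exact minimizer given F, G)
    F_ij ← F_ij (A⁺ + F B⁻)_ij / (A⁻ + F B⁺)_ij ,  A = Xᵀ W G S, B = Sᵀ Gᵀ W G S
    G_ij ← G_ij (C⁺ + W G D′⁻)_ij / (C⁻ + W G D′⁺)_ij ,  C = W X F Sᵀ, D′ = S Fᵀ F Sᵀ

with M± the positive/negative parts. On hard 0/1 partitions S is exactly the
w-weighted block mean (tested against a brute-force oracle). Numerical
choices: denominators are floored at 1e-12 so entries at exactly 0 stay 0
(multiplicative updates cannot revive a zero); exact factorizations are fixed
points of both updates; convergence is declared when the relative objective
change per sweep drops below 1e-6 (default), capped at 500 sweeps.

Three design questions were genuinely open; the choices and their reasons:

**Update exponent.** The multiplicative ratio can be applied bare or under a
square root (both share the same fixed points). A 1000-instance fuzz of full
S → F → G sweeps from random row-stochastic starts found zero objective
increases for the bare ratio, so the bare form is used (`UPDATE_EXPONENT =
1.0`); the square-root form remains available as a parameter.

**When to renormalize rows.** Renormalizing F and G rows after *every*
update breaks the non-increasing objective guarantee (observed increases up
to 2% in fuzzing, for either exponent): the rescaling is not a descent step.
Rows are therefore renormalized once, after the final sweep — this restores
the sum-to-one convention of the returned model without touching per-row
argmax, and every recorded objective value comes from an actual descent
sweep.

**Restarts.** Multiplicative-update descent stalls on saddle points where the
factorization collapses in rank (observed on noiseless planted blocks: the
stalled objective sits far above the global minimum). `fit` therefore runs
`n_init` independent random starts (default 10) with seeds derived
deterministically from the caller's seed and returns the lowest-objective
run. Each run's trace is monotone; determinism is bitwise given the seed.

**What a single fit can and cannot identify.** Because the row-sum constraint
is relaxed during iteration, the objective constrains the *subspace* spanned
by the factors much more strongly than the basis within it: distinct sample
partitions can sit within a fraction of a percent of the same objective
value, and on noisy data the argmax labels of the single best run are not
reliable. Two consequences are baked into the package. First, gene-cluster
argmax is mathematically unidentifiable when a gene centroid lies in the
conic hull of the others in sample-centroid space — generic whenever m > c —
so gene groupings should always be read from the consensus, not one run.
Second, final labels (CLI default, and what the benchmark uses) come from the
consensus procedure below rather than a single fit.

## Consensus and model selection

The fit is repeated n_runs times (default 50) from seeds base_seed + r;
each run contributes 0/1 same-cluster connectivity matrices for samples and
genes, averaged into consensus matrices M̄_s (n × n) and M̄_g (d × d).
Consensus runs are single-start (`n_init = 1`): the ensemble supplies the
restarts, and run-to-run variability is exactly the signal being measured.
Final labels cluster the distances 1 − M̄ with average linkage, cut into the
requested number of groups. Stability is scored by the cophenetic correlation
ρ between the condensed distances 1 − M̄ and the dendrogram's ultrametric
distances; a partition-consistent 0/1 consensus yields ρ = 1 exactly (the two
distance vectors coincide, a case returned as exactly 1 rather than through
the correlation routine's round-off). A constant distance vector — every pair
always together or always apart — is scored 1 with a warning.

(m, c) selection evaluates (ρ(M̄_s) + ρ(M̄_g))/2 on a grid and suggests, per
m, the last c before the averaged coefficient first strictly decreases (the
largest c, with a warning, when it never does), then the candidate with the
highest coefficient, ties to smaller c then smaller m. Average linkage
follows the consensus-clustering lineage this procedure comes from; it and
the tie rules are configurable/overridable because stability-based selection
is known to be conservative (merging true clusters also looks stable — the
README example shows c = 2 edging out the true c = 3), so the full table is
always emitted.

## Simulator

The generator produces the conditions the benchmark needs: subtype signal
that flows along a known network, plus genes whose signal has been destroyed.

- **Network:** random directed graph, no self-loops or duplicate edges;
  regulator propensities follow a Pareto(3.5) law so a minority of hubs has
  many targets. Heavier tails (e.g. Pareto 1.5) were rejected: a single hub
  then monopolizes the propagated weight mass and, after max-normalization,
  the effective number of genes with non-negligible weight collapses to a
  handful, which no real curated network exhibits.
- **Expression:** a `driver_fraction` of genes (default 0.3) are subtype
  markers: each is up-regulated by `effect_size` (default 2.0) in one random
  subtype and 0 elsewhere. Markers of the same subtype form co-expressed
  modules, the way signature genes behave in real subtype panels; an earlier
  design with i.i.d. Gaussian per-subtype baselines was rejected because it
  yields a continuum of gene patterns with no module structure, and the
  co-clustering objective then has minima that do not align with the planted
  subtypes (verified by deep convergence) — no optimizer can fix a
  misspecified generator. Every gene's value is its baseline plus
  `propagation` (default 0.5, |γ| < 1 required) times the mean of its
  regulators' values, solved exactly as x = (I − γP)⁻¹b per subtype, plus
  i.i.d. Gaussian noise (sd 0.5 default).
- **Noisy genes:** weights are trained on the network alone (NMAD replaced by
  ones), and the l lowest-weight genes (ties by gene order) have their rows
  independently permuted across samples — marginal distribution preserved,
  subtype signal destroyed (their ANOVA p-values are uniform, tested).
- **Default study scale:** 900 genes (~4 edges/gene), 150 samples in 3
  balanced subtypes, l = 100 (≈ 11% of genes). This is a desk-scale version
  of a large tumor-cohort study (thousands of genes, hundreds of samples,
  noise fractions from ~10% up); the same code expresses the full scale.

What the simulator does *not* emulate: batch effects, library-size or
platform artifacts, correlated noise, partially wrong or undirected network
edges, unbalanced subtype prevalences, or expression-level-dependent
variance. Passing benchmarks here show the pipeline recovers clean planted
structure through its own weighting and factorization machinery — not that it
is robust to the full messiness of cohort data.

## Evaluation

Clustering accuracy maximizes label agreement over one-to-one cluster
matchings, solved exactly on the contingency table (Hungarian assignment;
equal to brute-force enumeration for ≤ 6 clusters, tested); unmatched
clusters contribute nothing when cluster counts differ. Per-gene subtype
discrimination uses one-way fixed-effects ANOVA; infinite F (perfect
separation) reports the smallest positive double, and an everywhere-constant
gene reports p = 1. The "top shared genes" list walks the p-value ranking
(ascending) and the weight ranking (descending) in lockstep prefixes,
collecting genes present in both, stopping at k, ordered by p-value —
ties in either ranking break by gene order.

## Known limitations

- Objective-value ties: near-optimal solutions with different sample
  partitions are a property of the relaxed model; anything downstream of a
  *single* fit's argmax labels inherits that instability. Use the consensus.
- The selection heuristic is conservative toward small c; treat the
  suggestion as a starting point and read the table.
- The weight solver assumes the network fits in memory as a sparse matrix;
  the iterative path exists for larger graphs but both are single-machine.
- ANOVA assumes within-cluster normality and equal variances; with heavy
  tails the p-value *ranking* (all the package uses it for) is still
  serviceable, but the absolute values are not calibrated.
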