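# Methods

## Model and procedure

`prnet` ranks candidate disease genes by combining two observations: genes
whose proteins physically interact are functionally coupled, and genes that
are co-expressed across tumour samples are co-regulated. The pipeline builds
a co-expression-weighted PPI network, isolates its disease-relevant
communities via seed genes, and scores genes by network centrality.

**Edge weighting.** For each PPI edge (A, B) present after merging and
deduplicating the input edge lists (unordered symbol-pair identity;
self-pairs dropped), the weight is the sample correlation of the two genes'
log2(x+1) expression profiles. Pairs without a PPI edge are never scored —
this is what distinguishes the approach from all-pairs co-expression
(WGCNA-style) networks. The correlation can be negative; both downstream
algorithms need non-negative weights, so the walk/PageRank weight is
|corr| while the signed value is preserved in all outputs. Strong negative
co-expression is still treated as functional association. Edges whose
correlation is undefined (a zero-variance endpoint) are dropped rather than
set to zero, keeping the graph free of spurious zero-weight edges. No
correlation-magnitude threshold is applied by default (`min_abs_corr = 0`);
the interaction evidence itself is taken as the confidence filter.

**Expression preprocessing.** Genes with nonzero expression in fewer than
`min_nonzero_fraction` (default 0.5) of samples are removed, then values are
log2(x+1)-transformed. Whether correlation should be computed on raw or
log values is genuinely open for normalized expression input; Pearson on
log-transformed values is the field default and is used here, with Spearman
selectable (`method="spearman"`) for monotone-but-nonlinear coupling.

**Community detection (walktrap).** A t-step random walk from node i ends at
k with probability P^t_ik, where one-step transitions are
w_ij / d(i) with d the weighted degree. The vertex distance is
r_ij = sqrt( Σ_k (P^t_ik − P^t_jk)² / d(k) ), and a community's distribution
is the mean of its members'. Starting from singletons, the *adjacent*
community pair minimizing the mean squared-distance increase
Δσ = (1/n)·(|C1||C2|/(|C1|+|C2|))·r² is merged; distances to a merged
community use the Ward-style Lance–Williams update
((s1+s3)Δσ13 + (s2+s3)Δσ23 − s3·Δσ12)/(s1+s2+s3) when both constituent
distances exist and are recomputed from the averaged distributions
otherwise. Weighted Newman modularity Q = Σ_c (e_c − a_c²) is recorded after
every merge, and the partition returned is the merge prefix maximizing Q
(the initial singleton partition included). Merging only adjacent pairs
guarantees no community ever spans two connected components. Ties in Δσ
break on the smallest community-id pair, so the procedure is deterministic
for a given node insertion order. Isolated nodes, for which the walk is
undefined, are removed and reported (the weighting stage never emits them).

The walk length is t = 4 — the customary walktrap default; the method's
description names no value — exposed as `--walk-steps`. Whether the
correlation weights should drive the community step is likewise unstated
upstream; weighted walks are the default here since the weighted network is
built expressly for the decomposition, and `--unweighted-communities`
restores the unit-weight behaviour.

**Disease-specific network and ranking.** Exactly the communities containing
at least one seed gene are retained; the induced subgraph on their union is
the disease-specific network. PageRank then iterates
PR(i) = (1 − q)/N + q Σ_{j∼i} PR(j)/L(j) from the uniform vector, where each
undirected edge acts as two directed links, L(j) is the link count
(`weighted=True` substitutes w_ij/strength(j)), degree-zero nodes
redistribute uniformly, and iteration stops when the L1 change drops below
`tol` (default 1e-10; q = 0.85, max 1000 iterations — non-convergence is a
fatal error reporting the residual). The printed recurrence is degree-based,
so unweighted is the default. One *global* run over the (possibly
disconnected) union keeps scores comparable across communities — per-run
normalization would make per-community scores incomparable; a
`--per-community` mode exists for comparison. Seed genes are scored and
ranked alongside all others. Final order is by decreasing PR with
lexicographic tie-breaks, making output byte-reproducible. Genes outside the
retained communities receive no score and are absent from the output.
Seed genes act purely as community *filters*; there is deliberately no
personalized-PageRank restart on them, which would be a different method
(network propagation from seeds).

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, with a
known ground truth:

* **Network** — planted partition: `n_genes` (default 300) genes in
  `n_blocks` (6) contiguous near-equal blocks; within-block pairs interact
  with `p_in` (0.3), cross-block with `p_out` (0.02). The first
  `n_disease_blocks` (2) blocks are the disease modules.
* **Expression** — each block gets a latent per-sample factor; gene g in
  block b has log2-scale signal √ρ·factor_b + √(1−ρ)·ε with ρ =
  `rho_within` (0.7) and ε ~ N(0, noise_sd²). Values are emitted as
  2^(5 + 1.5·z) − 1 (clipped at 0), an FPKM-like scale whose log2(x+1)
  transform recovers an affine image of z — so the pipeline's own
  preprocessing is exercised and within-block Pearson correlation of the
  processed values equals ρ by construction at the default noise_sd = 1
  (other values attenuate it to ρ/(ρ + (1−ρ)·noise_sd²)). `n_samples`
  defaults to 100, a typical tumour-cohort size.
* **Seeds** — `cags_per_block` (3) genes drawn uniformly without replacement
  from each disease block.

A master seed derives independent per-stage sub-seeds, so all generators are
bit-reproducible and regenerating one input does not perturb the others.

What the generator does **not** emulate: realistic PPI degree distributions
(hubs, scale-free tails), library-size or batch effects, count noise,
overlapping modules, or expression distributions of any particular tumour
type. Passing benchmarks therefore demonstrates algorithmic correctness and
recovery under the model's assumptions — block-modular interactions with
block-diagonal co-expression — not performance on real cohorts, where symbol
mismatches, hub genes and weak module structure all bite.

## Evaluation

Rankings are scored for recovery of the *non-seed* disease-module genes.
The evaluation universe is every truth gene except the seeds (seeds are the
method's input, not its discoveries, so they count neither as positives nor
as negatives); genes absent from the ranking are placed tied below every
ranked gene, so filtering a gene out is an implicit negative call. AUROC
uses the Wilcoxon rank-sum identity with half-credit for ties (equal to the
fraction of correctly ordered positive–negative pairs); precision@k is taken
over the top k ranked non-seed genes; rank medians are computed on the
combined ordering. Community recovery is the adjusted Rand index between the
detected partition and the planted blocks.

## Numerical choices and degenerate inputs

* Transition matrices are dense (`n × n`); the intended problem sizes
  (hundreds to a few thousand network genes per run) fit comfortably, and
  `P^t` is formed by repeated multiplication.
* Modularity is tracked incrementally from per-community internal-weight and
  strength tallies; tests verify the trace equals direct evaluation at every
  dendrogram prefix to 1e-12.
* PageRank conservation (Σ PR = 1) holds to 1e-9 including disconnected and
  dangling cases; accuracy against a dense solve of (I − qM)p = (1−q)/N·1 is
  better than 1e-8 at the default tolerance.
* Duplicate expression rows are fatal rather than averaged — silent
  aggregation could change correlations.
* An expression filter that removes every gene, a weighting step that leaves
  zero edges, and a filter step that retains zero communities are all fatal
  errors with actionable messages (the last advises checking the symbol
  namespace, the most common cause).
* Floating-point ties in Δσ resolve by community-id pair; PR ties resolve by
  gene symbol.

## Benchmark problem sizes

The standard conditions used by the test-suite and the acceptance script:
community recovery at n = 200 genes / 4 blocks over 20 seeds; end-to-end
recovery at n = 300 genes / 6 blocks / 2 disease modules / 3 seeds per
module over 20 master seeds; PageRank oracle comparisons on 50 random graphs
of up to 50 nodes; filter exactness on 500 random instances; determinism on
a 60-gene toy configuration.

## Known limitations

* Gene identity is exact string match; real inputs mixing symbol namespaces
  (aliases, Ensembl ids, isoform suffixes) must be harmonized upstream.
* The dendrogram is cut at a single global merge prefix; on graphs where
  different components peak at different prefixes, a per-component cut could
  score slightly higher modularity.
* The dense walk matrix puts a practical ceiling (~10⁴ nodes) on network
  size; genome-scale interactomes would need a sparse t-step representation.
* Communities are disjoint; overlapping or hierarchical module structure is
  out of scope, as are alternative community algorithms.
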