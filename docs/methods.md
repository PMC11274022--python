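# Methods

## Model and procedure

The pipeline operates entirely downstream of differential-expression
testing: its inputs are per-comparison gene statistics tables whose
q-values are assumed to be Benjamini–Hochberg-adjusted p-values from an
upstream fit (DESeq2 or similar). Six comparisons (three doses × two
timepoints) are the default design, but any set of labelled comparisons
works.

**DEG rule.** A gene is differentially expressed when q < α strictly
(default α = 0.05). The boundary q = α is *not* a DEG. Called genes are
partitioned by sign(log2FC); an exactly-zero log2FC goes to an
"unchanged-direction" bucket with a warning rather than being silently
assigned.

**Ego filter.** The interactor set is the seed node's first shell only:
nodes adjacent to the seed via an edge with combined score ≥
`min_score` (default 0.4, the conventional STRING medium-confidence
cutoff; scores are normalised to [0,1] from the raw 0–1000 scale on
load). The seed itself is excluded from its interactor set by default —
the seed's own regulation is a separate question from what its
interactors do — with an `include_seed` flag to override. No
second-shell expansion is attempted. The per-comparison query for all
later stages is DEGs ∩ interactors, with log2 fold changes carried
along.

**Overrepresentation.** For a query of n genes in a universe of N, a
term with K universe genes and overlap k, p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n) — the one-sided Fisher's exact / PANTHER-style
overrepresentation test. The universe defaults to the annotated genes
(every gene with ≥ 1 surviving annotation); a custom gene list can be
supplied instead. Query genes outside the universe are dropped with a
logged count. Terms with fewer than `min_term_size` (default 2)
universe genes are skipped *before* correction, so the BH family
contains exactly the tested terms. Significance is q < α strictly,
mirroring the DEG rule. BH is the step-up
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1; the implementation computes
p·(m/j) so that a vector tied at c adjusts to exactly c.

**Common terms.** For a grouping (all comparisons, or the three doses
at one timepoint) the common set is the intersection of the per-
comparison significant term sets. A single-comparison grouping degrades
to that comparison's significant set with a warning.

**Scores.** For term t and comparison c with query set D(c):
ratio r = |D(c) ∩ genes(t)| / |genes(t)|, and
fc-weighted s = r · Σ_{g ∈ D(c) ∩ genes(t)} |log2FC(g)|.
Term gene counts are taken within the analysis universe, not a full GO
release — the ratio is then interpretable against the same universe the
test used. The score matrix stores per-cell provenance (k and Σ|FC|),
and s = r · Σ|FC| holds exactly, cell by cell, as a float identity.
Fold changes are log2 throughout; a `fc_scale: linear` switch instead
uses sign(l)·2^|l| for users who want fold-change units.

**Clustering and the GLM cut.** Score-matrix rows (terms) are clustered
agglomeratively; distance and linkage are configurable with Euclidean /
complete as defaults (the defaults of the common heatmap tooling; the
method is not otherwise constrained). Agglomeration and tie-breaking
are delegated to scipy's deterministic implementation. The merge
heights h₁ ≤ … ≤ h_m (m = n_leaves − 1) are then modelled by a
generalized linear model with Gaussian family and logarithmic link,
E[h_i] = exp(β₀ + β₁·i), regressed on the 1-based merge index — the
only covariate the height sequence offers. The fit is IRLS with
weights μ², working response η + (y − μ)/μ, initialised from OLS on
log(h + ε) with ε = 10⁻⁸·max(h), step-halving on deviance increase,
and convergence when the relative coefficient change drops below 10⁻⁸
(at most 100 iterations). Scanning merges in ascending order, the cut
index i\* is the first with residual d_i > tol_rel·h_i
(tol_rel = 10⁻⁶; a pure sign test is meaningless at machine precision
on well-fitted data). Performing merges 1..i\*−1 leaves
k = n_leaves − (i\* − 1) clusters; if no residual qualifies, k = 1.
The intuition: heights tracking the fitted exponential reflect
agglomeration within structure, and the first height breaking above the
trend marks where genuinely separate clusters are being forced
together. Matrices with fewer than three rows, or all-zero heights,
skip the GLM and report k = 1. Cluster membership is computed by
cutting the merge sequence (scipy `cut_tree`), which equals replaying
merges 1..i\*−1.

**Term network.** Per comparison, each selected term is a node with
n_degs = |D(c) ∩ genes(t)|, sum_fc = Σ signed log2FC, node size
c·log(n_degs + 1) (the +1 keeps empty terms finite; base and constant
are presentation choices), and a direction label (up if
sum_fc > balance_tol, down if < −balance_tol, else balanced; default
tolerance 0). Two terms are linked iff they share ≥ 1 DEG; the edge
carries the shared count and the gene list. The DEG set per node is the
DEG ∩ interactor set of that comparison, consistent with the ego
filter; a different selection can be passed explicitly. Graphs export
to GraphML (round-trippable), GML and TSV.

## Synthetic studies

The generator emulates the study conditions end to end from one RNG
seed: 2,000 genes; 120 terms with sizes log-uniform in [5, 200],
sampled independently (so terms overlap by chance), grouped under 10
parents plus a root for true-path propagation tests; a seed protein
wired to exactly 400 interactors with scores uniform on the 400–1000
STRING grid (all at or above the 0.4 default threshold, so thresholding
recovers the set exactly) plus 4,000 background edges with scores from
150–1000; and six comparison tables. Gene tables are generated at the
table's semantic level rather than via read counts — the pipeline's
contract starts at the gene table, and count-level simulation is
upstream scope. A gene is a DEG with probability π₀ = 0.10, raised to
min(1, ρ·π₀) = 0.5 (ρ = 5) for genes that belong to a planted term
*and* interact with the seed, so the same truth exercises both the ego
filter and the enrichment stage. DEG q ~ U(0, 0.05), non-DEG
q ~ U(0.05, 1), p = q·U(0,1), DEG log2FC ~ Normal(±1.0, 0.5) with
random sign, non-DEG log2FC ~ Normal(0, 0.1).

Planted terms are drawn from terms with ≥ 20 interactor members
(`min_planted_overlap`): a planted effect reaching only a handful of
interactor genes is not a measurable enrichment condition at these
rates, so eligibility guarantees each planted term a detectable signal
carrier. With these rates the per-comparison detection probability of a
planted term is intrinsically moderate (≈ 0.4–0.6): the query is itself
interactor-enriched, which inflates the null overlap expectation, and
the hypergeometric z-score attainable at ρ·π₀ = 0.5 against a
π₀ = 0.10 background with 20% interactor density plateaus near 3.
Recovery is therefore assessed at study level — a planted term counts
as recovered when it reaches q < 0.05 in at least one of the six
comparisons — which is also how an analyst reads a multi-comparison
study. Measured over 20 seeds this recovery is ≈ 0.8–0.9, and in every
seed the planted terms' median −log q exceeds the non-planted median.

What the generator does *not* emulate: count overdispersion and
library-size effects (q-values are constructed, not estimated),
correlated co-expression within terms, realistic GO term nesting depth,
scale-free interactome topology, or dose–response monotonicity across
comparisons (each comparison draws independently unless per-comparison
fold-change scales are configured). Passing tests therefore demonstrate
the correctness of the pipeline's set logic, statistics and
determinism, not performance on real sequencing data.

## Numerical and design choices

- Hypergeometric tails come from scipy's survival function (log-space
  internally); arguments are validated strictly.
- BH is hand-authored (sort, p·(m/j), suffix-min, cap) so the step-up
  identity is exact and testable bitwise against a definitional oracle.
- Gene identifiers match by exact, case-sensitive string equality; an
  optional two-column alias table bridges protein ids and gene symbols
  at interactome load.
- GAF rows with a NOT qualifier are excluded by default; only aspect P
  is read by default. True-path propagation (annotate ancestors within
  the same namespace) is on by default and idempotent; terms missing
  from the ontology stay unpropagated with a warning.
- Pipeline outputs are split into `results/` (pure functions of config
  and inputs; byte-identical across reruns) and `meta/` (manifest with
  checksums, stage counts and timestamps). Determinism claims and tests
  apply to `results/`.
- Problem sizes in the test suite: structural tests run on scaled-down
  studies (300–500 genes); statistical properties (recovery, null FDR,
  ρ-monotonicity) run at the default 2,000-gene design across seeds.
- The acceptance script reports cluster counts and the term network
  over the union of per-comparison significant terms: at synthetic
  scale the all-comparison intersection is often a single term, too
  small to cluster, while the union (typically 3–15 terms) exercises
  the same code paths on a data-driven selection.

## Known limitations

- The cut rule's covariate (merge index), scan direction and the i\*→k
  mapping are one convention among several the height-modelling idea
  admits; they are isolated in `choose_cluster_count` so alternatives
  can be swapped without touching other stages.
- Only `is_a` is honoured in the ontology; `part_of`/`regulates` edges
  are ignored (logged).
- BH exactness is defined by the p·(m/j) evaluation order; other
  implementations can differ in the last ulp.
- No graph layout or heatmap rendering: exports target Cytoscape/Gephi
  and standard plotting stacks.

## Configuration reference (YAML keys)

`comparisons` (list of `{path, dose, timepoint[, label]}`),
`interactome_path`, `gaf_path`, `obo_path`, `seed_node` (required);
`alias_path`, `min_score` (0.4), `alpha` (0.05), `universe_mode`
(`annotated`|`custom`), `custom_universe_path`, `min_term_size` (2),
`propagate` (true), `fc_scale` (`log2`|`linear`), `distance`
(`euclidean`), `linkage` (`complete`), `tol_rel` (1e-6), `balance_tol`
(0.0), `size_coeff` (1.0), `score_scale` (`raw_0_1000`|`unit`),
`rng_seed` (0). Unknown keys are rejected with a suggestion.
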