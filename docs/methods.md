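# Methods

## Coexpression table construction

A coexpression dataset is a square Mutual-Rank (MR) matrix.  Starting from
a gene × run matrix of mapped-read counts with a run → experiment mapping:

1. **Run filter** — runs with total mapped count < 10,000,000 are removed
   (shallow libraries give unstable correlations).
2. **Gene filter** — genes whose maximum count across the surviving runs
   is < 100 are removed (consistently silent genes carry rank noise only).
   Filtered genes are absent from all downstream tables; no placeholder
   rows are kept.
3. **Log transform** — `log2(count + 0.125)`.  The pseudocount keeps zeros
   finite (`log2(0.125) = -3`).
4. **Quantile normalization within experiment** — every run column inside
   one experiment is mapped onto the mean-of-sorted-columns reference of
   its group, removing distributional batch differences between runs while
   leaving between-experiment contrasts to the correlation step.  Tie
   handling: reference values are assigned by *stable ordinal rank*, so
   after the step all columns of a group carry exactly the same sorted
   multiset of values even when the input had ties (midrank interpolation
   would only approximate this).  The grouping unit is whatever the
   run-metadata declares; a single-experiment input normalizes all runs
   together.
5. **Centering** — each gene row is mean-centered over all surviving runs.
6. **Correlation** — Pearson correlation between all gene pairs.  An
   optional non-negative per-sample weight vector switches to weighted
   Pearson correlation; the default is unweighted.  Zero-variance genes
   are excluded with a warning.
7. **Mutual Rank** — for each ordered pair, `rank_a(b)` is the midrank of
   *b* among all genes ≠ *a* sorted by descending correlation with *a*;
   `MR(a,b) = sqrt(rank_a(b) · rank_b(a))`.  Midranks make ties
   deterministic and symmetric.  MR lies in `[1, n−1]`, is symmetric, and
   is invariant under any strictly monotone per-gene transformation of the
   correlation scale — the property that makes MR comparable across
   platforms with different correlation calibrations.

## COXSIM and significance

Ranked lists are built per guide gene: all other genes by ascending MR,
ties broken by gene identifier (total order, reproducible).  Before
comparison, genes without a counterpart in the other dataset's gene
universe are dropped from both lists (order preserved).  The statistic is

    COXSIM_gr = Σ_{i=1..k} n(i) / Σ_{i=1..k} i ,

with `n(i)` the number of genes among the top `i` of the guide's list
whose mapped counterpart lies in the top `i` of the reference's list.
Early agreement is thus weighted more heavily than agreement deep in the
lists.  Depth `k` defaults to the top 1% of the (restricted) guide list,
with `k = max(1, ceil(0.01·L))` so the prefix is never empty.  COXSIM is
asymmetric in general (restriction and `k` depend on the guide side);
whole-dataset similarity therefore averages the two directions.

Gene correspondence: identity within a species; across species the
reciprocal-best-hit (RBH) partial bijection derived from pairwise Blastp
bitscore tables.  Reference guide sets use one-directional best hits (one
candidate per other dataset; skipped when the candidate is absent from
that dataset's table).  Same-species sister datasets contribute the
identical gene.

Significance: the null distribution is the set of COXSIM values between
arbitrary (almost surely unrelated) guide × reference pairings of two
datasets.  The full cross product is quadratic, so a seeded uniform
subsample (default cap 10⁶ pairs) is permitted; fewer than 1,000 samples
triggers a warning because tail quantiles become unstable.  The threshold
for level α is the smallest null value whose empirical survival is
≤ α/m, where m is the number of reference lists compared (Bonferroni; m
is a parameter because it depends on the study's dataset count).  A guide
earns one star per level reached (α = 0.1, 0.01, 0.001 by default).  When
α/m falls below the null's resolution the threshold is set just above the
largest null sample, with a warning — nothing can then reach that level,
which is the conservative behavior.  An option to exclude known ortholog
pairs from the null exists but is off by default: with genome-scale gene
counts their contribution to the null is negligible.

## Dataset-quality scores

**GO score** (10⁻⁴ units).  GO biological-process terms annotating 5–20
genes within the table's universe are selected (specific enough to be
informative, large enough to form pairs; no GO-graph propagation is
attempted).  Genes carrying ≥ 1 selected term enter the evaluation; every
unordered pair of them is *positive* iff the two genes share a selected
term.  Pairs are ranked by ascending MR and scored by the unnormalized
partial ROC area for FPR ∈ [0, 0.01] (maximum 0.01), reported × 10⁴, so
perfect separation scores 100 and an exchangeable ranking scores
0.01²/2 × 10⁴ = 0.5 in expectation.  The pair-level reading (rather than
ranking each guide's neighborhood separately) is the design choice here:
it compares the coexpression degrees of sharing vs non-sharing pairs in
one ROC and needs no per-guide aggregation rule.

**Codon score** (10⁻² units).  Codon usage is a 61-dimensional count
vector over the sense codons (stop codons excluded; the longest isoform
per gene is used; trailing partial codons and ambiguous triplets are
skipped with warnings).  Codon vectors → Pearson correlation → MR gives a
codon-similarity table; the score is the median over guides of COXSIM
between the coexpression list and the codon-similarity list (identity
correspondence, same top-1% depth rule as everywhere else), × 100.
Because codon usage needs only the genome, this score applies to species
without annotation resources.

**Reproducibility score** (10⁻¹ units).  For each guide with a non-empty
reference set, maxCOXSIM is normalized by the *reference adequateness*
`bitscore(g→r̂) / bitscore(g→g)` — an alignment-score proxy for the
evolutionary proximity of the chosen reference (1 for the identical gene;
a ratio > 1 is possible in pathological score tables and is flagged).
The score is the median over guides, × 10.  Guides without references are
excluded from the median; `guides=` restricts the median to a subset when
the question is about a particular gene set rather than the whole
platform.

## Orthology

Best hits take the maximal bitscore (ties: lexicographically smallest
subject; self-matches excluded for same-species tables; duplicate records
keep the maximum).  RBH pairs require mutual best hits.  Multi-species
orthologous groups are full RBH *cliques* — one gene per species with
every cross-species pair reciprocal — the strictest and fully
deterministic reading; since best hits are unique, each gene determines
at most one candidate group, which is then validated pairwise.

## Dataset comparison and lineage classification

Dataset similarity = median COXSIM over corresponding guide pairs;
symmetric similarity = mean of both directions; distance = 1 −
similarity; complete-linkage agglomerative clustering with dataset ids
sorted for deterministic tie-breaks; Newick export with heights.

An ortholog pair's coexpression strength across a set of datasets is the
geometric mean of its MR values (MR is ratio-scaled; geometric averaging
matches the sqrt-of-product structure of MR itself).  Classification from
the dicot-clade and monocot-clade averages:

* both < strong → conserved;
* one < strong, other > weak → lineage-specific;
* both > weak → not coexpressed;
* otherwise indeterminate.

Genome-scale defaults are strong = 500 and weak = 5000 at ~2×10⁴ genes,
where the background (unrelated-pair) average MR peaks near half the gene
count.  The weak bound sits below that background bulk with a deliberate
indeterminate gap to avoid overcalling specificity.  For smaller tables
the thresholds scale with gene count (`scaled_lineage_thresholds`: 5% and
15% of n); simulation of the unrelated-pair null shows its geometric
average concentrates near n/e with the 5th percentile near 0.15 n, so
single pairs still misclassify at a few percent — module-level calls
(`classify_module_lineage`, median over the module's pairs) damp this and
are the recommended unit of interpretation.

## Networks and enrichment

Networks start from query genes plus each query's strongest coexpressed
genes (default 20); every node then links to its 3 strongest partners
*within the node set* (deduplicated).  The top-3-edge rule yields a
medium-density network regardless of query size.  Edges can be flagged as
supported when the orthologous pair's MR in another dataset falls below
the strong threshold.

Subnetworks: connected components split by Clauset–Newman–Moore greedy
modularity (components of ≤ 2 nodes stay whole); the algorithm is a
pluggable choice, selected for determinism and testability by exhaustive
modularity enumeration on small graphs.  Enrichment per subnetwork is a
one-sided hypergeometric over-representation test per category, Bonferroni
corrected within each category family (GO terms and heptamers are separate
families with separate divisors).  Promoter categories are the distinct
7-mers of the proximal window [−300, −1] on the coding strand (category
space 4⁷ = 16,384); windows with ambiguous bases are skipped, and reverse
complements are off by default (strand handling is a stated option, not an
assumption).

## Synthetic study design

The default fixture mirrors the four-species, two-clade, two-platform
design at desk scale: 2 clades × 2 species × 2 datasets, 200 genes, 30
runs in 3 experiments per dataset.  Genes 0–49 form ten 5-gene modules
(4 conserved, 3 dicot-specific, 3 monocot-specific); module genes share a
per-run latent factor (loading 2.0 in log2 units, residual SD 0.4, within-
module correlation ≈ 0.95).  Counts are Poisson draws around
depth-scaled log-normal abundances (library depth 15 M; 2 runs per
dataset planted at ×10⁻⁴ depth to exercise the run filter; the last 10
genes planted at negligible abundance to exercise the peak filter).
Orthology is positional (gene i ↔ gene i) with reciprocal top bitscores,
decoy hits, and an optional reciprocity-breaking noise fraction.  CDS
carry per-module codon bias for the first half of the modules (so codon
similarity mirrors part of the module structure); promoters are uniform
random with the heptamer CACGTGT planted at [−150, −144] in the genes of
module M0.  GO terms cover each module (sizes within the 5–20 window)
plus one size-4 and one size-21 term straddling the selection window and
random background terms.

What the fixture does *not* emulate: read-level sequencing artifacts,
negative-binomial overdispersion beyond the latent factor, paralogy and
gene-family structure, GO-term hierarchy, real codon-usage phylogeny, and
genome-scale gene counts (k is 2 rather than ~200, making COXSIM values
coarse).  Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure at desk scale, not
biological performance on real compendia.

## Numerical and degenerate-input conventions

Ranked-list ties break by gene id; best-hit ties lexicographically;
maxCOXSIM ties by (dataset id, gene).  Empty restricted lists make COXSIM
0 at the comparison level and "unassessable" at the guide level (rendered
blank, never imputed).  Guides without references are excluded from
medians.  All generators and subsampling take explicit seeds;
`numpy.random.default_rng` sequences derive from (seed, stream-offset)
pairs so adding a generator never shifts another's draws.

## Known limitations

* The weighted-PCC sample weighting used by some upstream resources is
  accepted as a user-supplied vector but no weighting scheme is derived
  here; the default is unweighted.
* The GO score needs both positive and negative pairs among annotated
  genes and errors otherwise rather than guessing.
* The published significance thresholds (0.081/0.189/0.377) depend on
  genome-scale null distributions; desk-scale nulls are coarser and the
  package recomputes thresholds from whatever null it is given rather
  than shipping those constants as defaults.
* Ortholog groups require full RBH cliques; hub-and-spoke families are
  deliberately excluded.
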