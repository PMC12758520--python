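# Methods

## The calling model

The package operates on the output schema of an upstream differential-
expression tool (DESeq2-style): per gene, a log2 fold change (LFC), raw and
BH-adjusted p-values, and optionally a Wald-type rank statistic and a base
mean. The DE test itself — dispersion fitting, shrinkage, batch correction —
is deliberately upstream; the contract is the results table.

Each gene's significance score is

SS = log2(FC) · (−log10 p_adj),

a π-value-style composite: symmetric in direction, zero when either the
effect or the evidence vanishes, and dominated by genes strong on both
axes. Adjusted p-values of exactly 0 are floored at a configurable epsilon
(default 1e-320, the smallest normal double's magnitude regime) before the
log so scores stay finite and the ranking is preserved.

Calling proceeds in two tiers. First an admission filter keeps genes with
p_adj < α (default 0.05, strict inequality). Then each SS sign side's |SS|
values are clustered into two clusters, and the side's threshold is the
smallest |SS| of the high-|SS| cluster. The model assumption is that the
admitted |SS| values are a bimodal mixture — a bulk of marginal genes and a
well-separated cluster of strongly changed ones — so the two-means boundary
lands in the valley between them. When the data are not bimodal the
procedure still returns the WCSS-optimal split, but the threshold then
falls inside the dominant component and the calls should be interpreted
with care. Boundary genes (SS equal to a threshold) are called: thresholds
are cluster minima, so the threshold gene is by definition in the extreme
cluster.

### Exact 1-D two-means

For k = 2 in one dimension the optimal partition is always an interval
split of the sorted values, so the clusterer scans all n − 1 splits with
prefix sums (O(n log n) total) and returns the global optimum. This removes
the initialization nondeterminism of iterative k-means; Lloyd's algorithm
(scikit-learn, seeded) is kept as an option for parity with interactive
statistics packages, and on well-separated mixtures the two agree. Ties in
WCSS resolve to the first optimal split in sorted order.

## Count preprocessing

Two standard steps are provided for raw count matrices. The low-count
filter drops genes whose row mean is strictly below a threshold (default
10 counts). Median-of-ratios normalization estimates sample size factors as
the median, over genes with strictly positive counts in every sample, of
the count-to-geometric-mean ratio. Size factors are reported rescaled to
geometric mean 1: the between-sample ratios — the quantity the estimator
actually determines — are unchanged, and the rescaling makes the operation
idempotent (renormalizing an already normalized matrix yields unit
factors). Genes with a zero count anywhere are excluded from the reference
set but normalized like all others; a matrix with no all-positive gene is
rejected with a specific error.

## Enrichment

ORA restricts everything to an explicit background first: query genes
outside it are dropped (logged), set members outside it do not count toward
the set size K. The p-value is the hypergeometric upper tail P(X ≥ k) for
overlap k, set size K, query size n, universe N; the one-sided Fisher exact
test on the same 2×2 table is numerically identical and available for
preference. Both BH-FDR and Bonferroni columns are always reported. Fold
enrichment is the ratio statistic (k/n)/(K/N); the true 2×2 odds ratio is
reported alongside since "enrichment ratio" is used both ways in the
literature. The ranking composite is ESS = fold_enrichment · (−log10 FDR),
with FDR = 0 floored at the same epsilon as above (warning emitted).
An ESS > 10 report filter is a presentation default for "top pathways",
not a test.

Weighted set cover reduces redundancy among significant sets (FDR below a
cutoff, default 0.05): greedily pick the set maximizing
(newly covered query genes) × (−log10 FDR), break ties by smaller FDR then
lexicographic name, stop when all query genes appearing in any candidate
are covered (or after top_k picks). Greedy set cover is within a
logarithmic factor of optimal; on the small instances tested exhaustively
it is within one set of the minimum.

Pre-ranked GSEA takes the caller-supplied row order as the ranking (rank by
a Wald-type statistic, descending, before the call). The enrichment score
is the signed extremum of the weighted Kolmogorov–Smirnov running sum with
hit increments proportional to |stat|^w (default w = 1); ties between the
positive and negative extremum resolve positive. The null permutes gene
labels — each permutation re-draws the set's positions uniformly — because
the input is a pre-ranked list and sample-level phenotype permutation is
not available at this interface. NES is ES divided by the mean |ES| of
same-sign permutations; the permutation p-value uses the add-one convention
(r + 1)/(m + 1) within the sign stratum (never exactly zero, uniform on a
grid under the null); FDR is the sign-stratified NES q-value, which reduces
to the p-value when a single set is tested. Sets smaller than min_size
(default 5) in the list, or covering the whole list (no miss step), are
skipped with a log entry.

## Null controls and meta-signatures

Matched random lists are uniform without-replacement draws from the
background at the query's size; replicate r is a pure function of
(seed, r). Type matching (e.g. protein-coding only) is achieved by
pre-filtering the background itself, so matching reduces to uniform
sampling. The calibration experiment reruns ORA per replicate and reports
the fraction of (replicate, set) pairs flagged at the FDR cutoff; under a
null collection this sits at or below the nominal level because BH controls
FDR under independence-like conditions, and the discreteness of the
hypergeometric makes it conservative in practice.

Meta-signature construction unions named DEG lists after id normalization
(whitespace trim, optional case folding — gene-symbol conventions differ
across studies): the combined total counts per-list sizes (duplicates
across lists counted), the nonredundant list is the first-seen-order union.
Intersection with a query signature yields the overlap and its proportion
of the union. Proportions are compared with the Pearson chi-square on the
2×2 counts table, continuity correction off by default (classical Pearson;
flag available). Which counts entered the published comparison of this
kind is not recoverable, so the module exposes the pairwise test and
reports per-replicate values.

## Synthetic data

The generators emulate the statistical structure the stages assume, not
any biology. The DE-table mode draws a mixture: a fraction π_up/π_down of
genes up/down-regulated, the rest null. Null genes get LFC ~ N(0, 0.2) and
raw p ~ Uniform(0, 1); regulated genes get |LFC| = 2 + |N(0, 0.25)| with
the status sign and raw p = 10^(−u), u ~ Uniform(8, 10); all p-values are
then BH-adjusted together. The regulated component is deliberately
concentrated: after adjustment the null |SS| stays below ~2 while the
regulated |SS| sits near 16–27, producing the bimodal-with-gap shape the
two-means threshold step is designed for. With 20% regulated genes at
these settings, regulated adjusted p lands at or below ~1e-6. Status
counts are exact (⌊n·π⌋ per stratum, deterministic) by default so planted
truth is sharp; a multinomial mode exists. A Wald-style rank statistic is
synthesized by inverting the two-sided normal tail at the raw p with the
LFC's sign, giving GSEA a realistic ranking.

Count mode draws negative-binomial counts (dispersion 0.1, base means
lognormal(5, 1.5)) for a 16-sample design: two conditions × 8 replicates,
two batches each holding 4 + 4. Regulated genes scale the second
condition's mean by 2^LFC; known size factors multiply every mean; a
multiplicative batch factor exists but is off by default since batch
correction is out of scope. Defaults for depth/dispersion are generic
choices for a cell-line bulk experiment and are documented as such, not
fitted to any particular dataset.

Gene-set mode samples sets uniformly from the background (sizes 20–100 by
default); spiked sets draw regulated genes at spike_factor (default 5)
times the background regulated rate, capped at 1.

What the generators do **not** emulate: correlation between genes,
mean-variance trends in the DE statistics, composition effects, partially
overlapping pathway structure, or any pathway identity. Passing tests
therefore demonstrate the pipeline's statistical correctness under its
stated assumptions, not performance on real tissue data.

## Numerical and format choices

- p_adj/FDR epsilon floor 1e-320, configurable everywhere a log is taken.
- Two-means and set-cover tie-breaks are fixed (first optimal split;
  smaller FDR then name) so reruns are byte-identical.
- Tab-separated outputs use "." decimals, no thousands separators, and
  %.17g float rendering — lossless round-trips, scientific notation below
  1e-4. Missing values are written as NA.
- ORA reports use the pinned column order set_name, k, K, n, N,
  fold_enrichment, pvalue, fdr, bonferroni, ess.
- Gene ids are matched as exact trimmed strings; case folding is an
  explicit opt-in for cross-dataset merges.
- The pipeline manifest (JSON, sorted keys) records inputs, parameters,
  seeds, derived thresholds and per-stage gene counts, so any run is
  auditable and reproducible from the manifest alone.

## Problem sizes in the shipped checks

The test suite and the acceptance script run on synthetic problems sized
for sharp statistics at desk scale: DE tables of 1000–2000 genes,
backgrounds of 2000 genes, 20–50-set collections, 200 random-list
replicates, 200 GSEA permutations, and 20–100 seed repetitions per
experiment. These sizes are the package's own defaults for its validation
suite; all scale linearly if larger runs are wanted.

## Known limitations

- The two-means threshold is only meaningful on genuinely bimodal |SS|
  distributions; no goodness-of-bimodality diagnostic is emitted yet.
- GSEA's gene-label permutation null ignores inter-gene correlation and is
  anti-conservative on correlated real data relative to phenotype
  permutation; with 200–1000 permutations the smallest attainable p is
  bounded by the add-one convention.
- The ORA engine models the common statistical core of the field's
  enrichment tools; proprietary engines differ in set curation and
  weighting, so absolute pathway lists will differ even at identical
  statistics.
- Batch effects are generated but never corrected; the flag exists to
  document robustness limits, not to replace a correction step.
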