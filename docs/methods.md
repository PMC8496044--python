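# Methods

This note documents the models, conventions and numerical choices behind
`ddrimmune`, and what the synthetic-data tests do and do not establish
about real data.

## Per-sample pathway activity

**Centering.** Expression values are assumed log2-scale abundances (e.g.
log2(TPM+1)).  Each gene is median-*subtracted* across samples so that a
sample's value expresses where it sits relative to the cohort.  Median
subtraction (not division) is the default because the data are already in
log space, where a multiplicative effect is additive; a `divide` mode
exists for users who prefer ratio scaling, with genes of median zero left
unscaled and logged.

**Ranking metric.** Each sample's genes are ordered by descending centered
value.  The enrichment statistic needs a signed metric, so the centered
value itself is the default; a `rank` mode replaces it with centered
integer ranks across samples (average ties), which makes the metric purely
ordinal.  Ties in the metric are always broken by ascending gene symbol —
determinism over elegance, everywhere.

**Enrichment score.** The weighted Kolmogorov–Smirnov running sum: hits add
`|score|^w` normalized by the sum over hits, misses subtract `1/(N−k)`; ES
is the running sum's extremum by absolute value (first position in list
order on exact ties).  `w = 1` by default, exposed as a parameter.  If
every hit score is zero (possible with the centered metric when a set's
genes all sit at their cohort median), hit increments fall back to the
uniform `1/k` so the statistic degrades to the classic unweighted KS form
rather than dividing by zero.  A set equal to the whole measured universe
has no misses and is rejected.

Internally, permutation nulls use an O(k log k) evaluation that exploits
the running sum's piecewise linearity (extrema can only occur at a hit or
immediately before one); observed scores use the straightforward O(N)
cumulative sum.  The two agree to floating-point precision, which the test
suite checks against a third, loop-based brute-force implementation.

**Null and calibration.** The null is gene-label permutation: random
same-size subsets of the measured genes, 1000 permutations by default,
cached per (sample, set size).  Sample-permutation nulls are not meaningful
for per-sample scoring, since each score is computed within a single
sample's ranking.  `NES = ES / mean |ES_null|` over *same-sign* null
values; the nominal p is the same-sign tail with add-one smoothing, so
p ≥ 1/(n_perm+1) and never exactly zero.  A cell with no same-sign null
value is reported as undefined (NaN) and excluded downstream — silently
zero-filling would bias the correlation stage.  FDR is Benjamini–Hochberg
per sample across pathways: simpler and better understood than the
NES-pooled FDR of classic GSEA, and adequate because downstream use is the
NES matrix, not per-cell significance calls.

**Reproducibility.** Each sample's permutation stream is seeded by
(root seed, CRC32 of the sample identifier), so cohort scoring is
bit-for-bit reproducible and invariant to sample order.  The pipeline
splits its root seed into per-stage seeds (first 32-bit words of the seed
sequence, masked to 31 bits, fixed stage order), so a stage can be rerun in
isolation.

**Set-size filter.** Sets are intersected with the measured genes and kept
if the intersected size is in [5, 500] — the common GSEA convention.  Gene
symbols are matched case-insensitively and stored upper-case, since symbol
case is inconsistent across pathway databases and literature lists.

**Clustering.** The samples × pathways NES matrix is clustered with
Euclidean distance and average linkage (standard heatmap defaults, both
configurable).  Undefined cells are imputed to 0 for distance computation
only, with a log entry.  SciPy's deterministic merge rules fix tie order.

## Immune features

**Content score.** Mean across-sample z-score (population sd) of the
immune-specific gene list; constant genes are dropped with a warning and
the score has cohort mean ≈ 0.  This z-mean is the simplest score
consistent with "summarize immune-specific gene expression per sample"; it
is invariant to anything that happens to non-immune genes.  The packaged
80-gene list is a curated stand-in spanning T/B/NK/myeloid lineage and
effector markers plus antigen presentation, and is user-replaceable (any
one-symbol-per-line file).

**Deconvolution.** Fractions come from regressing the sample on the
signature columns over their shared genes (at least max(10, 2·k) genes
required).  Both sides are standardized with the *mixture's* mean and sd:
because true fractions sum to one, applying one affine transform to the
mixture and every signature column preserves the mixing identity exactly,
so noiseless mixtures are recovered to machine precision — per-vector
z-scoring would not have this property.  Default solver is NNLS
(deterministic, no tuning); `nu_svr` fits a linear ν-SVR over
ν ∈ {0.25, 0.5, 0.75} and keeps the lowest reconstruction RMSE, mirroring
the common SVR-based deconvolution recipe.  Negative coefficients are
clipped and fractions renormalized to the simplex; an all-zero solution
falls back to uniform fractions with a warning.  No empirical significance
test is attached to the fractions — they are used descriptively.  The
packaged default signature is synthetic (block-structured marker genes
generated by the simulator, labelled as such); no published signature
matrix is redistributed.

## Association statistics

Spearman ρ is computed as Pearson on average-tie ranks, vectorized over all
column pairs.  Two-sided p-values use the t-approximation
`t = ρ√((n−2)/(1−ρ²))` for n ≥ 10 and exhaustive enumeration of all n!
orderings below (|ρ_perm| ≥ |ρ_obs| with a 1e-12 guard against float
noise).  Constant columns yield undefined cells, reported as missing, never
as 0.  BH q-values are computed over the whole matrix as one family — the
DDR × immune matrix is read as a single figure, not per-row families.  In
all cases q ≥ p element-wise, which the tests assert.

The over-representation test is Fisher's exact on the 2×2 table
(in-set/out-of-set × foreground/rest-of-background), two-tailed by the
"sum all tables no more likely than observed" convention used by mainstream
implementations.  Odds ratio is the sample (a·d)/(b·c), infinite when
b·c = 0 with a·d > 0.  Fold-change quartiles split upregulated proteins
(fold change > 1) by ascending fold change into Q1..Q4 with minimum-rank
tie assignment, so boundary ties deterministically fall into the lower
group; downregulated proteins stay ungrouped.

## Synthetic cohort

The generator emulates a tumor cohort of 80 samples × 12,000 genes by
default: baselines are log-normal (log-mean 1.2, log-sd 0.4, i.e. typical
log2 abundances around 3–4); each planted pathway has a standard-normal
per-sample latent that shifts its members by `effect_size` (default 1.0
log2 units per latent sd — a strong but realistic pathway program);
per-gene Gaussian noise has sd 0.5.  The designated pathway latent and the
immune latent come from a Gaussian copula whose Pearson parameter
`2·sin(πρ*/6)` yields Spearman ρ* (default −0.6).  Immune-responsive genes
(the immune list at weight 1.0, immune pathway members at 0.8) shift with
the immune latent.  Cell fractions are Dirichlet with concentrations tilted
by `exp(±0.8·L_immune)` (+ for immune types, − for the stromal type), so
the immune share rises with infiltration; marker-gene expression is the
signature × fractions mixture plus noise.

A gene belonging to several planted pathways is driven by one *primary*
pathway — the designated pathway if it contains the gene, else the first
containing pathway in collection order.  Overlapping sets therefore
intercorrelate through shared members (as real KEGG/Reactome collections
do) without diluting the designated pathway's own latent; no separate
overlap parameter is exposed, since the packaged collection's natural
redundancy provides it.

What the generator does **not** emulate: count-level noise (a
Poisson-lognormal count mode exists behind a flag but the analysis is
rank-based), batch effects, tumor purity gradients, co-expression beyond
pathway latents, or realistic cell-type signature collinearity.  Passing
tests therefore show the pipeline recovers planted rank-correlation
structure of realistic magnitude under Gaussian log-space noise — not that
any particular biological dataset will show such structure.

## Packaged gene sets

The DDR collection contains 27 pathways named for the canonical repair
mechanisms (MMR, BER, NER, HR, NHEJ), double-strand-break sub-processes
(including the RAD51-mediated *homologous DNA pairing and strand
exchange* step, end resection, D-loop resolution), damage checkpoints,
replication-coupled repair and related programs, with member genes curated
in the style of the KEGG and Reactome collections.  The immune pathway file
holds eight hallmark-style stand-in sets (interferon responses,
inflammation, TNF/NF-κB, IL-6/JAK/STAT3, complement, antigen presentation,
cytotoxicity).  All three resources are ordinary GMT/text files and can be
replaced by user-supplied ones at every entry point.

## Problem sizes used in the automated checks

The oracle-equivalence checks use 1000 random ranked lists of up to 50
genes; null calibration uses 200 random sets against a 150-gene profile
with 500 permutations; planted-shift detection uses 40 samples × 2000
genes; deconvolution recovery uses 100 four-cell-type mixtures; the
end-to-end recovery check runs 50 replicate cohorts at the generator's
default conditions (80 samples, 12,000 genes, ρ* = −0.6) scored with 200
permutations per null — enough for a stable NES ordering, since the
correlation stage consumes ranks of NES rather than p-values.

## Known limitations

* NES comparability across samples relies on each sample's own permutation
  null; strongly skewed per-sample score distributions can shift NES scale.
* The exact-permutation Spearman p is enumerated only below n = 10 and
  grows factorially; n = 9 is noticeably slower than n = 8.
* Deconvolution assumes the signature's cell types span the mixture; an
  unmodeled compartment is absorbed into the closest columns.
* The packaged gene sets are curated stand-ins: category names and sizes
  mirror the standard collections, but member-level fidelity to any
  specific database release is not claimed.
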