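# ddrimmune

Per-sample DNA-damage-response/repair (DDR) pathway profiling and
immune-landscape correlation for bulk tumor transcriptomes.

Tumors with active DNA repair can evade immune surveillance: in small cell
lung cancer, activity of the RAD51-mediated *homologous DNA pairing and
strand exchange* step of homologous recombination is inversely related to
immune infiltration.  `ddrimmune` turns that style of analysis into a
tested, reusable pipeline: it converts a genes × samples expression matrix
into a per-patient pathway activity profile over a curated 27-pathway DDR
collection, summarizes each sample's immune landscape (content score,
immune pathway activity, deconvolved cell fractions), and links the two
blocks with a Spearman correlation matrix.  It is aimed at computational
biologists who have a bulk RNA-seq cohort (log2 expression) and want
pathway-level DDR/immune associations without assembling five tools by
hand.

## Method

For each gene *g*, expression is median-centered across samples,
`x̃(g,s) = x(g,s) − median_s x(g,·)`, and each sample's genes are ranked by
descending centered value.  Pathway activity is a pre-ranked gene-set
enrichment score: walking down sample *s*'s ranked list, a gene in set *S*
adds `|x̃|^w / Σ_{hits} |x̃|^w` and a gene outside *S* subtracts
`1/(N − |S|)`; the enrichment score ES is the running sum's maximal
deviation from zero (weight *w* = 1 by default).  ES is calibrated against
a gene-label permutation null (random same-size sets, 1000 permutations by
default): `NES = ES / mean |ES_null|` over same-sign null values, with a
smoothed one-tailed nominal p and Benjamini–Hochberg FDR per sample.

Immune features per sample are (i) the immune content score — the mean
across-sample z-score of a curated immune-specific gene list; (ii) NES of
immune pathway sets; (iii) cell-type fractions from regressing the sample
on a genes × cell-types signature matrix (non-negative least squares by
default, or linear ν-SVR over ν ∈ {0.25, 0.5, 0.75} keeping the lowest
reconstruction RMSE), clipped and renormalized to the simplex.
Associations are Spearman ρ with two-sided p (t-approximation for n ≥ 10,
exact permutation enumeration below) and BH q over the matrix as one
family.  A Fisher's-exact over-representation test with fold-change
quartile grouping supports proteomics-style enrichment analyses.

A synthetic cohort generator plants per-pathway latent activities, an
immune-infiltration latent coupled to a designated DDR sub-pathway through
a Gaussian copula (Pearson parameter `2·sin(πρ*/6)` for target Spearman
ρ*), and Dirichlet cell mixtures, so the whole pipeline is testable with
known ground truth.

## Worked example

```python
import ddrimmune as di
from ddrimmune.enrichment import EnrichmentParams

cohort = di.generate_cohort(di.CohortConfig(n_samples=40, n_genes=3000, seed=1))
print(f"cohort: {cohort.expr.shape[0]} genes x {cohort.expr.shape[1]} samples, "
      f"planted rho = {cohort.realized_rho:+.3f}")
scores = di.score_cohort(cohort.expr, cohort.collection,
                         EnrichmentParams(n_perm=200, seed=1))
content = di.immune_content_score(cohort.expr, cohort.immune_genes)
cm = di.spearman_matrix(scores.nes, content.to_frame())
print(cm.rho.iloc[:, 0].sort_values().head(3).round(3))
```

prints

```
cohort: 3000 genes x 40 samples, planted rho = -0.653
HOMOLOGOUS_DNA_PAIRING_AND_STRAND_EXCHANGE   -0.694
REPLICATION_FORK_PROTECTION                  -0.380
FANCONI_ANEMIA_PATHWAY                       -0.371
Name: immune_content_score, dtype: float64
```

The generator planted a Spearman correlation of −0.6 (realized −0.653 in
this draw) between the latent activity of the RAD51 pairing/strand-exchange
pathway and the immune latent; the pipeline recovers it as the most
negative DDR row (−0.694) of the pathway-NES × immune-content-score
correlation column.  The next rows are HR-adjacent pathways that share
member genes with the designated one.

The same analysis is available from the shell:

```sh
ddrimmune simulate --outdir sim --seed 1
ddrimmune run-all --config config.yaml     # or: score / immune / correlate
```

`run-all` emits the NES matrix, the immune feature matrix, both correlation
matrices (rho/p/q, wide and long), hierarchical clustering orders, and a
`manifest.json` with config echo, input checksums, per-stage seeds and
timings.

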