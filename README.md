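# adipodyn

Visceral and subcutaneous adipose tissue contribute differently to the
metabolic consequences of obesity, and part of that difference is laid
down during adipogenesis itself.  `adipodyn` is a reusable pipeline for
asking *which genes differentiate differently between two fat depots*:
it scores genes for divergent expression dynamics between two conditions
(e.g. murine epididymal "epi" vs inguinal "ing" pre-adipocyte lines,
proxies for human visceral and subcutaneous fat) over a differentiation
time course (days −2, 0, 2, 4, 6, 8 around induction), clusters
trajectory *slopes* to separate genes with congruent versus divergent
dynamics, and relates depot-specific expression to obesity phenotypes
(BMI, waist-to-hip ratio) in a paired-biopsy human cohort.

Because the kind of raw data this pipeline consumes is rarely publicly
deposited, the package ships a first-class synthetic-data module that
generates time courses, detection-above-background (DABG) tables and
cohorts with known ground truth, so every stage is testable end to end.

## The method

Let `x_g(c, t)` be the replicate-mean log2 expression of gene `g` in
condition `c` at day `t`, and `d_g(t) = x_g(epi, t) − x_g(ing, t)` the
per-day log2 fold change.  Four scores capture complementary aspects of
divergence:

| score | definition | emphasizes |
|---|---|---|
| integral | trapezoid of \|d\| over a day interval (early [−2,0], middle [0,4], late [6,8], whole [−2,8]) | absolute expression change |
| dynamic | \|OLS slope of d vs t\| × course duration | slow, sustained drift |
| peak | max over t of \|d(t) − median_t d\| | fast transient change |
| relevance | ln(1 + PubMed count for a stimulus term, default "fat distribution") | prior knowledge |

Each score is tested against a robust empirical null across genes
(z = (s − median)/(1.4826·MAD), one-sided upper tail, p < α = 0.05);
genes whose mean replicate variance exceeds the 95th percentile are
flagged unstable.  A **consensus score** min-max scales the four scores
across genes, averages them and rescales to [0, 1], so the top-ranked
gene scores exactly 1.000.  **Candidates** are genes significant in all
four scores and stable; the **top set** is the strict upper quartile of
candidate consensus scores (137 distinct candidate scores yield exactly
34 top genes).

For dynamics, each gene contributes one slope vector per condition
(central differences at interior days, one-sided at the ends).  Both
conditions are pooled into a single k-means model (k = 8); centroids are
translated into rise/constant/fall patterns and a gene is *congruent*
iff both its condition profiles land in the same cluster.  The cohort
stage assigns subjects to lean / sc-obese / vis-obese groups (BMI < 30;
vis/sc area ratio cutoff 0.4), computes Spearman correlations of
depot-wise expression with BMI and WHR, Mann-Whitney group comparisons
(exact for small tie-free samples, tie-corrected normal approximation
otherwise) and age/sex-adjusted OLS.

## Worked example

```bash
adipodyn run-all --n-genes 2000 --seed 1 --out demo
```

or in Python:

```python
from adipodyn import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(n_genes=2000, fraction_divergent=0.05,
                                     seed=1, out_dir="demo"))
```

The run simulates 2,000 genes (100 truly divergent), filters them
through the DABG rule, scores, clusters and validates; `demo/` then
contains the score table, gene lists, cluster/congruence tables, cohort
associations and a run report.  With seed 1 the score summary reads:

```
genes scored:          1803
significant (any):     444
candidates (all four, stable): 99
top set (> upper quartile):    25

top 10 genes by consensus score:
        consensus  dynamic   peak  integral_whole  relevance
g01457      1.000    2.560  7.193          40.206      3.555
g00595      0.966    7.188  5.230          25.387      3.258
...
```

99 of the 100 truly divergent genes are recovered as candidates (the
one miss falls to the instability filter), the top consensus gene
scores exactly 1.000, and the clustering stage recovers the eight
schematic trajectory shapes as centroid patterns
(`rise`, `constant`, `fall-constant`, `rise-constant-fall`, ...) with
BSS/TSS ≈ 0.95.  The cohort summary shows the simulated 63-subject
cohort split 25/21/17 into lean / sc-obese / vis-obese and recovers the
configured expression–phenotype correlations, e.g. `ALX1` sc expression
vs BMI ρ = −0.78 (p ≈ 9e−14) at its target of −0.61 ± sampling noise.

Each stage is also available separately (`adipodyn simulate|filter|
score|cluster|validate`, see `--help`) and as library calls
(`TimeCourseDivergence(...).fit()`, `SlopeKMeans(...).fit()`,
`DepotPhenotypeAssociation(...).fit()` — each returning a results
object with a `summary()`).

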