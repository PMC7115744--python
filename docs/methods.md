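# Methods

## Scope and data model

`adipodyn` analyzes a balanced two-condition differentiation time
course: log2 expression for each gene in two depots ("epi" and "ing" by
default), on a strictly increasing day grid (default −2, 0, 2, 4, 6, 8
relative to induction) with a constant replicate count per
(condition, day) cell (default 3).  Inputs are assumed already
background-corrected and normalized (e.g. RMA); missing values are not
supported and raise errors rather than being imputed — the arrays this
models are complete by construction.

## Expressed-gene filter

A gene is *expressed* iff in at least one sample at least half of its
exons (configurable fraction) have a detection-above-background p-value
strictly below α = 0.05.  "Half" is read inclusively: a gene with 2 of
4 exons detected passes.  The filter operates on whatever gene/exon
table it is given; it is monotone in α and in the fraction.

## Divergence scores

All difference-based scores use the condition-mean difference curve
d(t), so a constant shift applied to both conditions leaves them
unchanged:

* **integral** — trapezoidal integral of |d| over a named day interval.
  Intervals: early [−2, 0], middle [0, 4], late [6, 8], whole [−2, 8].
  Days 4–6 deliberately fall in no named sub-interval and are covered
  only by "whole".  Units: log2 · day.
* **dynamic** — |OLS slope of d against day| × (day_max − day_min).
  Captures sustained drift; exactly 10 for d(t) = t + 2 on this grid,
  and 0 for any constant or day-symmetric d.  Units: log2.
* **peak** — max over days of |d − median(d)|.  The median centering
  removes constant offsets, isolating transients.  Units: log2.
* **relevance** — ln(1 + publication count) for the gene under a fixed
  stimulus term; genes absent from the count table score 0.  The log
  compresses the heavy-tailed count distribution and maps count 0 to 0.

These three expression scores were designed so each has closed-form
values on simple curves (rectangle, triangle, linear drift, pure
offset), which the test suite pins to 1e−9.

### Significance and instability

Per-score significance uses a robust empirical null across genes:
z = (s − median)/(1.4826 · MAD), one-sided upper-tail normal p,
significant iff p < α.  Rationale: with triplicates there are only 20
condition-label permutations per gene — far too few for p < 0.05 — while
the cross-gene distribution is dominated by null genes and provides a
stable scale.  If the MAD is zero the SD is used; if that is also zero
nothing is significant.  Integral significance means significant in at
least one interval (intervals exist to catch localized change); the
consensus uses the whole-course integral only.

The instability index is the mean over (condition, day) cells of the
replicate variance (ddof = 1); a gene is unstable iff its index strictly
exceeds the 0.95 quantile of all genes' indices.  Note this flags ~5% of
genes by construction, which bounds attainable recall of any
"stable and significant" selection at about 95%.

### Consensus and selection

The consensus score min-max scales each of the four scores to [0, 1]
across genes (a score constant across genes contributes 0 for
everyone — a documented convention), averages the four, and min-max
rescales the averages; the top gene therefore prints exactly 1.000 and
the bottom 0.  Min-max (not rank) scaling preserves relative gaps.
Candidates = significant in all four scores AND stable; whether the
literature-based relevance score should participate in the "all four"
conjunction is interpretive — this implementation includes it.  The top
set applies a strict `> Q3` rule to the candidates' consensus scores,
with the linear-interpolation quantile definition; on 137 distinct
scores this selects exactly 34 genes.  Fewer than 4 candidates skips the
rule with a warning.

## Slope clustering and congruence

Slope vectors use central differences over the actual day spacing at
interior days and one-sided differences at the endpoints (equivalently
`numpy.gradient`), yielding one slope per day; central differences are
exact for quadratics and the whole vector is exact for affine profiles.
Both conditions' vectors are pooled as separate observations into one
k-means model (k = 8, k-means++, best of 25 restarts by within-SS,
seeded) — pooling is the only arrangement under which "same cluster in
both depots" is well defined.  The BSS/TSS ratio is reported, and
`bss_tss_profile` sweeps k = 2..12 as an elbow diagnostic.  All-identical
observations make TSS zero and raise an error.

Centroid patterns use the rise/constant/fall grammar with a tolerance
ε for "constant", defaulting to 0.1 × the 95th percentile of |slopes|
in the clustered data (a strict x′ = 0 rule is measure-zero).  A gene is
congruent iff its two condition profiles share a cluster; the records
also flag combinations where exactly one side sits in an all-constant
cluster (a gene responding to induction in one depot only).  Permuting
cluster ids renames combinations but cannot change the
congruent/divergent partition.

## Synthetic data

### Time course

Eight piecewise-linear archetype templates on the day grid, normalized
to unit amplitude (the all-constant shape is identically zero), encode
the schematic trajectory shapes; each template's central-difference
slope pattern reproduces its name under the grammar.  A replicate value
is `baseline + amplitude · template(day) + N(0, noise_sd)`.

Defaults: 2,000 genes, 5% divergent, amplitudes U(2, 4) log2 units,
baselines U(6, 12) (a conventional log2 array range; the true dynamic
range of such arrays is platform-dependent), noise SD 0.25, triplicates.
Null genes use one archetype/amplitude/baseline for both conditions, so
their difference curve is pure noise.  **Divergent genes** are this
package's operational definition of divergent dynamics: two *different*
archetypes whose amplitude draw is accepted only when the difference
curve has (a) a pointwise gap ≥ 2 log2 units and (b) a sustained drift
(|OLS slope| × duration) ≥ 1 log2 unit, plus a baseline offset of
0.25–0.75 log2 units with random sign.  The drift requirement excludes
shape pairs that differ only in ways no drift-sensitive score could ever
see (e.g. two mirrored transients), which would represent a different
phenotype than the sustained depot divergence being modelled; the
baseline offset reflects that depot-specific genes differ in level
already before induction.  The ground-truth flag itself is the
deterministic rule "different archetype OR amplitude ratio outside
[0.8, 1.25]".

What the generator does **not** emulate: correlated noise across genes,
array batch effects, amplitude/variance dependence, same-shape
different-level divergent genes (all simulated divergent genes change
shape, so the congruence stage sees no "same cluster, different level"
divergents), or heavy-tailed replicate noise.  Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under clean
conditions, not performance on real arrays.

### DABG table and literature counts

DABG p-values are U[0, 0.05) for "present" exon/sample cells and
U[0.05, 1] otherwise; designated expressed genes are present in ~80% of
cells and additionally have ⌈half⌉ of their exons forced present in one
sample, so the filter provably recovers exactly the designated set.
Literature counts give divergent genes 1 + Poisson(30) and null genes
Poisson(0.3): for a specific stimulus term most genes have no
publications while genuinely relevant genes have tens, which is what the
relevance score exists to encode.

### Cohort

63 subjects by default, with group sizes fixed at 25 lean / 21 sc-obese
/ 17 vis-obese; phenotypes drawn from truncated normals matching the
modelled cohort's moments (age 53 ± 16 in [18, 90], BMI 36.1 ± 14.0 in
[15, 70] split at 30 by group, WHR 0.953 ± 0.149 in [0.5, 1.5], vis/sc
ratio ~N(0.4, 0.25) in [0, 1.5] truncated per group at the 0.4 cutoff);
~75% female.  Expression couples to a phenotype through a latent
Gaussian derived from the phenotype's ranks, Z = Φ⁻¹((rank − ½)/n), with
a Spearman target ρ converted to a latent loading r = 2·sin(πρ/6)
(Gaussian-copula relation), residual variance 1 − Σr².  This makes the
sample Spearman correlation converge to the target and equal ±1 exactly
for |ρ| = 1.  BMI and WHR are drawn independently here (they correlate
in real cohorts), so joint targets are honored marginally.  Default
per-gene targets mimic the magnitudes of depot-specific obesity
correlations (e.g. ALX1 sc/BMI −0.612); the expression scale
10·exp(0.5·Z) is arbitrary-unit and rank-preserving.

## Cohort statistics

Group assignment: lean iff BMI < 30 (the lean definition is not
standardized; the cutoff is configurable), otherwise sc-obese iff
vis/sc ratio < 0.4 else vis-obese; a ratio exactly 0.4 — unassigned by
strict-inequality definitions — counts as visceral (configurable).
Spearman correlations use average ranks on pairwise-complete pairs with
the t-approximation p (n − 2 df); zero-variance inputs return a flagged
NaN.  Mann-Whitney: exact enumeration p when n_a + n_b ≤ 12 without
ties, tie-corrected normal approximation with continuity correction
otherwise; an all-tied comparison returns U = n_a·n_b/2 with p = 1,
flagged.  Adjusted regression: OLS of expression on phenotype + age +
sex (female = 0, male = 1) with a rank check that names collinear
columns.  All p-values are two-sided and uncorrected for multiple
testing; results tables carry per-test n.

## Pipeline

One global seed fans out to fixed per-stage offsets (+0 simulate, +101
DABG, +202 literature, +303 clustering, +404 cohort), so stages are
individually reproducible and an identical config yields an identical
sha256 manifest.  The pipeline's DABG "expressed" design keeps all
divergent genes plus 90% of nulls (a gene undetected on the array cannot
be called dynamically divergent).  Clustering defaults to the candidate
set, mirroring the analysis of the most prominent genes, and is
configurable to the full expressed set.

## Problem sizes and numerical notes

The shipped tests and the acceptance script use 2,000-gene simulations
(recovery), 1,000-gene low-noise runs (congruence), n = 2,000 cohorts
(rank-correlation recovery) and 1,000 null simulations (type-I error);
these sizes give stable estimates in seconds.  Quantiles use numpy's
linear-interpolation definition throughout.  K-means ties between
restarts resolve to the first best restart (scikit-learn behavior).
Integrals use `numpy.trapezoid` on the day grid.  Replicate variances
use ddof = 1 so the instability index estimates the noise variance
unbiasedly.

## Known limitations

* The four score formulas are this package's concrete definitions of
  the verbal contrasts they implement (absolute / sustained / transient
  change); other formalizations exist and will rank borderline genes
  differently.
* The robust-z null assumes most genes are null; with a large divergent
  fraction the threshold inflates and power drops.
* The consensus score is min-max scaled and therefore sensitive to a
  single extreme outlier gene compressing everyone else's scores.
* Congruence is cluster-resolution-limited: two genuinely different
  shapes merged by k = 8 read as congruent.
* Cohort regression treats sex as binary and applies no multiple-testing
  correction by design; interpret tables accordingly.
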