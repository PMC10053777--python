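# Methods

This note documents the models, estimators, defaults and numerical choices
behind each stage of the pipeline, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Count model and differential expression

Counts are modeled as negative binomial, `Var(Y) = μ + αμ²`, with a single
dispersion `α` shared across all genes and treatment groups. A common
dispersion is the appropriate regime for small designs (2–4 replicates per
group) where per-gene estimates are too unstable; it is also the regime the
synthetic generator simulates, so dispersion recovery is directly testable.

**Size factors** are median-of-ratios against the per-gene geometric-mean
pseudo-reference, falling back to library-size ratios (normalized to
geometric mean 1) when fewer than 50 genes have all-positive counts.

**Dispersion estimation** maximizes the profile log-likelihood of `α` over
all genes, with each replicated group's mean parameter plugged in as total
count over total size factor, plus the Cox–Reid adjustment
`−½ Σ_g log(Σ_j w_j)` with `w = μ/(1+αμ)`. The adjustment compensates for
the degrees of freedom absorbed by the fitted group means; without it the
shared estimate is biased low by roughly a third at n = 3 per group, well
outside the ±0.01 recovery we require of the estimator at 10,000 genes.
Groups without replication are excluded (they carry no dispersion
information once their mean is fitted). Optimization is a 40-point
log-scale grid scan on `α ∈ [10⁻⁸, 10]` followed by bounded refinement of
the bracketing interval; a boundary minimum at the lower bound is reported
as-is (the data look Poisson).

**Per-gene testing** uses the two-group log-link GLM with the size-factor
offset. The group mean parameter is estimated as total count over total
size factor — the exact GLM solution whenever size factors are equal
within a group, and in general the quasi-Poisson estimating-equation
solution. This choice makes `log2FC = log2(m_T/m_C)` exactly equivariant
under rescaling counts and size factors together, a property the full NB
weighting only satisfies approximately. The Wald variance is
`1/I_C + 1/I_T` with group information `I_g = Σ_j μ_j/(1+αμ_j)` evaluated
at the fitted means, and the p-value is two-sided normal. Monte-Carlo
calibration on null simulations (α = 0.05, n = 3 per group) puts the raw
type-I error within 0.05 ± 0.01 and the null p-value distribution
indistinguishable from uniform by a KS test at 5,000+ genes.

Genes with zero counts in both groups are reported as missing and excluded
from the BH family. Genes observed in only one group get a half-count
continuity correction on both group totals before the fold change and the
information are evaluated, so they receive large-but-finite effect sizes
and a usable test rather than infinities.

This is deliberately not a full DESeq2 replication: there are no per-gene
or trended dispersions, no LFC shrinkage, no independent filtering, no
count-outlier replacement. DEG counts from a given count matrix are
therefore close to, but not bit-identical with, what DESeq2's defaults
would produce.

**Outlier screening** embeds samples by classical (Torgerson)
multidimensional scaling — eigendecomposition of the double-centered
squared Euclidean distance matrix — on log2(CPM+1). "Raw reads" screening
could also be read as operating on untransformed counts; log-CPM is used
because sample distances are otherwise dominated by sequencing depth. A
sample is flagged when its embedded distance to its group centroid exceeds
median + 3×MAD of within-group centroid distances pooled across groups.
Flags are advisory; removal is the caller's decision
(`RunConfig.drop_mds_outliers`).

## Cross-mixture comparison

Discordance is counted on the union of the two contrasts' DEG sets: a gene
is discordant when both log2FCs are nonzero with opposite signs, and
"discordant and significant in both" additionally requires DEG membership
in both contrasts. Genes missing from either table count as non-discordant
and are reported separately.

The potency regression is least squares through the origin. The no-intercept
coefficient of determination `r² = 1 − RSS/Σy²` is used; note this differs
from squared Pearson correlation, and the two can disagree noticeably, so
the convention is stated here. The weaker mixture is conventionally `y`, so
the slope is its potency relative to the stronger mixture (< 1 means
scaled-down responses). The CI uses `t₀.₉₇₅,n−₁`; simulation puts the
reported SE within 15% of the empirical spread of slope estimates and CI
coverage at ~95%.

For heatmap structure, missing log2FC values are rendered as 0 (a gene
absent from a contrast showed no measured change); rows are partitioned by
the best of `starts` Lloyd's k-means runs (k = 8, 500 starts by default).
Each start is seeded from a stream spawned off the master seed, so results
are reproducible and adding starts only appends runs — the best
within-cluster sum of squares never increases. Initialization is random
centroid selection (scikit-learn's `init="random"`). Treatment columns are
ordered by average-linkage hierarchical clustering on Euclidean distances.
PCA of treatments in gene space centers but does not scale features —
log2FCs already share units, and scaling would up-weight noise genes.

## Overrepresentation and term topology

The hypergeometric upper tail is computed exactly (verified against
rational-arithmetic enumeration for all universes up to 30 genes). BH
adjustment runs within each (query, namespace) family, since BP/CC/MF are
separate databases with separate term counts. This replaces the g:SCS
correction of the g:profiler web service, which has no published closed
form suitable for exact replication; term counts obtained with g:SCS on
real GO data will differ. The background universe is every gene with a
defined DE test result — what was actually measurable — not the whole
genome; a whole-genome background would inflate every enrichment. Query
sets for the three-way design (A-only / overlap / B-only) use the relaxed
|log2FC| ≥ 0.5 threshold. Term size filtering (15–400 in-universe genes,
inclusive) happens after intersection with the universe.

In the enrichment map, node identity is (term, query set): a term enriched
for two queries appears twice, with edges computed on term gene sets only,
mirroring displays where node color encodes the query. Components with
more than three terms expose annotation slots; themes are manual notes,
never auto-generated. Redundancy reduction takes the top 60 terms by
enrichment ratio per treatment and namespace (ties broken by term id),
pools them, clusters by Jaccard distance with **complete** linkage — no
linkage is canonical here; complete linkage is chosen because it guarantees
every pair inside a merged group is within the cut distance — and cuts
strictly below 0.45. Merged terms take the name of the smallest (fewest
in-universe genes) constituent, ties lexicographic. Merging stays within
namespace by default (`pool_namespaces=True` pools everything).

## Screen statistics

Plate QC fails a plate when mortality exceeds two fish in either the
negative (vehicle) or positive (trimethyltin) control arm; exactly two is a
pass. Incidence CIs are Clopper–Pearson ("exact binomial"; Wilson by
option) — conservative by construction, with ≥95% empirical coverage at
(p = 0.3, n = 40). Fisher's exact test is two-sided by the probability-mass
rule (all tables with point probability ≤ observed), stated explicitly
because two-sided conventions differ. The endpoint profile optionally BH
adjusts across endpoints; this is off by default since the primary
screen comparison is a single pre-specified test.

## Chemistry summaries

The total PAH is a sum of per-analyte replicate means; its variance sums
per-analyte variances of the mean (independence assumed — a correlation
option is deliberately not defaulted on, as replicate correlations are not
identifiable from triplicates), with a t CI at df = replicates − 1. When
only a reference sample is replicated, its per-analyte CVs transfer to the
target sample (uncertainty scales with the concentration it attaches to),
which reproduces the familiar pattern of CI width growing proportionally
with the total. Sub-LOQ values enter totals as zero (flagged) and are
excluded from diagnostic ratios. Ratios use replicate-mean concentrations
and are scale-invariant per sample by construction.

## Synthetic-data generator

The generator is first-class, tested code defining the conditions under
which the pipeline's guarantees are verified:

- **Counts**: NB via the gamma–Poisson mixture, `μ_gj = μ_g s_j 2^{L_gt}`
  with `L = 0` (control), `θ_g` (strong mixture), `βθ_g + ε_g` (weak
  mixture, ε only on perturbed genes so nulls stay exactly null). Defaults:
  β = 0.59, ε sd 0.3, α = 0.05, 10% of genes perturbed with
  `θ ~ ±U(0.5, 3)` log2 units, baseline means lognormal (median 100,
  log-sd 1), size factors lognormal(0, 0.1). The effect-ratio structure is
  the study condition; the DE fraction and effect-size law are exercise
  defaults, as no generative model is implied by any real dataset.
  Additional single-chemical arms apply a scalar multiple of θ.
- **Gene sets**: background term sizes uniform on 15–400; planted
  coherent terms draw ≥ 90% of members from same-sign perturbed genes and
  use sizes 15–60 (coherent pathways are small relative to the filter
  window).
- **Screen**: binomial per (treatment, dilution, endpoint) at n = 40, with
  8-well negative/positive control arms per plate; default true-incidence
  curves saturate at the 1% dilution, separate the mixtures at 0.2%
  (67.5% vs 26.5% any-effect), and sit at control level below.
- **Chemistry**: site B = 1.63 × site A per analyte with mean-preserving
  lognormal replicate noise (default CV 0.1, triplicates), over a bundled
  representative 33-analyte panel.

One master seed fans out to per-generator streams (`SeedSequence` spawn
keys), so generators are independently reproducible and consuming one does
not perturb another.

What the generator does **not** emulate: gene–gene correlation, GC/length
biases, batch structure, outlier counts, overlapping or hierarchically
nested annotation (terms are sampled independently), endpoint correlation
within a fish, or analyte-profile differences beyond a pure scale factor.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every artifact of real data.

## Problem sizes and determinism

Statistical checks run at the sizes where their tolerances are meaningful:
5,000 genes for calibration (type-I error band ±0.01), 10,000 for
dispersion recovery (±0.01), 100 seeds × 1,000 pairs for slope coverage,
10,000 draws for CI coverage. The demo uses 6,000 genes × 12 samples and
completes in seconds. All randomness descends from explicit seeds; a fixed
seed reproduces every output file byte-for-byte, and the run manifest
records seed, parameters, versions and per-stage row counts.

## Known limitations

- The common-dispersion NB Wald test is anti-conservative when true
  dispersions vary strongly across genes; the shared-α model is an
  assumption, not an inference.
- Exact DEG counts from published studies are reproducible from their
  per-gene supplementary tables by threshold filtering, but not from raw
  counts alone, because upstream tool defaults (shrinkage, filtering,
  outlier handling) are not replicated here.
- g:SCS-adjusted term lists and GO-version-dependent term counts are out
  of reach by design; BH within namespace is the documented substitute.
- The enrichment map is emitted as GraphML/TSV for external layout;
  no visual rendering is attempted.
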