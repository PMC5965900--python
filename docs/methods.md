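# Methods

This note documents the statistical models and procedures implemented in
`pvnhkit`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not establish about
behaviour on real cohorts.

## Variant model and qualifying-variant filters

Variants enter the analyses as annotated records (effect class, PolyPhen-2
HumDiv/HumVar scores, caller QC metrics, population-database frequencies);
calling and annotation are upstream. Two QC gates are implemented as pure
predicates:

* **De novo hard filters** — SNVs fail on QD < 2, MQ < 40, FS > 60,
  HS > 13, MQRS < −12.5 or RPRS < −8; indels on QD < 2, RPRS < −20 or
  FS > 200. All inequalities are strict: a metric exactly at its threshold
  passes. HS (HaplotypeScore) is no longer emitted by modern callers; a
  missing metric raises an explicit error rather than silently passing,
  unless the caller declares the column absent (`absent_fields`).
* **Collapsing-analysis filters** — depth ≥ 10, QUAL ≥ 30, GQ ≥ 20,
  QD ≥ 2, MQ ≥ 40, RPRS > −3, MQRS > −6, FS ≤ 200 for indels, VQSR pass,
  not blacklisted, and an alternate-allele ratio ≥ 25% for het genotypes.

A dominant-model qualifying variant is absent from EVS and ExAC, has ≤ 4
allele copies in the combined cohort, and is LoF (stop gained, frameshift,
splice acceptor/donor, start lost, exon deleted) or — in the wider model —
missense with HumDiv "probably damaging". The label is operationalised as
HumDiv ≥ 0.957, PolyPhen-2's published cut for that category. Biallelic
qualifying sites require the same functional classes at MAF < 0.001 in
EVS, ExAC and the cohort. Compound-heterozygous genotypes are unphased
(two distinct qualifying het sites in one gene); when trio data trace both
alleles to a single parent a `same_parent` flag is emitted so downstream
filtering can drop likely-cis configurations. Hemizygous logic applies to
male X genotypes only. Mendelian-inconsistent records are flagged, never
silently dropped.

## De novo calibration

The expected cohort-wide synonymous de novo count is
`2 · n_trios · Σ_g μ_g^syn`, the factor 2 accounting for the two
chromosomes; per-gene rates come from a trinucleotide-context mutation-rate
table supplied as TSV (X-chromosome genes are excluded from the
calibration, which is an autosomal expectation). The probability-score
threshold is then the largest score at which Sanger-confirmed candidates
plus untested candidates above threshold reach that expectation. Confirmed
candidates are always accepted, refuted ones always rejected. Ties at the
threshold are all accepted — the acceptance count may exceed the
expectation by the tie size — because a deterministic, seed-free rule was
preferred over random tie-breaking. Expectations are carried as real
numbers and rounded only for display.

The score itself is a pluggable supervised classifier (default:
scikit-learn gradient-boosted trees) over caller-supplied feature columns;
the package reports stratified cross-validated sensitivity and
specificity. Per-call scores are treated as independent across a trio;
correlated caller errors within a trio are not modelled.

## Hot-zone analysis

Deleteriousness x is 0 for synonymous, 1 for LoF, and the HumVar score for
missense variants; intolerance y is the RVIS percentile (consumed as
annotation, never recomputed). Only single-nucleotide de novo
substitutions participate. Per individual, the variant minimising
√((1−x)² + y²) is kept; exact distance ties break by (chrom, pos, alt) so
results are seed-free. LoF variants enter the hot-zone membership test at
x = 1 and therefore satisfy the score ≥ 0.95 clause by construction. The
2×2 hot-zone × case/control table is tested two-tailed by Fisher's exact
test; the odds ratio and 95% CI are the conditional maximum-likelihood
estimates (`scipy.stats.contingency.odds_ratio`), which remain defined
(0 or ∞ with one-sided CIs) for empty strata.

## Architecture likelihood

The likelihood is a per-gene two-component Poisson mixture: each gene is
independently a risk gene with prior π, and the cohort count of
nonsynonymous de novo variants in gene g is Poisson with mean λ_g
(= 2·n_trios·μ_g) or γ·λ_g. This concrete form was chosen because it
realises exactly the two parameters the analysis estimates — the fraction
of (intolerant) genes conferring risk and their relative risk — and
supports the published outputs (likelihood surface, point estimates, LRT).
**It is a surrogate**: the original study's supplementary derivation is
not reproduced here, and a form that conditions on the total count or
models proband ascertainment differently would give different estimates on
real data. Counts are conventionally restricted to nonsynonymous variants
in intolerant genes (RVIS lowest quartile); that restriction is applied by
the caller when assembling `DeNovoCounts`.

Numerics: the surface is evaluated on a log-spaced grid, π ∈ [10⁻⁴, 1]
(50 points) and γ ∈ [1, 10⁵] (60 points) — the γ range extends far past
10³ because credible estimates on strong-effect phenotypes can. The LRT
Λ = 2(ℓ_max − ℓ_{γ=1}) is calibrated by parametric simulation under γ = 1
(default 10,000 draws, seeded); γ = 1 is a boundary at which π is
unidentified, so the χ² approximation is invalid and Λ has an atom at
zero of roughly 0.4 under the null. Joint 95% confidence statements use
the χ²₂-based likelihood region evaluated at exact parameter values (not
grid lookups); per-parameter profile intervals use the χ²₁ cut and
conservatively extend one grid step past the outermost grid point inside
the cut, since the true crossing lies between grid points. All-zero count
vectors fit to a null-equivalent surface with a warning.

## Gene-level collapsing

Each gene × individual indicator is 1 iff the individual carries ≥ 1
qualifying variant (dominant) or genotype (biallelic). Association is the
two-tailed Fisher exact test with the point-probability tail rule (the
convention of standard exact-test implementations; the tail rule is a
package choice). Genome-wide significance is α/(genes × models). Ranks are
ascending in p with ties sharing the minimum rank and name-ordered rows.

Because qualifying variants are ultra-rare, null p-values are far from
uniform; the expected QQ curve is estimated by permuting case/control
labels (preserving counts), recomputing all gene p-values per permutation,
and averaging order statistics rank by rank. Genes with zero carriers
overall have no defined test and are excluded from the ranking (full
output reports them at p = 1). A calibration fact worth knowing when
reading QQ plots: the permutation curve estimates the *expectation* of
each order statistic; a single cohort's extreme order statistics fluctuate
around it by several tenths of a log₁₀ unit, so the package's calibration
test compares the permutation curve against the rank-wise mean over many
independent null cohorts rather than a single draw.

## Pathway higher criticism

Gene-level p-values inside the pathway machinery come from the 1-df
chi-square closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without continuity
correction — cheap enough to recompute across thousands of permutations,
and adequate as a ranking statistic because the null distribution is
permutation-derived anyway (zero-margin tables report p = 1). The HC
statistic maximises √m·(i/m − p₍ᵢ₎)/√(p₍ᵢ₎(1−p₍ᵢ₎)) over the smallest
⌈α₀·m⌉ p-values; α₀ defaults to 0.5, the standard search range. The
weighted variant replaces i/m with the weighted empirical CDF and m with
the effective size (Σw)²/Σw²; the natural intolerance weighting is
w_g = 1 − RVIS percentile, and centrality weights are caller-supplied.
p-values of exactly 0 or 1 are clamped to [1/(2mB), 1 − 1/(2mB)] with a
warning — and only those, since shrinking legitimate small p-values would
create ties among extreme statistics and destroy permutation resolution.

One permutation matrix is shared by all pathways: it yields each pathway's
permutation p = (1 + #{HC_b ≥ HC_obs})/(B+1) and drives the step-down
min-p family-wise adjustment (within-column ranks give per-permutation
p-values; the step-down walks pathways from most to least significant
against minima over the not-yet-rejected set, with monotonicity enforced),
preserving the correlation induced by overlapping gene sets.

## Co-expression prioritization

Expression datasets carry donor structure; every sample is weighted by the
inverse of its donor's sample count, so each donor contributes unit total
weight to the weighted Pearson correlations regardless of how many regions
were assayed. Analyses are restricted to the developmentally relevant
4–38 weeks post conception before anything else happens. The empirical
threshold draws many random gene sets of the candidate-list size
(excluding query genes, so the null is uncontaminated), pools each random
gene's maximum |weighted r| against the query, and takes the lowest value
of the highest 20% — implemented as the type-1 (lower-value) 80th
percentile for determinism. A candidate is prioritized only when its
maximum |weighted r| strictly exceeds the threshold in *every* analyzed
dataset; a candidate absent from a dataset is reported absent and not
prioritized. Leave-one-out validation recomputes thresholds per held-out
query gene and compares the reprioritization count against the rate at
which random non-query genes pass the same thresholds (one-sided binomial
test). Query-set cohesion is the mean within-set pairwise |weighted r|,
ranked against random equal-size sets.

## Synthetic cohorts

The generators emulate the study design the analyses were built for:
535 trios, 196 cases versus 13,151 controls, a per-trio autosomal
synonymous de novo rate of 0.303, and a 14-gene query module for the
expression arm. Gene-to-gene mutation-rate heterogeneity is log-normal
(σ = 0.7, mimicking CDS-length variation), scaled so the diploid
synonymous expectation matches the configured rate exactly; the
nonsynonymous:synonymous rate ratio is ~2.64, putting the total de novo
rate near 1.1 per trio. De novo counts are Poisson per gene
(the standard thin-sampling model for mutation counts; real per-trio
counts may be over-dispersed, which is not modelled because no dispersion
information is available to calibrate it). Risk genes are drawn Bernoulli(π)
per gene — matching the mixture likelihood exactly — and inflate only
nonsynonymous means by γ. Simulated PolyPhen-like scores are 1 for LoF,
0 for synonymous and Beta(0.5, 0.5) for missense, populating both sides of
the 0.95 hot-zone boundary; 20% of nonsynonymous events are LoF.

In the carrier-matrix generator, background genes draw Bernoulli carrier
indicators at a shared rate (default 0.002) identically in cases and
controls, while a *spiked* gene places an exact carrier count
round(p·n) per arm: a spike emulates a printed carrier configuration, and
binomial sampling of the spiked count would make "the spiked gene ranks
first" hold only ~90% of the time purely through spike-count noise,
which is not what a configuration spike is meant to test. The expression
generator plants a module on one latent factor (loading 0.9 by default,
unit marginal variance), leaves background genes independent, skews donor
sample counts by a Dirichlet draw, and spans ages 4–38 pcw.

Every generator builds its own `numpy` Generator from the config seed plus
a per-generator stream tag: fixed configs are bit-reproducible and the
four generators are mutually independent. Ground-truth sets (risk, spiked,
module) are kept disjoint.

**What the synthetic tests do not show.** The generators contain no
batch effects, no relatedness or population stratification, no
cell-line artifacts, no correlated QC failures, and no realistic linkage
between intolerance and expression. Passing calibration and recovery
tests therefore demonstrates that the statistical machinery is correct
under its own assumptions — not that those assumptions hold in any real
cohort.

## Problem sizes used in the calibration suite

Parameter recovery for the architecture model uses 100 replicate cohorts
of 5,000 trios over a 300-gene universe (the per-gene rates scale with the
universe, so gene count trades resolution against replication; 300 genes
give ~18 expected events per gene at this depth). Null-LRT calibration
uses 500 shared parametric null simulations against 200 replicate null
cohorts; because the null LRT distribution depends only on the λ vector,
sharing one null sample across replicates is valid and is what makes the
check cheap. QQ calibration uses 200 genes at the 196/13,151 design with
B = 1,000 permutations against 100 independent null cohorts; spiked-gene
recovery uses 20 seeds over a 500-gene universe; leave-one-out uses the
14-gene module over a 600-gene universe with 200 random sets of 107.

## Known limitations

* The architecture likelihood is a declared surrogate for the study's
  unpublished derivation (above); estimates on real data may differ.
* The conservative simulation p-value for the LRT inherits the null atom
  at Λ = 0: it is valid but strictly conservative near p = 1.
* Compound-het detection without phase over-calls cis configurations; the
  `same_parent` flag recovers only the trio-inferable subset.
* The chi-square gene-level test inside the pathway machinery is
  anti-conservative for very sparse carrier tables; it is used only as a
  permutation-ranked statistic, never for reported significance.
* The empirical co-expression threshold depends on the candidate-list
  size; comparing prioritization across candidate lists of different sizes
  requires recomputing thresholds per list.
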