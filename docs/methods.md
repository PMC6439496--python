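# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user should know before trusting an edge
case.

## Data model and conventions

Genotypes are diploid ALT-allele dosages in {0, 1, 2} with −1 for missing,
stored alongside a same-shaped per-genotype quality matrix (NaN where
unknown). Coordinates are 1-based as in VCF; all internal interval logic is
half-open `[start, stop)`, so a segment quoted as running "between
positions a and b" has length b − a (the 578-bp mtDNA control-region
segment between positions 1,169 and 1,747 is the reference case).
"Minor" alleles are computed per analysis from the data in hand, never
stored. Phase separators in VCF genotypes are ignored: every analysis here
is genotype-based.

## Filtering

The canonical chain is: biallelic SNPs → excess heterozygosity → sample
missingness → genotype-quality masking → site missingness → rare alleles →
LD pruning. The source study implies that the heterozygosity and sample
filters precede the per-analysis site filters but does not fully serialize
the order; this package fixes it as above so that attrition reports
compose deterministically.

Boundary semantics are encoded exactly as stated by the design:
heterozygosity ≥ 0.6 removes the site (collapsed paralogs); sample
missingness > 0.80 drops the sample (strict); site missingness < 0.30
keeps the site (strict); MAF ≥ 0.05 keeps the site (inclusive); genotype
quality ≥ 10 keeps the call. Sites that are entirely missing are removed
by the first filter that computes a per-site statistic (the
heterozygosity filter in the canonical order) and appear in its report.

Two screens stand in for procedures whose original details are not
public, and are labelled as such:

* **Sex linkage.** Birds are ZW-female, so a Z-linked locus shows
  heterozygotes only among males. A per-site Fisher exact test compares
  heterozygote counts between known-sex groups (default α = 0.01,
  requiring ≥ 3 samples of each sex). This captures the
  female-hemizygous signature without claiming to reproduce the original
  screen.
* **Close kin.** The KING-robust method-of-moments estimator
  φ = (N_het,het − 2·N_opposite-hom) / (N_het(i) + N_het(j)), with the
  conventional 0.177 threshold separating first from second degree
  (duplicates ≈ 0.5, parent–offspring ≈ 0.25). From each flagged pair the
  sample with more missing data is dropped, ties broken by sample id.

LD pruning is a greedy scan keeping sites whose genotype r² with every
retained site within 500 kb on the same scaffold is ≤ 0.2 — common
defaults for the pruning approach the study cites, which does not state
its thresholds; both are configurable.

## Structure

**PCA** centers dosages and imputes missing cells by three rounds of
rank-min(10, n−1) SVD reconstruction seeded with site means (the study
names only the SVD-imputation concept; round count and rank are this
package's choices — recovery is insensitive to both in the tested range).
Axis signs are fixed by making each axis's largest-magnitude score
positive.

**Admixture** is maximized by plain EM. The tool the study used applies
quasi-Newton acceleration; plain EM is retained here for transparency and
provable monotonicity, with the quoted stopping rule (log-likelihood gain
< 1e-9) and a 10,000-iteration guard. Cluster frequencies are free to
reach the boundary; the log-likelihood floors its argument at 1e-300 so a
boundary frequency meeting a conflicting genotype degrades gracefully
instead of producing −∞.

**Cross-validation for K** masks random non-missing genotype cells
(default 5 folds × 5 replicates), refits, and scores the hidden dosages
by squared error against their expectation 2·Σ_k q_ik p_kj. The cited
tool's exact CV loss is unpublished; cell masking with dosage-scale
squared error is the package's documented choice.

**DAPC assignment** trains on a stratified 60% split, reduces to the
first *a* PCA axes (a = 1..10, 20 replicates each by default), classifies
with a linear discriminant, and averages held-out accuracy over the whole
(axis, replicate) grid. Missing genotypes are imputed with per-site
training means only — the test fold never leaks into the imputation.

## Differentiation and divergence

Per-site Weir–Cockerham (1984) variance components a, b, c are computed
from sample sizes, allele frequencies, and observed heterozygosity of the
two groups; the weighted estimate is Σa / Σ(a+b+c) over sites with ≥ 2
called genotypes per group. Per-site ratios a/(a+b+c) are reported for
outlier screens, are undefined where a+b+c ≤ 0, and are never clamped:
negative estimates at undifferentiated sites are information, not error.
The outlier threshold is the empirical 0.99 quantile of defined ratios
with linear interpolation between order statistics.

Hudson's sequence-based F_ST is 1 − Hw/Hb with Hw the unweighted mean of
the two within-group mean pairwise difference rates and Hb the
between-group mean, under pairwise deletion of non-ACGT columns.

Windowed divergence expects a callset that retains invariant sites,
drops sites with > 60% missing calls, and accumulates windows of exactly
5,000 retained positions per scaffold; a terminal window is kept only if
it has at least half that many (the study is silent on terminal windows).
Per site, D_XY = p_x(1−p_y) + p_y(1−p_x); D_X and D_Y use the
sample-size-unbiased within-group form 2p(1−p)·n/(n−1). The genome
estimate is the unweighted mean over windows, matching the study's
"averaged the windows together" wording. D_A = D_XY − 0.5(D_X + D_Y), and
t = D_A / 2μ with negative D_A flagged non-estimable rather than reported
as a negative time.

mtDNA distances use Tamura–Nei (1993) with gamma rate variation at shape
0.05. The study's exact distance was a maximum-composite-likelihood model
that additionally corrects for composition bias among sequences; that
correction is **not** implemented — TN93+Γ is the documented substitute,
adequate at control-region divergences but a known simplification.
Saturated pairs (non-positive correction argument) return NaN with a
warning.

The per-individual inbreeding coefficient is the method of moments
F = (O_hom − E_hom)/(L − E_hom) with E_hom = Σ 1 − 2p(1−p)·2n/(2n−1) from
group allele frequencies; values below zero (heterozygote excess) are
legitimate output.

## f3 admixture tests

f3(X; Y, Z) per site is (x̄−ȳ)(x̄−z̄) − x̄(1−x̄)/(n_X−1), where the
correction term removes the sampling-noise bias using only the target
population X, as in the admixture-test literature (the study names the
statistic and software but not the formula). Standard errors come from a
delete-one block jackknife over blocks of 50 consecutive SNPs in matrix
order; a short terminal block is retained with equal weight (the weighted
jackknife is a noted alternative that matters only when block counts are
tiny). No heterozygosity normalization is applied. All ordered triples of
regions are enumerated — 8 regions give 336 tests, matching the study's
count; a `dedup` flag halves this by the Y↔Z symmetry.

## AIM panel design and concordance

Candidates are per-site F_ST ranks between the island reference and the
pooled remainder, after removing pooled-MAF < 0.05 sites (such sites
cannot carry large frequency differences). The design filters accept
candidates top-down requiring ≥ 30 bp of flanking sequence on each side,
no non-rare variant (pooled MAF ≥ 0.05 anywhere in the dataset — "rare"
is interpreted dataset-wide) within the flank, and one site per scaffold,
stopping at the panel size (default 11 selected, of which assays
historically succeed for ~10; downstream code accepts any panel size).

Cross-platform concordance counts only (sample, site) pairs called in
both datasets, classifies each discrepancy as het-vs-hom or
opposite-homozygote, and reports the percentage rounded half-up to two
decimals (8 discrepancies among 1,013 comparable calls print as 0.79%).

## Ancestry (S, H) estimation

The three-class mixture likelihood is exact for unlinked loci and plug-in
reference frequencies; reference-frequency uncertainty from the finite
reference samples (the study used 12 and 28 individuals) is deliberately
not propagated, matching the method the study applied. Estimation is an
exhaustive grid over the feasible triangle at step 0.005 (the original
method's resolution is unstated) followed by Nelder–Mead refinement that
rejects infeasible proposals; results are clipped onto the triangle to
absorb round-off, so no estimate ever violates H ≤ 2·min(S, 1−S).
Individuals with fewer than 7 called panel loci are skipped, mirroring
the study's at-least-7-genotypes rule. A zero-probability genotype
contributes log(1e-300) instead of −∞ so a single genotyping error cannot
dominate the surface — a documented softening of the strict likelihood.

Hybrid classes follow the study's cuts: H ≥ 0.5 high (early-generation
hybrids), 0.25 ≤ H < 0.5 intermediate, otherwise low; S > 0.5 flags
island-cluster majority ancestry.

## mtDNA haplotypes

Uncorrected p-distances use pairwise deletion. The NJ tree is classic
Saitou–Nei agglomeration (via scikit-bio) with negative branch lengths
clamped to zero; on additive matrices NJ reproduces the generating tree
exactly, which the test suite exploits as an oracle. Haplotype collapsing
treats N as incompatible with everything (sequences differing only at an
N site are *not* merged — conservative, and the study is silent); an
explicit trim step restricts to the well-covered interval first. The
haplotype network is a minimum spanning tree over Hamming distances with
ties broken by label — a deliberate substitute for median-joining network
inference, which additionally infers unobserved median haplotypes; MST
edges are a subset of what median-joining would draw and carry no
inferred intermediates.

## Synthetic data: what it emulates, what it does not

The generator plants the statistical structure the analyses assume:

* **Drift.** Regional frequencies follow Balding–Nichols:
  Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ Uniform(0.05,
  0.95) (bounded away from 0/1 to keep sites informative). Variance is
  F·p(1−p), so Weir–Cockerham F_ST between two regions has expectation
  near the mean of their F parameters. Defaults mirror the study's
  conditions: eight regions at the published sample sizes (12 island /
  107 continental), island F = 0.14 against continental F = 0.004, which
  lands island-vs-rest weighted F_ST in the published 0.06–0.09 band and
  continental pairs at ≤ 0.01.
* **Admixed individuals** are planted per (region, S, H) spec, each locus
  independently assigned an ancestry class with probabilities
  (S − H/2, H, 1 − S − H/2) — the estimation model run forward. Loci are
  unlinked, as the downstream analyses assume post-pruning.
* **Missingness and quality** are tiered by DNA source (defaults: tissue
  and blood 8% missing, toe pads 50%, feathers 85%; qualities from a
  discretized gamma per tier). Only the ordering relative to the GQ = 10
  threshold matters downstream. The published account gives counts of
  dropped samples, not a missingness distribution, so tier rates are free
  parameters chosen to reproduce the qualitative outcome: feather-tier
  samples fail the 80% filter, tissue-tier samples pass.
* **mtDNA** uses a star-like coalescent approximation per region — each
  sequence carries Poisson(θ/2) private mutations at globally distinct
  positions, so the expected pairwise difference is θ — with the island
  group constrained to a configurable small number of haplotypes
  (default two, one mutational step apart, major haplotype frequency
  0.7). The exact genealogy model is immaterial to the tests, which
  assert summary properties only.

Not emulated: linkage disequilibrium and recombination maps, read-level
errors (the generator starts at genotypes), isolation-by-distance among
continental regions, mutation-model heterogeneity in mtDNA, and
reference-bias artifacts of cross-species mapping. Passing tests
therefore demonstrate estimator correctness and pipeline behavior under
the planted conditions, not robustness to those real-data complications.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the simulator derives
independent substreams for frequencies, genotypes, quality, and mtDNA
from its single seed, and identical seeds give bit-identical VCF/FASTA
output. The orchestrated pipeline expands one global seed into per-stage
seeds as (seed·1000 + stage index) mod 2³¹, so any stage can be rerun in
isolation.

The test suite and the acceptance script use deliberately scaled problem
sizes — 5,000 SNPs for F_ST recovery at the published 12-vs-107 sample
sizes, 20,000 SNPs for f3 Z-scores, 500-locus panels for (S, H) recovery,
300–4,000-SNP matrices for cross-validated K and DAPC — chosen as the
smallest sizes at which the targeted effects are comfortably larger than
Monte-Carlo noise.

## Known limitations

* EM admixture is slower to converge than accelerated implementations;
  at the quoted 1e-9 tolerance, thousands of iterations are normal.
* TN93+Γ underestimates distances relative to the composition-bias-aware
  model at high divergence; divergence-time outputs inherit every caveat
  of the D = 2μt approximation (rate transfer across taxa, saturation,
  gene flow shrinking D_A) and should be read as order-of-magnitude.
* The sex-linkage and kinship screens are principled reconstructions,
  not reimplementations of the original (unpublished) procedures.
* The MST haplotype network omits median (unobserved) haplotypes, so
  multi-step edges appear where median-joining would interpose nodes.
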