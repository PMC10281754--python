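# Methods

This note documents the statistical model behind each stage, the defaults and
their rationale, what the synthetic cohort does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Measurement model

### Pyrosequencing methylation and QC

Targeted bisulfite pyrosequencing reports, per donor and CpG, a methylation
percentage measured in duplicate. The QC rule is a range check on the raw
percentage scale: a record is excluded when its replicates differ by more
than `qc_threshold` (default 5 percentage points). The rule is
shift-invariant — adding a constant to both replicates never changes the
verdict — and a single replicate passes vacuously. The retained value is the
replicate mean, stored as a proportion β = mean% / 100.

### β and M scales

Hypothesis tests run on M = log₂(β / (1 − β)). M-values are closer to
homoscedastic across the β range than β itself, which matters here because
group sizes are very unequal (tens of fetal limb donors versus over a
hundred aged donors). β is clamped to [ε, 1 − ε] with ε = 10⁻⁶ before the
logit so boundary measurements (0% or 100%) stay finite; the inverse
transform is exact away from the clamp. Effect sizes — group differences,
genotypic effects — are always reported on the percentage scale, which is
how methylation differences are read in practice.

### Differential methylation

Welch's two-sample t on M-values provides the p-value (unequal variances and
unequal n are the rule in this design); the effect and its 95% CI are the
difference of group means on the percentage scale with Welch–Satterthwaite
degrees of freedom. P-values are adjusted across the CpG panel per comparison
by Benjamini–Hochberg. The CI sits on the reporting scale while p comes from
the testing scale; the two always agree in sign because the logit is strictly
increasing.

### qPCR expression

Relative expression is 2^(−ΔCt) with ΔCt = Ct(target) − mean Ct over the
housekeeping panel (18S, HPRT1, GAPDH in the shipped simulation).

## mQTL model and the genotypic effect

The mQTL fit is an ordinary least-squares regression of M-values on
effect-allele dosage (0/1/2, additive coding); the p-value is the slope's
t-test. An additive linear model was chosen over a rank-based
genotype-class comparison because the effect summaries of interest are
graded per-allele quantities; a Kruskal–Wallis alternative would discard the
dosage ordering.

The genotypic effect (GE) summarizes the fit in percentage points:

- if both homozygote classes carry at least two donors, GE is the absolute
  difference between the dosage-2 and dosage-0 mean percentages;
- otherwise GE falls back to twice the absolute per-allele OLS slope on the
  percentage scale (the extrapolated homozygote contrast).

The homozygote-contrast-with-fallback rule is this package's definition:
no closed formula for the quantity exists in common usage, and the fallback
keeps GE defined at loci where an extreme allele frequency empties one
homozygote class. GE is invariant to relabelling which allele is "effect"
(the magnitude is absolute; the stored sign flips).

Adjustment scope: BH across the CpG panel within each tissue for mQTLs;
Bonferroni across each gene's CpGs for meQTLs (a small, fixed family where
control of the family-wise error is conventional).

## AEI: normalization and the exact signed-rank test

Each heterozygous donor contributes triplicate allele-A percentages for cDNA
and for genomic DNA. Both triplicates are QC'd with the same 5-point range
rule on the percentage scale. The per-replicate allelic ratio is
A/(100 − A); the record's normalized ratio is the geometric mean of the cDNA
replicate ratios divided by the geometric mean of the gDNA replicate ratios.
The gDNA denominator absorbs assay-specific amplification bias, since a
heterozygous genomic template is obligately 50:50. The geometric (not
arithmetic) mean is deliberate: relabelling the alleles maps every replicate
ratio to its reciprocal, and only the geometric combination maps the
normalized ratio exactly to its reciprocal (and log₂ ratio to its negation)
under that flip. With identical replicates both means coincide.

Per gene and tissue, balanced expression (log₂ ratio = 0) is tested with an
exact two-sided Wilcoxon signed-rank test. Zeros are dropped before ranking
and tied magnitudes receive midranks. For n ≤ 25 the distribution of the
positive-rank sum over all 2ⁿ sign assignments is built by a counting
recursion (a generating-polynomial product) on integer-doubled ranks, so
midranks are handled without floating-point rank arithmetic; the two-sided
p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1. Above n = 25 the normal
approximation with continuity and tie corrections is used; at the boundary
the two agree to well under 0.01. The exact test's two-sided p at n
unanimous-direction values is 2/2ⁿ — 0.0078 at n = 8, 0.0156 at n = 7 —
the smallest attainable at those sizes, which is why those values appear as
reported extremes in small heterozygote panels. Being discrete, the exact
test is conservative: its realized size at α = 0.05 is at most nominal.

A transcript SNV in linkage equilibrium with the association SNV cannot use
the heterozygote-ratio design; for that case a two-group rank-sum comparison
of cDNA ratios between association-SNV heterozygotes and homozygotes is
provided (`unphased_group_test`).

## Co-methylation structure

Pairwise-complete Pearson correlation of donor × CpG β values; pairs with
fewer than 3 complete observations are reported missing, never imputed.
CpGs are ordered by average-linkage agglomerative clustering on the signed
distance d = 1 − r. The signed distance is essential at loci where one
genetic signal drives two CpG clusters in opposite directions: those blocks
sit near d = 2 and stay separate at any reasonable cut, whereas a distance
on |r| would fuse them. Flat clusters come from cutting the merge tree at a
height in [0, 2]: cutting at 0 yields singletons, at 2 a single cluster.

## Interval algebra

All interval work is BED-style 0-based half-open; printed 1-based positions
(CpGs, SNVs) are converted exactly once, inside `intersect_points`
(1-based p occupies 0-based base p − 1).

Consensus peaks use a base-level definition: a maximal run of bases covered
by the peak calls of at least k of the group's n samples (defaults k = 4 of
6 for fetal groups, 3 of 5 for aged). This definition is deterministic,
order-independent, idempotent under interval pre-splitting, reduces to the
merged union at k = 1 and the intersection at k = n, and is directly
checkable against a per-base brute-force oracle — the test suite does
exactly that. Occupancy-style consensus tools built on peak-count overlap
chaining can differ at the margins; this package's semantics are the
coverage definition, not a clone of any tool.

Four-way classification labels every region of the merged union of the four
consensus sets by which sets it touches (≥ 1 bp by default;
`min_overlap_frac` exposes a stricter rule): present in all four, unique to
the fetal pair, unique to the aged pair, or other. Total bases are conserved
across labels by construction.

Chromatin-state enrichment assigns each peak the state of maximal base
overlap ("unannotated" when no state covers it), compares the observed
peak fraction per state with the state's share of annotated genome length,
and reports fold and a two-sided exact binomial p.

LD-proxy prioritization keeps proxies with r² strictly above 0.8 that fall
inside at least one consensus set, and classifies each by timing:
all-tissues, fetal-only, aged-only, or partial.

## The synthetic cohort

The generator emulates the features the analysis relies on, at the study's
design sizes (19 FL, 75 FC, 139 AC donors for molecular assays; 6/6 fetal
and 5/5 aged samples for peak sets):

- genotypes drawn i.i.d. from Hardy–Weinberg proportions at each locus's
  effect-allele frequency;
- a latent methylation β per donor × CpG: tissue baseline + dosage × GE/2
  (percentage scale) + a fixed per-CpG offset, clamped to (0.01, 0.99);
  duplicate measurements add Gaussian technical noise (default SD 1.5%) and
  records drop out independently (default rate 5%). Effects are planted
  additively on the percentage scale precisely so that GE recovery is a
  closed-loop test of the estimator;
- AEI records for heterozygous donors only: the latent log₂ ratio is the
  tissue's mean imbalance plus `meqtl_slope` × (donor M − tissue mean M) — 
  the planted meQTL — realized as an allele percentage with triplicate noise,
  and gDNA triplicates centred on 50%;
- peak sets on a 10-Mb toy contig with planted shared / fetal-only /
  aged-only regions, per-sample presence probability 0.95 and boundary
  jitter SD 20 bp;
- marker-gene Ct values with a configurable cartilage offset (default
  ΔCt = −2, i.e. 4-fold higher marker expression in cartilage).

The noise magnitudes are configuration defaults chosen as plausible for
replicate agreement under a 5-point QC rule, not estimates of any particular
dataset. The generator does **not** emulate: bisulfite conversion error,
sequencing reads or peak calling, cell-type composition, age trends within a
tissue, LD between loci, or correlated dropout. Passing closed-loop tests
therefore demonstrates that the estimators recover what the model plants
under realistic noise — not that real tissue data meet the model's
assumptions.

Determinism: every stage derives its RNG from the spec seed plus a fixed
per-stage offset, and per-record draws occur before any dropout branch, so
outputs are reproducible bit-for-bit and insensitive to record-count changes
elsewhere in the stream. Pipeline TSVs are written with a fixed float format;
identical config + seed gives byte-identical bundles (verified by checksum
in the manifest).

## Problem sizes in the test and acceptance suites

Closed-loop recovery uses 200 simulated cohorts of 60 donors (single locus,
single CpG) for GE; type-I calibration uses 2000 null fits at n = 60 (mQTL)
and 2000 null panels of 12 ratios (AEI); oracle-equivalence suites run 500
random instances per interval operation on a 300-bp toy contig. These sizes
give Monte-Carlo error comfortably inside the asserted bands while keeping
the default test run fast.

## Known limitations

- The mQTL/meQTL models are strictly linear and additive; dominance or
  threshold effects would be mis-summarized by GE.
- The exact signed-rank test assumes exchangeable signs under the null;
  donor-level correlation (e.g. repeated joints) is not modelled.
- Chromatin-state enrichment treats peaks as exchangeable units; no
  length-weighting or GC matching is attempted.
- `differential_methylation` is unpaired; a paired hip/knee design would
  need a paired test, which the API does not currently expose.
- The locus table stores optional array-discovery p-values but no stage
  computes with them.
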