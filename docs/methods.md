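# Methods

## Allelic ratio model

The observable at a heterozygous SNP is a pair of read counts (ref, alt)
in each RNA library and in genomic DNA. The RNA ratio is normalized to the
gDNA ratio of the same site, r = (ref_RNA/alt_RNA)/(ref_gDNA/alt_gDNA),
which cancels locus-specific assay bias; a perfectly balanced site then
has r = 1 regardless of capture or mapping bias, provided that bias is
shared between RNA and DNA. Filters, in order:

1. RNA reads < `min_reads` (default 20) → LOW_READS. The filter is applied
   per fraction, so a SNP can pass in the cytosol and fail on polysomes.
2. gDNA reads < `min_reads`, or gDNA minor-allele fraction <
   `het_minor_fraction` (default 0.2) → NOT_HET. A truly heterozygous
   diploid site has expected minor fraction 0.5; 0.2 tolerates sampling
   noise at 20–50 reads while rejecting homozygous sites with a few
   erroneous reads.
3. Either RNA allele count 0 → MONOALLELIC and excluded, because the ratio
   is unusable downstream (infinite / zero). An optional pseudocount mode
   adds 0.5 to both alleles instead; it is off by default so that default
   output never contains manufactured ratios.

Thresholds are inclusive (M ≥ 2, D ≥ 2) and exposed as config parameters.

### Orientation across SNPs

Multiple SNPs of one transcript must be averaged with a consistent allele
in the numerator, but short-read data gives no phase. Each SNP is oriented
by its most informative fraction: among the SNP's passing ratios, the one
with the largest |ln r| decides, and if that ratio is below 1 the SNP is
inverted in every fraction simultaneously. The alternative of always
anchoring on the cytosol fails in exactly the case this analysis exists
for: a variant that acts only on loading leaves the cytosol balanced, so a
cytosol anchor flips each SNP by noise, and with two SNPs per transcript a
mixed flip averages the polysome ratio toward (ρ + 1/ρ)/2 — for a 4-fold
effect that is ≈ 2.1, sitting on the decision threshold. Anchoring on the
strongest fraction keeps flips consistent whenever any fraction carries
signal, while under the global null the flip is shared by both fractions
at each SNP, so the cross-fraction statistic D is unaffected (measured
false-flag rate at depth 200, 2 SNPs/gene: 0 of 1500). Per-SNP joint
inversion leaves both M and D invariant by construction.

Genes with no passing cytosol SNP are skipped (status NO_ANCHOR) rather
than oriented by the polysome alone, avoiding an asymmetric bias between
fractions; the cytosol mean under the null is still biased slightly above
1 by orientation (max(r, 1/r)-type selection), which is why calibration is
asserted on D, not on M.

## Loading profiles

FPKM_i = counts_i · 10⁹ / (length_i · N) with N the effective library
size. Size factors are median-of-ratios: s_j = median_i over all-nonzero
features of counts_ij / geomean_j(counts_ij), rescaled to geometric mean 1;
the effective N_j is the geometric-mean raw total scaled by s_j. Loading
is L = log₂((FPKM_poly + c₀)/(FPKM_cyt + c₀)) with pseudo-FPKM c₀ = 1
bounding dropout features; significance is a two-sided one-sample t-test
of the per-sample L against 0 (the replicate structure is paired by
sample), BH-corrected across features. A degenerate all-zero L vector is
defined as p = 1. Under a simulated null (λ = 1, 2000 features) the
p-values are uniform within Kolmogorov distance 0.05, which is what the
BH step assumes.

The χ² comparison of two classes' L distributions uses 20 equal-width bins
over the pooled range, merged left-to-right until the smaller group's
expected count is ≥ 5 in every merged bin (df = bins − 1, no continuity
correction).

## Isoform usage

Usage f is the isoform's share of the gene's summed FPKM per (sample,
fraction); FPKM (not raw counts) makes f a molar share, insensitive to
isoform length. Δ = f_poly − f_cyt is computed per sample and averaged
before thresholding at |Δ| > 0.20 — an absolute shift of 20 usage points,
not a relative change (a 67% → 31% isoform shifts by −0.36). A strict mode
requires the per-sample criterion in every sample instead; the default
mean mode matches the "consistent across replicates" reading and is less
conservative at 3 samples. The cross with allelic ratios is restricted by
default to major isoforms (usage > 0.5 in either fraction), because a
shared SNP's ratio mostly reflects the major isoform.

## microRNA enrichment

CPM is computed within the small-RNA library of each (sample, fraction) —
small RNAs are sequenced as separate libraries, so whole-transcriptome
totals are not a meaningful denominator. ρ = (CPM_poly + pc)/(CPM_cyt + pc)
with pc = 0.5 bounding zero counts. A microRNA is ENRICHED when ρ > 1 in
every sample, DEPLETED when ρ < 1 in every sample, MIXED otherwise; only
consistent microRNAs are ranked (by geometric-mean ρ, ties broken on id).
The Mann–Whitney U test compares the per-sample CPM values of the two
fractions: exact by full enumeration of C(n+m, n) group assignments with
midranks for ties when n + m ≤ 16 (at 3 vs 3 samples this is 20
arrangements, so the smallest attainable two-sided p is 0.1), otherwise
the normal approximation with tie and continuity correction.

## Rényi divergence and clustering

D_α(p‖q) = (1/(α−1)) ln Σ p^α q^{1−α} in nats, summed over the joint
support; empty joint support, or α > 1 with p-mass outside q's support,
gives +∞. Default α = ½: symmetric, finite under partial support overlap,
and the obvious choice when the order is otherwise unconstrained. Profiles
are compared at maximum-likelihood proportions with no smoothing by
default (an optional +0.5 per category is available but off, so defaults
are visible in the config). Bootstrap CIs resample both profiles from
Multinomial(N, p̂) at the observed totals and take the percentile interval,
widened to include the point estimate — every resampled divergence of two
identical profiles is positive while the observed value is 0, and an
interval excluding its own point estimate is not a useful summary.
Infinite replicates are retained (they sort to the upper tail). Clustering
is scipy agglomerative linkage (UPGMA default) after capping infinities at
1.5× the largest finite off-diagonal entry; trees are exported as Newick
via scikit-bio.

## The synthetic-data generator

The generator emulates the count-level structure the analysis assumes, at
the study's stated scale (3 samples, cytosol + pooled ≥3-ribosome polysome
fraction, ~20-read minimum coverage):

- **Sequencing depth**: negative-binomial with mean `depth_mean_rna`
  (default 200 reads/SNP) and size 10 — overdispersed relative to Poisson,
  as RNA-Seq coverage is.
- **Allele counts**: Binomial(depth, p) per SNP with p shared across a
  gene's SNPs (perfect phasing inside the simulator; phasing ambiguity is
  the analysis module's problem). gDNA is Binomial(depth, 0.5). Genes are
  split deterministically (seeded permutation, rounded counts) into null
  (p_c = p_p = 0.5), expression-AEI (p_c = p_p = ρ_e/(1+ρ_e), default
  ρ_e = 2) and loading-AEI (p_c = 0.5, p_p = ρ_l/(1+ρ_l), default ρ_l = 4);
  keeping the loading group's cytosol exactly balanced lets the D statistic
  isolate the loading effect.
- **Expression**: gene means lognormal (median 300 counts, σ = 1); polysome
  mean multiplied by a class-dependent λ (log₂ λ normal with mean 0 for
  protein-coding, −1 pseudogene, −0.5 antisense, −1.5 lincRNA, −2 other
  lncRNA, sd 0.5), reproducing the direction of noncoding depletion on
  polysomes. Per-sample lognormal noise is wider in the cytosol (σ = 0.4)
  than on polysomes (σ = 0.1): polysomal occupancy is modeled as the more
  tightly regulated quantity, which is what makes polysome profiles
  cluster more tightly than cytosolic ones.
- **Isoforms**: 1–3 per gene, Dirichlet(5) usage; a shifted gene moves δ
  (default 0.3) of usage from its top isoform to the runner-up on
  polysomes. Usage is molar; read counts split multinomially with
  probability ∝ usage × length (lengths uniform 500–3000 b).
- **microRNAs**: lognormal baseline composition; polysome composition
  multiplies in a per-microRNA enrichment factor drawn log-uniformly over
  `mirna_effect_range` (default 0.1–10); library totals NB around 10⁵.
  The target map assigns 5–20 genes per microRNA, biased toward high-λ
  genes for enriched microRNAs.

All draws descend from one seed through named substreams, so identical
parameters give bit-identical datasets and the pipeline's reports are
byte-identical across runs.

What the generator does **not** emulate: reference-mapping bias, RNA
editing, positional/GC coverage bias, correlated noise between fractions,
amplification distortion, isoform-level allelic coupling, and microRNA
target-site mechanics. Passing recovery tests therefore show that the
statistics behave correctly under the stated sampling model — not that
they are robust to alignment artifacts or assay bias in real data.

## Problem sizes and numerical choices

Tests run the generator at a few hundred genes and the calibration suites
at 500 null / 100 effect genes, 200 bootstrap-coverage pairs at N = 5000
with B = 1000 — sizes at which the binomial/multinomial standard errors
are far smaller than the margins being asserted, chosen to keep the suite
fast. Ratios are compared on the natural scale with inclusive thresholds;
ties in rankings break lexicographically; UPGMA tie-breaking follows
scipy's deterministic ordering. Degenerate inputs (all-zero columns,
single-isoform genes, empty groups) are either defined explicitly (p = 1
for an all-zero L vector; Δ = 0 for single isoforms) or rejected with a
named error, never silently imputed.

## Known limitations

- AEI magnitudes from the cytosol mean are slightly inflated under the
  null by orientation; use D, which is calibrated, for cross-fraction
  claims.
- With 3 samples the per-microRNA exact U test cannot reach p < 0.1;
  ranking, not the p-value, carries the information at this design size.
- The analysis consumes a microRNA→target map; it does not predict
  targets.
- Counts are taken as given: alignment, deduplication and allele counting
  are upstream of this package.
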