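# Methods

`haploscan` analyzes diploid genotype panels sampled from multiple
populations along an environmental gradient. Its goal is to find large
structural-variant haploblocks, test whether their arrangement frequencies
form latitudinal clines beyond what drift explains, scan the genome for
local adaptation and native/invaded divergence, quantify how strongly
haploblocks are enriched among scan outliers, and estimate degeneracy-based
genetic load. This note records the models, the tunable parameters that
matter, and the design choices made where the design was genuinely open.

## Haploblock detection

**Model.** A segregating megabase-scale structural variant (typically an
inversion) suppresses recombination between its two arrangements, so SNPs
inside it behave like alleles of one locus. In a window-by-window PCA the
affected windows show sample structure driven by arrangement genotype
rather than by geography, and samples fall into three PC1 clusters:
arrangement homozygotes at the ends, heterokaryotypes in the middle with
elevated SNP heterozygosity.

**Procedure.** Genotypes are mean-imputed (only inside covariance
computations — never for frequency estimates) and a samples x samples
covariance matrix is computed per 100-kbp window (`window_size`, default
100,000 bp; windows with fewer than `min_sites` = 20 SNPs are excluded;
50 is available for denser data). Window dissimilarity is the Frobenius
norm of the difference of rank-k (k = 2) trace-normalized covariances —
trace normalization removes window-to-window diversity differences, the
rank truncation keeps only the leading structure. Windows are embedded by
classical (Torgerson) MDS on 5 axes with deterministic sign fixing. For
every axis pair and each diagonal direction (±1, ±1)/√2, windows whose
projection exceeds the 1 − `tail` (default 0.05) quantile are corner
outliers. Same-corner outlier runs (gap ≤ `max_gap` = 1 analyzed windows,
length ≥ `min_windows` = 3) become candidate regions; overlapping
candidates from different corners are unioned, replacing the manual
curation step such analyses traditionally use.

**Genotyping.** Candidates are genotyped by 1-D 3-means on PC1 scores
(centers initialized at min/median/max). Two guards replace visual
inspection: a sample farther than `assign_frac` (0.25) x PC1-span from its
center is left unassigned, and the call is rejected as non-trimodal when
the gap between adjacent cluster centers is below `min_separation` (6.0)
pooled within-cluster SDs. The threshold was calibrated on the two regimes
it must separate: 3-means applied to unimodal Gaussian scores never
exceeded ~4 pooled SDs (n = 40–200), while genuine arrangement clusters
from the generator sit at 20+. Arrangement "A" is the globally more
frequent one, so cline signs are comparable across runs.

**Validation.** A call is *confirmed* when the heterozygosity criterion
passes: mean ± SEM of per-sample heterozygosity in the heterokaryotype
class is disjoint from both homozygote intervals and highest. Classes with
fewer than 2 samples make the test inconclusive rather than failed. An LD
diagnostic is also reported — the drop in median pairwise r² between all
samples and the major-homozygote subset, with pass threshold δ = 0.2 — but
it is not required for confirmation: δ is a package convention, and in the
synthetic data LD between non-marker SNPs is absent by construction (see
below), which dilutes the region-wide median.

## Clines and parallelism

Arrangement (or SNP) dosages are modeled per individual as Binomial(2)
with logit(q) = β0 + β1·|latitude|, fit by vectorized IRLS. Perfect
separation is detected through saturation of the linear predictor and
refit with a ridge of 10⁻⁶, flagged `separation`. Significance is not
asymptotic: a unit is significant when its slope falls outside the
two-sided 5% cutoffs (2.5% per side) of slopes from 10,000 SNPs sampled
outside genes and haploblocks. Those SNPs carry the same drift covariance
as the tested unit, so the empirical tail calibrates the test under
population structure; on fresh null SNPs the type-I error is 5% within
binomial error. The two-sided reading was chosen because parallelism needs
signed directions; a one-sided mode is available. A unit is *parallel*
when ≥ 2 ranges are significant with the same sign. A joint
range × |latitude| GLM with interaction is available; the interaction is
dropped when its likelihood-ratio p ≥ 0.05.

## Genome scans

Population allele frequencies (populations with n ≤ 2 excluded) are
standardized per SNP, p̃_j = (p_j − p̄)/√(p̄(1−p̄)), and their J × J
covariance Ω is estimated from 10,000 background SNPs, shrunk toward its
diagonal with weight 0.05. The shrinkage is what makes Ω invertible:
centering on the across-population mean forces Σ_j p̃_j ≈ 0, so the raw
covariance is singular.

* **XtX\*** = (J/(J−1)) · p̃ᵀ Ω⁻¹ p̃. The J/(J−1) factor is a
  degrees-of-freedom bias correction for estimating the ancestral
  frequency by the across-population mean; with it the null mean equals J,
  the convention used for XtX-style statistics. Without it the null mean
  is ≈ J−1.
* **Contrast C\*** = (cᵀp̃)²/(cᵀΩc) with c = (1/J₁, …, −1/J₂, …). No dof
  correction is needed: c is orthogonal to the all-ones direction that the
  centering removes. Under the null C* is χ²(1) to KS-test accuracy at
  10,000 SNPs.
* **EAA** is Kendall's τ-b between population frequencies and an
  environment variable (≥ 4 populations required).
* **Fay & Wu's H** = θ_π − θ_H over the unfolded SFS of polarized,
  fully-called sites, at fixed chromosome count n; sites with missing
  genotypes or unknown ancestral state are excluded and counted.
* **GWAS** regresses the phenotype on dosage plus the top 2 PCs of a
  background-SNP covariance matrix (partial-correlation t-test).

These moment-based statistics are deterministic surrogates for the
hierarchical-MCMC posteriors some pipelines use; outputs label them
surrogates so the two are not conflated.

Per-SNP statistics become empirical p-values by genome-wide rank
(rank/(N+1), never 0) and are aggregated in 10-kbp nonoverlapping windows
(100 kbp in the examples, matching their SNP density) by the weighted-Z
scheme: z_i = Φ⁻¹(1−p_i), weights w_i = p̄_i(1−p̄_i),
Z_W = Σw_i z_i/√(Σw_i²). The mean across-population frequency is used for
the weights; published weighted-Z variants differ here and the choice is
configurable. Windows with < 2 usable SNPs are flagged and excluded from
ranking. Outlier tails are presets per scan: 5% (XtX/EAA), 1% (contrast),
0.1% (GWAS).

## Enrichment

All enrichment works at the window level. A window belongs to a haploblock
when its midpoint falls inside the interval (an overlap-fraction rule is
available). Enrichment of outlier windows in a haploblock is upper-tail
hypergeometric, Bonferroni-corrected across the haploblocks tested;
overlap between outlier sets from two scans uses the same machinery. The
distributional shift of haploblock vs non-haploblock window scores is a
two-sided Mann–Whitney U with 0.05/0.01/0.001 star coding.

## Degeneracy and load

A coding position is zero-fold degenerate when all three substitutions
change the amino acid (substitutions creating a stop count as changes —
they are nonsynonymous in effect), four-fold when none does. CDS segments
are assembled in translation order, the initial phase trimmed, minus-strand
codons read from the reverse complement; transcripts whose CDS length is
not a multiple of 3 after phase are skipped with a warning, and sites whose
class conflicts between overlapping transcripts are "ambiguous".

Load is the mean derived-allele frequency per group and class, with each
group first downsampled without replacement to the smallest group's size so
unequal sampling cannot bias the means. Sites with unknown ancestral state
are excluded — polarization is an input, not something the package infers.
Confidence intervals use a 20%-of-sites subsampling bootstrap, 100 reps,
2.5/97.5 percentiles. This subsampling scheme is deliberately conservative
(rep means are noisier than the full-sample mean); a classical
full-resample bootstrap is available as a non-default option.

## The synthetic cohort

The generator produces exactly the structure the detectors assume, and no
more:

* Neutral background: per SNP, ancestral frequency π ~ Uniform(0.05, 0.95);
  population frequencies Beta-distributed around π with drift intensity
  F = 0.1 (Balding–Nichols); Hardy–Weinberg dosages. SNP positions are
  uniform; sites are unlinked.
* Haploblock: each sample draws an arrangement genotype from a logit-linear
  cline (default slope 0.1/degree, anchored so frequency runs 0.1 → 0.9
  over the default 10–54° latitude span). Marker SNPs (150 per block) equal
  the arrangement dosage except with probability ε = 0.02, when they are
  resampled uniformly from the two other dosage values — making
  heterokaryotype marker heterozygosity exactly 1 − ε.
* Ranges are interleaved along the gradient (native, invaded-1, invaded-2,
  …) so every range spans the gradient and per-range clines are estimable.
* Traits: y = a·g_hb + Σ b_k g_k + e with a = 1, 100 polygenic background
  SNPs (effect SD 0.05), residual SD 1.
* Coding contig: toy genes with random stop-free CDS, alternating strand,
  one multi-exon gene with phase 2 on its downstream segment; truth
  degeneracy computed during construction by exhaustive codon-substitution
  enumeration. Load genotypes draw derived frequencies Uniform(0.05, 0.5),
  multiplied by 0.3 at zero-fold sites to emulate purifying selection.

Default scale: 10 populations × 20 diploids, 2 chromosomes × 20 Mbp,
20,000 background SNPs, one 2-Mbp haploblock. This runs in ~3 s per
cohort, so the test suite exercises 20 independent seeds for detection,
false-positive control and load separation; load cohorts use a compact
config (6 populations × 10, 12 genes) since only the coding contig
matters there.

**What passing tests do not show.** The generator has no linkage outside
haploblocks, no recombination gradient, no missing data by default, no
genotype uncertainty (hard calls, not genotype likelihoods), and no real
demography beyond symmetric drift. Detection power and false-positive
behavior on low-depth, LD-rich real data can differ; in particular the
corner-outlier sensitivity under hard-call substitution for
genotype-likelihood covariance has not been measured here.

## Numerical conventions

Internal coordinates are 0-based half-open; VCF positions convert at the
boundary. Missing dosages are −1; they are mean-imputed only for
PCA/covariance work. Multi-allelic sites are dropped, not split. Ancestral
state resolution: sidecar table > configured INFO tag > unknown. MDS axis
signs and PC1 signs are fixed by largest-magnitude loading, k-means is
deterministically initialized, and every sampling operation takes a seed,
so identical inputs give identical outputs.

## Known limitations

Breakpoints are window-quantized (±100 kbp at default settings); the
caller does not classify inversion vs deletion vs complex variants;
the moment surrogates approximate but do not reproduce hierarchical
Bayesian posteriors; arrangement frequencies near 0 or 1 leave too few
heterokaryotypes for the heterozygosity criterion, which then reports
inconclusive rather than confirming.
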