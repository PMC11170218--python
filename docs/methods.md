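# Methods

## Scope and data model

The package operates downstream of whole-genome alignment, SV calling and
genotyping: its inputs are annotation tables, genotype VCFs, SNP VCFs,
bedGraph tracks and sample metadata. All intervals are normalized on read to
0-based half-open coordinates; 1-based inclusive dialects (SyRI tables,
GFF3, VCF POS) are converted at the boundary and restored on write, so all
overlap and length arithmetic uses one convention.

Diploid genotypes are stored as counts of the alternate arrangement per
sample: 0, 1, 2, or missing. Half-calls (`./1`) are treated as missing:
an unresolved short-read genotype carries no trustworthy allele count.
Missing calls shrink denominators everywhere; nothing is imputed.

## Per-population status and SD/SP/SSP classification

For one SV in one population, the carrier-allele frequency is
Σ genotypes / (2 × genotyped samples). Status is ABSENT at frequency ≤ t,
FIXED at ≥ 1 − t, else POLYMORPHIC, with `fixed_tolerance` t = 0 by default:
"fixed" means every genotyped allele carries the arrangement. A tolerance
flag (e.g. 0.02) allows near-fixed calls, since sequencing error can break
exact fixation in large samples. SVs genotyped in fewer than `min_alleles`
(default 10) alleles are UNRESOLVED rather than risk a confident
misclassification from a handful of chromosomes.

Symmetric SVs (inversions, translocations) are genotyped in population A
against reference A — where ALT is the genome-B arrangement — and in
population B against reference B, where ALT is the genome-A arrangement.
Harmonization expresses both in one polarity: p_B-in-A passes through,
p_B-in-B = 1 − freq(B vs ref B). A single-reference mode passes both
through unflipped. The decision table on the harmonized statuses:

| status in A \ in B | ABSENT | POLYMORPHIC | FIXED |
|---|---|---|---|
| **ABSENT** | private/artifact (both-absent) | SP | SD |
| **POLYMORPHIC** | SP | SSP | SP |
| **FIXED** | SD (polarity-inverted) | SP | private/artifact (both-fixed) |

Either population UNRESOLVED makes the SV UNRESOLVED. The
(FIXED, ABSENT) cell — each reference carrying the arrangement its own
species lacks — is kept as SD with a raised `polarity_inverted` flag rather
than silently merged, and the private/artifact cell carries a sub-label
(`both_absent` / `both_fixed`), because both cases are diagnostically
interesting: they point at reference-individual private alleles or
assembly/scaffolding errors. Duplications and unaligned regions are
asymmetric and receive only per-host-genome status and spectra, never an
SD/SP/SSP category.

## Linkage

The all-individuals 0/1/2 matrix pools both populations after flipping
population-B calls into genome-B polarity. Correlation is Pearson over
pairwise-complete samples (minimum 3 shared, configurable): listwise
deletion would discard most of a matrix with scattered missingness, and the
pairwise estimate is exactly what a direct per-pair recomputation on the
shared samples gives (a property the tests assert to 1e−12). Pairs where
either column is constant on the shared samples have undefined correlation
and are dropped. Linked means R² ≥ 0.6, threshold inclusive. Physical
separation is the gap between the two intervals (0 when they overlap or
abut), not a midpoint distance; cross-chromosome pairs have no separation.

## Fixation index

The two-population Weir & Cockerham (1984) θ is implemented directly from
the variance components (a: among populations, b: among individuals within
populations, c: within individuals), with observed heterozygote proportions
from the genotype counts. θ is undefined when a+b+c = 0 (monomorphic
across both populations) and is **not** clamped: slightly negative
estimates near zero differentiation are retained so region averages stay
unbiased. A fixed difference with no heterozygotes gives θ = 1 exactly.

Two multi-locus summaries are provided: the conventional weighted
(ratio-of-sums) estimate Σa / Σ(a+b+c), and the unweighted mean of per-SNP
θ. The weighted form is the standard multi-locus estimator and is nearly
unbiased — on Balding–Nichols data with F = 0.1 it recovers 0.095–0.107
across seeds — while the unweighted mean is pulled toward zero by
low-information SNPs (≈ 0.085 under the same conditions). Calibration
checks therefore use the weighted form.

## Per-region aggregation and contrasts

SNP density counts a SNP at `pos` for region [start, end) iff
start ≤ pos < end; overlapping regions each count it. Region means of the
windowed ρ track weight each window's value by its base-pair overlap with
the region (a whole-window mean is available by flag; the overlap weighting
is invariant to splitting a window into contiguous equal-valued halves).
Region means of per-SNP θ are unweighted over informative SNPs; undefined
θ values are excluded rather than zero-filled, which would bias
differentiated regions toward zero. Regions with nothing informative are
undefined and excluded downstream.

Region selection before the contrasts keeps SVs classified as fixed
differences (SD; optionally also both-fixed private calls) with length
≥ 2,000 bp, and genes/TEs by length only. Low-frequency arrangements cannot
leave a detectable population footprint, and events shorter than the 1-kb
track window contribute mostly noise.

Contrasts are one-way fixed-effects ANOVA followed by Tukey–Kramer HSD for
unequal group sizes on the studentized-range distribution with df = N − k,
with syntenic regions as the reference level; per-group 95% CIs of the mean
use the t distribution. Groups with fewer than two finite values are
excluded with a logged notice; an all-constant input is flagged degenerate
instead of raising. `compute_pairwise=False` skips the pairwise step when
only the omnibus test is needed (the studentized-range quantile costs tens
of milliseconds per call, which matters in replicate loops). The
implementation is checked against the plasma etch-rate worked example of
Montgomery's *Design and Analysis of Experiments* (four RF power levels,
five wafers each: F = 66.80, all six pairwise differences significant at
α = 0.05, smallest pair p_adj = 0.0294) and against statsmodels'
`pairwise_tukeyhsd` on unbalanced data.

## QC and site filters

Sample filters remove, in fixed order with one reason per sample: coverage
< 10×, alignment < 75%, then the PCA-outlier flag (emulating hybrid/
mislabeled-sample removal). Site filters remove sites carried by < 10% of
genotyped samples, sites with summed alternate-supporting read depth < 20
across carrier samples (a per-carrier-sample mode is available; summed is
the default reading of "fewer than 20 supporting reads"), and indels/
multiallelic records. All boundaries are strict: values exactly at a
threshold are kept. Genome-composition proportions divide per-type region
totals by the scaffolded portion of the assembly (assembly length ×
fraction-in-scaffolds), the denominator consistent with the accounting the
inputs use; a flag restores the raw assembly length.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process:

* **SNPs** — ancestral frequency p ~ Uniform(0.05, 0.95); each population's
  frequency is an independent Beta(p(1−F)/F, (1−p)(1−F)/F) draw
  (Balding–Nichols; F defaults to 0.1 and equals the expected fixation
  index); genotypes are Binomial(2, p_pop) under Hardy–Weinberg; per-call
  depths are Poisson(15.4), matching the mean sample coverage of the kind
  of study emulated. Independent Beta draws share no lineage beyond the
  ancestral frequency: this is drift calibration structure, not a
  coalescent, and it carries no linkage disequilibrium between SNPs.
* **SVs** — each symmetric SV draws true frequencies from its category:
  SD → (0, 1); SP → one frequency in (0.1, 0.9), the other 0 or 1;
  SSP → both in range; private/artifact → (0, 0) or (1, 1). Default counts
  per symmetric sv_type are SD 2, SP 31, SSP 11, private 81 — the category
  proportions a recently diverged species pair shows at desk scale
  (divergences rare, most alignment-predicted events unsupported).
  Genotypes are binomial per sample; missingness is i.i.d. at 20%,
  mirroring ~80% genotyping success. Asymmetric events (duplications,
  unaligned) are genotyped only in their host population, mostly fixed,
  the remainder high-frequency. An optional linked-block mode copies one
  latent carrier draw across k SSPs so positive linkage recovery is
  testable; block members' recorded truth frequencies are then those of
  the first member, by design.
* **Layout** — features are placed non-overlapping along a toy genome
  (default 2 × 3 Mb) with syntenic gaps; feature lengths are 2–8 kb so the
  ≥ 2 kb selection keeps them. Non-overlap makes the ρ-track midpoint
  attribution unambiguous.
* **ρ track** — 1-kb windows valued rho_base × effect(region type at the
  window midpoint) × mean-one lognormal noise (σ = 0.1), with
  rho_base = 0.05 and effects above the syntenic baseline for genes (2.0),
  TEs (1.8) and duplications (1.5), below it for translocations (0.8) and
  unaligned regions (0.7). A region's expected mean is exactly
  rho_base × effect, recorded in the truth table.
* **Samples** — coverage Uniform(10.0, 48.7)×, alignment Uniform(78,
  98.8)%: the reported ranges of the emulated study, so default samples
  pass QC.

Every stage derives its own generator from the single seed via named
substreams, so stages are independently reproducible and one seed fixes
every output byte. Emitted files are read back by the package's own
parsers in the test suite (self-consistency), and the end-to-end recovery
checks run at 100 diploids per population with 500 SVs.

What passing these tests shows — and does not. Recovery of categories,
frequencies, and F is demonstrated under the generator's assumptions:
unlinked SNPs, binomial genotype sampling, unbiased genotyping,
missingness independent of genotype. Real short-read SV genotyping has
genotype-correlated failure (the study's own motivation for caution with
unaligned regions), reference bias, and LD structure; performance there is
not established by these fixtures.

## Numerical choices

* Correlation, θ and region means are float64 throughout; the linkage
  oracle agreement is asserted at 1e−12.
* θ undefined (NaN) propagates by exclusion, never as zero.
* Tukey adjusted p-values are capped at 1.
* Frequency-spectrum binning follows numpy histogram semantics (last bin
  closed on the right so frequency 1.0 is counted).
* The SyRI parser keeps top-level records and drops nested alignment
  records by default (`keep_nested` retains them), since composition
  accounting is over blocks, not their internal alignments.

## Known limitations

* Two populations only; the θ estimator is the two-population special case.
* No haplotype-based LD (D′) and no SNP–SV LD; linkage is genotype
  correlation only.
* The generator's toy genomes are collinear apart from annotated events;
  translocations do not actually move sequence between coordinates.
* ANOVA/Tukey assume exchangeable per-region means within a type; spatial
  autocorrelation along chromosomes is not modeled.
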