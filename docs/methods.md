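# Methods

This note documents the models, conventions and numerical choices behind
`ploidosage`, and what the synthetic-data tests do and do not demonstrate.

## Genomotypes and abundances

A genomotype is a genome composition over the two parental haplomes P and A
(`GenomotypeSpec`); ploidy is the sum of haplome copy numbers. Abundances
are FPKM, `count · 10^9 / (length_bp · total_mapped_fragments)`; FPKM and
RPKM are treated as the same fragment-based quantity, and the formula takes
whatever fragment total the caller supplies (pairs plus singletons is the
convention of the upstream counting used in the motivating study design).
Expression tables are per-library; gene identifiers are opaque strings, and
tables from different annotation universes (de novo unigenes vs genome-mapped
gene ids) are never merged.

## Ratio profiles

Fold changes divide numerator FPKM by denominator FPKM for every shared
gene. Zero abundances have no published convention, so the default policy
excludes genes with a zero on either side (the only choice that keeps fold
changes finite without inventing a pseudocount magnitude); a pseudocount
mode (default shift 0.5 FPKM) is available in `AnalysisConfig`. The profile
median uses the midpoint convention for even n. Both chi-square forms omit
the Yates continuity correction: at the count magnitudes of interest
(tens of thousands) it is irrelevant, and the uncorrected statistic is the
classical formula. The goodness-of-fit test is the default for a single
lower/higher split; the 2x2 form compares two splits.

## Dosage classes

SE is strict: `|log2 R| < t` with `t = 1` by default. Class boundaries
(0.75, 1.25, 1.75) partition the SE band. Published interval notation
leaves the boundary points themselves unassigned — measure-zero for
continuous data but real for rounded inputs — so class I is closed
`[0.75, 1.25]` and class II half-open `(1.25, 1.75]`, biasing ties toward
the compensated/dosage-sensitive labels. Both the SE threshold and the
boundaries are configurable, with a validity check that the boundaries lie
strictly inside the SE band.

## Differential expression

With one library per genomotype there is no replication to estimate
biological dispersion, so the per-gene p-value is a two-library exact
binomial test: conditional on the total count `n = n_A + n_B`, `n_A` is
Binomial(n, s) under the null, with `s` the numerator library's share of
the combined library size. Two-sidedness sums the probabilities of all
outcomes no more likely than the observed one (the "minimum-likelihood"
rule); both counts zero returns p = 1. This is a deliberately simple
engine whose absolute calls should not be compared against
dispersion-modelling DE tools; the pipeline's specified element is the
correction that follows.

FDR correction is the Benjamini–Yekutieli step-up, valid under arbitrary
dependence between tests (gene-level tests on a single pair of libraries
are strongly dependent): `q_(i) = min_{j>=i} min(1, p_(j) · m · c(m) / j)`
with `c(m) = Σ_{k=1..m} 1/k`. It dominates Benjamini–Hochberg pointwise.
DE requires `q <= 0.05` by default; SE and DE are computed independently —
a gene may be neither.

Reported percentages round half away from zero: per-class and per-group
shares to integers, DE share of the total to one decimal.

## Additivity

The hybrid expectation is the copy-weighted half-sum of the parental
diploid values, `E = (c_P·PP + c_A·AA)/2` — each haplome copy contributes
half of the corresponding diploid's output. This reduces to `PP/2 + AA/2`
for PA and `PP/2 + AA` for PAA, and degrades sanely for the parental forms
themselves (`E_AA = AA`). The additive window is strict,
`-1 < log2(obs/E) < 1`. When observed or expected is zero the log ratio is
infinite; no finite category assignment would be principled, so such genes
are `undefined` and excluded from percentage summaries. The
under- vs over-expressed imbalance among non-additive genes is tested with
the same 1-df goodness-of-fit chi-square as the ratio profiles.

## Genome-normalized qPCR and transcriptome size

Amplification efficiency is fixed at 2 (pure Livak `2^-ΔΔCq`); no
per-target efficiency calibration is modelled. Each sample's
`ΔCq = mean target cDNA Cq − mean reference gDNA Cq`; averaging reference
Cqs arithmetically on the log (cycle) scale is exactly geometric-mean
normalization of the linear quantities. ΔΔCq is the difference of
genomotype mean ΔCqs (not a mean of pairwise ratios, matching standard
Livak practice); per-sample relative quantities are retained only for the
reported SD. Because genomic DNA from the same extraction is the
normalizer, the resulting quantity is expression per genome; multiplying by
the ploidy ratio (3/2 for PAA/PA) gives expression per cell, and dividing
by the RNA-seq per-transcriptome ratio gives the relative transcriptome
size. One-sample t-tests (two-sided; sidedness is a convention choice)
compare the per-gene size ratios against 1.5 and 1.0. Outlier screening
uses Tukey hinges — medians of the lower/upper halves with the overall
median included in both halves for odd n — and 1.5-IQR fences. Zero sample
variance with a mean off the null returns p = 0 with a warning; n < 2 is
an error. Reported one-decimal values round half away from zero.

## Synthetic data generator

The generator emulates the study structure: four genomotypes with one
RNA-seq library each, and a qPCR plate with 5 biological x 3 technical
replicates per genomotype, six cDNA targets and three gDNA reference
targets.

* AA abundances are log-normal (`baseline_log_mean = 2.0`,
  `baseline_log_sd = 1.2` in natural-log units, giving a median around
  7 FPKM with a realistic right tail). PP is AA times `2^δ`,
  `δ ~ N(0, 1)` log2 units of parental divergence.
* PA is the exact mid-parent value; PAA is either the exact additive value
  (for `additive_fraction` of genes) or PA times a true fold change drawn
  log2-uniformly inside the assigned class interval. Class draws sit a
  1e-3 margin inside the classification boundaries so floating-point
  round-trips cannot flip a boundary gene; `DE_up`/`DE_down` labels draw
  `|log2| > 1.05`; any unallocated remainder draws uniformly across the SE
  band. The default mixture (I:II:III:IV = 45:17:34:4) matches the
  whole-body juvenile class proportions of the study system.
* Measurement noise is independent per-library multiplicative log2-normal
  (`measurement_log2_sd = 0.2` by default), applied last. Counts are
  derived from noisy FPKM by inverse-FPKM rounding against the configured
  library sizes (20 M fragments per library).
* qPCR wells get independent Gaussian Cq noise (`cq_noise_sd = 0.15`
  cycles); with zero noise the Livak estimate equals the configured true
  ratio exactly. Default true per-genome ratios are the study-like values
  (0.6–0.9).

What the generator does **not** emulate: biological replication of RNA-seq
libraries, count overdispersion, gene-length or GC bias shared across
libraries, per-target amplification efficiencies, or biological
replicate-to-replicate variation in qPCR beyond well noise (so `sd_ratio`
on simulated plates reflects technical noise only). Passing tests on this
generator demonstrate the correctness of the arithmetic and the estimators'
statistical behavior under the stated noise models, not performance on real
libraries.

Two behaviors of the full system under the default noise levels are worth
stating explicitly, because they are properties of the design rather than
implementation defects:

* **Class-boundary diffusion.** Independent per-library log2 noise σ gives
  the PAA/PA log2 ratio noise σ√2 (≈ 0.28 at σ = 0.2), comparable to the
  class widths (0.49–0.74 log2 units). Noisy class tallies therefore
  deviate from the generated mixture by several percentage points (net
  flux across each boundary is proportional to the density difference on
  its two sides), and ~9% of SE genes diffuse out of the SE band
  altogether. Only noise much smaller than the class width preserves
  tallies to within sampling error.
* **Correlated size estimates.** All cDNA targets in a sample are
  normalized against the same gDNA reference wells, so the per-gene
  transcriptome-size estimates share a common error component. The
  one-sample t-test across genes assumes independent estimates and
  therefore over-rejects a true null (measured ≈ 19% rejection of a true
  size 1.0 at nominal α = 0.05 with the default plate). The test against
  1.5 is unaffected in practice because the effect size is enormous.

## Pipeline and reproducibility

Stages are independently invokable; the full pipeline is their composition
and skips (with a logged reason) any stage whose inputs are missing. The
run manifest records the tool version, a config hash, input/output SHA-256
digests and per-stage record counts; the report digest is computed over
stage content only, so reruns on identical inputs are digest-identical
regardless of timestamps. All simulation randomness derives from a single
integer seed through spawned `numpy` seed sequences; identical seed and
config produce byte-identical output files.

## Problem sizes

Default test and demonstration runs use 20 000 genes (the order of a
vertebrate gene count and of the genome-mapped liver dataset), 200
simulation replicates for recovery checks, and the 5x3x(6+3) plate layout
throughout; these sizes make every distributional claim in the test suite
measurable while keeping runs on a laptop-scale machine short.
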