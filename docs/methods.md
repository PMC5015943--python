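# Methods

## Phenotype derivation

The unit of analysis is one mouse × session dose–response series: Penh
values at methacholine doses 0, 3.1, 6.2, 12.5, 25 mg/ml (the default
protocol grid; any strictly increasing grid starting at 0 is accepted).
Derivation proceeds per mouse:

1. **Baseline averaging.** The two baseline replicate sessions are averaged
   dose-by-dose. Doses present in only one replicate (after truncation)
   keep the available value; a single available replicate is used as-is.
   Replicates must share at least two doses.
2. **Percent-control normalisation.** Each response is divided by the
   dose-0 response and multiplied by 100, so the series starts at exactly
   100. A missing or non-positive dose-0 value makes the phenotype
   undefined (flagged, never an exception escaping the pipeline).
3. **Quadratic fit.** Ordinary least squares of percent-control on
   (1, d, d²), the dose-0 anchor included as an ordinary point. Three
   points saturate the model (RSS = 0); two points fall back to a line;
   fewer leave the phenotype undefined. Duplicate doses within a session
   are averaged before fitting.
4. **Inversion.** PC₁₅₀ is the smallest positive real root of
   `fit(d) = 150`, accepted only up to `extrapolation_cap × max_dose`
   (default 2 × 25 = 50 mg/ml). Root selection rationale: the provocative
   concentration is the first dose at which the animal crosses the
   threshold. With no admissible root the animal is "unresponsive".
5. **Linear fallback.** Only when the quadratic admits no admissible root
   *and* the least-squares line through the same points has positive slope
   with an admissible root, the linear root is used and the series is
   flagged. This mirrors the occasional concave series that flattens below
   threshold under a quadratic but clearly trends across it.
6. **Delta.** `delta = baseline − final` in mg/ml; positive = allergen
   increased responsiveness; negative values are retained.

The threshold parameter (percent-control, default 150) trades phenotype
spread against definability: raising it widens the distribution but makes
more animals' values uncomputable. Raising the threshold never lowers a
defined PC value (monotonicity, property-tested).

**Transform choice.** A Box–Cox profile over λ ∈ [−2, 2] with a 95 %
likelihood-ratio region is reported as a diagnostic. The pipeline applies
ln to baseline and final PC₁₅₀ and identity to delta regardless of the
profile — the standard choice for these phenotypes — so the diagnostic
informs but does not silently change the analysis.

**Lung resistance.** Invasive resistance recordings (one value per 2-sec
cycle over a 3-min window per dose) are collapsed to per-dose means and fed
through the identical percent-control/PC₁₅₀ machinery; a Welch two-sample
t-test contrasts two strains' resistance PC₁₅₀ values.

## Genome scan

The additive model regresses the transformed phenotype on the n×8 expected
founder-dosage matrix plus an intercept, marker by marker. Because dosage
rows sum to 2, the intercept is exactly collinear with the dosage columns;
each marker design is therefore reduced to an orthonormal basis of its
column space (SVD with a rank cut at `s₀·n·eps`), which fixes the residual
sum of squares — and hence the Gaussian maximum-likelihood LOD
`(n/2)·log10(RSS₀/RSS₁)` — without dropping an arbitrary founder. The
marker bases are cached, so a permutation scan is a single tensor
contraction; 10⁴ permutations over 500 intervals at n = 150 take seconds.

Numerical choices:

- RSS₁ is floored at `1e-12 × RSS₀`, capping a perfect fit's LOD at
  `6n` rather than infinity; peak locations are unaffected.
- A constant phenotype yields all-zero LOD with a warning; n ≤ 10 is an
  error; missing phenotypes are removed listwise with n reported.
- Peak ties break to the lowest genomic position (first occurrence in map
  order).
- Permutation thresholds use the order statistic of rank
  `ceil(q·(n_perm+1))` from below — the conservative convention — with
  q = 0.95 "significant" and q = 0.80 "suggestive". Permutations shuffle
  the phenotype only; the design stays fixed; collapsed intervals are
  permuted as-is.
- The 1.5-LOD support interval spans the contiguous run of markers within
  1.5 LOD of the peak, extended one marker past the run on each side
  (outer convention, conservative coverage); intervals clipped at a
  chromosome end are flagged.
- Variance explained is the R² of the peak-locus regression, clipped to
  [0, 1].
- Allele effects: centred regression coefficients (pseudo-inverse, with
  standard errors propagated through the centring contrast) plus
  homozygote group means, classifying a mouse as homozygous for founder f
  when its dosage ≥ 1.8 (a declared cutoff; probabilistic dosages have no
  canonical rule). Founders without homozygotes report absent means;
  unclassified mice are counted.
- Adjacent markers with element-wise equal dosage matrices (within a
  tolerance) can be collapsed to single intervals positioned at the run
  midpoint, the usual reduction of a dense SNP map to recombination
  intervals.

## Synthetic studies

The generator emulates the structure of a longitudinal allergen-challenge
study in a partially inbred 8-founder population, with every downstream
quantity known:

- **Mosaic genomes.** Each haplotype is a first-order Markov chain over
  the 8 founder labels along the marker grid; a switch occurs across a gap
  of g Mb with probability `1 − exp(−rate·g)` (default rate 0.05/Mb) and
  draws the new founder uniformly from the other seven, so realized switch
  counts match the Poisson expectation. Residual homozygosity of partially
  inbred animals is modelled by a second two-state Markov mask (stationary
  IBD probability `1 − heterozygosity`, default heterozygosity 0.10,
  segment-coherent); where the mask is IBD the second haplotype copies the
  first. This is deliberately not a pedigree/funnel meiosis simulation:
  the scan consumes dosages, and the Markov mosaic reproduces the features
  that matter to it (block structure, founder balance, partial
  homozygosity) at a fraction of the complexity.
- **Phenotypes.** `ln PC₁₅₀ = intercept + Σ_f dosage_f·effect_f + noise`,
  with centred length-8 effect vectors, bivariate-normal noise linking the
  baseline and final sessions (default sd 0.55 on the ln scale, chosen so
  the population spans roughly two orders of magnitude of PC₁₅₀;
  correlation 0.6 mimicking the strong observed baseline–final
  correlation). QTL are placed at the nearest marker (ties to the lower
  position). When a QTL carries a `target_variance`, its effect vector is
  rescaled after the noise draw so the locus explains *exactly* that
  fraction of the simulated phenotype's variance — the stated study
  condition holds by construction in every replicate, not merely in
  expectation.
- **Penh curves.** Per mouse and session a percent-control curve
  `100 + β₁d + β₂d²` passes through (0, 100) and (PC₁₅₀, 150): β₂ is drawn
  uniformly from a positive range (default 0.05–0.5), β₁ solved from the
  constraint. With β₂ > 0 the positive crossing is unique, so PC₁₅₀ is
  identifiable by construction and the zero-noise pipeline inverts it
  exactly (≤ 1e-6, property-tested). Curves are scaled to raw Penh by a
  per-mouse dose-0 level (uniform 0.3–0.9), and additive Gaussian noise
  (default sd 10 percent-control units) is applied per dose. Truncation
  emulates removal of distressed animals: doses after the first whose
  *noiseless* response exceeds the removal threshold (default 500 %) are
  dropped and the series flagged — applying the rule to the noiseless
  curve keeps removal deterministic per mouse, as the observer reacts to
  the animal, not to measurement noise. Measurement-noise magnitudes are
  calibration knobs of the generator, not estimates of any instrument.
- **Biomarkers.** Lognormal inflammation markers correlated with final
  PC₁₅₀ through a Gaussian copula at Pearson `r = 2·sin(π·ρ_s/6)`, which
  induces the requested Spearman ρ_s. The default panel spans the
  magnitudes typical of allergic-airway-disease studies (ρ from 0.1 to
  about 0.4).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage-disequilibrium structure of real CC
funnels, SNP-level genotyping error and haplotype-inference uncertainty,
instrument-specific Penh noise (heteroscedastic in practice), litter and
batch effects, and any kinship structure (the scan is a fixed-effects
model by design, matching its intended use).

## Downstream statistics

Per-strain summaries (mean/SE of baseline, final, delta) with paired
two-sided t-tests on pairwise-complete data (df = n_pairs − 1), a pooled
"population" row; one-way fixed-effects ANOVA computed from explicit sums
of squares so degenerate inputs behave sensibly (equal group means → F = 0)
with p from the F distribution; Spearman correlations (average-rank ties)
using the t approximation for n ≥ 8 and full permutation enumeration below
that; Welch's t for the two-strain resistance contrast (the variance-equal
assumption is not defensible for 2 small groups of different strains). Raw
p-values are reported without multiplicity correction, matching the
descriptive role of these tables.

## Problem sizes and determinism

The default study size is 150 mice over 5 × 100 intervals with 200–1000
permutations; the test fixtures use 20 mice × 50 intervals (tiny) and the
full default (demo). Calibration checks use 100 replicate simulations at
200 permutations, and interval-coverage checks 100 replicates at n = 150 —
sizes at which the binomial error of the checked rates is a few percent.
Every random stage draws from a seed derived from the run seed via
`numpy.random.SeedSequence`; identical configs rerun byte-identically
(manifest checksums are compared in the tests).

## Known limitations

- The linear-fallback criterion (quadratic rootless + positive linear
  slope with admissible root) is a declared convention; borderline concave
  series near the threshold are sensitive to it. Every use is flagged.
- The extrapolation cap (2× top dose) is a convention for calling animals
  unresponsive; published analyses rarely state theirs.
- Whether published quadratic fits include the dose-0 anchor is usually
  unstated; here it is included (config-switchable in the fit routine by
  omitting the point from the series).
- LOD-based inference here assumes Gaussian residuals of the transformed
  phenotype; permutation thresholds are robust to this, pointwise LOD
  interpretation less so.
- The homozygote cutoff (dosage ≥ 1.8) approximates "most probable founder
  haplotype" classification; with noisy real dosages the two differ for
  mice of ambiguous ancestry.
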