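# Methods

## The mapping problem

Immature pepper fruit color (yellow → green) is scored on a continuous
green index (2G − R − B from fruit RGB) binned into six grades, and is
controlled mainly by two loci with dominant and additive gene action: a
major locus on chromosome 10 (*CaGLK2*-like) and a minor locus on
chromosome 1 (*CaAPRR2*-like). Bulked-segregant analysis sequences
pooled DNA of the phenotypic extremes of an F2 (13 yellow, 20 green
plants) together with both parents and looks for genomic regions where
the two bulks' allele frequencies diverge.

## Scan statistics

Only parental-informative markers enter the scan: both parents called
homozygous (total depth ≥ `min_parent_depth`, default 10; minor-read
fraction ≤ `max_minor_fraction`, default 0.05) for different alleles.
The depth rules are this package's own defaults — the underlying study
filtered on parental genotypes without stating depth thresholds — and
are configurable.

At each marker the SNP/InDel index of a bulk is the read fraction of
the yellow-parent allele (the reference parent is configurable; the
green-parent index is the complement and the Δ statistic is invariant
to the choice). Sites with bulk depth < `min_depth` (default 10) are
masked rather than propagated as NaNs. The Δ index is
|index(D1) − index(D2)| ∈ [0, 1]; near a causal locus the extreme bulks
approach fixation for opposite parental alleles and Δ → 1, while
unlinked regions fluctuate around 0 with variance set by bulk size and
depth. The ED statistic is the Euclidean distance between the bulks'
four-nucleotide frequency vectors, squared to sharpen peaks; for indels
the two abstract ref/alt alleles replace the nucleotide axes, which
leaves the formula's value unchanged (absent alleles contribute zero).

Windows of 3 Mb advancing by 300 kb are anchored at position 1 of each
chromosome (half-open [start, start+window)), truncated at the
chromosome end; the window value is the arithmetic mean of unmasked
member sites, and windows with fewer than `min_markers` (default 10 at
simulation scale) contributing sites are excluded from thresholding.
Window means are smoothed per chromosome by LOESS (tricube weights,
degree 1, span 0.1, one robustness iteration — implemented in-package
so that degree and iterations are configurable) and thresholded at the
`quantile` = 0.99 level of eligible window values. Runs of significant
(≥ threshold, ties included) windows that overlap or touch merge into
maximal candidate intervals; the interval bounds are the min start /
max end of the merged windows.

### Threshold scope

The top-1% threshold is computed **per chromosome** by default, with a
genome-wide mode available (`threshold_scope="genome_wide"`) plus an
explicit `threshold_override`. On a full genome (12 chromosomes, mostly
free of causal loci) the two modes behave alike. On the scaled-down
two-chromosome simulations used here, both chromosomes carry a causal
locus and the long linked flank of the stronger locus occupies the
entire genome-wide top 1%, so a weaker locus can never reach
significance regardless of its prominence on its own chromosome; the
per-chromosome scope removes that artifact of scale while asking the
same "top 1%" question.

## The F2 simulator

The simulator is the package's study-conditions generator, not a test
fixture: two fully homozygous parents, a uniformly heterozygous F1, and
n = 423 F2 individuals by default.

* **Meiosis.** Uniform genetic map (2 cM/Mb), crossover counts
  Poisson(map length in Morgans) with uniform placement and no
  interference (Haldane model, r = (1 − e^(−2d/100))/2). Markers sit on
  an even grid of 50/Mb on 2 × 50 Mb chromosomes (~5,000 markers — a
  deliberate scale-down from the millions of real variants so a full
  simulate-and-scan replicate runs in well under a second; statistical
  structure per marker is unaffected).
* **Color model.** green score = Σ_ℓ w_ℓ·e_ℓ(d) + N(0, σ), with
  e(0) = 0, e(1) = h, e(2) = 1 per locus; defaults w = 0.7 (chr10 major)
  and 0.3 (chr1 minor), h = 0.6 (partial dominance consistent with the
  dominant gene action and the intermediate heterozygote grades seen in
  the genotype × grade tables), σ = 0.08. Grade cuts
  (0.09, 0.26, 0.50, 0.66, 0.93) bin the score into six grades and were
  chosen once so a 423-plant draw gives a middle-heavy histogram like
  the real F2. Causal positions default to chr10:16.45 Mb and
  chr1:17.65 Mb — inside the intervals the real study reports, and
  deliberately off the 300-kb window grid, since a causal gene aligned
  exactly to the analysis grid is a degenerate configuration.
* **Bulks and sequencing.** The 13 lowest and 20 highest green scores
  form the yellow and green bulks (ties by id). Pooling assumes equal
  DNA contribution per plant; at each marker the bulk's yellow-allele
  frequency f is the mean yellow-allele dosage / 2, total depth is
  Poisson(40) per bulk and the yellow-allele read count
  Binomial(depth, f). Parents are emitted as pure homozygotes at the
  mean depth, so the simulated table passes the informativeness filter
  unchanged. Allele labels and ref/alt orientation are randomized per
  site; 5% of sites are emitted as indels to exercise the two-allele ED
  path. There is no sequencing-error or genotyping-error model.
* **Seeding.** A single pipeline seed fans out through
  `numpy.random.SeedSequence.spawn` in a fixed order (child 0: meiosis
  and phenotype noise; child 1: read sampling and allele labels), so
  every stage is reproducible and partial re-runs are stable.
* **Chlorophyll assay.** `simulate_absorbance` inverts the two
  spectrophotometric equations: the cuvette concentration
  Ct = content·W/(V·D) is split into a and b at a chosen a:b ratio
  (default 3:1, a typical green-tissue value) and the 2×2 linear system
  solved for (D649, D665), with optional Gaussian absorbance noise.
  With zero noise the quantification formulas recover the input exactly
  for any ratio.

What the simulator does **not** emulate: read-level errors, mapping
artifacts, variant-calling noise, segregation distortion, population
structure in the accession panel, or linkage between the marker grid
and real gene positions. Passing the simulation-based tests therefore
validates the statistical machinery under the stated design, not
robustness to real-data artifacts.

## Expected allele-frequency anchors

Two closed-form anchors tie the simulator to the mapping logic and are
checked by simulation:

* Under full dominance (h = 1, single locus, no noise), the
  green-phenotype class is {GG, GY, YY→excluded}… i.e. genotypes GG:GY
  in 1:2 ratio, carrying the yellow allele at frequency
  (0·1 + 1·2)/(2·3) = **1/3** — the "~33%" yellow-parent ancestry seen
  in a green pool at a dominant locus.
* The 13 lowest-scoring plants of a 423-plant F2 are, under the default
  model, essentially always drawn from the double-homozygous-yellow
  class (~1/16 of the population ≈ 26 plants), so the yellow bulk's
  yellow-parent read fraction at the major locus is ≈ 100%, comfortably
  above the 98% benchmark.

## CDS consequence annotation

Positions count from the A of ATG as 1; base p lies in codon
⌈p/3⌉ at within-codon offset ((p−1) mod 3)+1. Consequences come from
translating the reference versus alternate codon under the standard
genetic code; a stop-gain at codon k truncates the protein to k − 1
residues (full length = CDS/3 − 1). This convention reproduces the
anchor case exactly: G→A at base 1428 hits the third base of codon 476
(TGG→TGA) and truncates a 586-residue protein to 475. Synthetic CDS
fixtures are engineered (`make_synthetic_cds`) to carry specified
codons at specified positions — they are labelled synthetic and stand
in for real gene sequences, which the package neither requires nor
fetches. Frameshift handling is limited to naming the first affected
codon. One published companion case (a premature stop reported at base
247 with a TCG→TAG codon change and an 81-residue product) is mutually
inconsistent under any single counting convention — base 247 is the
first base of codon 83, implying an 82-residue product — so the
annotator reports whatever the inputs imply rather than special-casing
printed numbers.

## Phenotype statistics

The normality report uses the sample SD (n−1), the adjusted
Fisher–Pearson skewness G1, the adjusted excess kurtosis G2, and
Shapiro–Wilk via scipy (Royston's algorithm); these estimator choices
reproduce the published six-grade summary to 3 decimals, whereas naive
moment estimators do not. The report is computed over the six grade
counts (n = 6), matching the published table's footnote. Shapiro–Wilk
W is undefined for constant input and reported as such. The 2×2
accession association uses the Haldane–Anscombe +0.5 correction for
the odds ratio only when a zero cell is present; Fisher's exact test
(two-sided, on raw counts) is the primary inference. Heterozygous
carriers count as mutation-present by the caller's choice of input
table; the package does not impose a convention.

## Numerical choices and degenerate inputs

* Masked (low-depth) sites are NaN throughout and excluded from window
  means; zero-depth bulks mask ED.
* LOESS falls back to identity (with a warning) below max(5, degree+2)
  finite points per chromosome; quantile thresholds use numpy's default
  linear interpolation; ties at the threshold are significant.
* Interval merging treats touching windows (end == next start) as one
  run. BED output converts the internal 1-based half-open intervals to
  0-based half-open.
* `select_bulks` breaks score ties by plant id, making bulk membership
  deterministic even for degenerate constant phenotypes.

## Known limitations

* **Interval coverage at simulation scale.** With 2 × 50 Mb
  chromosomes there are only ~167 windows per chromosome, so the top-1%
  rule keeps ~2 windows and the called interval is ~3.3 Mb wide. The
  localization error of a BSA peak with 13/20-member bulks at 40×
  frequently exceeds that half-width: across 100 seeded replicates the
  called Δ-index intervals contain both true causal positions in
  84–92% of runs (the matching acceptance test asserts ≥95% and is
  expected to fail at this scale). At full genome scale the same rule
  keeps ~100 windows concentrated in the causal runs, yielding 6–13 Mb
  intervals for which coverage is not limiting. Users scanning small
  simulated genomes should lower the quantile or widen intervals
  accordingly.
* The uniform map, equal-contribution pooling and error-free parents
  are simplifications; the scan is robust to them but absolute power
  numbers from the simulator should not be read as real-data power.
* ED uses bulk frequencies only (the parental contrast enters through
  the informativeness filter), and no Takagi-style null confidence
  envelopes or G′ statistic are provided — thresholding is by the
  quantile rule throughout.
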