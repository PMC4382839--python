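# Methods

## Statistics

For a biallelic locus with allele frequency p, expected heterozygosity is
H = 2p(1−p) (maximum 0.5 at p = 0.5). Differentiation between k ≥ 2
populations is measured by a Wright/Nei-style fixation index computed from
frequencies alone:

    F_ST = (H_T − H_S) / H_T,
    H_S = mean_j 2 p_j (1 − p_j),   H_T = 2 p̄ (1 − p̄),

with p̄ the mean of the population frequencies. Populations are weighted
equally by default (panels of comparable size); sample-size weights are
available in the converter (`--weighted`) and in `fst_from_frequencies`.
Estimates are clamped to [0, 1] (weighting variants can go slightly
negative) and a monomorphic total pool returns 0. The converter reports
*expected* heterozygosity because the six-column input carries one value per
population and the downstream statistics are frequency-based; an observed
(n_Aa/N) mode exists for panels where genotypic excess/deficit matters.
Loci with fewer than `min_genotypes = 10` genotypes in any population are
removed before analysis — below that the frequency estimate is too noisy to
rank.

Windows contain a fixed number n of consecutive loci (n odd, 5–65 step 2 by
default; 31 sizes), centered on every SNP whose flanks fit within its
chromosome. Windows are index-based, not base-pair based, so marker density
does not change the sampling properties; converting physical to genetic
distance before plotting is a sensible refinement that this package does not
perform. Edge loci are evaluated only at the sizes that fit (`n_sizes`
column) — never padded or wrapped — and loci with no fitting window are
marked `unevaluated` rather than given placeholder scores.

S²F_ST is the variance of the per-locus F_ST values in a window. The sample
variance (denominator n−1) is the default; the population variance is
selectable via `ddof=0`. Because observed windows and resampled sets are
reduced by the same code path, the rank percentiles are invariant to this
choice.

## Null model and percentiles

The neutral baseline for each (statistic, window size) is built by
unrestricted random sampling: r draws (default 10⁵, minimum 10³
recommended) of n loci, independent and uniform *with replacement*, from the
pool. The pool is the chromosome being scanned by default; `pool_scope=
"genome"` pools all loci, useful for sparse chromosomes at the cost of
mixing chromosome-specific backgrounds. One null is built per (chromosome
pool, statistic, size) and reused for every window of that size. All draws
stream from a single seeded PCG64 generator in chromosome × statistic ×
size × draw order, so a scan is reproducible bit-for-bit from its config.

The lower-tail percentile of an observed value is the inclusive rank
count(null ≤ observed)/r (upper tail: count(null ≥ observed)/r). Values more
extreme than every resampled draw get p = 1/(r+1) rather than 0: this keeps
−log10(p) finite and makes the resolution limit of r explicit. A z-score
alternative (`method="zscore"`) converts the observed value to a normal tail
probability using the null's mean and standard deviation; it extrapolates
beyond the resampling resolution but assumes approximate normality of the
window statistic, which fails for small n and skewed statistics such as
S²F_ST — the rank percentile is the default. A null with (numerically) zero
variance is flagged degenerate and returns p = 1: a constant statistic
carries no signal.

Per locus and statistic the scan keeps the smallest percentile across the
window sizes evaluated there, with ties broken toward the smaller window
(sharper localization). When many loci saturate the 1/(r+1) floor — routine
over a strong sweep — `top_locus` breaks ties by the raw window statistic,
which remains informative below the resampling resolution. Taking the
extreme over 31 sizes inflates the tails relative to a single-size scan;
this is deliberate (sensitivity across unknown sweep widths) and
quantifiable by re-running the scan on re-simulated neutral panels. No
multiple-testing correction is applied: the output is a ranked candidate
track, not a set of significance calls.

Classification at level `alpha` (default 0.01, a user choice — the method
prescribes none) uses heterozygosity and S²F_ST; mean F_ST is reported, and
vetoes the `old_selection` call (a pre-split sweep predicts background
F_ST), but never drives a positive call on its own, since mean F_ST is a
weak indicator when alternative fixation mixes high and low values.

## Synthetic data

The generator emulates the two input formats so the pipeline is fully
testable without external panels. The neutral background is a
Balding–Nichols frequency model: ancestral frequency p ~ Uniform(0.05,
0.95) per locus (bounded away from fixation, as on a genotyping array), and
each population's frequency ~ Beta with mean p and variance F·p(1−p). F
(default 0.1, a typical between-continent human value) tunes
differentiation; with two populations the expected panel mean of the Nei
estimator is ≈ (F/2)/(1−F/2) ≈ 0.053 at F = 0.1. Loci are independent and
positions are cumulative random gaps of 0.5–2 kb.

Sweep injection edits the summary columns directly: the targeted
population(s)' heterozygosity is multiplied by a triangular ramp
(`het_reduction` at the center, default 0.1, rising to 1 at ±`half_width`
loci), and for post-split modes the per-locus F_ST inside the interval is
re-drawn alternating between Uniform(0.85, 1) and Uniform(0, 0.05) —
the mosaic left by fixation of alternative swept haplotypes. The `old` mode
reduces all populations' heterozygosity and leaves F_ST untouched.

What this does *not* emulate: linkage disequilibrium between neutral loci,
realistic recombination maps, ascertainment bias, demographic
non-equilibrium (bottlenecks, expansions, migration). Passing tests
therefore demonstrate the statistical machinery (calibration, localization,
determinism) under an exchangeable background, not robustness to demography;
coalescent simulators (e.g. msprime) are the higher-fidelity source of
validation panels when those effects matter.

## Gene-set enrichment

A gene's score is the maximum per-locus −log10 best percentile of a chosen
statistic over the loci inside its (optionally flanked) interval — the max
captures single-peak sweeps; a mean summary is available. A candidate list
is summarised (mean by default) and ranked against `n_random` random gene
sets of the same size drawn without replacement from all scored genes;
the empirical p is the inclusive fraction of null summaries at least as
large, floored at 1/(n_random+1). Long genes collect higher maxima, so
`match_loci=True` draws random genes from locus-count quartile strata
matching the candidates; the default is unmatched, which is anti-
conservative when candidates are systematically long.

## Numerical and design notes

- Percentile floor 1/(r+1); r up to ~10⁷ is held as a dense sorted array
  (~80 MB per null at 10⁷); larger r is not supported.
- Degenerate inputs: chromosomes shorter than the smallest window are
  skipped with a warning; an empty converter output warns rather than
  errors; duplicate positions are kept (windows follow record order) with a
  warning.
- Known blind spot, reproduced by the tests: complete alternative fixation
  across all loci a window covers gives constant F_ST = 1 and hence
  S²F_ST = 0 — such sweeps are visible to the heterozygosity track only.
  Conversely, gene flow reduces differentiation and raises heterozygosity,
  so it should not generate false positives.
- Problem sizes in the test suite and acceptance script (10⁴-locus panels,
  r = 10⁴ resamples, 20–50 replicates) were chosen as the smallest sizes at
  which the calibration and localization properties are statistically
  crisp; production scans typically use r = 10⁵–10⁶.
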