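# Methods

## Setting and assumptions

The package analyses strand-specific per-base DNA modification calls
(modA/6mA on adenines; modC/4mC/5mC on cytosines) on an assembled
genome.  All internal coordinates are 0-based half-open; 1-based formats
(GFF3) are converted only at the parse/serialize boundary.  A
minus-strand call's `base` field is the complement of the forward-strand
letter, canonicalized once at parse time — downstream analyses never
re-complement.  Calls at N bases are dropped (their context is
undefined) with a logged tally; a methylation fraction (`frac`) that is
absent is treated as missing, never as zero, because upstream callers
emit fractions only for identified modifications.

## K-mer context enrichment

The observed table counts, for each call of a class, the strand-resolved
k-mer whose fixed offset is the called base (minus-strand context is the
reverse complement of the forward window).  The background table counts
every window with the target base at that offset over *both* strands of
the genome.  Both tables exclude windows containing N or truncated at a
contig end, symmetrically, so expectations stay unbiased; excluded call
contexts are tallied as dropped.  Scanning both strands (rather than
forward only) is chosen for strand symmetry: reverse-complementing the
genome and flipping all call strands leaves every statistic unchanged (a
tested invariant).

Enrichment uses the adjusted goodness-of-fit standardized residual
r = (O − E)/√(E(1 − p)), which has unit variance under the null and so
reads directly as "standard deviations from expectation"; the plain
Pearson variant (O − E)/√E is exposed as an option, and the chi-square
statistic Σ(O−E)²/E equals the sum of squared Pearson residuals.  When
E = 0: O = 0 is reported as missing, O > 0 as +∞.  Selection of enriched
k-mers sorts by descending residual with lexicographic tie-break;
default top-N choices are 500/5000 for 7-mers.  PWMs use weighted counts
with an optional pseudocount (default 0); column information content is
2 − H(column) bits.  The 7-mer convention places the modified base at
position 3 (offset 2).  EM-style motif discovery is deliberately out of
scope — residual-ranked k-mer sets plus a PWM give a deterministic,
testable surrogate.  The trimer depletion ratio compares both-strand
trimer frequency with an order-0 (mononucleotide product) expectation.

## Spacing and periodicity

Distances are between *adjacent* calls within a contig: per
(contig, strand) in same-strand mode, per contig ignoring strand
otherwise (two strands at one position yield a recorded 0, excluded from
the histogram; totals satisfy counts + overflow + zeros = pairs).
Controls redraw the same number of sites per (contig, strand) stream
uniformly without replacement from eligible same-base positions, seeded;
the default is 100 replicates.

The periodogram detrends the histogram with a centered moving average
(default width 20 bp, shrinking at the edges) before the FFT, because
the histogram's monotone decay otherwise dominates low frequencies; raw
spectra are available by flag.  Two numerical choices matter and are
package design decisions:

* **Short-range window.** The helical analysis transforms distances
  1–100 bp by default (flag to use the full histogram).  The
  nucleosome-repeat spike near 175 bp shares no phase with a 10 bp comb
  (175 ≡ 5 mod 10): on the full 1–200 range it suppresses the power bin
  at exactly 10 bp and reinforces the 5 bp harmonic, flipping the
  band-limited argmax even for a cleanly planted lattice.  Restricting
  to short range separates the two phenomena; the nucleosome scale has
  its own estimator.
* **Zero-padded peak readout.** The dominant period is the power argmax
  within the search band (default 5–20 bp) on a zero-padded (≥1024-point)
  spectrum, which localizes the peak off the coarse N-point frequency
  grid.  The reported power array stays on the native grid and satisfies
  Parseval's identity against the detrended counts.

The nucleosome-scale estimator smooths observed and mean-control counts
(centered window, default 10 bp) and takes the argmax of their ratio in
100–200 bp; zero control bins are floored at ε = 1e-9 with a flag, and a
control with no band mass yields an undefined-peak signal rather than an
exception.  Empty histograms likewise yield an undefined period, not an
error.

## Feature enrichment

Per feature class, overlapping intervals are merged so each base counts
once; eligible bases are target-base occurrences on both strands
(#base + #complement on the forward axis).  The test is an exact
two-sided binomial (minimum-likelihood summation, via
`scipy.stats.binomtest`) with success probability
eligible_in/eligible_total; membership of a call is strand-agnostic by
default (regions, not strand-matched features; a strand-matched mode
exists).  Benjamini–Hochberg adjustment runs across feature classes or
across repeat families; families under a minimum eligible-base count
(default 100) are excluded and reported separately.  Promoters absent
from an annotation are derived as fixed strand-aware upstream windows
(default 500 bp, clipped at contig bounds).  Expression strata default
to unexpressed ≤ 0.1, high ≥ 10 (inclusive on the high boundary), on the
male-sample abundance.

## Linkage and dosage

Per-window (default 10 kb) *median* depth over the coverage step
function resists repeat-driven spikes; uncovered bases count as depth 0.
A final partial window joins the previous window when shorter than half
a window.  The diploid peak is the majority histogram mode of window
medians (bin width max(1, guess/100), ties to the lower mode) — valid
when autosomal sequence dominates, the documented assumption.  The
haploid band is (0.35, 0.65) × peak, bracketing 0.5× symmetrically
(configurable); a contig is X-linked when more than the threshold
fraction (default 0.8) of its windows lie in the band.  Classification
is invariant under global depth rescaling (tested).

Dosage ratios are log2((male + c)/(female + c)) with pseudocount c = 1;
genes whose larger abundance is below 1 are excluded.  Classes are
compared with a two-sided rank-sum test, plus a two-sample KS statistic
for the distribution-equality claim; a class with fewer than two genes
skips the comparison with a flag.

## Nanopore signal shift

Per 6-mer with at least `min_events` (default 50) events: mean shift
Δ = native − model mean (pA), z = Δ/(model sd/√n), and a one-sample KS
statistic against N(model mean, model sd) with its asymptotic p-value.
The *shifted* set is defined by a concrete rule — BH-adjusted KS p ≤ α
(default 0.01) AND |Δ| ≥ 1 pA — replacing a qualitative judgement with a
reproducible decision; the set is monotone in both thresholds (tested).
Low-coverage k-mers are reported but never flagged; k-mers absent from
the model are skipped with a tally.  Sub-motif enrichment counts every
m-mer window (all offsets) in the shifted set against the modeled
universe and applies the same standardized-residual formula, offset-free.

## Synthetic data generator

Every generator is a pure function of (config, seed) and emits a
complete `SimTruth` (each planted call with origin, every
contig/gene/k-mer label).  What it emulates, and what it does not:

* **Genome**: i.i.d. bases at configurable GC (default 38%, an AT-rich
  insect-like composition).  No repeats, no composition heterogeneity —
  so motif recovery here does not demonstrate robustness to repeat
  families or CpG islands.
* **Motif modifications**: each occurrence of a motif (both strands)
  modified independently with a per-site probability; methylation
  fractions are Beta(8,2) for identified classes (high-frequency mode)
  and Beta(2,2) for generic modA/modC; spurious background calls land
  uniformly on eligible bases.  `background_rate_for_rate_ratio` solves
  the background level b = p(1 − ρf)/(ρ − 1) that fixes the expected
  context/base rate ratio ρ given motif fraction f.
* **Periodic modifications**: arrays of sites at multiples of the
  helical period (endpoints always present, interior points with
  `fill_prob`, default span 16 periods), per-site rounded Gaussian
  jitter, arrays placed so consecutive arrays' nearest calls sit one
  nucleosome repeat apart; planted sites have their genome base
  rewritten to the canonical base so the call set stays sequence-
  consistent.  This is a phenomenological lattice, not a nucleosome
  positioning model.
* **Coverage**: per-window negative-binomial depths at λ (haploid) or 2λ
  (diploid), Poisson in the infinite-dispersion limit; overdispersion is
  the realistic stress for the 80% band rule, and classification
  accuracy degrades as dispersion grows.
* **Expression**: log-normal baselines (meanlog log 200, sdlog 1);
  female = baseline, male = baseline (halved for X genes without
  compensation) times log-normal noise with median 1 at the configured
  CV, so the uncompensated X median log2 ratio is −1 by construction
  (up to pseudocount attenuation of order 2/baseline).
* **Events**: per-k-mer Gaussian event means from a synthetic pore model
  (uniform means 60–120 pA, sds 1–2.5 pA over all 4096 6-mers — *not* a
  real pore model), with a constant additive shift for the planted set.
  Real nanopore effects (k-mer cross-talk, segmentation error,
  heavy tails) are not simulated, so passing tests bound statistical
  behaviour, not chemistry.

## Problem sizes and tolerances

Recovery tests run at desk scale chosen so sampling tolerances are
meaningful: 2 Mb genomes (motif/PWM recovery, 100 seeds, ≥95 expected
successes), 1 Mb for the ratio-7.5 recovery (±10%, the 3σ binomial
window at ≥2000 planted sites), 500 phased arrays for periodicity
(period within ±0.5 bp, peak within 170–180 bp), 1000 tiled features for
binomial null calibration (5% ± 3 Monte-Carlo σ), 50 contigs for linkage
(exact recovery in the Poisson regime), 2000 genes for dosage (median
within ±0.05), and the full 4096-k-mer table for shift recall
(≥99%).  Oracle comparisons are exact to 1e-9 (residuals) and 1e-10
(binomial p-values).

## Known limitations

Flat GFF3 intervals only (no feature hierarchies); no BAM/fast5 input —
event tables and pore models are consumed as TSV; the diploid-peak
estimator assumes a majority-diploid genome and will misread a genome
that is mostly haploid; the periodogram's short-range default assumes
helical-scale periodicity lives below 100 bp; the binomial model treats
calls as independent, so locally clustered modifications inflate
feature-level significance.
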