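# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention); GTF's 1-based
closed intervals are converted on ingestion. The TSS of a minus-strand
transcript is `end − 1` and its TTS is `start`: a TSS is a base, not a
boundary, which keeps the window arithmetic symmetric between strands.
Analysis windows constructed near a chromosome edge may temporarily have
negative starts; `clip_to_chromosome` intersects them with
`[0, chrom_length)` before any counting, and densities always use the
clipped length. Coordinates parsed from files must be non-negative.

## Pausing index

The promoter window spans 200 bp upstream to 300 bp downstream of the
TSS base (500 bp exactly, before clipping); the body window spans 300 bp
downstream of the TSS to 1000 bp downstream of the TTS (length L + 700
for a transcript of length L). Density is the number of fragment
*midpoints* per bp of the clipped window. Midpoint counting is a design
choice: each fragment is tallied in exactly one window, so the
promoter/body boundary never double-counts, and the synthetic generator's
analytic expectation becomes exact. A 5′-end counting mode
(`mode="five_prime"`) is provided for comparison; 5′ ends use the
fragment strand.

Per gene, isoforms of length ≤ 200 nt are excluded (strict inequality)
and the qualifying isoform with the maximum PI represents the gene. A
zero body density makes the PI undefined; undefined genes are excluded
from distributions rather than mapped to infinity, which keeps ECDFs and
rank tests finite. The number of undefined genes is logged per sample.
PI is computed on deduplicated fragments before any normalization — a
per-sample scale factor cancels in the ratio.

Duplicate removal keeps one fragment per (chrom, start, end, strand)
key, the fragment-level equivalent of paired-end PCR-duplicate marking.

## Rank tests and summaries

`mann_whitney` computes U from midranks. For n1 + n2 ≤ 12 without ties
the p-value is exact, by full enumeration of the C(n1+n2, n1) rank
assignments; otherwise the normal approximation with tie-corrected
variance and continuity correction is used (delegated to
`scipy.stats.mannwhitneyu`). The regime boundary is a numerical choice:
enumeration is cheap up to 924 arrangements and removes approximation
error exactly where it is largest. If every pooled value is identical
the test is degenerate and returns p = 1 with a warning.

Boxplot summaries use linearly interpolated quartiles and Tukey
whiskers: the farthest data points within 1.5 × IQR beyond the
quartiles. ECDFs are right-continuous, F(x) = #{values ≤ x}/n.

## Spike-in calibration and coverage

Fragments are partitioned by chromosome-name prefix (default `spike_`),
mirroring alignment to a concatenated target+spike reference. Two
normalization modes are exposed because published pipelines vary:
`spikein` (factor = R / n_spike, R = 10⁶) makes total scaled spike
signal identical across samples — the defining property of calibration —
while `library` (factor = R / n_target, R = 10⁷, or 10⁶ for uncalibrated
factor ChIP) is plain depth scaling. Samples default to `spikein` when
spike fragments are present; neither behaviour is hard-coded as "the"
published one.

Coverage tracks store mean per-base coverage per bin (default 50 bp,
matching the metagene bin width). A partial terminal bin still divides
by the full bin width, so total signal (Σ bins × bin_size) equals the
scale factor times total fragment length — an invariant the tests check
against per-base accumulation. Replicate averaging returns per-bin mean
and SEM (sample SD / √n).

## Occupancy classification and expression groups

Gene-body targeting uses ≥ 1 bp half-open overlap between a peak and the
full TSS..TTS span of any isoform; no trimming is applied because none
is defined for this rule. TSS-window targeting requires the peak to be
*fully contained* in TSS ± 5 kb of some isoform — partial overlap does
not count. A gene is a target if any isoform qualifies.

Expression groups are contiguous FPKM-rank quartiles (High,
Intermediate, Low, No), ties broken by gene id so the grouping is
deterministic and order-invariant; when n is not divisible by 4 the
earlier groups take the extra gene. Whether the "No" class should
instead be exactly FPKM = 0 is genuinely ambiguous in practice, so an
alternative `no_group="fpkm_zero"` scheme is exposed; the rank-quartile
scheme is the default because it always partitions evenly.

## Metagene matrices

The scaled layout uses fixed 50 bp flank bins (5 kb each side) around a
body rescaled onto 10 kb — 100 + 200 + 100 = 400 columns. Body rescaling
averages coverage over each normalized bin's *proportional genomic
sub-interval*, computed as an exact integral of the binned step function
with fractional bounds. This area-preserving choice (rather than
nearest-neighbour sampling) makes two properties exact: uniform coverage
yields an exactly flat matrix (to float rounding, ~1e-12 relative), and
at bin_size = 1 the body-row sum times L/region_size equals the total
coverage over the gene span. Minus-strand rows tile the same genomic
bins in reverse, so a minus-strand row is the exact reversal of the
equivalent plus-strand row and column 0 is always 5′. The representative
isoform per gene is the longest transcript (ties by id). Flanks past a
chromosome end average over the clipped region; sub-bin-length genes
yield finite rows.

Profiles winsorize each column at its (1 − exclude_p) quantile (default
exclude_p = 0.01, linear-interpolation quantile) before computing mean
and SEM. Winsorization is applied per column, which damps outlier loci —
the evident purpose of the parameter — without discarding rows; this is
a documented interpretation of upstream practice, not claimed to be
bit-identical to any external tool. Heatmap ordering sorts rows by
descending mean of the key matrix's body columns, stable under ties.

TSS-centred matrices cover TSS ± halfwidth (default 5 kb; 1 kb for
close-up insets). Sense/antisense modes build per-strand coverage from
stranded fragments and select the same/opposite strand per gene; the two
modes sum exactly to the all-fragments matrix.

## Synthetic data generator

The generator emulates a two-genotype experiment: wild type with pausing
fraction 0.30 versus double knockout with 0.45 (the contrast the
pausing comparison is designed to detect), elevated TSS-flanking
acetylation in the knockout (amplitude 1.6 vs 1.0), and a
condition-independent spike-in sequenced at per-sample depth. Defaults:
2 Mb target chromosome, 200 kb spike chromosome, gene lengths uniform in
1–8 kb with ≥ 2 kb gaps, 25% silent genes with the rest log-normal
around 10 FPKM, 200 bp fragments, promoter mixture component centred
+50 bp from the TSS with 60 bp SD (an arbitrary but documented paused-
peak shape), acetylation flank peaks at TSS ± 500 bp with 150 bp SD and
a 10% uniform background. 30% of genes carry a second, shorter isoform
sharing the TSS, exercising the max-PI isoform rule without changing
window truth.

Pol II fragment midpoints are drawn from a two-component mixture: with
probability p a truncated normal confined to the promoter window, else
uniform over the body window. Because the components are *confined* to
their windows and counting uses midpoints, the expected PI is exactly
p(L+700)/(500(1−p)) — the oracle every recovery test uses. Midpoint
placement (rather than 5′-end placement) is deliberate for the same
reason. Fragment counts are Poisson around scale × FPKM, or a fixed
expected count per gene for controlled experiments.

The SILAC generator plants enriched proteins with oriented log2 ratios
~ Normal(effect, sd) in both experiments, and converts to raw H/L ratios
through the label-swap convention; null proteins are centred at 0, so
the analytic false-positive rate at threshold τ is the product of two
one-sided normal tails.

What the generator does *not* emulate: sequence content, mappability,
read errors, fragment-length distributions, copy-number or chromatin-
accessibility biases, correlated replicate noise, and peak-caller
behaviour (truth peaks are planted, not called). Passing tests therefore
demonstrate the correctness of the statistics and the pipeline's
plumbing under the stated model, not robustness to real-data artefacts.

Every generator draws from an independent, deterministic stream keyed by
(seed, operation, condition), so adding a sample never perturbs another
sample's data.

## Problem sizes and tolerances

The recovery checks use 500 genes × 2000 fragments for the pausing
operating point (median PI within 10% of 45.6), 500 genes × 300
fragments for the genotype shift, 50 seeds × 500 genes × 60 fragments
for the matched-null calibration (two-sided p > 0.05 in ≥ 90% of seeds),
200 genes × ~100 signal fragments/gene for amplitude recovery (within
5%), and 100 random instances of up to 500 genes/peaks for the occupancy
oracles — sizes at which Monte-Carlo noise sits comfortably inside each
stated tolerance while the whole suite runs in well under a minute per
check. Spike-in conservation is exact up to float rounding (checked at
1e-6 relative); the metagene flat field is checked at 1e-9 relative.

## Known limitations

- No input-chromatin (ChIP/input) correction is implemented.
- The Mann–Whitney exact regime requires no ties; tied small samples
  fall back to the asymptotic approximation.
- BAM ingestion is convenience-only (properly paired reads → one
  fragment per pair; single-end reads → read-length fragments) and
  requires pysam.
- Winsorization semantics for profile outlier damping are per-column, a
  documented interpretation rather than a reimplementation of any
  specific external tool.
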