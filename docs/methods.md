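# Methods

## Ratio computation

A CpN o/e ratio compares the observed count of a dinucleotide to the
count expected under independence of adjacent bases. Four formulations
are implemented (`Formula.F1`–`F4`); F1,

    o/e = #CpG / (#C · #G) · l² / (l − 1),

is the default, and F2 is the same without the small-sample length
correction (F1 = F2 · l/(l−1)). F3 divides the per-base dinucleotide
frequency by the squared fractional C+G content; F4 divides the raw
dinucleotide count by the squared half of the C+G count. For a
dinucleotide other than CpG the two letters substitute for C and G
everywhere (CpA uses #C·#A), matching how CpA o/e is used as a
repeat-induced-point-mutation signature in fungi.

**Ambiguity codes.** `l` and all counts run over unambiguous (A/C/G/T)
positions only, and a pair spanning an ambiguous base is never counted.
The alternative — total length including ambiguity codes — would
inflate expected counts for N-rich records; since the length filter is
itself phrased in unambiguous nucleotides, the unambiguous convention
is applied consistently. Dinucleotide counting is overlapping ("AAA"
contains two ApA).

**Degenerate cases.** A zero dinucleotide count or a zero denominator
(e.g. no C at all) yields a ratio of 0 rather than a missing value; the
cleaning stage removes zeros as artifacts, so both cases end up treated
identically downstream. Sequences with fewer than 200 unambiguous
nucleotides (default `min_len`) are dropped before any ratio is
computed, because short sequences produce mostly zeros or extreme
values.

## Cleaning

Zeros are removed first; their share is reported relative to the raw
sample. Outliers are then removed outside the closed interval
`[Q25 − k·IQR, Q75 + k·IQR]`. The multiplier `k` takes the smallest
integer in {2, 3, 4, 5} whose removal share, relative to the zero-free
sample, is ≤ 1%; if none qualifies, k = 5. The ≤ reading of "not more
than 1%" is used, and values exactly on an interval endpoint are kept.
Quantiles everywhere use linear interpolation of order statistics with
quantile p at rank 1 + (n − 1)p (numpy's default), fixed once for
reproducibility. Fewer than 500 cleaned values trigger a
`LowSampleWarning` — an empirical reliability guideline for the KDE,
not an error.

## Density estimation and mode detection

The KDE uses the Gaussian kernel and the normal-reference bandwidth

    h = 1.06 · min(sd, IQR/1.34) · n^(−1/5)

with the sample standard deviation (denominator n − 1). When the IQR is
zero in a heavily tied sample, the spread term falls back to the sd
alone rather than collapsing the bandwidth to zero. The density is
evaluated on 512 equally spaced grid points (`grid_size`) spanning
`[min − 4h, max + 4h]`: four bandwidths of padding keep the truncated
kernel mass below 1e−4 even for extremely concentrated samples, so the
trapezoidal integral of the grid density is 1 to well within 1e−3.

Modes are interior grid points whose density strictly exceeds both
neighbors; minima are defined symmetrically, and a flat plateau of tied
values collapses to its midpoint so that discretization ties cannot
produce duplicate modes. Each mode's probability mass integrates the
density (trapezoidal rule) between the nearest local minima on either
side; the outermost modes integrate to the grid ends, which stand in
for ±∞. Masses are normalized by the total grid integral, so they sum
to 1 to within 1e−6 by construction. If the estimate is monotone over
the whole grid (no interior maximum, only possible for pathological
inputs), the higher grid end is reported as a single mode of mass 1.

**Post-processing.** Two rules are applied in order. (a) While any two
consecutive modes are closer than 0.2 o/e units (`min_distance`), the
closest such pair is merged: the member with the higher density keeps
the position, masses add, integration bounds unite, and the survivor is
flagged `close`. Nearest-pair-first iteration makes the result
deterministic and independent of input order. (b) Modes with less than
1% mass (`min_mass`) are then pruned, each dropped mass reassigned to
the nearest surviving neighbor so the reported masses stay normalized;
reassignment (rather than renormalization or silent loss) keeps the
sum-to-one property exact and attributes contamination mass locally.
Modes with mass < 0.1 carry a `weak` display flag (dashed in the
figure); this is a rendering cue, not a removal rule. In the summary
table, "Number close modes" counts post-processed modes carrying the
`close` flag and "Modes (close modes excluded)" the remainder — i.e. a
merged cluster counts as one close mode.

**Classification.** A mode position below 0.75 (`threshold`) predicts a
presumably methylated sequence population; at or above 0.75, presumably
non-methylated. The boundary itself is non-methylated.

## Bootstrap

Stability is assessed by case resampling: each of B = 1500 (default)
replicates redraws n values with replacement and reruns the full
pipeline, including bandwidth selection. The shares of replicates with
the same / more / fewer modes than the original sample are reported.
Confidence intervals use only replicates passing two safeguards: the
mode count must equal the original, and after matching modes in
ascending-position order, no matched mode's mass may differ from the
original's by more than 20% relative (`mass_tolerance`; the relative
reading of "strong changes in probability mass" is adopted). Percentile
intervals at level 0.95 are taken per mode over the surviving
replicates; percentile rather than BCa because the simplest method
suffices for a stability readout. Replicate RNG streams derive from
`SeedSequence(seed, spawn_key=(replicate,))`, so results are
bit-identical for any thread count. A replicate that degenerates (e.g.
a constant resample with zero bandwidth) counts as zero modes.

Note the percentile CI quantifies resampling variability around the
*sample's* mode estimate; at moderate n its width can be smaller than
the estimator's own sampling error, so it should not be read as a
confidence interval for the true population mode position.

## Synthetic data generator

`generate_population` draws i.i.d. sequences at a chosen GC content
(C and G each at gc/2) and then rewrites each CG occurrence — scanning
non-overlapping pairs left to right, mirroring per-site deamination —
to TG with probability d (`depletion`). Defaults used in the tests and
the acceptance run: two populations of 2000 sequences of 1500 nt at GC
0.5, depletion 0.5 (methylated-like) versus 0.0 (unmethylated-like),
shuffled together as a mosaic. These sizes give well-separated modes at
a sample size where the KDE is in its reliable regime while keeping a
full run in seconds.

Because the CG→TG rewrite also removes a C from the expected-count
denominator, the expected o/e after depletion is
(1 − d)/(1 − d·gc/2) — about 0.571 rather than the naive 0.5 at d =
0.5, gc = 0.5. Tests assert this corrected expectation.

What the generator does *not* emulate: codon structure and composition
heterogeneity within a sequence, length variation, sequencing error,
partial (intermediate) methylation levels, and skewed unimodal
distributions typical of real transcriptomes. Passing the recovery
tests therefore shows the pipeline identifies well-separated
composition classes at realistic sample sizes; it does not certify
behavior on heavily skewed or overlapping real distributions, where the
bootstrap stability shares are the intended diagnostic.

## Numerical choices and limitations

- Quantile convention, grid size, padding and integration rule are
  fixed as above; changing them moves mode positions by at most a grid
  step (~1/500 of the padded range).
- Mode positions are quantized to the grid; bootstrap CIs inherit that
  granularity.
- The merge rule keeps the higher-density member's position instead of
  a mass-weighted average; with the 0.2 distance threshold the
  difference is at most 0.2 and in practice far smaller.
- Very small cleaned samples (< 4 values) cannot be processed; < 500
  values warn.
- The method reads *historical* methylation recorded in composition; a
  recently acquired or lost methylation state leaves no o/e signal.
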