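# Methods

This note documents the models and numerical choices behind `tethermap`:
what each operator computes, what the synthetic-data generator emulates,
which parameters matter, and where the design was genuinely open.

## Coordinates and fragments

All intervals are 0-based half-open (BED convention); 1-based inputs must
be converted at the boundary. A *fragment* is the interval spanned by one
sequenced paired-end insert; its length is `end - start`. Duplicate
fragments are retained — tethered-nuclease digestion releases each
particle once, and no deduplication step is part of the model (an
optional flag could be added at ingestion, but nothing downstream assumes
it). The canonical size classes — ≤120 bp (TF-protected) and ≥150 bp
(nucleosomal) — are caller-supplied bounds, not constants.

## Tracks and normalization

Fragment *ends* count both termini: each fragment records two cleavage
events, so an end-density track has mass `2 × |F|` and a length-1
fragment contributes 2 to its single base. Coverage tracks add 1 per
covering fragment per base.

Standard normalization divides every base by the sample's total mapped
read ends; one constant per sample serves both its end and coverage
tracks, so within-sample track shapes are preserved and the constant
cancels any true global change in cleavage. Spike-in normalization
divides by the number of fragments mapped to the heterologous spike-in
genome (a count of fragments, not base pairs), which is proportional to
the constant spike-in yield and therefore preserves absolute scale
between samples. The distinction is what the digestion-time-course
analysis measures: with cleavage rising 4-fold at constant spike-in,
spike-normalized site signal rises ~4-fold while standard-normalized
signal stays ~flat.

bedGraph output is run-length-compressed with zero runs omitted; values
are written at full float precision (`repr`), with a fixed-decimal mode
for bit-exact diffs. Reading rejects overlapping intervals.

## Motif sites and scanning

Position count matrices (JASPAR text, parsed with `Bio.motifs`) become
log2-odds matrices with a per-base pseudocount (default 0.25) against a
uniform or user-supplied background. `N` bases score the
background-weighted column mean. Scanning scores every window on the +
strand and, for the − strand, the reverse-complement matrix, so all
coordinates stay on the + strand frame; a site's center base is
`start + width // 2`. Significance is a plain log-odds threshold: no
E-value calibration is attempted, because downstream analysis needs only
deterministic site lists and the simulator supplies ground truth for
validating recovery. Best-match lookup for an interval extends it ±100 bp
by default and breaks ties leftmost-then-+ for reproducibility.
Cross-factor confounds are removed reciprocally: sites of either factor
whose centers lie within 50 bp of a site of the other are dropped from
both lists, keeping the two analyses symmetric.

## Aggregation operators

`site_matrix` extracts `[center − flank, center + flank)` per site and
reverses rows of − strand sites, so column `p` is oriented relative
position `p`; sites too close to a chromosome edge are dropped and
counted. Profiles are columnwise means or medians; percent-of-max
rescales the mean profile to its window maximum = 100.

Smoothing is a centered moving average with an odd window (default
11 bp); edge windows shrink to the available positions rather than
padding — truncation avoids inventing boundary values.

Cleavage periodicity is estimated from the residual of the 1-bp profile
against its 11-bp smooth: Pearson-type normalized autocorrelation
(mean-subtracted residual, scaled by lag-0 variance) at lags 1–50, with
the dominant interior local maximum reported as the period. A ~95%
white-noise band `2/√n` guards against spurious periods; note the
high-pass filtering itself induces correlation at lags below the
smoothing window, so the band is meaningful only beyond it (the tests
account for this). The G+C indicator profile over the same oriented
windows is the sequence-composition control: real cleavage periodicity
should have no counterpart in base composition.

`footprint_width` is the maximal contiguous run of positions containing
relative position 0 whose values fall below `depletion_frac` (default
0.25) of the mean over the outer 25% of positions on each side of the
(unsmoothed) profile. The threshold fraction is an operational choice —
"footprint width" has no unique definition — so the operator is
parameterized and validated by parameter recovery against the generator's
protected span. `tramtrack_separation` returns the distance between the
end-density maxima in `[-search, 0)` and `[0, +search)` (ties resolve
toward the center), the paired-hotspot geometry characteristic of CTCF.

Occupancy scores order heat-map rows: `span-mean` is the row mean over
±1 kb; `center-minus-flank` is the summed signal over `[-30, +30)` minus
the sums over `[-1000, -700)` and `[+700, +1000)`, a background-corrected
occupancy. Ordering is stable-descending and returns the permutation so a
second matrix (e.g. the other size class) can be ordered identically.
Cumulative count curves sum each row's center window, rank rows by an
external score (e.g. motif similarity), and report the cumulative percent
of counts, ending at 100.

## Peak calling

The threshold method: θ is a percentile (default 99.5) of per-base
values; maximal runs ≥ θ are merged across gaps < 100 bp and filtered to
widths 50–1000 bp; score is the sum of values (additive under merging)
and the summit the leftmost maximum. Two open choices are pinned and
recorded: (1) the percentile is computed genome-wide over *nonzero*
positions only — on sparse cleavage tracks the zero-dominated genome
would pin any high percentile at zero; an all-positions flag exists.
(2) gaps are closed before width limits are applied (merge-then-filter);
the alternative order is behind a flag. The percentile uses numpy's
linear interpolation between order statistics ("type 7") for
bit-reproducibility. `threshold_for_peak_count` bisects the percentile to
hit a target peak count, returning the closest achievable value.

## Contacts

A cleavage peak overlapping (≥1 bp, half-open, ± optional slop) any
native-ChIP peak is *direct*; otherwise *indirect*. The partition is
checked on every call. Contact-fragment pairs (7-column BEDPE, optional
score filter such as ≥15) are annotated with each anchor's category; the
unordered pair label is symmetric under anchor swap. The association
between cleavage and contact strength is summarized over direct–indirect
pairs: the indirect anchor's peak score (the track-sum score; max and
mean are alternatives, sum is used and labeled) is looked up, rows are
ranked by it descending, and centered moving averages (default window
1500, truncated at edges, shrunk with a warning when rows < window) of
both scores are reported. The random control redraws intervals with the
same count and width distribution uniformly over the genome under an
explicit seed.

## Solubility

`log2((total + pc) / (soluble + pc))` per base, with pseudocount default
1 raw-count-equivalent (scaled appropriately for normalized tracks) since
log space needs a zero policy; the same contract serves high-vs-low-salt
comparisons. Fraction tracks should be spike-in normalized first so the
ratio reflects absolute recovery. Median profiles over unoriented
midpoints (e.g. centromeres) use columnwise medians, robust to outlier
windows.

## The synthetic generator

`simulate` emulates the generative structure the analysis assumes. A
random genome (default 600 kb over 3 chromosomes) carries planted sites
on a jittered grid ≥2 kb apart and ≥1.1 kb from edges: *direct* sites
with an exact 12-bp non-palindromic consensus (reverse-complemented on −
strand; chance occurrences elsewhere are scrubbed by a single point
mutation so scans recover exactly the truth set), motif-free *indirect*
sites each paired with a random direct partner, and unoriented
*centromere-like* sites.

TF-class fragment ends are drawn independently left and right of a
protected core — the half-open 20-bp interval `[center − 10, center + 10)`
in which **no** fragment of any class may have a terminus (bound protein
blocks cleavage; background fragments falling there are resampled).
Cleavage distance `d` from the core edge follows a 10-bp-periodic comb
(off-spike weight 0.15) under a symmetric truncated-Gaussian envelope
(σ = span/7) peaked mid-flank and decaying to background over the 100-bp
flank span. The envelope's peak position is derived from the configured
TF length mode (`μ_d = (mode − 2·halfwidth − 2)/2`), and its symmetry
makes the mode of the end-offset convolution — hence the fragment-length
mode — land exactly on the configured value (100 bp by default); a purely
monotone-decaying end density, the naive alternative, cannot produce a
~100 bp length mode from independent ends, which is why the envelope is
bell-shaped rather than decaying from the core edge. `tf_length_pmf`
exposes the exact implied length distribution, and a test pins the
sampled mode to it. The comb phase puts end spikes every 10 bp, giving
the aggregate profile its sawtooth and the residual autocorrelation its
10-bp dominant lag. For the CTCF-like template, each end independently
relocates to a fixed hotspot offset (±22 bp, probability 0.6), producing
tram-tracks 44 bp apart.

Minus-strand sites map oriented offset `o` to genomic `center − 1 − o`,
which keeps the protected core at the same genomic interval on both
strands and makes oriented aggregation align features exactly.

Nucleosome-class fragments (length ~N(150, 6), rounded) center on phased
dyads at ±(95 + k·165) bp, k = 0..2 with decaying weights and ±8 bp
jitter. Background fragments are uniform (20 per kb by default, length
~N(120, 40) clipped to [20, 500]). Site-level counts are Poisson with
mean `frags_per_site × timecourse_factor × rate_scale`; indirect sites
draw `rate_scale` from Uniform(0.3, 1.5) so contact-association tests
have signal, and contact scores are proportional to it. The spike-in
genome (50 kb) receives an exact, time-independent fragment count
(default 2000). The default digestion schedule multiplies cleavage by
(1, 2, 3, 4) — a 4-fold rise at constant spike-in. Fractionation thins
each class Bernoulli-wise (defaults: TF 0.95, nucleosome 0.85, background
0.6, centromere-like 0.02), so centromere-like particles appear
essentially only in total DNA.

Everything is deterministic under `(seed, config)`: genome construction
uses the seed directly and each time point derives an independent stream
from `(seed, time_index)`.

### What the generator does *not* emulate

Sequence-level reads (no FASTQ, base errors, mappability or GC bias in
sampling), PCR duplicates, chromatin accessibility heterogeneity,
overdispersed site counts (Poisson only), cross-site interference, and
realistic genome composition. Passing parameter-recovery tests therefore
show that the operators measure what they claim on data with the assumed
structure — not that real libraries satisfy those assumptions.

## Problem sizes in tests and the acceptance script

The shipped tests run the generator at 160–200 kb genomes with 40–60
direct sites, and the acceptance script at the 600 kb / 200-site
defaults with 5 seeds for footprint/periodicity, 3 for tram-tracks and
length modes (≥20,000 fragments per class), and one 4-point time course —
sizes at which every recovered quantity is stable across seeds while the
whole computation stays interactive.

## Known limitations

* The footprint operator requires a nonzero distal flank level; on
  background-free profiles it raises rather than guessing a reference.
* `threshold_for_peak_count` assumes peak count is monotone in the
  percentile; merging can create rare local non-monotonicity, handled by
  returning the closest count seen.
* The BEDPE reader expects exactly two anchors plus one score column;
  richer ChIA-PET formats must be projected down first.
* Alignment ingestion takes properly paired, coordinate-resolvable
  records (leftmost mate, TLEN > 0) and does not reconstruct pairs from
  name-sorted input.
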