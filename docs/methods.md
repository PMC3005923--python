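# Methods

## Model and rationale

Library fragments are deposited on the sequencing surface by a process that
is, to excellent approximation, spatially random. Under that null, any
statistic that depends only on a read's *content* — base or color-code
composition, quality, alignability — is exchangeable across surface
positions, so a surface map of such a statistic should be flat up to
sampling noise. surfqc treats every departure from flatness as evidence of
an assay artifact (fluidics bands, optics donuts/stripes, chemistry-linked
gradients) and provides the same logic cycle-wise: composition per
sequencing cycle should be constant unless the chemistry itself drifts or
cycles.

Reads are located through their identifiers. Two Illumina dialects are
supported (legacy `machine:lane:tile:x:y#index/mate` and the 7-field
CASAVA-1.8 form, autodetected from the first record and then fixed per
file) plus SOLiD bead names (`panel_x_y_tag`). Identifiers that carry no
coordinate are counted per file and excluded from spatial statistics — never
silently dropped — and a file is rejected outright only when more than half
of its first 1000 identifiers fail, which indicates a wrong dialect rather
than occasional damage.

## Statistics

**Composition fractions.** Always over *called* symbols: `N` (basespace) and
`.` (colorspace) count toward read totals but never toward denominators.
All aggregation is count-weighted — counts are pooled first and divided
once — so sample-level series equal what a recomputation from raw reads
gives, regardless of unequal tile depths.

**Unevenness score.** Within-tile counts on a fixed `gx x gy` grid (default
20 x 20, configurable) are compared to the uniform expectation by the
Pearson chi-square statistic divided by its degrees of freedom
(cells − 1). The division makes tiles with equal grids directly comparable
and gives the score expectation ≈ 1 under the null; it is 0 iff all cells
are equal and undefined (NaN, flagged) for empty tiles. The grid is "fixed"
deliberately: a simple, deterministic binning keeps the score cheap,
single-pass and comparable across runs.

**Quality.** The per-tile/per-cell quality summary is the mean of per-base
Phred scores (bases weighted, not reads), which keeps pooling exact for
ragged read lengths.

**Alignment metrics.** A read's hits collapse to one outcome: unique (one
mapped location in the file) or multiple, with the mismatch stratum
{0, 1, 2, 3+} taken from the best (lowest-NM) hit. Uniqueness is derived
from the file itself — one occurrence of the (read id, mate) key — so the
pipeline is agnostic to aligner-specific tags; mapped records without an NM
tag are counted separately and excluded from the strata. The per-cycle
mismatch rate uses unique hits only, with masks reconstructed from MD tags
and flipped back to sequencing-cycle order for reverse-strand alignments;
the denominator at cycle c is the number of reads covering c. Target
coverage is counted at alignment starts (one count per read per bin), not
per-base pileup — sufficient for spotting uneven coverage at plot
resolution and much cheaper.

**Paired-end classification.** Precedence: both ends unusable → excluded
(counted); exactly one usable end → unpaired (by end: forward = only end 1,
reverse = only end 2 — instruments often read the two ends with different
efficiency, so they are kept apart); different references → different
chromosome; strand test (convergent libraries expect opposite strands;
`orientation="same"` flips the test for tandem mate-pair protocols) →
wrong orientation; then the absolute separation |start1 − start2| against
the configured closed interval [min, max] — the bounds themselves are
good, values strictly outside are below/above range. Ends that map
non-uniquely are treated as unmapped here, since an ambiguous location
cannot support a separation or orientation call. Signed distances
(start1 − start2, hence possibly negative) of good pairs are histogrammed
separately by the strand of the first end so strand bias is visible.

**Subset QC.** User lists are normalized (whitespace-truncated; `/1`, `/2`,
`#index` and SOLiD tag suffixes stripped) and matched against the sample;
per-tile subset counts are rendered side by side with the full sample under
identical layout and scale conventions. The accompanying chi-square test
compares subset counts to expectations proportional to the full counts,
pooling tiles with expected < 5 (smallest first) to keep the asymptotic
approximation honest; fewer than two bins leaves the test undefined. The
test is a formal supplement to the primary visual side-by-side comparison
and is labeled as such in the report.

## Synthetic data

The generator emulates the *shape* of the artifacts the metrics are built to
detect, with a single integer seed governing all randomness (same seed →
byte-identical files):

* linear within-tile composition gradient: `P(symbol) = 0.25 + a·x/x_extent`
  (default study amplitude a = 0.05), repeated identically on every tile;
* periodic cycle bias: +a on the focal symbol at every period-th cycle
  (default a = 0.05, period 5), emulating primer-reset periodicity in
  sequencing-by-ligation;
* per-tile quality offsets, per-tile mappability drops, and within-tile
  placement weights (e.g. an annular "donut" deficit with retention 0.3);
* per-cycle substitution rates with NM/MD tags exactly consistent with the
  injected masks;
* exact paired-end category mixes with truncated-normal insert sizes
  (default N(2000, 300²) within a 500–5000 bp window).

Infeasible specifications (probabilities leaving [0, 1]) are rejected before
any file is written. A JSON `TruthRecord` sidecar stores the effect
parameters and per-tile counts, sufficient to recompute every expected
statistic.

What the generator does **not** model: base-caller error correlation,
optical duplicates, realistic quality-score distributions, indels, or
reference sequence content (alignments are self-consistent SAM records over
an abstract reference). Passing recovery tests therefore demonstrates the
statistics are computed correctly and have the claimed sensitivity on
stylized effects — not that real artifacts of a given physical cause will
match these shapes.

## Defaults and problem sizes

The miniature test layout is 5 rows × 4 columns of 1000 × 1000 tiles (a
second 8 × 8 layout has the four corners unused, as on slides whose corners
carry no assay). Recovery analyses use 10⁵ reads of 30 cycles; null
calibrations use 200 tiles at ~500 reads each on a 5 × 5 grid (expected 20
reads per cell, comfortably above the chi-square approximation's needs) and
500 random 1 % subsets. These sizes give the quoted tolerances — gradient
slope error < 0.005, periodic amplitude error < 0.01, per-cycle rates
within 3 binomial SD — directly from binomial error propagation.

## Numerical and design choices

* Quality-offset autodetection: minimum quality character < 59 → Phred+33;
  ≥ 64 → Phred+64; the ambiguous 59–63 window defaults to +33 with a logged
  warning.
* Coordinates are treated as 0-based after subtracting the per-file minimum
  (taken over the same leading buffer used for offset detection); layout
  extents are half-open upper bounds. Out-of-extent reads are counted and
  clamped into the edge cell.
* Heat-map scales auto-range to the extrema of non-missing cells; unused
  layout regions and empty tiles render in a reserved color and never enter
  the scale.
* Unevenness ties break lexicographically by tile id; undefined scores sort
  last, flagged.
* Mismatch buckets {0, 1, 2, 3+} and the hit-count default (unique hits
  only, configurable) are package choices where multiple conventions exist.
* The report is static HTML assembled by the library (stdlib string
  formatting); PNGs are written without embedded timestamps so re-rendering
  unchanged results is byte-identical, and each plot's TSV regenerates it
  exactly through the same plotting functions.
* The CLI runs single-process; at the problem sizes the package targets the
  full pipeline completes in seconds, so job-level parallelism and cluster
  submission are out of scope.

## Limitations

Aligner invocation, BAM/CRAM input, per-base pileups, variant calling and
automated root-cause classification (fluidics vs optics) are out of scope:
alignments are consumed as SAM from an upstream aligner, and the report
presents patterns for human interpretation. The subset uniformity test
assumes the list was drawn from *this* sample's reads; ids from other runs
simply count as unmatched.
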