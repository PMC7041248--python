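# Methods

## The problem

In nanowell printing platforms for linked optical and single-cell RNA
sequencing, a droplet sorter records each cell's fluorescence as it is
dispensed to a known well of a nanoliter-scale plate, together with one
or more poly-dT capture beads. After pooled Drop-Seq-style library
preparation, each bead's reads share a bead barcode, but the pooling
destroys any physical record of which well the bead came from. The link
is restored chemically: every well is pre-printed with three
polyadenylated "coordinate oligos" that are captured on the bead
alongside the mRNA and sequenced as a separate well-index library.
`welltrace` implements the informatic side of this design: plate
indexing, coordinate-oligo counting, bead-to-well decoding, multi-bead
merging, fluorescence linkage, and the quality-control statistics used
to validate the decoding.

## Plate indexing model

Plates are tiled from `subarray_rows x subarray_cols` subarrays (14x14
by default). Each subarray shares one set of 14 *x* oligos (selected by
within-subarray column) and 14 *y* oligos (within-subarray row), and
carries one *z* oligo unique to the tile. A plate of `R x C` wells
therefore needs only `sub_c + sub_r + (R/sub_r)(C/sub_c)` distinct
oligos — 40 for the 56x42 (2352-well) format, 44 for 56x56 — while every
well receives a unique (x, y, z) triple. Because the x and y sets are
shared across tiles, the triple space is exactly the well set: the
triple-to-well table is a complete bijection, and a "wrong" but
well-formed triple always points at some other well rather than at
nothing. Decoding errors therefore manifest as misplacements, which is
precisely what the checkerboard concordance statistic is designed to
catch.

Conventions, chosen once and used everywhere (print plan, print log,
layout, truth tables): positions are 0-based, row-major, row 0 at the
top; subarray tiles are numbered row-major and the z index follows the
tile number.

Oligo barcodes are 8-mers designed by seeded rejection sampling with
pairwise Hamming distance >= 3 and no homopolymer run of 5+. Distance 3
guarantees that single-substitution correction during counting is
unambiguous (2·1 + 1 = 3). The published oligo sequences are not
bundled; generated sequences are drop-in equivalents for every
computation here, since only the id <-> sequence mapping matters.

## Well-index counting

Read 1 of the well-index library carries the bead barcode (12 nt) and
UMI (8 nt) on a 25 bp read, per the Drop-Seq bead design; read 2 (75 bp)
carries the 8-base coordinate barcode at a configurable offset (default
0) followed by poly-A. Counting collapses reads to one count per
distinct (bead, oligo, UMI) triple. Oligo matching accepts at most one
substitution (exact match wins; ambiguity returns no match); UMIs are
compared exactly — at these depths (tens of UMIs per bead-oligo pair
against a 4^8 UMI space) the collision rate is negligible. Quality
scores are ignored. No knee filtering is applied to bead barcodes; an
explicit bead whitelist (typically the barcodes present in the DGE) can
be supplied instead. Output rows are keyed by sorted barcode so the
matrix is invariant to read order.

## Decoding algorithm

For a bead x oligo UMI count matrix:

1. **Scale.** Each bead's counts are divided by its total UMIs. Beads
   with zero total are flagged and excluded (`zero_signal`).
2. **Background.** The per-oligo ambient level is the arithmetic mean of
   scaled values over all unflagged beads — including beads for which the
   oligo is true signal; no iterative re-estimation is attempted. It is
   subtracted from every row and negative results are clamped to 0
   (negative abundances are meaningless and would distort ratios).
3. **Dominance filter.** Within each axis the top and second corrected
   values are found. An axis passes when the top value is positive and
   at least `dominance_threshold` (default 3.0) times the second; the
   boundary is inclusive ("at least three times"). A runner-up of exactly
   0 passes with infinite ratio; an exact tie at the top has ratio 1 and
   fails any threshold above 1. A bead failing on *any* axis is removed
   (`failed_dominance`).
4. **Lookup.** The (x, y, z) triple of axis winners is looked up in the
   layout's inverse table; an absent triple yields `invalid_triple`
   (possible only if ids are used on the wrong axis), otherwise the bead
   is assigned to the well.

**Merging.** DGE columns of all beads assigned to one well are summed.
Counts are *not* re-deduplicated across beads: each bead carries its own
barcode, so a molecule cannot legitimately appear on two beads, and
summation preserves totals exactly.

**Annotation.** The merged matrix is joined to the print log on (row,
col). Logged wells missing from sequencing are reported as dropouts;
recovered wells missing from the log are flagged unmatched rather than
dropped, preserving visibility of misprints.

### Known degenerate case

On a plate consisting of a single subarray there is exactly one z oligo,
present on every bead; the background estimate for it approaches the
signal level itself and subtraction zeroes the z axis for beads whose z
fraction is below the mean, which then fail dominance. This is inherent
to the "mean across all beads" background model and harmless on real
multi-tile plates, where each z oligo is carried by only `1/n_tiles` of
beads. Use at least two tiles.

## QC and linked statistics

- **Species purity** (barnyard QC): per well, the fraction of mapped
  transcripts from the alphabetically first species; a well is pure when
  the majority fraction is at least the purity threshold (default 0.90,
  inclusive), otherwise mixed.
- **Pattern concordance**: the fraction of *non-mixed* wells whose
  species call matches the planned checkerboard; mixed wells are
  excluded from numerator and denominator and reported separately.
- **Beads recovered per well** and **transcripts by beads recovered**
  summarise recovery efficiency; with `k` printed beads each surviving
  independently with probability `p`, per-well recovery is
  Binomial(k, p) and the fraction of wells with at least one bead is
  `1 - (1-p)^k`.
- **Cell filters**: wells detecting at least `min_genes` genes
  (count > 0; boundary inclusive) are kept, optionally requiring a
  matched fluorescence record. Presets of 300 (cell-cycle style
  analyses) and 100 (surface-marker analyses) match common practice.
- **Sliding-window state fractions** (window 50) and **moving-average
  expression** (bin 30): cells are sorted ascending by the ordering key
  (stable sort; ties keep input order) and the window slides by one
  cell, yielding `n - w + 1` positions. Implemented with cumulative
  sums; tests compare against direct O(n·w) recounts.
- **Enrichment factor**: post-sort over pre-sort frequency of a target
  population.

## Synthetic experiment generator

The generator emulates a two-species checkerboard printing experiment —
the design used to validate positional decoding — and emits exactly the
files the pipeline consumes plus ground truth. Per planned well: a
misprint swaps the dispensed entity with probability `misprint_rate`
(the log keeps the intended label; the fluorescence is that of what was
actually dispensed); `beads_per_well` beads are printed and each is
recovered with `bead_recovery_prob`; each recovered bead draws
Poisson(`signal_index_umis`) UMIs on its well's three oligos and
Poisson(`ambient_index_rate`) on every other oligo; the cell's
transcript total is gamma-Poisson (negative binomial, mean
`transcripts_per_cell_mean`, shape `transcripts_dispersion`) over
per-species gene abundances (lognormal weights), split uniformly across
the well's recovered beads, with a `cross_contamination_rate` fraction
rehomed to uniformly random other beads. Fluorescence is lognormal per
channel per entity. All randomness derives from one mandatory seed via
spawned substreams, so identical configurations give byte-identical
output files.

Defaults (chosen once as a realistic operating point; the platform's
published experiments report no ambient or contamination magnitudes):
56x42 plate, 4 beads/well, recovery 0.75, signal 60 UMIs/oligo, ambient
0.05 UMIs/off-target oligo, transcripts mean 1500 with dispersion 2.0,
250 genes/species, cross-contamination 2%, misprint 0.5%. Under these
defaults a full run recovers ~99.5% of wells with ~99% pure wells and
~99.3% pattern concordance — the same regime the platform demonstrates.

What the generator does *not* model: sequencing quality scores beyond
uniform substitution errors, barcode synthesis errors, bead-specific
capture efficiency, doublets, gene-length or GC biases, and droplet or
optics physics. Passing tests therefore demonstrate the correctness of
the decoding and statistics under the stated noise model, not
performance on any particular public dataset.

## Numerical choices

- Scaled rows sum to 1 within 1e-9; all ratio comparisons are plain
  floating point with the inclusive boundary expressed as `>=`.
- Stable sorts everywhere an ordering is exposed (axis argmax ties,
  window orderings), so results are independent of input permutation.
- Problem sizes in the test suite and acceptance script are the
  published plate formats (2352 wells, up to 9408 beads) for end-to-end
  checks and small plates (14x28) for FASTQ-level round trips; these
  sizes give sub-second to few-second runtimes per check.

## Limitations

- The decoder assumes one plate per index library; multi-plate pooling
  would need per-plate z oligo sets (supported implicitly by larger
  layouts but not as separate files).
- Background subtraction is global, not per-axis; with extremely skewed
  bead populations concentrated in few wells the mean-based background
  can erode true signal (see the single-tile degenerate case above).
- Merging sums counts without cross-bead UMI deduplication; if the same
  molecule were somehow counted on two beads it would be counted twice.
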