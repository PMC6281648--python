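# Methods

## The model

RELACS replaces sonication with an intranuclear restriction digestion: the
enzyme CviKI-1 recognizes the degenerate tetramer RG|CY (R = A/G, Y = C/T)
and cuts bluntly between positions 2 and 3. Chromatin fragments therefore
have boundaries drawn from a fixed, genome-determined set of cut positions;
which boundaries are realized in a given nucleus depends on local chromatin
accessibility. Each sample's fragments receive a hairpin adapter carrying an
inline barcode at both ends, samples are pooled into one ChIP, and reads are
assigned back to samples from the barcode prefix on each mate.

This package models exactly that chain: deterministic site geometry
(`genome_digest`), coding-theoretic barcode decodability (`barcode_design`,
`demultiplex`), quantitative normalization from multiplexed inputs
(`quantnorm`), and a generative simulator tying them together (`simulate`).

## Motif scanning

Coordinates are 0-based, half-open everywhere (including BED output). A cut
site is recorded as the position of the first base 3′ of the blunt cut,
i.e. match start + `cut_offset` (2 for RG|CY).

A genome base matches a pattern code only when it is a concrete A/C/G/T
contained in the code's set; N (or any ambiguity code) in the *genome* never
matches. This is conservative and reproducible — assembly gaps produce no
phantom sites.

RGCY is its own reverse complement as a degenerate pattern, so forward-strand
scanning is complete. The scanner nevertheless supports non-palindromic
motifs: the reverse strand is scanned by matching the reverse-complement
pattern on the forward strand (a match starting at `s` cuts at
`s + len − cut_offset`) and merging deduplicated cut positions. Successive
RGCY matches can never overlap (no suffix of RGCY is a prefix of RGCY under
the IUPAC sets), which also keeps the match-count variance near-binomial —
used by the density sanity checks.

Implementation: per pattern position a 256-entry boolean lookup table over the
byte-encoded sequence, AND-combined across shifted views; memory stays at a
few bytes per genome base, so full mammalian chromosomes fit comfortably.

## Gaps and bias tables

* **Gaps** are inter-site intervals (fragments) of length strictly greater
  than the threshold (default 1000 bp). Chromosome-terminal segments are
  excluded by default and included behind a flag; with no interior sites and
  terminals included, a whole chromosome counts as one gap. The blind
  fraction is gap bases over total genome length (all sequences in the FASTA;
  no decoy filtering unless an include-pattern is given). N-runs are not
  excluded from the denominator.
* **Cutability** (`site_density_by_class`): cut positions falling in each
  class's intervals divided by class length in kbp. Intervals are merged per
  class first, making the statistic invariant to how intervals are split.
* **Accessibility** (`cut_usage`): each observed fragment contributes two
  boundary positions; boundaries that do not coincide with an indexed cut
  position are tallied as violations and excluded. Ends-per-site is computed
  per class and divided by the genome-wide mean to give relative usage.

## Barcodes and decoding

Decoding is nearest-neighbour under Hamming distance on the first L bases of
each mate, accepting only a unique minimum within the mismatch budget
(default 1). The sphere-packing condition min-distance ≥ 2m + 1 guarantees
zero misassignment for reads with ≤ m barcode-region errors; validation
enforces it and the test suite verifies it exhaustively by corrupting every
barcode at every position.

Discard categories: `too_short` (prefix shorter than L), `ambiguous` (tied
minimum), `mate_disagreement` (both mates decode but to different barcodes —
the biological expectation is agreement, since both fragment ends carry the
same sample's adapter; a flag relaxes this for chimera-tolerant decoding),
and for budget violations `no_match` when the best distance exceeds L/2 (the
prefix does not resemble any barcode) versus `mismatch_exceeded` otherwise.
That boundary is this package's own convention; both categories mean
"discarded" downstream. N in a read counts as a mismatch by default.

One junction base (the T complementing the A-tail) is expected between
barcode and insert and is trimmed with the barcode but not checked against a
fixed letter, keeping decoding robust to chemistry variants. Unassigned
pairs are written to `undetermined` FASTQ files, never silently dropped.

The default hairpin template (stem, loop with one cleavable deoxyuridine,
barcode slot, 3′ T-overhang) is schematic: it has the right architecture for
round-trip tests but makes no claim of matching any vendor oligo. Real
adapter sequences are supplied by the user.

## Quantitative normalization

Fragments are attributed to 10 kb bins by midpoint — the simplest unbiased
rule; this deliberately differs from per-base extended coverage used by
coverage-track tools, and matters only at bin boundaries. Fragments with
blacklisted midpoints are dropped; bins fully inside blacklist intervals are
masked.

Scaling factors use the median-of-ratios estimator (per sample, the median
over bins of count / per-bin geometric mean across samples) on unmasked bins
non-zero in every sample, rescaled to geometric mean 1. The estimator is
robust to a minority of enriched bins; with fewer than 50 shared non-zero
bins it falls back to total-count ratios with a warning. Under the
geometric-mean convention, a sample with exactly double counts gets factor
√2 and its partner 1/√2 (ratio 2).

FRiP is the fraction of fragments overlapping any merged peak by ≥ 1 bp; the
RPKM-scale enrichment is FRiP divided by the fraction of the genome covered
by peaks, times 1e6, so pure background scores exactly 1e6 regardless of the
peak set's size. Log2 ChIP/input ratios use pseudocount 1 (one count per bin)
by default; masked bins are emitted as NaN.

## The simulator

`simulate` generates: (1) a uniform random genome at a configurable GC
(default 0.5, giving one RG|CY site per ~64 bp); (2) a block partition
(5 kb blocks) into region classes with accessibility weights and optional
ChIP enrichment multipliers; (3) fragments sampled with replacement from the
inter-site intervals inside a length window (default 30–1000 bp, a stand-in
for library size selection, configurable and recorded in the manifest) with
probability ∝ class weight; (4) read pairs whose mates are
`barcode + junction T + insert` from the fragment's two ends (mate 2 reverse
complemented), truncated at the fragment boundary when the insert is short;
(5) i.i.d. substitution errors at the configured rate, uniform over the three
alternatives, with barcode-region error counts recorded per mate; (6) flat
duplicate re-emission and optional chimeric pairs (mates carrying different
samples' barcodes) to exercise the corresponding discard paths. Every read
pair is linked to its sample and fragment in a JSON truth manifest; a single
integer seed makes all outputs byte-identical across runs.

Not modelled, hence not demonstrated by passing tests: PCR amplification bias
beyond flat duplicates, indel errors, quality-score profiles, mappability and
repeat structure, nucleosome positioning, and the outer Illumina-index
multiplexing layer. Real genomes are also far from uniform in composition, so
absolute site densities and gap counts on real assemblies are checked
separately against the whole-genome references rather than inferred from the
simulator.

## Problem sizes and numerical choices

The test suite runs the pipeline at desk scale: 100,000-pair demultiplexing
roundtrips, 2 Mb genomes for factor recovery, 10,000-bin estimator checks.
The acceptance script uses a 5 Mb genome and 4 × 200,000 read pairs —
large enough that median-of-ratios noise sits well below the 10% consistency
band being demonstrated, small enough to run in well under a minute.
Stochastic assertions use 5-σ binomial bands or 5–15% relative tolerances at
these sizes, and every random draw flows from one seed. Scaling factors are
validated to geometric mean 1 within 1e-9; gap thresholds are strict
inequalities; degenerate inputs (empty site sets, all-zero samples,
zero-length intervals, desynchronized mate files) raise typed errors rather
than propagating NaNs.
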