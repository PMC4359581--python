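# Methods

This note documents the models, conventions and numerical choices behind
`gbskit`, in the order data flows through the package.

## Library geometry

A GBS template molecule is

```
[in-line barcode][site ... insert ... site][common adapter]
```

where `site` is the restriction enzyme's recognition sequence (IUPAC
degenerate codes allowed; ApeKI `GCWGC` cuts `G^CWGC`, i.e. cut offset 1).
Read 1 starts at the barcode; read 2 reads the opposite strand, so its
sequence is revcomp(barcode + fragment) followed by the adapter — it runs
through the reverse-complemented barcode before reaching the adapter.
Fragments are short (size-selected), so adapter read-through on both mates
is the norm rather than the exception.

## In silico digest

Cut sites are found by scanning the top strand with the IUPAC pattern
(overlapping matches allowed; each match contributes the cut position
`match_start + cut_offset`). If the pattern is not its own reverse
complement at the IUPAC level, the reverse-complement pattern is scanned
too and its cuts mapped back onto the top strand; the merged set is
deduplicated. Fragments are the inter-cut intervals, so their lengths sum
exactly to the chromosome length. Conventions chosen where the field's
formats force or the literature leaves a choice:

* Coordinates are 0-based half-open; BED output is standard BED4.
* Size selection is inclusive on both bounds.
* Chromosome-end fragments lack one restriction end, so they are reported
  (`chrom_end` category) but never counted as sequencable.
* `include_full_site` extends each retained fragment's frame left by the
  left enzyme's cut offset and right by (site length − cut offset) of the
  right enzyme, clamped to the chromosome — the overhang-completion that is
  otherwise done by editing the BED by hand.
* The fragment-length histogram uses 10 bp bins by default (configurable).
* A third-enzyme screen counts retained fragments containing ≥ 1 match of
  that enzyme (either strand) fully inside the fragment interval.
* Sequenced-base totals are the union of the per-fragment read intervals.

## Barcode design

Barcodes are codewords of a nucleotide Hamming(15,11) code: each base maps
to two bits (A=00, C=01, G=10, T=11) and each bit plane is encoded
independently with the binary Hamming(15,11) code (parity at positions 1,
2, 4, 8). Two distinct codewords differ in ≥ 3 bits within at least one
plane, hence in ≥ 3 nucleotide positions; a single nucleotide substitution
flips ≤ 1 bit per plane and is corrected by per-plane syndrome decoding.
An `N` is read as `A` and flagged as a correction.

Variable lengths: a barcode of target length L ≤ 15 is a codeword whose
data symbols at codeword positions > L are forced to `A` and then cut off
(poly-A padding). Positions 9–15 are all data positions and the last
parity position is 8, so for L ≥ 8 re-appending `A`s reconstructs the
exact codeword and the correction guarantee survives. Length 16 extends a
full 15 nt codeword by one random base; it has no algebraic guarantee, so
every set-level constraint is enforced on it by explicit checking.

Set-level constraints (all with respect to the design enzyme):

* no barcode contains a recognition match, nor creates one at the
  barcode/site junction (checked on barcode + recognition with
  compatible-expansion semantics, degenerate codes worst-cased);
* no barcode is a prefix of another barcode's (sequence + recognition)
  string — prefixes are what collide in left-to-right matching;
* every pair of (barcode + recognition) strings differs in ≥ 3 positions
  over their shared prefix, where a position with intersecting IUPAC
  expansions on the two sides counts as distance 0 (conservative: the
  degeneracy can never be relied on for separation).

Generation draws random codewords per target length (lengths cycle over
the requested range so the enzyme site is staggered across sequencing
cycles), rejects constraint violators, and among a pool of valid
candidates greedily picks the one minimising the per-cycle max−min base
count spread — the nucleotide-balance heuristic that protects cluster
calling on low-diversity libraries. Generation is deterministic for a
fixed seed; an exhausted attempt budget raises an error suggesting fewer
barcodes or a wider length range.

## Demultiplexing and trimming

Matching compares the read start with each sample's probe (barcode, plus
recognition site in `rad`/`gbs` modes). Barcode mismatches are plain
character mismatches; site mismatches are IUPAC-aware, and an `N` read
base never satisfies any pattern position (N-rich reads must not match
everything). A sample is a candidate if barcode and site mismatches are
within their budgets (defaults 1 and 1). The winner has the fewest barcode
mismatches, then the fewest site mismatches, then the longest barcode; a
surviving tie goes to `undetermined` (the demultiplexer never guesses).
Reads shorter than a probe skip that probe. Undetermined reads are written
untrimmed so barcode discovery can run on them.

3' trimming searches left to right and trims at the first (leftmost)
signature match — the conservative choice for short-insert libraries:

* `gbs`, read 1: recognition site (≤ site budget) followed by the first
  `a = min(|adapter|, bases remaining)` adapter bases with
  ≤ floor(a × 0.1) mismatches; `a` may be 0 when the site ends flush with
  the read end.
* `rad`/`inline`, read 1: adapter alone, minimum overlap 3.
* read 2 (`rad`/`gbs`): recognition site followed by the
  reverse-complemented barcode of the matched sample (full barcode budget;
  ≥ 3 barcode bases must be visible), and — when the barcode is fully
  visible and an adapter is configured — the adapter start after it, under
  the same partial-overlap rule as read 1. The adapter anchor exists
  because a fragment can by chance contain a site-plus-barcode lookalike
  within the mismatch budgets; genuine read-through always continues into
  the adapter, and if sequencing errors corrupt the adapter beyond its
  budget the read is simply left untrimmed and repaired by the pair
  consistency step below. Read 2 beginning with a recognition match is
  5'-trimmed symmetrically to read 1.

Paired-end consistency: when at least one mate was 3'-trimmed and the
trimmed lengths differ, the first `min(w, |short|)` bases of the longer
read are compared with the reverse complement of the last bases of the
shorter read, with `w = |site| + longest barcode` and a budget of
site + barcode mismatch budgets. A match means both mates end at the same
template position, so the longer read is cut to the shorter length;
otherwise the longer read is trusted and the shorter one is re-cut from
its untrimmed form to the longer length. This step is what lets paired
data recover reads whose own junction is censored by the read end.

## Simulator

The simulator emits, for every (barcode, fragment) pair, equal numbers of
reads from both fragment ends (the right end uses the reverse-complemented
fragment): read 1 = barcode + fragment + adapter, read 2 =
revcomp(barcode + fragment) + adapter, both padded with `A` to the read
length and truncated to it. Sequencing noise is an independent per-base
substitution with probability `error_rate` (default 0.01); the substituted
base is uniform over the other four symbols of {A, C, G, T, N}. The
"one error per 100 bases" magnitude is implemented as an independent 1%
rate rather than exactly-one-per-100, because only co-occurring errors in
a barcode can defeat a 1-mismatch budget, and an observable
demultiplexing loss of ~1% at this rate requires that possibility.
Qualities are constant `I` (Phred 40): the toolkit never filters on
quality, so a quality model would add nothing to what the tests measure.
Output is byte-identical for a fixed seed.

Random fragment sets draw lengths uniformly over the requested range and
build (concrete site) + random insert + (concrete site), redrawing any
candidate with an extra internal recognition match — a real digest product
cannot retain one. Reference mode extracts size-selected digest fragments
with both full sites included. What the synthetic data does *not* emulate:
indels, PCR duplicates, coverage and GC bias, quality decay along the
read, and chimeric molecules. Passing tests therefore demonstrate the
correctness of the matching/trimming logic under substitution noise, not
robustness to every artefact of a real instrument run.

## Evaluation conventions

Units are reads, or pairs counted once in paired mode (the barcode lives
on read 1, so assignment is per pair). Sensitivity = correctly assigned /
total simulated units; misassignments are reported per million units
(1 decimal). Trimming statistics are computed over the correctly assigned
units: a unit is correctly trimmed when its **read 1** length equals the
length a perfect trimmer with pair information would produce. With
fragment length F, site length R, barcode length B and read length L,
that expectation is min(F − 2R, window) for `gbs`/`rad` (window =
L − B − R after the default 5' trim), min(F − R, window) for single-end
`rad` (no pair information can remove the trailing site), and
min(F, L − B) for `inline`. Read 2 is not scored directly: inserts whose
far junction falls between the two mates' visible windows are
unresolvable for read 2 by any method, while the pair-consistency step
resolves read 1 — scoring read 1 measures exactly what the correction can
and cannot do. Percentages are rounded to 2 decimals and trimming errors
per thousand to the nearest integer, the precisions used throughout the
reports.

## Scale of the shipped validation

The acceptance protocol runs at desk scale: 10 samples (barcode lengths
8–16), 500 fragments of 60–200 bp, 4 reads per locus — 20,000 pairs — at
1% error; plus a 5-sample, 200-fragment error-free control with fragments
of 60–80 bp. The control's fragment range is chosen so that every 3'
junction lies fully inside a 100 bp read: with longer fragments some
junctions are censored by the read end, which is a geometric property of
the library (it is what depresses *single-end* trimming sensitivity by a
few percent in the noisy runs), not an error-model effect, and the
zero-noise run is meant to isolate the latter. Digest correctness is
checked against an independent brute-force scan on twenty random genomes
of up to 10 kb.

## Known limitations

* Recognition sequences with interior gaps (BcgI-style) and methylation
  sensitivity are out of scope; nicking enzymes are not modelled.
* Degenerate-palindromy is decided at the IUPAC-set level; enzymes whose
  biological symmetry differs from their pattern symmetry are scanned on
  both strands, which is correct but slightly slower.
* Barcode design below length 8 would cut into the parity positions and
  lose the algebraic guarantee; the generator's supported range is 8–16.
* The demultiplexer is single-threaded; `--threads` is accepted for
  pipeline compatibility and output order is always stable.
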