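# gbskit

Tools for designing and processing **genotyping-by-sequencing (GBS)**
experiments — reduced-representation libraries built by restriction
digestion, in-line barcoding and short-read sequencing.

GBS libraries have a distinctive geometry: every fragment starts and ends
with the restriction enzyme's recognition site (e.g. ApeKI, `G^CWGC`,
W = A/T), and each sample is tagged by a variable-length **in-line barcode**
read in the first sequencing cycles, immediately 5' of the site remnant.
Standard Illumina demultiplexing cannot handle in-line barcodes, and generic
trimmers ignore the restriction-site structure. `gbskit` covers the whole
workflow:

* **digest** — in silico digestion of a reference genome: IUPAC-aware cut
  site discovery on both strands, fragment size selection, per-enzyme and
  two-enzyme statistics, fragment-length histogram, and a BED file of the
  bases a given read length would actually sequence.
* **barcodes** — random, self-correcting barcode sets built from nucleotide
  Hamming(15,11) codes (A=00, C=01, G=10, T=11 over two independently
  encoded bit planes). Any two barcodes differ in ≥ 3 positions over their
  shared prefix *including the enzyme site*, no barcode contains or creates
  a recognition site, and a single substitution in any barcode is corrected.
  Shorter barcodes are poly-A padded codewords, so correction survives
  truncation (lengths 8–15; length 16 adds one checked extra base).
* **demux** — assigns reads to samples by barcode (+ optional enzyme site,
  modes `inline` / `rad` / `gbs`), with configurable mismatch budgets
  (default 1 barcode + 1 site), trims the 5' barcode/site and the 3'
  read-through (site + common adapter on read 1; site + reverse-complement
  barcode + adapter on read 2), and applies a paired-end consistency
  correction that reconciles the two mates' trim points. Per-sample FASTQ
  plus a statistics table come out.
* **discover** — counts candidate barcodes (lengths 6–16) in a FASTQ,
  keyed by the enzyme whose site follows them; use it on a large
  undetermined fraction.
* **simulate / evaluate** — a GBS read simulator with per-read ground truth
  (substitution errors at a configurable per-base rate, adapter
  read-through, both fragment ends), and an evaluator reporting
  demultiplexing sensitivity, misassignments per million reads, trimming
  sensitivity and trimming errors per thousand reads.

Everything is importable from Python (`import gbskit`) as well.

## Worked example

Design six ApeKI barcodes, simulate a small paired-end experiment with a 1%
per-base error rate, demultiplex it and score the result:

```sh
gbskit barcodes --enzyme ApeKI -n 6 --min-len 8 --max-len 16 --seed 7 --out barcodes.tsv
gbskit simulate --random-fragments 200 --enzyme ApeKI --min 60 --max 200 \
    --barcodes barcodes.tsv --reads-per-locus 4 --error-rate 0.01 --seed 7 --out sim
awk -F'\t' '{printf "S%02d\t%s\t%s\n", NR, $1, $2}' barcodes.tsv > sheet.tsv
gbskit demux --r1 sim/reads.R1.fastq --r2 sim/reads.R2.fastq --sheet sheet.tsv \
    --mode gbs --adapter AGATCGGAAGAGCG --out demux
gbskit evaluate --truth sim/truth.tsv --demux-dir demux --mode gbs --paired --out eval.tsv
```

`eval.tsv` then reads:

```
total_units	4800
assigned	4766
correctly_demultiplexed	4766
misassigned	0
undetermined	34
sensitivity_pct	99.29
misassignments_per_million	0.0
correctly_trimmed	4763
trimming_sensitivity_pct	99.94
trimming_errors_per_thousand	1
```

4,800 simulated pairs; 99.29% were assigned to the right sample (the ~0.7%
loss is pairs whose barcode or site collected ≥ 2 sequencing errors, beyond
the 1+1 mismatch budget), none were misassigned (the distance-3 code keeps
samples ≥ 3 mismatches apart), and 99.94% of correctly assigned pairs were
trimmed to exactly the true insert length — the paired-end consistency step
repairs trims that either mate misses.

An in silico digest of a reference works the same way:

```sh
gbskit digest --fasta genome.fasta --enzyme ApeKI --min 60 --max 200 \
    --read-length 100 --include-full-site --out digest
```

which for a random 50 kb test genome reports 102 ApeKI cut sites, 103
fragments of which 20 fall in the 60–200 bp sequencable range, and writes
`digest/sequenced.bed` with the predicted sequenced bases.

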