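# Methods

`lasv` calls insertions and deletions in the 50–10,000 bp range from
synthetic long-read (SLR / linked-read) sequencing, optionally augmented
with low-coverage long reads.  This note describes the model behind each
stage, the tunable parameters, the synthetic-data generator, and the
numerical and design choices that are not obvious from the code.

## Problem setting and overall model

SLR technologies (stLFR, TELL-Seq, 10x linked reads) shear input DNA into
long fragments of 5–100 kbp, attach a per-fragment barcode, and sequence
short read pairs from each fragment.  Short reads alone resolve few SVs in
the 50 bp–10 kbp range; whole-genome assembly resolves more but is
expensive.  `lasv` takes a middle road: it tiles the reference into
overlapping windows, uses barcodes to decide which reads genuinely
originate from each window, assembles each window locally, aligns the
contigs back to the window, and reads indels directly off the alignment
CIGAR.  In hybrid mode, long reads overlapping a window join the assembly
and close gaps between contigs.

The stages, with their key assumptions:

1. **Badly-aligned read filtering.**  A read pair is *badly aligned* when
   it is high quality — every base Phred strictly above `min_base_phred`
   (default 20) on both mates — yet shows a placement problem: a mate
   unmapped or on an unplaced contig, soft-clipping above
   `max_softclip_fraction` (default 0.20) of the stored bases, or a zero AM
   tag (the LongRanger flag for reads that could not be clustered with
   same-barcode reads).  The quality gate is a necessary condition and the
   placement/AM signals are alternatives: *quality AND (placement OR
   zero-AM)*.  Low-quality reads mis-align for reasons unrelated to
   variation, so they are never recruited.  Kept pairs go into a
   barcode-keyed map `M`; `M(B)` returns all stored pairs whose barcode is
   in a list `B`.  Pairs without a barcode on either mate cannot be
   recruited into a distant window and are dropped (counted).  An absent AM
   tag (non-LongRanger aligners) simply never triggers the AM condition.

2. **Windowing and barcode selection.**  Windows are `segment_length`
   (50 kbp) long and advance by `segment_length − segment_overlap`
   (40 kbp), so interior bases near boundaries lie in exactly two windows.
   The overlap bounds the largest deletion the caller can see: an event
   that swallows a whole overlap region is split across windows and lost,
   which is why the reportable ceiling (`max_sv_len`, 10 kbp) equals the
   overlap.  A barcode joins the window's list `B(s)` when at least
   `min_barcode_pairs` (3) of its read pairs align inside the window and
   the extent from leftmost alignment start to rightmost alignment end is
   strictly greater than `min_barcode_span` (5 kbp).  Both thresholds
   separate fragments truly drawn from the window (many pairs, broad
   extent) from spurious repeat hits (few reads, locally clustered).  The
   extent is measured within the window to avoid leakage from neighboring
   windows.  Only primary, mapped alignments count.  Gathering collects
   window-aligned pairs of selected barcodes (fetching out-of-window mates
   by indexed lookup, capped at `max_mate_lookups` = 10,000 per window)
   plus everything in `M(B(s))` — including unmapped reads, which is how
   inserted sequence absent from the reference becomes assemblable.

3. **Local assembly.**  A de Bruijn graph over (k+1)-mers (k = 55,
   single-k; odd so no k-mer is its own reverse complement) counted on
   both strands of every read, making the graph invariant under read order
   and orientation.  Short-read k-mers need `solid_coverage` (2)
   occurrences; long-read k-mers are admitted only with corroboration
   (present in the short-read spectrum, or in ≥ 2 distinct long reads),
   because even 0.1–1 % per-read error floods a 55-mer spectrum with
   singleton artifacts.  Edges are compacted into unitigs; every unitig has
   a reverse-complement twin and the two share one usage budget.

   Three behaviors distinguish this assembler from a bacterial-style one:

   * *Relaxed simplification.*  Only short (< k+10 bp) coverage-1 dead
     ends (sequencing-error tips) and bulge branches below a heterozygous
     coverage floor (`het_coverage_floor_frac` = 0.25 of the
     length-weighted median unitig coverage, when a parallel branch is
     above it) are removed.  Balanced bulges are the two alleles of a
     heterozygous variant and long tips mark coverage drops; both carry
     signal and both survive.
   * *Relaxed path deduplication.*  Paths are seeded from every unused
     unitig in descending length order and extended greedily both ways
     (successor choice: available capacity, then highest coverage, then
     sequence — fully deterministic).  The per-unitig usage cap of two
     lets a bulge's branches each be spelled through the shared flanks —
     one contig per allele — and guarantees termination on tangled
     graphs.
   * *Tip-aware extension.*  At a junction, if a long dead-end unitig
     (length ≥ `tip_vicinity_len` = 2k) is incident at the junction node
     or its immediate neighbors — excluding the path itself and the
     candidate successor — extension stops and the path is flagged.  A
     long tip at a junction is the signature of a local coverage drop
     inside one copy of a repeat; extending through such a junction splices
     sequence across the gap and manufactures a false deletion.  The check
     applies at every junction regardless of out-degree, because the
     chimera presents as a two-way branch (dead-end branch plus repeat
     shortcut).  Excluding the chosen successor itself keeps legitimate
     dead ends traversable: a backbone that simply ends (window edge,
     fragmented coverage) is entered and the path stops there naturally.

   In hybrid mode, contig ends are joined when a long read carries
   end-anchored matches to both (anchors ≥ `gap_anchor_len` = 200 bp at
   ≥ `gap_anchor_identity` = 0.85, chosen so a 1 %-error HiFi-like read
   passes while random sequence fails with negligible probability); joins
   are applied greedily by support count, each contig end used once, and
   the gap is spelled by the best-identity supporting read — with
   HiFi-grade error a single read is within the accuracy the downstream
   aligner tolerates, so no multi-read consensus is computed.

4. **Contig alignment and calling.**  Contigs at least `min_contig_len`
   (2k) long are aligned to their window ± `align_pad` (1 kbp, so events at
   window edges resolve): unique 31-mer seeds, longest collinear chain, and
   Gotoh affine-gap DP between adjacent anchors (match +1, mismatch −4,
   gap open −6, gap extend −1; a length-L gap costs open + L·ext).  The DP
   is exact (validated against a full-matrix oracle); problems beyond
   4×10⁷ cells fall back to a unit-cost alignment rescored with the affine
   scheme.  Both strands are tried; the better score wins.  Alignments
   below 90 % *gap-compressed* identity (each indel run counts one column,
   so an SV-sized gap does not mask a faithful alignment) are discarded.
   Leading/trailing indel operations are converted to soft clips so window
   edges cannot emit artifact calls.  Every I/D operation with length in
   `[min_sv_len, max_sv_len]` becomes a call; calls are left-aligned
   (standard VCF normalization — without it, the same event found in two
   overlapping windows or from two allele contigs can sit at different
   coordinates in repetitive context and survive deduplication twice),
   deduplicated on (chrom, pos, type, length) keeping the first by segment
   then contig order, sorted, and written as sequence-resolved VCF 4.2
   with SVTYPE/SVLEN/END and `./.` genotypes (no genotyping is attempted).

5. **Evaluation.**  Deletions and insertions are compared separately.  A
   call matches a truth record on the same chromosome and type when the
   breakpoints are within `match_distance` (500 bp) and, optionally
   (default on, disableable for a pure distance criterion), lengths agree
   within a 0.7 size-similarity ratio.  Matching is greedy by ascending
   distance and one-to-one; on small instances it provably agrees with
   optimal assignment (tested by brute force).  Empty callsets report
   precision 1.0 with an explicit undefined flag and recall 0.

## Synthetic-data generator

The generator emulates the state of data *after* a barcode-aware aligner,
without running one: fragment provenance is known, so each read is written
to a position-sorted BAM at its true reference-projected coordinate.

* Diploid genomes: a uniform-random ACGT background, optionally with
  planted interspersed repeat pairs (identical copies), with
  non-overlapping indels (≥ 2 kbp apart, kept clear of chromosome ends)
  applied per zygosity to one or both haplotypes.  The default size
  mixture covers Alu-like (~300 bp), L1-like (4–6 kbp), short
  STR-like, and uniform events; explicit length/type lists override it.
  Truth VCF and haplotypes are mutually consistent by construction
  (property-tested against independent string surgery).
* SLR reads: fragments uniform 5–100 kbp (clipped at chromosome ends so
  coverage stays uniform there), one fragment per barcode by default
  (TELL-Seq-like; collisions configurable), read pairs (2×150 bp, insert
  350 ± 35) sampled along each fragment at ~0.2× per-fragment coverage
  until the requested genome coverage is met; per-base substitution errors
  at 0.001 by default.  Reads crossing an SV junction are soft-clipped at
  the junction; reads inside inserted sequence are unmapped (placed at
  their mate when possible); clipped reads carry AM:0, everything else
  AM:1 — the minimal emulation that exercises the filter's AM condition.
  An optional zero-coverage interval suppresses all pairs overlapping it
  (the coverage-drop scenario).
* Long reads: lengths uniform 9–12 kbp, per-read error uniform
  0.001–0.01, 90 % substitutions / 10 % single-base indels, with a
  truth-aligned BAM (clip-aware position, simple M CIGAR — positions are
  only used for window overlap).

What the generator does **not** emulate: GC and chemistry-specific
coverage biases, chimeric fragments, barcode collisions under 10x-style
chemistry (unless configured), alignment-error artifacts of a real
aligner, and realistic repeat landscapes (repeats exist only where
planted).  Passing tests therefore demonstrate algorithmic correctness
under controlled conditions, not performance on real genomes.

## Benchmark suites and the problem sizes used

The replicated suites in `lasv.benchmarks` (shared by the test suite and
`scripts/acceptance.py`) fix these conditions:

* **Homozygous exactness** — 20 replicates, 1 Mbp genome, 10 homozygous
  SVs per replicate with lengths cycling {60, 300, 1000, 5000, 9500} ×
  {DEL, INS}, 40× error-free SLR reads.  Checks per-replicate precision
  and recall ≥ 0.9 and that every matched call has exactly the implanted
  length.
* **Heterozygote retention** — 50 replicates, one het SV each (length
  uniform 50–5,000 bp), diploid 40× reads on a 40 kbp genome (one window:
  the behavior under test is graph-level, so a single segment suffices).
* **Coverage-drop guard** — 50 replicates, 30 kbp genome, identical
  300 bp repeat copies at 8.0 and 11.0 kbp, a 500–2,000 bp zero-coverage
  gap between them, no SV.  With the tip rule: deletion calls in at most
  1/50 replicates; with the rule ablated: false deletions in ≥ 10/50,
  showing the rule (not chance) prevents them.
* **Hybrid benefit** — 50 paired-seed replicates, 80 kbp genome, 8
  homozygous SVs (150/600/2,500 bp), deliberately reduced 15× SLR
  coverage, with vs without 5× long reads.  At 15× the 55-mer spectrum
  has occasional holes that fragment contigs and cost recall; long-read
  k-mers and gap closing recover most of it.  Eight events per replicate
  give the recall comparison enough resolution to observe strict gains.

Genome lengths for the last three suites are the package's choice: large
enough to contain the phenomenon (full barcode selection, the repeat/gap
geometry, several independently placed events), small enough that 50
replicates of a full pipeline run remain a routine test.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; conversion to 1-based
  happens once, at VCF writing.  Call positions use the VCF anchor-base
  convention.
* k must be odd and ≥ 15; k+1 ≤ 56 so packed k-mers fit two 64-bit words
  (counting uses 2-bit packed integers in a numba kernel; identity of the
  result with direct string enumeration is oracle-tested).
* Ties during path extension are broken by coverage then lexicographic
  sequence; unitig numbering derives from deterministic edge insertion
  order, so assemblies are byte-identical across runs.  Per-segment seeds
  derive from SHA-256 of (global seed, segment id).
* Reads with non-ACGT bases are split at those bases before counting.
  All-too-short read sets yield an empty graph and an empty contig list;
  empty windows produce a header-only VCF.
* A segment failure is isolated and recorded; the run aborts only when
  more than 10 % of segments fail.  Execution is sequential; results are
  independent of scheduling by construction (each segment's work depends
  only on its own inputs), and `--threads` is accepted for interface
  compatibility.
* Palindromic unitigs (possible since k+1 is even) twin with themselves;
  the shared usage budget covers this case.

## Known limitations

* Deletions longer than the window overlap (10 kbp) are invisible by
  design; inversions, translocations, and genotype (het/hom)
  classification are out of scope, and the VCF reports `./.` genotypes.
* Tandem arrays longer than ~k collapse into cycles in the graph, so STR
  expansions/contractions whose repeat tract exceeds the k-mer length are
  generally not resolved — consistent with the known weakness of
  assembly-based callers in simple repeats.
* A single contig alignment (best chain) is used per contig; split-contig
  breakend calls are not attempted.
* Nearby small gaps in one alignment are not merged into a single SV, so
  an event an aligner splits into several operations may be reported
  fragmented or missed.
* The mate-lookup cap trades completeness for bounded I/O on
  high-coverage regions; beyond it, half-pairs stay single (their mate is
  treated as absent).
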