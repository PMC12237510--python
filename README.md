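# lasv — local-assembly structural variant calling for linked reads

`lasv` calls insertions and deletions in the 50–10,000 bp range from
synthetic long-read (SLR / linked-read) sequencing data — stLFR, TELL-Seq,
10x-style libraries in which short read pairs carry a per-fragment barcode
(BX tag) — optionally augmented with low-coverage (~5×) long reads.  It is
aimed at the size class where short-read callers lose sensitivity
(especially for insertions) but deep long-read sequencing is not available.

Instead of whole-genome assembly, `lasv` tiles the reference into 50 kbp
windows overlapping by 10 kbp and assembles each window locally from the
reads whose barcodes demonstrably originate there, plus all *badly
aligned* read pairs sharing those barcodes (high base quality, but
unmapped, heavily soft-clipped, on an unplaced contig, or carrying a zero
AM tag) — the reads that concentrate at SV breakpoints and inside inserted
sequence.  A window's barcode `b` enters its list B(s) when ≥ 3 of its
read pairs align in the window with an aligned extent > 5 kbp.  The local
de Bruijn assembler (k = 55) deliberately departs from consensus-oriented
assembly in three ways: heterozygous bulges are kept and both alleles are
spelled as contigs; only unambiguous error artifacts are simplified away;
and path extension refuses to cross a junction with a long dead-end
nearby, the signature of a coverage drop that would otherwise be spliced
into a false deletion.  Contigs are realigned to their window (seed,
chain, affine-gap DP: match +1, mismatch −4, gap open −6, extend −1) and
every I/D CIGAR operation in the size window becomes a call; calls are
left-aligned, deduplicated on (chrom, pos, type, length), and written as
sequence-resolved VCF 4.2.  In hybrid mode long reads also feed the graph
(with corroboration requirements) and join contigs across assembly gaps.

The package ships a simulator (diploid genomes with implanted SVs,
barcoded SLR reads written as a truth-aligned BAM, HiFi-like long reads)
and a Truvari-style evaluator (±500 bp breakpoint tolerance, optional 0.7
size-similarity gate, precision/recall/F1), so the whole pipeline runs and
is testable with no external data or aligner.

## Worked example

```bash
lasv simulate --out-dir sim --genome-length 200000 --n-svs 5 \
    --slr-coverage 40 --short-read-error 0 --seed 7
lasv call --reference sim/reference.fa --bam sim/slr.bam --out run --seed 7
lasv evaluate --calls run/calls.vcf --truth sim/truth.vcf
```

or equivalently from Python (`examples/02_call_svs.py`):

```text
calls written to .../run/calls.vcf
  chrS:16759 DEL 60 bp
  chrS:57108 DEL 9500 bp
  chrS:83785 DEL 1000 bp
  chrS:106317 INS 5000 bp
  chrS:134797 INS 300 bp
precision 1.00  recall 1.00  f1 1.00
```

Five implanted events, five calls, each with the exact implanted length —
with error-free 40× linked reads the assembly is exact, so the contig
CIGAR reproduces every event precisely.  The hybrid workflow adds
`--long-bam` (see `examples/03_hybrid_mode.py`); `examples/` contains one
short script per capability.

## Layout

- `src/lasv/` — library: `io`, `filtering`, `segments`, `assembly`,
  `align`, `calling`, `simulate`, `evaluate`, `pipeline`, `benchmarks`
- `src/lasv/cli.py` — `lasv call | simulate | evaluate`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, parameters, generator scope, limitations
- `tests/` — pytest suite (unit, property, behavioral)
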