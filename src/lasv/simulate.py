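"""Synthetic data generation: diploid genomes with implanted indels,
barcoded linked-read (SLR) pairs, and HiFi-like long reads.

The generator emulates the data a linked-read aligner would hand the
caller, without requiring any external aligner: because fragment provenance
is known, every read is written to a position-sorted BAM at its true
reference-projected coordinate, with soft clips across SV junctions, reads
from inserted sequence unmapped, a per-fragment BX barcode, and a minimal
AM tag (0 for junction-ambiguous reads).  Reads sharing a barcode derive
from one long fragment, as in stLFR/TELL-Seq-style library preparation
where input DNA is sheared into 5-100 kbp fragments before barcoding.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from .io import write_vcf
from .model import Reference, SVCall, revcomp

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthSV:
    """An implanted event; ``pos`` is the 0-based anchor base before the
    event (same convention as SVCall)."""

    chrom: str
    pos: int
    svtype: str
    svlen: int
    seq: str = ""  # inserted sequence for INS
    zygosity: str = "hom"  # "hom" | "het"
    haplotype: str = "both"  # "0" | "1" | "both"

    def to_call(self, reference: Reference) -> SVCall:
        ref = reference.sequences[self.chrom]
        anchor = ref[self.pos]
        if self.svtype == "DEL":
            return SVCall(self.chrom, self.pos, "DEL", self.svlen,
                          ref_allele=ref[self.pos:self.pos + 1 + self.svlen],
                          alt_allele=anchor)
        return SVCall(self.chrom, self.pos, "INS", self.svlen,
                      ref_allele=anchor, alt_allele=anchor + self.seq)


#: default SV size mixture: (name, low, high, weight) — mobile-element-like
#: short (Alu ~300 bp) and long (L1 up to ~6 kbp) insertions/deletions,
#: short tandem expansions/contractions, and a uniform background.
DEFAULT_SV_CLASSES = [
    ("alu", 250, 350, 0.4),
    ("l1", 4_000, 6_000, 0.15),
    ("str", 50, 200, 0.25),
    ("uniform", 50, 10_000, 0.2),
]


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    chrom_name: str = "chrS"
    n_svs: int = 10
    sv_classes: list = field(default_factory=lambda: list(DEFAULT_SV_CLASSES))
    sv_lengths: Optional[list[int]] = None   # explicit lengths (cycled)
    sv_types: Optional[list[str]] = None     # explicit types (cycled)
    zygosity: str = "hom"                    # "hom" | "het" | "mixed"
    min_sv_spacing: int = 2_000
    # SLR library
    slr_coverage: float = 40.0
    fragment_length_range: tuple[int, int] = (5_000, 100_000)
    fragments_per_barcode: int = 1
    fragment_coverage: float = 0.2
    read_length: int = 150
    insert_size_mean: int = 350
    insert_size_sd: int = 35
    short_read_error: float = 0.001
    # long reads
    long_read_coverage: float = 0.0
    long_read_length_range: tuple[int, int] = (9_000, 12_000)
    long_read_error_range: tuple[float, float] = (0.001, 0.01)
    long_read_indel_fraction: float = 0.1
    # structure
    repeat_pairs: list = field(default_factory=list)  # (pos_a, pos_b, length)
    coverage_gap: Optional[tuple[int, int]] = None    # zero-coverage interval
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.short_read_error <= 1:
            raise ValueError("short_read_error must be in [0,1]")
        for lo, hi in (self.fragment_length_range, self.long_read_length_range,
                       self.long_read_error_range):
            if lo > hi:
                raise ValueError("range bounds must be ordered")

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump({k: v for k, v in self.__dict__.items()}, fh,
                      indent=2, default=list)
        return path


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


# -- genome + SVs ----------------------------------------------------------


def _draw_sv_lengths(sim: SimConfig, rng: np.random.Generator) -> list[int]:
    if sim.sv_lengths is not None:
        return [sim.sv_lengths[i % len(sim.sv_lengths)]
                for i in range(sim.n_svs)]
    names, weights = zip(*[(c[0], c[3]) for c in sim.sv_classes])
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    lows = {c[0]: c[1] for c in sim.sv_classes}
    highs = {c[0]: c[2] for c in sim.sv_classes}
    out = []
    for _ in range(sim.n_svs):
        cls = names[rng.choice(len(names), p=probs)]
        out.append(int(rng.integers(lows[cls], highs[cls] + 1)))
    return out


def _place_positions(sim: SimConfig, lengths: list[int],
                     rng: np.random.Generator) -> list[int]:
    margin = max(2_000, min(10_000, sim.genome_length // 10))
    spacing = sim.min_sv_spacing
    lo, hi = margin, sim.genome_length - margin
    positions: list[int] = []
    forbidden: list[tuple[int, int]] = [
        (a, a + ln) for a, b, ln in sim.repeat_pairs
    ] + [(b, b + ln) for a, b, ln in sim.repeat_pairs]
    for length in lengths:
        placed = False
        for _ in range(1_000):
            pos = int(rng.integers(lo, max(lo + 1, hi - length)))
            span = (pos - spacing, pos + length + spacing)
            if any(not (span[1] <= s or span[0] >= e)
                   for s, e in [(p - spacing, p + l + spacing)
                                for p, l in positions] + forbidden):
                continue
            positions.append((pos, length))
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place SVs with the required spacing; "
                "use fewer or smaller SVs or a longer genome")
    return [p for p, _ in positions]


def simulate_genome_with_svs(sim: SimConfig, truth_vcf: Optional[str] = None):
    """Random background genome with implanted indels.

    Returns ``(reference, (hap0, hap1), truths)`` and writes a truth VCF
    when ``truth_vcf`` is given.  Repeat pairs listed in the config copy the
    sequence at one locus to another (planted interspersed repeats).
    """
    rng = np.random.default_rng(sim.seed)
    genome = list(_random_dna(rng, sim.genome_length))
    for pos_a, pos_b, length in sim.repeat_pairs:
        genome[pos_b:pos_b + length] = genome[pos_a:pos_a + length]
    genome = "".join(genome)
    reference = Reference({sim.chrom_name: genome})

    lengths = _draw_sv_lengths(sim, rng)
    positions = _place_positions(sim, lengths, rng)
    if sim.sv_types is not None:
        types = [sim.sv_types[i % len(sim.sv_types)] for i in range(sim.n_svs)]
    else:
        types = [("DEL" if rng.random() < 0.5 else "INS")
                 for _ in range(sim.n_svs)]
    truths: list[TruthSV] = []
    for pos, length, svtype in sorted(zip(positions, lengths, types)):
        if sim.zygosity == "hom":
            zyg, hap = "hom", "both"
        elif sim.zygosity == "het":
            zyg, hap = "het", str(int(rng.integers(0, 2)))
        else:
            zyg = "hom" if rng.random() < 0.5 else "het"
            hap = "both" if zyg == "hom" else str(int(rng.integers(0, 2)))
        seq = _random_dna(rng, length) if svtype == "INS" else ""
        truths.append(TruthSV(sim.chrom_name, pos, svtype, length, seq,
                              zyg, hap))
    haplotypes = (apply_svs(genome, [t for t in truths
                                     if t.haplotype in ("both", "0")]),
                  apply_svs(genome, [t for t in truths
                                     if t.haplotype in ("both", "1")]))
    if truth_vcf:
        write_vcf([t.to_call(reference) for t in truths], reference, truth_vcf)
    return reference, haplotypes, truths


def apply_svs(genome: str, events: list[TruthSV]) -> str:
    """Apply sorted, non-overlapping events to a sequence."""
    parts = []
    cursor = 0
    for ev in sorted(events, key=lambda e: e.pos):
        parts.append(genome[cursor:ev.pos + 1])
        if ev.svtype == "DEL":
            cursor = ev.pos + 1 + ev.svlen
        else:
            parts.append(ev.seq)
            cursor = ev.pos + 1
    parts.append(genome[cursor:])
    return "".join(parts)


def _haplotype_blocks(genome_len: int, events: list[TruthSV]):
    """Collinear (hap_start, hap_end, ref_start|None) blocks for projection;
    ref_start None marks inserted sequence."""
    blocks = []
    ref_cursor = 0
    hap_cursor = 0
    for ev in sorted(events, key=lambda e: e.pos):
        end = ev.pos + 1
        blocks.append((hap_cursor, hap_cursor + end - ref_cursor, ref_cursor))
        hap_cursor += end - ref_cursor
        if ev.svtype == "DEL":
            ref_cursor = end + ev.svlen
        else:
            blocks.append((hap_cursor, hap_cursor + ev.svlen, None))
            hap_cursor += ev.svlen
            ref_cursor = end
    blocks.append((hap_cursor, hap_cursor + genome_len - ref_cursor, ref_cursor))
    return blocks


def _project_read(blocks, starts, s: int, e: int, min_mapped: int = 20):
    """Project hap interval [s, e) to (ref_pos, cigar) using the largest
    reference-collinear overlap; None when unmappable (inside insertion)."""
    i = bisect_right(starts, s) - 1
    best = None
    for hs, he, rs in blocks[max(0, i):]:
        if hs >= e:
            break
        lo, hi = max(s, hs), min(e, he)
        if rs is None or hi - lo < min_mapped:
            continue
        if best is None or hi - lo > best[2]:
            best = (lo, hi, hi - lo, rs + (lo - hs))
        if hi - lo == e - s:
            break
    if best is None:
        return None
    lo, hi, _, ref_pos = best
    cigar = []
    if lo > s:
        cigar.append((4, lo - s))  # S
    cigar.append((0, hi - lo))     # M
    if e > hi:
        cigar.append((4, e - hi))
    return ref_pos, cigar


def _apply_substitutions(seq: np.ndarray, rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = (lut[seq[pos]] + shift) % 4
    seq = seq.copy()
    seq[pos] = _BASES[idx]
    return seq


# -- SLR reads -------------------------------------------------------------


def simulate_slr_reads(haplotypes: tuple[str, str], sim: SimConfig,
                       reference: Reference,
                       truths: list[TruthSV],
                       out_bam: str,
                       out_fastq: Optional[str] = None) -> dict:
    """Sample barcoded read pairs from long fragments and write a sorted,
    indexed truth-aligned BAM.  Returns simple counters."""
    rng = np.random.default_rng(sim.seed + 1)
    chrom = sim.chrom_name
    glen = reference.lengths[chrom]
    hap_events = ([t for t in truths if t.haplotype in ("both", "0")],
                  [t for t in truths if t.haplotype in ("both", "1")])
    blocks = [_haplotype_blocks(glen, ev) for ev in hap_events]
    starts = [[b[0] for b in bl] for bl in blocks]
    hap_arr = [np.frombuffer(h.encode(), dtype=np.uint8) for h in haplotypes]

    read_len = sim.read_length
    total_pairs = int(round(sim.slr_coverage * glen / (2 * read_len)))
    gap = sim.coverage_gap

    frag_lo, frag_hi = sim.fragment_length_range
    qual_str = "I" * read_len  # Q40
    stats = {"pairs": 0, "fragments": 0, "unmapped_reads": 0,
             "bases": 0}
    lines: list[str] = []
    pair_idx = 0
    barcode_idx = 0
    frag_in_barcode = 0
    while stats["pairs"] < total_pairs:
        hap = int(rng.integers(0, 2))
        hlen = len(haplotypes[hap])
        flen = int(rng.integers(frag_lo, frag_hi + 1))
        flen = min(flen, hlen)
        # allow fragments to overhang sequence ends (clipped) so coverage
        # stays uniform near chromosome boundaries
        min_keep = 2 * read_len
        fstart = int(rng.integers(min_keep - flen, hlen - min_keep + 1))
        fend = min(fstart + flen, hlen)
        fstart = max(fstart, 0)
        flen = fend - fstart
        if frag_in_barcode == 0:
            barcode = f"BX{barcode_idx:08d}-1"
        frag_in_barcode += 1
        if frag_in_barcode >= sim.fragments_per_barcode:
            frag_in_barcode = 0
            barcode_idx += 1
        stats["fragments"] += 1
        n_pairs = max(1, int(round(flen * sim.fragment_coverage
                                   / (2 * read_len))))
        n_pairs = min(n_pairs, total_pairs - stats["pairs"])
        for _ in range(n_pairs):
            insert = int(rng.normal(sim.insert_size_mean, sim.insert_size_sd))
            insert = max(2 * read_len, min(insert, flen))
            p = int(rng.integers(0, flen - insert + 1))
            s1 = fstart + p
            s2 = fstart + p + insert - read_len
            if gap is not None and not (
                    s1 + read_len <= gap[0] or s1 >= gap[1]) or \
               gap is not None and not (
                    s2 + read_len <= gap[0] or s2 >= gap[1]):
                continue
            name = f"pair{pair_idx}"
            pair_idx += 1
            seq1 = _apply_substitutions(hap_arr[hap][s1:s1 + read_len],
                                        sim.short_read_error, rng)
            seq2 = _apply_substitutions(hap_arr[hap][s2:s2 + read_len],
                                        sim.short_read_error, rng)
            proj1 = _project_read(blocks[hap], starts[hap], s1, s1 + read_len)
            proj2 = _project_read(blocks[hap], starts[hap], s2, s2 + read_len)
            new = _pair_sam_lines(name, chrom, seq1, seq2, proj1, proj2,
                                  qual_str, barcode, read_len)
            stats["unmapped_reads"] += (proj1 is None) + (proj2 is None)
            lines.extend(new)
            stats["pairs"] += 1
            stats["bases"] += 2 * read_len
    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{chrom}\tLN:{glen}\n"
    _write_sorted_bam_from_sam(header, lines, out_bam)
    if out_fastq:
        _write_pair_fastq(out_bam, out_fastq)
    return stats


def _cigar_str(cigartuples) -> str:
    ops = "MIDNSHP=X"
    return "".join(f"{ln}{ops[op]}" for op, ln in cigartuples)


def _pair_sam_lines(name, chrom, seq1, seq2, proj1, proj2, qual_str,
                    barcode, read_len) -> list[str]:
    out = []
    for idx, (seq, proj, mate_proj) in enumerate(
            ((seq1, proj1, proj2), (seq2, proj2, proj1))):
        flag = 0x1 | (0x40 if idx == 0 else 0x80)
        flag |= 0x10 if idx == 1 else 0x20  # read2 sampled from the - strand
        clip = 0
        if proj is None:
            flag |= 0x4
            if mate_proj is not None:  # place at mate for sorting
                rname, pos, cig, mapq = chrom, mate_proj[0] + 1, "*", 0
            else:
                rname, pos, cig, mapq = "*", 0, "*", 0
        else:
            rname, pos, mapq = chrom, proj[0] + 1, 60
            cig = _cigar_str(proj[1])
            clip = sum(ln for op, ln in proj[1] if op == 4)
        if mate_proj is None:
            flag |= 0x8
            mrname, mpos = (("=", pos) if proj is not None else ("*", 0))
        else:
            mrname, mpos = "=", mate_proj[0] + 1
            if rname == "*":
                rname, pos = chrom, mate_proj[0] + 1
                mrname = "="
        am = 0 if clip >= max(10, 0.2 * read_len) else 1
        out.append(
            f"{name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cig}\t{mrname}\t"
            f"{mpos}\t0\t{seq.tobytes().decode()}\t{qual_str}\t"
            f"BX:Z:{barcode}\tAM:i:{am}")
    return out


def _write_sorted_bam_from_sam(header: str, lines: list[str], out_bam: str):
    import os
    import tempfile

    fd, tmp = tempfile.mkstemp(suffix=".sam",
                               dir=os.path.dirname(out_bam) or ".")
    with os.fdopen(fd, "w") as fh:
        fh.write(header)
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    pysam.sort("-o", out_bam, tmp)
    os.unlink(tmp)
    pysam.index(out_bam)
    return out_bam


def _write_pair_fastq(bam_path: str, out_fastq: str):
    openf = open
    if out_fastq.endswith(".gz"):
        import gzip
        openf = gzip.open
    with openf(out_fastq, "wt") as fh, \
            pysam.AlignmentFile(bam_path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            seq = rec.query_sequence
            if rec.is_reverse:
                seq = revcomp(seq)
            bx = rec.get_tag("BX")
            mate = 1 if rec.is_read1 else 2
            fh.write(f"@{rec.query_name}/{mate} BX:Z:{bx}\n{seq}\n+\n"
                     f"{'I' * len(seq)}\n")


# -- long reads ------------------------------------------------------------


def simulate_long_reads(haplotypes: tuple[str, str], sim: SimConfig,
                        reference: Reference,
                        truths: list[TruthSV],
                        out_bam: str,
                        out_fastq: Optional[str] = None) -> dict:
    """HiFi-like reads: 9-12 kbp, 0.1-1 % per-read error (mostly
    substitutions), written as a truth-aligned sorted BAM."""
    rng = np.random.default_rng(sim.seed + 2)
    chrom = sim.chrom_name
    glen = reference.lengths[chrom]
    hap_events = ([t for t in truths if t.haplotype in ("both", "0")],
                  [t for t in truths if t.haplotype in ("both", "1")])
    blocks = [_haplotype_blocks(glen, ev) for ev in hap_events]
    starts = [[b[0] for b in bl] for bl in blocks]

    lo, hi = sim.long_read_length_range
    e_lo, e_hi = sim.long_read_error_range
    mean_len = (lo + hi) / 2
    n_reads = int(round(sim.long_read_coverage * glen / mean_len))
    lines: list[str] = []
    fastq: list[str] = []
    stats = {"reads": 0, "bases": 0}
    for i in range(n_reads):
        hap = int(rng.integers(0, 2))
        hlen = len(haplotypes[hap])
        rlen = int(rng.integers(lo, hi + 1))
        rlen = min(rlen, hlen)
        s = int(rng.integers(0, hlen - rlen + 1))
        seq = haplotypes[hap][s:s + rlen]
        rate = float(rng.uniform(e_lo, e_hi))
        seq = _mutate_long_read(seq, rate, sim.long_read_indel_fraction, rng)
        proj = _project_read(blocks[hap], starts[hap], s, s + rlen,
                             min_mapped=500)
        name = f"long{i}"
        qual = "I" * len(seq)
        if proj is None:
            lines.append(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}")
        else:
            # CIGAR must consume the post-error sequence length
            clip_lead = proj[1][0][1] if proj[1][0][0] == 4 else 0
            m = len(seq) - clip_lead
            cig = (f"{clip_lead}S" if clip_lead else "") + f"{m}M"
            lines.append(f"{name}\t0\t{chrom}\t{proj[0] + 1}\t60\t{cig}\t*\t"
                         f"0\t0\t{seq}\t{qual}")
        if out_fastq:
            fastq.append(f"@{name}\n{seq}\n+\n{qual}\n")
        stats["reads"] += 1
        stats["bases"] += len(seq)
    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{chrom}\tLN:{glen}\n"
    _write_sorted_bam_from_sam(header, lines, out_bam)
    if out_fastq:
        openf = open
        if out_fastq.endswith(".gz"):
            import gzip
            openf = gzip.open
        with openf(out_fastq, "wt") as fh:
            fh.writelines(fastq)
    return stats


def _mutate_long_read(seq: str, rate: float, indel_fraction: float,
                      rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    n_indel = rng.binomial(n_err, indel_fraction)
    arr = _apply_substitutions(arr, (n_err - n_indel) / len(arr), rng)
    s = arr.tobytes().decode()
    for _ in range(n_indel):
        p = int(rng.integers(0, len(s)))
        if rng.random() < 0.5:
            s = s[:p] + _random_dna(rng, 1) + s[p:]
        else:
            s = s[:p] + s[p + 1:]
    return s
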