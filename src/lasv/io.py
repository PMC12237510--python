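"""Readers and writers for FASTA, BAM and VCF.

All parsing goes through pysam; this module only maps between pysam records
and the package's domain types.
"""

from __future__ import annotations

import logging
import os
from typing import Iterator, Optional

import pysam

from .model import CIGAR_OPS, Reference, SVCall

log = logging.getLogger(__name__)


def read_fasta(path: str) -> Reference:
    """Load a (multi-)FASTA into memory, uppercasing sequences.

    Record names are taken up to the first whitespace.  Raises ``ValueError``
    on an empty file or duplicate names.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                if name in sequences:
                    raise ValueError(f"duplicate FASTA record name: {name}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"FASTA {path} does not start with a header")
                chunks.append(line)
    if name is None:
        raise ValueError(f"empty FASTA: {path}")
    if name in sequences:
        raise ValueError(f"duplicate FASTA record name: {name}")
    sequences[name] = "".join(chunks).upper()
    return Reference(sequences)


def write_fasta(reference: Reference, path: str, width: int = 80) -> str:
    with open(path, "w") as fh:
        for name, seq in reference.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def _to_record(aln: pysam.AlignedSegment, unplaced: Optional[set[str]] = None,
               lite: bool = False):
    """Convert a pysam alignment to a ReadRecord; returns None on malformed.

    ``lite`` skips base qualities and CIGAR (adequate for gathering, where
    only sequence, pairing and placement are used).
    """
    from .model import ReadRecord

    seq = aln.query_sequence
    if seq is None:
        return None
    if lite:
        return _to_record_lite(aln, seq)
    quals = aln.query_qualities
    quals = quals if quals is not None else [30] * len(seq)
    if len(quals) != len(seq):
        return None
    cigar = []
    if aln.cigartuples:
        cigar = [(CIGAR_OPS[op], ln) for op, ln in aln.cigartuples]
    chrom = aln.reference_name if not aln.is_unmapped else None
    rec = ReadRecord(
        name=aln.query_name,
        sequence=seq,
        base_qualities=quals,
        is_mapped=not aln.is_unmapped,
        chrom=chrom,
        pos=aln.reference_start if not aln.is_unmapped else None,
        cigar=cigar,
        mapq=aln.mapping_quality,
        barcode=aln.get_tag("BX") if aln.has_tag("BX") else None,
        mate_is_mapped=aln.is_paired and not aln.mate_is_unmapped,
        am_value=int(aln.get_tag("AM")) if aln.has_tag("AM") else None,
        is_first_in_pair=(not aln.is_paired) or aln.is_read1,
        is_on_unplaced_contig=bool(chrom and unplaced and chrom in unplaced),
        is_secondary_or_supplementary=aln.is_secondary or aln.is_supplementary,
        is_reverse=aln.is_reverse,
        mate_chrom=(aln.next_reference_name
                    if aln.is_paired and not aln.mate_is_unmapped else None),
        mate_pos=(aln.next_reference_start
                  if aln.is_paired and not aln.mate_is_unmapped else None),
    )
    return rec


def _to_record_lite(aln: pysam.AlignedSegment, seq: str):
    """Minimal record for gathering: sequence, pairing and placement only."""
    from .model import ReadRecord

    try:
        bx = aln.get_tag("BX")
    except KeyError:
        bx = None
    unmapped = aln.is_unmapped
    paired = aln.is_paired
    mate_mapped = paired and not aln.mate_is_unmapped
    return ReadRecord(
        name=aln.query_name,
        sequence=seq,
        base_qualities=[],
        is_mapped=not unmapped,
        chrom=aln.reference_name if not unmapped else None,
        pos=aln.reference_start if not unmapped else None,
        barcode=bx,
        mate_is_mapped=mate_mapped,
        is_first_in_pair=(not paired) or aln.is_read1,
        is_secondary_or_supplementary=aln.is_secondary or aln.is_supplementary,
        mate_chrom=aln.next_reference_name if mate_mapped else None,
        mate_pos=aln.next_reference_start if mate_mapped else None,
    )


class BamStats:
    """Counters accumulated while streaming a BAM."""

    def __init__(self):
        self.yielded = 0
        self.skipped_malformed = 0


def read_bam_records(
    bam_path: str,
    region: Optional[tuple[str, int, int]] = None,
    unplaced: Optional[set[str]] = None,
    stats: Optional[BamStats] = None,
    lite: bool = False,
) -> Iterator:
    """Stream ReadRecords from a coordinate-sorted, indexed BAM.

    With ``region`` (chrom, start, end), yields records overlapping the
    region in coordinate order; without it, streams the whole file including
    unmapped records.  Malformed records are skipped with a warning.
    """
    if region is not None and not (
        os.path.exists(bam_path + ".bai")
        or os.path.exists(os.path.splitext(bam_path)[0] + ".bai")
        or os.path.exists(bam_path + ".csi")
    ):
        raise FileNotFoundError(f"BAM index missing for {bam_path}")
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if region is None:
            it = bam.fetch(until_eof=True)
        else:
            chrom, start, end = region
            it = bam.fetch(chrom, start, end)
        for aln in it:
            rec = _to_record(aln, unplaced, lite=lite)
            if rec is None:
                if stats is not None:
                    stats.skipped_malformed += 1
                log.warning("skipping malformed record %s", aln.query_name)
                continue
            if stats is not None:
                stats.yielded += 1
            yield rec


def write_vcf(calls: list[SVCall], reference: Reference, out_path: str,
              sample: str = "SAMPLE") -> str:
    """Write calls as sorted, sequence-resolved VCF 4.2.

    INFO carries SVTYPE, SVLEN (negative for deletions) and END.  Genotypes
    are emitted as ``./.`` (no genotyping performed).  Raises ``ValueError``
    if a call's REF allele disagrees with the reference sequence.
    """
    for call in calls:
        if call.chrom not in reference:
            raise ValueError(f"call on unknown chromosome: {call}")
        expected = reference.fetch(call.chrom, call.pos, call.pos + len(call.ref_allele))
        if expected != call.ref_allele:
            raise ValueError(
                f"REF mismatch for call at {call.chrom}:{call.pos + 1}: "
                f"call says {call.ref_allele[:20]!r}, reference has {expected[:20]!r}"
            )
    order = {name: i for i, name in enumerate(reference.sequences)}
    calls = sorted(calls, key=lambda c: (order.get(c.chrom, 1 << 30), c.pos, c.svtype, c.svlen))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lasv\n")
        for name, length in reference.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length, negative for deletions">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end of the event on the reference">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for i, call in enumerate(calls):
            svlen = call.svlen if call.svtype == "INS" else -call.svlen
            end = call.end  # 0-based exclusive == 1-based inclusive end
            info = f"SVTYPE={call.svtype};SVLEN={svlen};END={end}"
            fh.write(
                f"{call.chrom}\t{call.pos + 1}\tlasv_{i}\t{call.ref_allele}\t"
                f"{call.alt_allele}\t.\tPASS\t{info}\tGT\t./.\n"
            )
    return out_path


def read_vcf_calls(path: str) -> list[SVCall]:
    """Parse SV calls back from a VCF produced by this package (or any VCF
    with sequence-resolved indel alleles and SVTYPE/SVLEN info)."""
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref, alts = rec.ref, rec.alts
            if not alts:
                continue
            alt = alts[0]
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                svtype = "DEL" if len(ref) > len(alt) else "INS"
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None:
                svlen = abs(len(alt) - len(ref))
            calls.append(SVCall(
                chrom=rec.chrom,
                pos=rec.pos - 1,
                svtype=str(svtype),
                svlen=abs(int(svlen)),
                ref_allele=ref,
                alt_allele=alt,
            ))
    return calls
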