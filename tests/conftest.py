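"""Shared fixtures: in-memory read/pair builders and programmatic BAMs."""

from __future__ import annotations

import random

import pysam
import pytest

from lasv.model import Config, ReadPair, ReadRecord


@pytest.fixture
def config() -> Config:
    return Config()


def make_read(name="r", seq="ACGT" * 30, qual=30, mapped=True, chrom="chr1",
              pos=100, cigar=None, barcode="BC1-1", am=None, first=True,
              unplaced=False, mate_mapped=True, mate_chrom=None,
              mate_pos=None) -> ReadRecord:
    quals = [qual] * len(seq) if isinstance(qual, int) else list(qual)
    if cigar is None and mapped:
        cigar = [("M", len(seq))]
    return ReadRecord(
        name=name, sequence=seq, base_qualities=quals, is_mapped=mapped,
        chrom=chrom if mapped else None, pos=pos if mapped else None,
        cigar=cigar or [], barcode=barcode, am_value=am,
        is_first_in_pair=first, is_on_unplaced_contig=unplaced,
        mate_is_mapped=mate_mapped, mate_chrom=mate_chrom, mate_pos=mate_pos)


def make_pair(**kwargs) -> ReadPair:
    """A pair of two clean mapped reads; per-mate overrides via r1_/r2_."""
    r1_kw = {k[3:]: v for k, v in kwargs.items() if k.startswith("r1_")}
    r2_kw = {k[3:]: v for k, v in kwargs.items() if k.startswith("r2_")}
    shared = {k: v for k, v in kwargs.items()
              if not (k.startswith("r1_") or k.startswith("r2_"))}
    name = shared.pop("name", "pair")
    r1 = make_read(name=name, first=True, **{**shared, **r1_kw})
    r2 = make_read(name=name, first=False, pos=shared.get("pos", 100) + 200,
                   **{**shared, **r2_kw})
    return ReadPair(r1, r2)


def write_bam(path, records, chrom_lengths=None):
    """Build a coordinate-sorted, indexed BAM from dict specs.

    Each record spec: name, flag fields handled via keys (unmapped, read2,
    ...), chrom, pos (0-based), seq, cigar, and optional tags (bx, am).
    """
    chrom_lengths = chrom_lengths or {"chr1": 1_000_000}
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in chrom_lengths.items()]}
    names = list(chrom_lengths)
    path = str(path)
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for spec in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = spec.get("name", "r")
            seq = spec.get("seq", "ACGT" * 25)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                chr(33 + spec.get("qual", 30)) * len(seq))
            a.is_paired = spec.get("paired", True)
            a.is_read1 = not spec.get("read2", False)
            a.is_read2 = spec.get("read2", False)
            if spec.get("unmapped"):
                a.is_unmapped = True
                if spec.get("pos") is not None:
                    a.reference_id = names.index(spec.get("chrom", "chr1"))
                    a.reference_start = spec["pos"]
            else:
                a.reference_id = names.index(spec.get("chrom", "chr1"))
                a.reference_start = spec.get("pos", 0)
                a.cigarstring = spec.get("cigar", f"{len(seq)}M")
                a.mapping_quality = spec.get("mapq", 60)
            if spec.get("mate_unmapped"):
                a.mate_is_unmapped = True
            elif a.is_paired:
                a.next_reference_id = names.index(spec.get("chrom", "chr1"))
                a.next_reference_start = spec.get("mate_pos",
                                                  spec.get("pos", 0))
            if spec.get("secondary"):
                a.is_secondary = True
            if "bx" in spec and spec["bx"] is not None:
                a.set_tag("BX", spec["bx"])
            if "am" in spec and spec["am"] is not None:
                a.set_tag("AM", spec["am"])
            bam.write(a)
    pysam.sort("-o", path, tmp)
    pysam.index(path)
    import os
    os.unlink(tmp)
    return path


def random_dna(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))
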