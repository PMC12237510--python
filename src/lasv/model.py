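"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the single
conversion to 1-based happens when records are written to VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: CIGAR operation codes in SAM order (pysam convention).
CIGAR_OPS = "MIDNSHP=X"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class ReadRecord:
    """One aligned or unaligned short/long read.

    ``barcode`` carries the BX tag verbatim (including any ``-1`` style
    suffix); ``am_value`` carries the LongRanger AM tag when present.
    ``pos`` is the 0-based leftmost aligned reference position.
    """

    name: str
    sequence: str
    base_qualities: list[int]
    is_mapped: bool = False
    chrom: Optional[str] = None
    pos: Optional[int] = None
    cigar: list[tuple[str, int]] = field(default_factory=list)
    mapq: int = 0
    barcode: Optional[str] = None
    mate_is_mapped: bool = False
    am_value: Optional[int] = None
    is_first_in_pair: bool = True
    is_on_unplaced_contig: bool = False
    is_secondary_or_supplementary: bool = False
    is_reverse: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    @property
    def reference_end(self) -> Optional[int]:
        """End of the aligned span (exclusive), from the CIGAR."""
        if not self.is_mapped or self.pos is None:
            return None
        if not self.cigar:  # lite records: approximate with read length
            return self.pos + len(self.sequence)
        span = sum(ln for op, ln in self.cigar if op in "MDN=X")
        return self.pos + span

    @property
    def softclip_fraction(self) -> float:
        """Fraction of stored bases that are soft-clipped.

        Hard clips are not part of the stored sequence and do not count.
        """
        if not self.sequence:
            return 0.0
        clipped = sum(ln for op, ln in self.cigar if op == "S")
        return clipped / len(self.sequence)

    @property
    def min_base_quality(self) -> int:
        return min(self.base_qualities) if self.base_qualities else 0


@dataclass(slots=True)
class ReadPair:
    """A read pair; ``read2`` is absent for orphans."""

    read1: ReadRecord
    read2: Optional[ReadRecord] = None

    @property
    def barcode(self) -> Optional[str]:
        if self.read1.barcode is not None:
            return self.read1.barcode
        if self.read2 is not None:
            return self.read2.barcode
        return None

    def reads(self) -> list[ReadRecord]:
        return [r for r in (self.read1, self.read2) if r is not None]


class Reference:
    """In-memory reference genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences
        self.lengths = {name: len(seq) for name, seq in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __eq__(self, other):
        return isinstance(other, Reference) and self.sequences == other.sequences


@dataclass(frozen=True)
class SVCall:
    """A sequence-resolved insertion or deletion call.

    ``pos`` is the 0-based position of the reference base *before* the event
    (the anchor base, VCF-style); conversion to 1-based happens only at VCF
    write time.  For a DEL, ``ref_allele`` spells anchor + deleted bases and
    ``alt_allele`` is the anchor alone; for an INS the converse.
    """

    chrom: str
    pos: int
    svtype: str  # "INS" | "DEL"
    svlen: int
    ref_allele: str
    alt_allele: str
    source_segment: str = ""
    contig_id: str = ""

    def __post_init__(self):
        if self.svtype not in ("INS", "DEL"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svlen < 1:
            raise ValueError("svlen must be >= 1")

    @property
    def end(self) -> int:
        """0-based exclusive reference end of the event."""
        if self.svtype == "DEL":
            return self.pos + 1 + self.svlen
        return self.pos + 1

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.svtype, self.svlen)


@dataclass
class Config:
    """Pipeline parameters with field defaults matching the method.

    Units are base pairs unless stated otherwise.
    """

    segment_length: int = 50_000
    segment_overlap: int = 10_000
    min_barcode_pairs: int = 3
    min_barcode_span: int = 5_000
    min_base_phred: int = 20
    max_softclip_fraction: float = 0.20
    min_sv_len: int = 50
    max_sv_len: int = 10_000
    max_long_reads_per_segment: int = 100
    kmer_size: int = 55
    match_distance: int = 500
    random_seed: int = 0
    # assembly details
    solid_coverage: int = 2
    tip_vicinity_len: Optional[int] = None  # default 2*k
    min_contig_len: Optional[int] = None    # default 2*k
    het_coverage_floor_frac: float = 0.25
    tip_rule_enabled: bool = True
    # gap closing (hybrid)
    gap_anchor_len: int = 200
    gap_anchor_identity: float = 0.85
    # contig alignment
    seed_len: int = 31
    align_pad: int = 1_000
    match_score: int = 1
    mismatch_score: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_alignment_identity: float = 0.90
    # evaluation
    size_similarity: float = 0.7
    size_similarity_enabled: bool = True
    # segment gathering
    max_mate_lookups: int = 10_000
    # primary chromosome detection override (regex of unplaced contig names)
    unplaced_regex: Optional[str] = None

    def __post_init__(self):
        if self.segment_overlap >= self.segment_length:
            raise ValueError("segment_overlap must be < segment_length")
        if self.min_sv_len >= self.max_sv_len:
            raise ValueError("min_sv_len must be < max_sv_len")
        if self.kmer_size % 2 == 0 or self.kmer_size < 15:
            raise ValueError("kmer_size must be odd and >= 15")
        if self.tip_vicinity_len is None:
            self.tip_vicinity_len = 2 * self.kmer_size
        if self.min_contig_len is None:
            self.min_contig_len = 2 * self.kmer_size
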