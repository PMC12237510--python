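"""Reference tiling, per-segment barcode selection, and read gathering.

The reference is tiled into overlapping windows (default 50 kbp, 10 kbp
overlap) so that any event shorter than the overlap is fully contained in at
least one window.  For each window a barcode list B(s) is selected: a
barcode qualifies when its reads show multiple independent pairs spread
across the window (at least ``min_barcode_pairs`` pairs, aligned extent
strictly greater than ``min_barcode_span``), the signature of a long
fragment genuinely sampled from the window rather than a spurious repeat
hit.  Gathering then collects window-aligned reads of those barcodes plus
the badly-aligned pairs M(B(s)) from the read map, and (in hybrid mode) up
to ``max_long_reads_per_segment`` long reads overlapping the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .filtering import ReadMap, pair_up_records
from .io import read_bam_records
from .model import Config, ReadPair, ReadRecord, Reference

log = logging.getLogger(__name__)


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    segment_id: str
    barcodes: set[str] = field(default_factory=set)
    local_pairs: list[ReadPair] = field(default_factory=list)
    recruited_pairs: list[ReadPair] = field(default_factory=list)
    long_reads: list[ReadRecord] = field(default_factory=list)

    @property
    def window(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def all_sequences(self) -> list[str]:
        """Short-read sequences gathered for assembly (local + recruited)."""
        seqs = []
        seen = set()
        for pair in self.local_pairs + self.recruited_pairs:
            for read in pair.reads():
                key = (read.name, read.is_first_in_pair)
                if key in seen:
                    continue
                seen.add(key)
                seqs.append(read.sequence)
        return seqs


def tile_reference(reference: Reference, config: Config) -> list[Segment]:
    """Tile each chromosome into overlapping windows.

    Windows start at 0 and advance by ``segment_length - segment_overlap``;
    the final window is truncated at the chromosome end.
    """
    step = config.segment_length - config.segment_overlap
    segments = []
    for chrom, length in reference.lengths.items():
        start = 0
        while True:
            end = min(start + config.segment_length, length)
            segments.append(Segment(chrom, start, end, f"{chrom}:{start}-{end}"))
            if end >= length:
                break
            start += step
    return segments


def _window_alignments(bam_path: str, window: tuple[str, int, int],
                       unplaced: Optional[set[str]] = None,
                       lite: bool = False) -> list[ReadRecord]:
    """Primary alignments overlapping a window, coordinate-sorted."""
    return [
        rec for rec in read_bam_records(bam_path, region=window,
                                        unplaced=unplaced, lite=lite)
        if rec.is_mapped and not rec.is_secondary_or_supplementary
    ]


def select_barcodes(window: tuple[str, int, int], bam_path: str,
                    config: Config) -> set[str]:
    """Select B(s) for one window.

    A barcode is included iff at least ``min_barcode_pairs`` of its read
    pairs have a mate primary-aligned in the window AND the distance from the
    leftmost alignment start to the rightmost alignment end of those reads is
    strictly greater than ``min_barcode_span``.
    """
    import pysam

    pair_names: dict[str, set[str]] = {}
    extent: dict[str, list[int]] = {}
    chrom, start, end = window
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for aln in bam.fetch(chrom, start, end):
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or not aln.has_tag("BX")):
                continue
            barcode = aln.get_tag("BX")
            pair_names.setdefault(barcode, set()).add(aln.query_name)
            pos, ref_end = aln.reference_start, aln.reference_end
            ext = extent.setdefault(barcode, [pos, ref_end])
            if pos < ext[0]:
                ext[0] = pos
            if ref_end > ext[1]:
                ext[1] = ref_end
    selected = set()
    for barcode, names in pair_names.items():
        if len(names) < config.min_barcode_pairs:
            continue
        lo, hi = extent[barcode]
        if hi - lo > config.min_barcode_span:
            selected.add(barcode)
    return selected


def _resolve_mates(singles: list[ReadRecord], bam_path: str,
                   config: Config) -> dict[tuple[str, bool], ReadRecord]:
    """Fetch mates of half-in-window reads by indexed position lookup.

    Lookups are capped at ``max_mate_lookups`` per segment; beyond the cap
    reads stay unpaired (mate treated as absent downstream).
    """
    import pysam

    from .io import _to_record

    found: dict[tuple[str, bool], ReadRecord] = {}
    wanted = [r for r in singles if r.mate_chrom is not None]
    wanted.sort(key=lambda r: (r.mate_chrom, r.mate_pos))
    lookups = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for rec in wanted:
            if lookups >= config.max_mate_lookups:
                break
            lookups += 1
            for aln in bam.fetch(rec.mate_chrom, rec.mate_pos, rec.mate_pos + 1):
                if (aln.query_name == rec.name
                        and aln.reference_start == rec.mate_pos
                        and not (aln.is_secondary or aln.is_supplementary)
                        and aln.is_read1 != rec.is_first_in_pair):
                    mate = _to_record(aln, lite=True)
                    if mate is not None:
                        found[(rec.name, not rec.is_first_in_pair)] = mate
                    break
    return found


def gather_segment_reads(segment: Segment, bam_path: str, read_map: ReadMap,
                         long_read_bam: Optional[str], config: Config) -> Segment:
    """Populate a segment with local pairs, recruited M(B(s)) pairs, and
    (hybrid mode) capped long reads."""
    import pysam

    from .io import _to_record_lite

    window = segment.window
    barcodes = segment.barcodes
    records = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for aln in bam.fetch(*window):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            try:
                if aln.get_tag("BX") not in barcodes:
                    continue
            except KeyError:
                continue
            seq = aln.query_sequence
            if seq is not None:
                records.append(_to_record_lite(aln, seq))
    # pair up within the window; singles keep their mate coordinates
    pairs = list(pair_up_records(records))
    halves = [p.read1 for p in pairs if p.read2 is None]
    in_window_names = {r.name for r in records}
    to_fetch = [r for r in halves
                if not (r.mate_chrom == segment.chrom
                        and segment.start <= (r.mate_pos or 0) < segment.end)]
    mates = _resolve_mates(to_fetch, bam_path, config) if to_fetch else {}
    completed: list[ReadPair] = []
    for pair in pairs:
        if pair.read2 is None:
            mate = mates.get((pair.read1.name, not pair.read1.is_first_in_pair))
            if mate is not None:
                r1, r2 = ((pair.read1, mate) if pair.read1.is_first_in_pair
                          else (mate, pair.read1))
                pair = ReadPair(r1, r2)
        completed.append(pair)
    completed.sort(key=lambda p: (p.read1.pos if p.read1.pos is not None else 1 << 60,
                                  p.read1.name))
    segment.local_pairs = completed
    segment.recruited_pairs = read_map.query(sorted(segment.barcodes))
    if long_read_bam is not None:
        long_reads = []
        for rec in read_bam_records(long_read_bam, region=window):
            if not rec.is_mapped or rec.is_secondary_or_supplementary:
                continue
            long_reads.append(rec)
            if len(long_reads) >= config.max_long_reads_per_segment:
                break
        segment.long_reads = long_reads
    return segment


def write_segment_bed(segments: list[Segment], path: str) -> str:
    """Debugging manifest of windows as BED."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.segment_id}\n")
    return path
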