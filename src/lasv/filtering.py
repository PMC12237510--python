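"""Badly-aligned read filtering and the barcode-keyed read map.

A read pair is *badly aligned* when it is high quality (every base above the
Phred floor on both mates) yet shows a placement problem: an unmapped mate,
an alignment on an unplaced contig, excessive soft-clipping, or a zero AM
tag (the aligner could not cluster the read with same-barcode reads).  Such
pairs concentrate around SV breakpoints and in sequence absent from the
reference, so they are stored in a barcode-keyed map and recruited later
into any segment that selects their barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional


from .model import Config, ReadPair, ReadRecord

log = logging.getLogger(__name__)

#: reason codes for the badly-aligned decision
REASON_UNMAPPED_OR_CLIPPED = "b"
REASON_ZERO_AM = "c"


@dataclass
class FilterDecision:
    keep: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self):
        return self.keep


def _mate_condition_b(read: Optional[ReadRecord], config: Config) -> bool:
    """Placement-problem test for one mate; an absent mate counts as unmapped."""
    if read is None:
        return True
    if not read.is_mapped:
        return True
    if read.is_on_unplaced_contig:
        return True
    if read.softclip_fraction > config.max_softclip_fraction:
        return True
    return False


def is_badly_aligned(pair: ReadPair, config: Config) -> FilterDecision:
    """Pure predicate: quality gate AND (placement problem OR zero AM).

    The quality gate requires every base of both present mates to exceed
    ``min_base_phred`` (strict).  An absent mate is treated as unmapped for
    the placement test and contributes nothing to the quality gate.
    """
    reads = pair.reads()
    if not reads:
        return FilterDecision(False)
    # (a) strict quality gate over all bases of both reads
    for r in reads:
        if r.min_base_quality <= config.min_base_phred:
            return FilterDecision(False)
    reasons = []
    if _mate_condition_b(pair.read1, config) or _mate_condition_b(pair.read2, config):
        reasons.append(REASON_UNMAPPED_OR_CLIPPED)
    if any(r.am_value == 0 for r in reads):
        reasons.append(REASON_ZERO_AM)
    return FilterDecision(bool(reasons), tuple(reasons))


@dataclass
class ReadMap:
    """Barcode-keyed store of badly-aligned read pairs (the map M).

    ``query(B)`` returns M(B): the union over barcodes in B of the stored
    pairs, deduplicated when B contains repeats.
    """

    pairs_by_barcode: dict[str, list[ReadPair]] = field(default_factory=dict)
    total_pairs: int = 0
    dropped_no_barcode: int = 0

    def add(self, pair: ReadPair) -> None:
        barcode = pair.barcode
        if barcode is None:
            self.dropped_no_barcode += 1
            return
        self.pairs_by_barcode.setdefault(barcode, []).append(pair)
        self.total_pairs += 1

    def query(self, barcodes: Iterable[str]) -> list[ReadPair]:
        out: list[ReadPair] = []
        for b in dict.fromkeys(barcodes):  # de-dup, preserve order
            out.extend(self.pairs_by_barcode.get(b, ()))
        return out


def query_read_map(read_map: ReadMap, barcodes: Iterable[str]) -> list[ReadPair]:
    return read_map.query(barcodes)


def pair_up_records(records: Iterable[ReadRecord]) -> Iterable[ReadPair]:
    """Group a stream of records into pairs by name.

    Secondary/supplementary alignments are ignored.  Reads whose mate never
    appears become orphan pairs (mate treated as absent).
    """
    pending: dict[str, ReadRecord] = {}
    for rec in records:
        if rec.is_secondary_or_supplementary:
            continue
        other = pending.pop(rec.name, None)
        if other is None:
            pending[rec.name] = rec
        else:
            first, second = (other, rec) if other.is_first_in_pair else (rec, other)
            yield ReadPair(first, second)
    for rec in pending.values():
        yield ReadPair(rec)


def build_read_map(bam_path: str, config: Config,
                   unplaced: Optional[set[str]] = None) -> ReadMap:
    """Scan a whole BAM and collect badly-aligned, barcoded pairs into M.

    The scan evaluates the cheap placement conditions on raw alignments
    first and only converts candidate pairs to domain records, so a clean
    pair costs almost nothing; the semantics are exactly those of
    ``is_badly_aligned`` (asserted by the predicate-equivalence test).
    """
    import pysam

    from .io import _to_record

    max_clip = config.max_softclip_fraction
    min_q = config.min_base_phred

    def placement_problem(aln) -> bool:
        if aln is None or aln.is_unmapped:
            return True
        if unplaced and aln.reference_name in unplaced:
            return True
        ct = aln.cigartuples
        if ct:
            clipped = sum(ln for op, ln in ct if op == 4)
            if clipped > max_clip * len(aln.query_sequence):
                return True
        return False

    def zero_am(aln) -> bool:
        if aln is None:
            return False
        try:
            return aln.get_tag("AM") == 0
        except KeyError:
            return False

    read_map = ReadMap()

    def consider(a1, a2):
        if not (placement_problem(a1) or placement_problem(a2)
                or zero_am(a1) or zero_am(a2)):
            return
        for aln in (a1, a2):
            if aln is not None:
                quals = aln.query_qualities
                if quals is not None and min(quals) <= min_q:
                    return
        recs = [_to_record(a, unplaced) for a in (a1, a2) if a is not None]
        recs = [r for r in recs if r is not None]
        if not recs:
            return
        if len(recs) == 2 and not recs[0].is_first_in_pair:
            recs.reverse()
        read_map.add(ReadPair(*recs))

    pending: dict[str, object] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
            else:
                first, second = (mate, aln) if mate.is_read1 else (aln, mate)
                consider(first, second)
    for aln in pending.values():
        consider(aln, None)
    log.info("read map built: %d pairs across %d barcodes (%d dropped, no barcode)",
             read_map.total_pairs, len(read_map.pairs_by_barcode),
             read_map.dropped_no_barcode)
    return read_map


def dump_read_map_tsv(read_map: ReadMap, config: Config, path: str) -> str:
    """Debugging dump of M: read name, barcode, reason code."""
    with open(path, "w") as fh:
        fh.write("read\tbarcode\treasons\n")
        for barcode, pairs in read_map.pairs_by_barcode.items():
            for pair in pairs:
                decision = is_badly_aligned(pair, config)
                fh.write(f"{pair.read1.name}\t{barcode}\t{','.join(decision.reasons)}\n")
    return path
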