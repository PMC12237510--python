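"""CIGAR-based indel extraction, normalization and genome-wide merging.

Contigs are aligned back to their segment window; every I/D CIGAR operation
whose length falls in the reportable size window becomes a candidate call.
Calls are left-aligned against the reference (so the same event discovered
in two overlapping segments or from two allele contigs lands on identical
coordinates) and deduplicated on (chrom, pos, type, length).
"""

from __future__ import annotations

import logging

from .align import ContigAlignment, align_contig, make_window_context
from .model import Config, Reference, SVCall

log = logging.getLogger(__name__)


def extract_indels_from_cigar(alignment: ContigAlignment, reference: Reference,
                              config: Config,
                              source_segment: str = "") -> list[SVCall]:
    """One SVCall per in-window I/D operation of the alignment.

    The anchor base convention is VCF's: ``pos`` is the 0-based position of
    the reference base immediately before the event.
    """
    calls: list[SVCall] = []
    ref = reference.sequences[alignment.chrom]
    qpos, rpos = 0, alignment.ref_start
    query = alignment.query_sequence
    for op, ln in alignment.cigar:
        if op in ("M", "=", "X"):
            qpos += ln
            rpos += ln
        elif op == "S":
            qpos += ln
        elif op == "I":
            if config.min_sv_len <= ln <= config.max_sv_len and rpos > 0:
                anchor = ref[rpos - 1]
                calls.append(SVCall(
                    chrom=alignment.chrom, pos=rpos - 1, svtype="INS",
                    svlen=ln, ref_allele=anchor,
                    alt_allele=anchor + query[qpos:qpos + ln],
                    source_segment=source_segment,
                    contig_id=alignment.contig_id))
            qpos += ln
        elif op == "D":
            if config.min_sv_len <= ln <= config.max_sv_len and rpos > 0:
                anchor = ref[rpos - 1]
                calls.append(SVCall(
                    chrom=alignment.chrom, pos=rpos - 1, svtype="DEL",
                    svlen=ln, ref_allele=ref[rpos - 1:rpos + ln],
                    alt_allele=anchor,
                    source_segment=source_segment,
                    contig_id=alignment.contig_id))
            rpos += ln
        elif op in ("H", "P", "N"):
            if op == "N":
                rpos += ln
    return calls


def left_align_call(call: SVCall, reference: Reference) -> SVCall:
    """Shift an indel to its leftmost equivalent position.

    For a deletion, the event can shift left while the base before the
    deleted block equals the block's last base; symmetrically for an
    insertion with its inserted sequence.  Standard VCF normalization.
    """
    ref = reference.sequences[call.chrom]
    pos = call.pos
    if call.svtype == "DEL":
        allele = list(ref[pos + 1: pos + 1 + call.svlen])
    else:
        allele = list(call.alt_allele[1:])
    while pos > 0 and allele and ref[pos] == allele[-1]:
        allele.insert(0, ref[pos])
        allele.pop()
        pos -= 1
    if pos == call.pos:
        return call
    anchor = ref[pos]
    if call.svtype == "DEL":
        return SVCall(call.chrom, pos, "DEL", call.svlen,
                      ref_allele=ref[pos:pos + 1 + call.svlen],
                      alt_allele=anchor,
                      source_segment=call.source_segment,
                      contig_id=call.contig_id)
    return SVCall(call.chrom, pos, "INS", call.svlen,
                  ref_allele=anchor,
                  alt_allele=anchor + "".join(allele),
                  source_segment=call.source_segment,
                  contig_id=call.contig_id)


def deduplicate_calls(calls: list[SVCall]) -> list[SVCall]:
    """Keep one call per (chrom, pos, svtype, svlen), first by input order
    (segment order, then contig id)."""
    seen: set[tuple] = set()
    out = []
    for call in calls:
        key = call.key()
        if key in seen:
            continue
        seen.add(key)
        out.append(call)
    return out


def call_segment(segment, contigs, reference: Reference,
                 config: Config) -> list[SVCall]:
    """Align a segment's contigs and extract size-filtered indels."""
    calls: list[SVCall] = []
    if not contigs:
        return calls
    context = make_window_context(segment, reference, config)
    for contig in contigs:
        for aln in align_contig(contig.sequence, segment, reference, config,
                                contig_id=contig.contig_id, context=context):
            calls.extend(extract_indels_from_cigar(
                aln, reference, config, source_segment=segment.segment_id))
    return calls


def write_raw_calls_tsv(calls: list[SVCall], path: str) -> str:
    """Debugging dump of pre-deduplication events."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tsvtype\tsvlen\tsegment\tcontig\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.svtype}\t{c.svlen}\t"
                     f"{c.source_segment}\t{c.contig_id}\n")
    return path


def call_genome(segments, contigs_per_segment, reference: Reference,
                config: Config) -> list[SVCall]:
    """Concatenate per-segment calls, left-align, deduplicate, sort."""
    raw: list[SVCall] = []
    for segment in segments:
        contigs = contigs_per_segment.get(segment.segment_id, [])
        raw.extend(call_segment(segment, contigs, reference, config))
    normalized = [left_align_call(c, reference) for c in raw]
    deduped = deduplicate_calls(sorted(
        normalized, key=lambda c: (c.source_segment, c.contig_id, c.pos)))
    order = {name: i for i, name in enumerate(reference.sequences)}
    deduped.sort(key=lambda c: (order.get(c.chrom, 1 << 30), c.pos,
                                c.svtype, c.svlen))
    return deduped
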