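"""End-to-end orchestration: filter → tile → per-segment assembly → call.

Segments are processed independently (failures are isolated per segment and
results depend only on segment identity, never on execution order); a run
manifest records per-segment status and counters, and completed segments
can be skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

from .assembly import assemble_segment
from .calling import call_segment, deduplicate_calls, left_align_call
from .filtering import build_read_map
from .io import read_fasta, write_vcf
from .model import Config, Reference, SVCall
from .segments import gather_segment_reads, select_barcodes, tile_reference

log = logging.getLogger(__name__)


@dataclass
class SegmentStatus:
    segment_id: str
    status: str = "pending"  # assembled | empty | failed | skipped
    barcodes: int = 0
    pairs: int = 0
    long_reads: int = 0
    contigs: int = 0
    raw_calls: int = 0
    seconds: float = 0.0


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    segments: dict = field(default_factory=dict)  # segment_id -> SegmentStatus
    counters: dict = field(default_factory=dict)

    def save(self, path: str) -> str:
        payload = {
            "config": self.config,
            "inputs": self.inputs,
            "segments": {k: vars(v) for k, v in self.segments.items()},
            "counters": self.counters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        manifest = cls(config=payload["config"], inputs=payload["inputs"],
                       counters=payload.get("counters", {}))
        for k, v in payload["segments"].items():
            manifest.segments[k] = SegmentStatus(**v)
        return manifest


def _unplaced_contigs(bam_path: str, reference: Reference,
                      config: Config) -> set[str]:
    """BAM contigs treated as unplaced: names absent from the supplied
    reference, plus any matching the configured override regex."""
    import re

    import pysam

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        names = set(bam.references)
    unplaced = {n for n in names if n not in reference.sequences}
    if config.unplaced_regex:
        pattern = re.compile(config.unplaced_regex)
        unplaced |= {n for n in names if pattern.search(n)}
    return unplaced


def segment_seed(global_seed: int, segment_id: str) -> int:
    """Deterministic per-segment seed independent of execution order."""
    digest = hashlib.sha256(f"{global_seed}:{segment_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (1 << 31)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while chunk := fh.read(1 << 20):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(reference_fasta: str, slr_bam: str,
                 long_read_bam: Optional[str], config: Config,
                 out_dir: str, resume: bool = False) -> tuple[str, RunManifest]:
    """Run the whole caller; returns (vcf_path, manifest).

    Raises ``RuntimeError`` when more than 10 % of segments fail.
    """
    os.makedirs(out_dir, exist_ok=True)
    seg_dir = os.path.join(out_dir, "segments")
    os.makedirs(seg_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.json")
    reference = read_fasta(reference_fasta)
    config_dict = {k: v for k, v in vars(config).items()}
    manifest = RunManifest(
        config=config_dict,
        inputs={
            "reference": {"path": reference_fasta,
                          "sha256_16": _checksum(reference_fasta)},
            "slr_bam": {"path": slr_bam, "sha256_16": _checksum(slr_bam)},
            "long_read_bam": ({"path": long_read_bam,
                               "sha256_16": _checksum(long_read_bam)}
                              if long_read_bam else None),
        },
    )
    prior = None
    if resume and os.path.exists(manifest_path):
        prior = RunManifest.load(manifest_path)
        if prior.inputs != manifest.inputs or prior.config != config_dict:
            log.warning("manifest does not match current inputs; not resuming")
            prior = None

    t0 = time.time()
    unplaced = _unplaced_contigs(slr_bam, reference, config)
    read_map = build_read_map(slr_bam, config, unplaced=unplaced)
    manifest.counters["read_map_pairs"] = read_map.total_pairs
    manifest.counters["read_map_seconds"] = round(time.time() - t0, 2)

    segments = tile_reference(reference, config)
    all_calls: list[SVCall] = []
    failed = 0
    for segment in segments:
        status = SegmentStatus(segment.segment_id)
        manifest.segments[segment.segment_id] = status
        cache_path = os.path.join(
            seg_dir, segment.segment_id.replace(":", "_").replace("/", "_")
            + ".json")
        if prior is not None:
            old = prior.segments.get(segment.segment_id)
            if old and old.status in ("assembled", "empty") \
                    and os.path.exists(cache_path):
                with open(cache_path) as fh:
                    cached = json.load(fh)
                all_calls.extend(SVCall(**c) for c in cached)
                status.__dict__.update(old.__dict__)
                status.status = old.status
                continue
        t1 = time.time()
        try:
            segment.barcodes = select_barcodes(segment.window, slr_bam, config)
            gather_segment_reads(segment, slr_bam, read_map, long_read_bam,
                                 config)
            status.barcodes = len(segment.barcodes)
            status.pairs = (len(segment.local_pairs)
                            + len(segment.recruited_pairs))
            status.long_reads = len(segment.long_reads)
            contigs = assemble_segment(segment, config)
            status.contigs = len(contigs)
            if not contigs:
                status.status = "empty"
            else:
                calls = call_segment(segment, contigs, reference, config)
                status.raw_calls = len(calls)
                all_calls.extend(calls)
                status.status = "assembled"
            with open(cache_path, "w") as fh:
                json.dump([vars_call(c) for c in all_calls
                           if c.source_segment == segment.segment_id], fh)
        except Exception:
            log.exception("segment %s failed", segment.segment_id)
            status.status = "failed"
            failed += 1
        status.seconds = round(time.time() - t1, 2)

    manifest.counters["segments"] = len(segments)
    manifest.counters["segments_failed"] = failed
    manifest.counters["raw_calls"] = len(all_calls)

    normalized = [left_align_call(c, reference) for c in all_calls]
    deduped = deduplicate_calls(sorted(
        normalized, key=lambda c: (c.source_segment, c.contig_id, c.pos)))
    order = {name: i for i, name in enumerate(reference.sequences)}
    deduped.sort(key=lambda c: (order.get(c.chrom, 1 << 30), c.pos,
                                c.svtype, c.svlen))
    manifest.counters["deduped_calls"] = len(deduped)
    vcf_path = os.path.join(out_dir, "calls.vcf")
    write_vcf(deduped, reference, vcf_path)
    manifest.save(manifest_path)
    if segments and failed > 0.1 * len(segments):
        raise RuntimeError(
            f"{failed}/{len(segments)} segments failed; see {manifest_path}")
    return vcf_path, manifest


def vars_call(call: SVCall) -> dict:
    return {
        "chrom": call.chrom, "pos": call.pos, "svtype": call.svtype,
        "svlen": call.svlen, "ref_allele": call.ref_allele,
        "alt_allele": call.alt_allele, "source_segment": call.source_segment,
        "contig_id": call.contig_id,
    }
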