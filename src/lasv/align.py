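"""Glocal contig-to-window alignment: exact seeds, collinear chaining, and
affine-gap dynamic programming between anchors.

The aligner is global in the contig and local in the reference window
(window padded by ``align_pad``).  Unique exact seed matches are chained by
longest-increasing-subsequence; the sequence between adjacent anchors is
aligned with Gotoh affine-gap DP (a gap of length L costs
``gap_open + L * gap_extend``), which is where SV-scale I/D operations in
the CIGAR come from.  Both strands are tried and the better-scoring one is
kept.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Config, Reference, revcomp

log = logging.getLogger(__name__)

NEG_INF = -(1 << 30)


@dataclass
class ContigAlignment:
    contig_id: str
    chrom: str
    ref_start: int  # 0-based, window coordinates already projected to chrom
    cigar: list[tuple[str, int]]
    identity: float
    strand: str  # "+" | "-"
    score: int = 0
    query_sequence: str = ""  # oriented as aligned


# -- affine-gap DP core ---------------------------------------------------


def affine_align(a: str, b: str, config: Config,
                 free_b_start: bool = False,
                 free_b_end: bool = False,
                 extension: bool = False) -> tuple[int, list[tuple[str, int]], int, int]:
    """Gotoh alignment of query ``a`` against reference ``b``.

    Global in ``a``; ``free_b_start``/``free_b_end`` make leading/trailing
    reference sequence free (no gap penalty, reported as an offset rather
    than D operations).  With ``extension`` the alignment is anchored at
    (0, 0) but free at both ends: the best-scoring cell wins and the
    unaligned query tail is soft-clipped — the mode for contig sequence
    running past the window (e.g. across a deletion whose far flank lies
    outside it).  Returns (score, cigar, b_start, b_end).
    """
    if extension:
        assert not free_b_start
        if len(a) == 0 or len(b) == 0:
            return 0, ([("S", len(a))] if a else []), 0, 0
    if len(a) == 0:
        if free_b_start or free_b_end:
            return 0, [], len(b) if free_b_start and not free_b_end else 0, \
                len(b) if free_b_start and not free_b_end else 0
        gap = config.gap_open + config.gap_extend * len(b) if b else 0
        return gap, ([("D", len(b))] if b else []), 0, len(b)
    if len(b) == 0:
        return (config.gap_open + config.gap_extend * len(a),
                [("I", len(a))], 0, 0)
    if len(a) * len(b) > 40_000_000:
        return _edlib_fallback(a, b, config, free_b_start, free_b_end)
    if extension:
        return _gotoh(a, b, config, False, True, extension=True)
    if len(b) < len(a) and not (free_b_start or free_b_end):
        # run DP over the shorter sequence as rows; swap I/D back
        score, cigar, _, _ = affine_align(b, a, config)
        cigar = [("I" if op == "D" else "D" if op == "I" else op, ln)
                 for op, ln in cigar]
        return score, cigar, 0, len(b)
    return _gotoh(a, b, config, free_b_start, free_b_end)


def _gotoh(a: str, b: str, config: Config,
           free_b_start: bool, free_b_end: bool, extension: bool = False):
    m, n = len(a), len(b)
    match, mismatch = config.match_score, config.mismatch_score
    open_, ext = config.gap_open, config.gap_extend
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    an = np.frombuffer(a.encode(), dtype=np.uint8)
    jj = np.arange(n + 1, dtype=np.int64)

    best_cell = (0, 0, 0)  # extension mode: best (score, i, j)
    H = np.empty(n + 1, dtype=np.int64)
    if free_b_start:
        H[:] = 0
    else:
        H[0] = 0
        H[1:] = open_ + ext * jj[1:]
    F = np.full(n + 1, NEG_INF // 2, dtype=np.int64)
    # traceback: tb_h: 0 diag, 1 from E (horizontal), 2 from F (vertical),
    # 3 free start; tb_e / tb_f: 1 = continue gap, 0 = open from H
    tb_h = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_e = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_f = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_h[0, :] = 3 if free_b_start else 1

    for i in range(1, m + 1):
        Hprev = H
        # vertical gaps
        F_cont = F + ext
        F_open = Hprev + open_ + ext
        F = np.maximum(F_cont, F_open)
        tb_f[i] = (F_cont >= F_open)
        # diagonal
        sub = np.where(bn == an[i - 1], match, mismatch)
        H0 = np.empty(n + 1, dtype=np.int64)
        H0[0] = open_ + ext * i
        H0[1:] = Hprev[:-1] + sub
        H0 = np.maximum(H0, F)
        # horizontal gaps via prefix max-scan:
        # E[j] = open_ + ext*j + max_{j'<j}(H0[j'] - ext*j')
        G = H0 - ext * jj
        Gmax = np.maximum.accumulate(G)
        E = np.full(n + 1, NEG_INF, dtype=np.int64)
        E[1:] = open_ + ext * jj[1:] + Gmax[:-1]
        H = np.maximum(H0, E)
        row_tb = np.zeros(n + 1, dtype=np.int8)
        row_tb[H == E] = 1
        row_tb[(H == H0) & (H == F)] = 2
        row_tb[(H == H0) & (H != F) & (H != E)] = 0
        # prefer diagonal on ties with E
        diag_ok = np.zeros(n + 1, dtype=bool)
        diag_ok[1:] = H[1:] == Hprev[:-1] + sub
        row_tb[diag_ok & (row_tb == 1)] = 0
        row_tb[0] = 2
        tb_h[i] = row_tb
        # E continuation info for traceback: E[j] came from extension iff
        # E[j] == E_prev_col + ext where E_prev_col = H-path... reconstruct
        # from scan: continuation when Gmax[j-1] != G[j-1]
        cont = np.zeros(n + 1, dtype=np.int8)
        cont[1:] = (Gmax[:-1] != G[:-1]).astype(np.int8)
        tb_e[i] = cont
        if extension:
            row_best = int(H.max())
            if row_best > best_cell[0]:
                best_cell = (row_best, i, int(np.argmax(H)))

    if extension:
        score, i_end, j_end = best_cell
    elif free_b_end:
        j_end = int(np.argmax(H))
        score = int(H[j_end])
    else:
        j_end = n
        score = int(H[n])

    # traceback
    ops: list[str] = []
    i, j = (i_end, j_end) if extension else (m, j_end)
    clip_tail = m - i if extension else 0
    state = "H"
    b_start = 0
    while i > 0 or (j > 0 and state != "H"):
        if state == "H":
            t = tb_h[i, j]
            if t == 3:
                break
            if t == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif t == 1:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            j -= 1
            if not tb_e[i, j + 1]:
                state = "H"
        else:  # F
            ops.append("I")
            i -= 1
            if not tb_f[i + 1, j]:
                state = "H"
        if i == 0 and state == "H":
            if free_b_start:
                break
            while j > 0:
                ops.append("D")
                j -= 1
    b_start = j
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    if extension and clip_tail:
        cigar.append(("S", clip_tail))
    return score, cigar, b_start, j_end


def _edlib_fallback(a: str, b: str, config: Config,
                    free_b_start: bool, free_b_end: bool):
    """Unit-cost alignment path for oversized DP problems, rescored with
    the affine scheme."""
    import edlib

    mode = "HW" if (free_b_start and free_b_end) else "NW"
    res = edlib.align(a, b, mode=mode, task="path")
    locs = res.get("locations") or [(0, len(b) - 1)]
    b_start, b_end = locs[0][0] or 0, (locs[0][1] or (len(b) - 1)) + 1
    cigar = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=XM" else ("I" if ch == "I" else "D")
            ln = int(num)
            num = ""
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + ln)
            else:
                cigar.append((op, ln))
    score = score_cigar(cigar, a, b[b_start:b_end], config)
    return score, cigar, b_start, b_end


def score_cigar(cigar: list[tuple[str, int]], a: str, b: str,
                config: Config) -> int:
    """Affine score of an explicit alignment (a vs the aligned b slice)."""
    i = j = 0
    score = 0
    for op, ln in cigar:
        if op == "M":
            for x in range(ln):
                score += (config.match_score if a[i + x] == b[j + x]
                          else config.mismatch_score)
            i += ln
            j += ln
        elif op == "I":
            score += config.gap_open + config.gap_extend * ln
            i += ln
        elif op == "D":
            score += config.gap_open + config.gap_extend * ln
            j += ln
    return score


# -- seeding and chaining --------------------------------------------------


def _unique_seed_index(window: str, seed_len: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(window) - seed_len + 1):
        km = window[i:i + seed_len]
        counts[km] = -1 if km in counts else i
    return {km: pos for km, pos in counts.items() if pos >= 0}


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with both coordinates strictly increasing (anchors are
    pre-sorted by query position)."""
    if not anchors:
        return []
    tails: list[int] = []       # smallest ref-end of chains by length
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for idx, (qi, ri) in enumerate(anchors):
        p = bisect_left(tails, ri)
        if p == len(tails):
            tails.append(ri)
            tails_idx.append(idx)
        else:
            tails[p] = ri
            tails_idx[p] = idx
        prev[idx] = tails_idx[p - 1] if p > 0 else -1
    chain = []
    idx = tails_idx[-1]
    while idx != -1:
        chain.append(anchors[idx])
        idx = prev[idx]
    chain.reverse()
    return chain


def _build_cigar_from_chain(contig: str, window: str,
                            chain: list[tuple[int, int]],
                            seed_len: int, config: Config):
    """Stitch anchor matches with DP-aligned inter-anchor pieces."""
    cigar: list[tuple[str, int]] = []
    score = 0

    def add(op: str, ln: int):
        nonlocal cigar
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    # collapse chain into non-overlapping blocks
    q0, r0 = chain[0]
    # prefix: extension alignment leftward from the first anchor (free at
    # both outer ends, so contig sequence with no support in the window —
    # e.g. beyond a deletion crossing the window edge — is soft-clipped)
    ref_lo = max(0, r0 - q0 - 200)
    pre_score, pre_cigar, _, b_end = affine_align(
        contig[:q0][::-1], window[ref_lo:r0][::-1], config, extension=True)
    pre_cigar = pre_cigar[::-1]
    ref_start = r0 - b_end
    score += pre_score
    for op, ln in pre_cigar:
        add(op, ln)
    add("M", seed_len)
    score += seed_len * config.match_score
    qa, ra = q0 + seed_len, r0 + seed_len
    for qi, ri in chain[1:]:
        if qi + seed_len <= qa or ri + seed_len <= ra:
            continue
        dq, dr = qi - qa, ri - ra
        if dq == dr and dq < 0:
            # overlapping anchors on the same diagonal: extend the match run
            add("M", qi + seed_len - qa)
            score += (qi + seed_len - qa) * config.match_score
            qa, ra = qi + seed_len, ri + seed_len
            continue
        if dq < 0 or dr < 0:
            continue  # conflicting overlap, drop anchor
        piece_score, piece_cigar, _, _ = affine_align(
            contig[qa:qi], window[ra:ri], config)
        score += piece_score
        for op, ln in piece_cigar:
            add(op, ln)
        add("M", seed_len)
        score += seed_len * config.match_score
        qa, ra = qi + seed_len, ri + seed_len
    # suffix: extension alignment rightward from the last anchor
    ref_hi = min(len(window), ra + (len(contig) - qa) + 200)
    suf_score, suf_cigar, _, b_end = affine_align(
        contig[qa:], window[ra:ref_hi], config, extension=True)
    score += suf_score
    for op, ln in suf_cigar:
        add(op, ln)
    return score, cigar, ref_start


def _trim_edge_indels(cigar: list[tuple[str, int]], ref_start: int):
    """Convert leading/trailing I to soft clips and drop edge D ops, so
    window-edge artifacts cannot become calls."""
    out = list(cigar)
    lead_clip = 0
    while out and out[0][0] != "M":
        op, ln = out.pop(0)
        if op in ("I", "S"):
            lead_clip += ln
        elif op == "D":
            ref_start += ln
    tail_clip = 0
    while out and out[-1][0] != "M":
        op, ln = out.pop()
        if op in ("I", "S"):
            tail_clip += ln
    if lead_clip:
        out.insert(0, ("S", lead_clip))
    if tail_clip:
        out.append(("S", tail_clip))
    return out, ref_start


def _identity(cigar, contig: str, window: str, ref_start: int) -> float:
    """Gap-compressed identity: each indel run counts as one column, so an
    SV-scale gap does not mask an otherwise faithful alignment."""
    qi, ri = 0, ref_start
    matches = columns = 0
    for op, ln in cigar:
        if op == "M":
            cs, ws = contig[qi:qi + ln], window[ri:ri + ln]
            matches += sum(1 for x, y in zip(cs, ws) if x == y)
            columns += ln
            qi += ln
            ri += ln
        elif op == "I":
            columns += 1
            qi += ln
        elif op == "D":
            columns += 1
            ri += ln
        elif op == "S":
            qi += ln
    return matches / columns if columns else 0.0


@dataclass
class WindowContext:
    """Cached per-window alignment state shared by a segment's contigs."""

    chrom: str
    win_lo: int
    window: str
    seeds: dict[str, int]


def make_window_context(segment, reference: Reference,
                        config: Config) -> WindowContext:
    chrom = segment.chrom
    win_lo = max(0, segment.start - config.align_pad)
    win_hi = min(reference.lengths[chrom], segment.end + config.align_pad)
    window = reference.fetch(chrom, win_lo, win_hi)
    return WindowContext(chrom, win_lo, window,
                         _unique_seed_index(window, config.seed_len))


def align_contig(contig: str, segment, reference: Reference,
                 config: Config, contig_id: str = "",
                 context: Optional[WindowContext] = None) -> list[ContigAlignment]:
    """Align one contig to its segment window (± pad); returns the best
    alignment, or an empty list when no seed chain is found."""
    if context is None:
        context = make_window_context(segment, reference, config)
    chrom, win_lo = context.chrom, context.win_lo
    window, seeds = context.window, context.seeds

    best = None
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        anchors = []
        for i in range(0, len(seq) - config.seed_len + 1):
            pos = seeds.get(seq[i:i + config.seed_len])
            if pos is not None:
                anchors.append((i, pos))
        chain = _chain_anchors(anchors)
        if not chain:
            continue
        score, cigar, ref_start = _build_cigar_from_chain(
            seq, window, chain, config.seed_len, config)
        cigar, ref_start = _trim_edge_indels(cigar, ref_start)
        if not cigar:
            continue
        identity = _identity(cigar, seq, window, ref_start)
        aln = ContigAlignment(
            contig_id=contig_id, chrom=chrom, ref_start=win_lo + ref_start,
            cigar=cigar, identity=identity, strand=strand, score=score,
            query_sequence=seq)
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        log.info("contig %s unplaced in %s", contig_id, segment.segment_id)
        return []
    if best.identity < config.min_alignment_identity:
        return []
    return [best]
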