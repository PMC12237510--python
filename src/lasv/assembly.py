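"""Local de Bruijn graph assembly of one segment's gathered reads.

The assembler is deliberately small and tuned for diploid SV discovery in
50 kbp windows rather than general-purpose genome assembly.  Three behaviors
distinguish it from a bacterial-style assembler:

* **Relaxed path deduplication** — parallel paths through a bulge are both
  spelled as contigs, so heterozygous alleles each yield a contig.
* **Relaxed simplification** — only unambiguous sequencing-error artifacts
  (short coverage-1 dead ends, sub-floor bulge branches) are removed; long
  tips and balanced bulges are kept because they carry diploid structure.
* **Tip-aware path extension** — a path is not extended through a junction
  when a long dead-end (the signature of a local coverage drop) is incident
  nearby; joining across such junctions is how assembly-based callers
  manufacture false deletions.

The graph is built over (k+1)-mers counted on both strands of every read,
so it is invariant under read order and orientation; every unitig has a
reverse-complement twin and the two share a usage budget during path
extension.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import Config, ReadRecord, revcomp

log = logging.getLogger(__name__)

_ACGT_SPLIT = re.compile("[^ACGT]+")


def _clean_sequences(sequences: Iterable[str]) -> list[str]:
    """Uppercase and split on non-ACGT characters."""
    out = []
    for seq in sequences:
        for part in _ACGT_SPLIT.split(seq.upper()):
            if part:
                out.append(part)
    return out


@dataclass
class Unitig:
    uid: int
    seq: str
    cov: float  # mean coverage over the unitig's edges

    def __len__(self):
        return len(self.seq)


class AssemblyGraph:
    """Compacted de Bruijn graph over solid (k+1)-mer edges.

    ``edges`` maps each solid (k+1)-mer (both strands present) to its
    coverage.  Unitigs are maximal non-branching paths; each has a
    reverse-complement twin (possibly itself for palindromes).
    """

    def __init__(self, k: int, edges: dict[str, int]):
        self.k = k
        self.edges = edges
        self.unitigs: dict[int, Unitig] = {}
        self._first_edge: dict[str, int] = {}
        self._last_edge: dict[str, int] = {}
        self._twin: dict[int, int] = {}
        self._compact()

    def _out_edges(self, node: str) -> list[str]:
        edges = self.edges
        return [e for c in "ACGT" if (e := node + c) in edges]

    def _in_edges(self, node: str) -> list[str]:
        edges = self.edges
        return [e for c in "ACGT" if (e := c + node) in edges]

    # -- construction -----------------------------------------------------

    def _compact(self) -> None:
        """Compact maximal non-branching edge paths into unitigs.

        Works on 2-bit packed edge arrays: node ids come from uniquing the
        packed prefix/suffix pairs, next-edge pointers follow unique
        non-junction nodes, and only unitig sequences are decoded back to
        strings.
        """
        import numpy as np

        from ._kmers import decode_nodes, pack_kmers

        k = self.k
        km = k + 1
        edge_strs = list(self.edges)
        n = len(edge_strs)
        self.unitigs = {}
        self._first_edge = {}
        self._last_edge = {}
        self._twin = {}
        if n == 0:
            return
        his, los = pack_kmers(edge_strs, km)
        covs = np.fromiter(self.edges.values(), dtype=np.int64, count=n)
        # node packing convention: last min(len,28) bases in lo, rest in hi
        if km <= 28:
            node_mask = (1 << (2 * (km - 1))) - 1
            pref = np.stack([np.zeros(n, np.int64), his * 0 + (los >> 2)], axis=1)
            suff = np.stack([np.zeros(n, np.int64), los & node_mask], axis=1)
        else:
            hi_len = km - 28
            hi_node_mask = (1 << (2 * (hi_len - 1))) - 1
            lo_mask56 = (1 << 56) - 1
            pref = np.stack([his >> 2,
                             (((his & 3) << 54) | (los >> 2)) & lo_mask56],
                            axis=1)
            suff = np.stack([his & hi_node_mask, los], axis=1)
        all_a = np.concatenate([pref[:, 0], suff[:, 0]])
        all_b = np.concatenate([pref[:, 1], suff[:, 1]])
        order = np.lexsort((all_b, all_a))
        sa, sb = all_a[order], all_b[order]
        new = np.empty(2 * n, dtype=bool)
        new[0] = True
        new[1:] = (sa[1:] != sa[:-1]) | (sb[1:] != sb[:-1])
        ids = np.cumsum(new) - 1
        inv = np.empty(2 * n, dtype=np.int64)
        inv[order] = ids
        pref_id, suff_id = inv[:n], inv[n:]
        nu = int(ids[-1]) + 1
        outdeg = np.bincount(pref_id, minlength=nu)
        indeg = np.bincount(suff_id, minlength=nu)
        junction = (outdeg != 1) | (indeg != 1)
        edge_of_node = np.full(nu, -1, dtype=np.int64)
        edge_of_node[pref_id] = np.arange(n)
        nxt = np.where(junction[suff_id], -1, edge_of_node[suff_id])
        is_start = junction[pref_id]

        visited = np.zeros(n, dtype=bool)
        chains: list[list[int]] = []
        nxt_l = nxt.tolist()
        start_l = is_start.tolist()

        def walk(e0: int) -> None:
            chain = [e0]
            visited[e0] = True
            j = nxt_l[e0]
            while j >= 0 and not visited[j]:
                visited[j] = True
                chain.append(j)
                j = nxt_l[j]
            chains.append(chain)

        for i in range(n):
            if start_l[i] and not visited[i]:
                walk(i)
        for i in range(n):  # isolated cycles
            if not visited[i]:
                walk(i)

        chars = "ACGT"
        node_len = km - 1
        pref_first = pref[[c[0] for c in chains]]
        prefixes = decode_nodes(
            np.ascontiguousarray(pref_first[:, 0]),
            np.ascontiguousarray(pref_first[:, 1]), node_len)
        last_base = (los & 3).tolist()
        unitigs: dict[int, Unitig] = {}
        first_edge: dict[str, int] = {}
        last_edge: dict[str, int] = {}
        for uid, chain in enumerate(chains):
            seq = prefixes[uid] + "".join(chars[last_base[e]] for e in chain)
            cov = float(covs[chain].mean())
            unitigs[uid] = Unitig(uid, seq, cov)
            first_edge[edge_strs[chain[0]]] = uid
            last_edge[edge_strs[chain[-1]]] = uid
        self.unitigs = unitigs
        self._first_edge = first_edge
        self._last_edge = last_edge
        by_seq = {u.seq: u.uid for u in unitigs.values()}
        self._twin = {u.uid: by_seq.get(revcomp(u.seq), u.uid)
                      for u in unitigs.values()}

    # -- topology queries --------------------------------------------------

    def twin(self, uid: int) -> int:
        return self._twin[uid]

    def successors(self, uid: int) -> list[int]:
        node = self.unitigs[uid].seq[-self.k:]
        return [self._first_edge[e] for e in self._out_edges(node)
                if e in self._first_edge]

    def predecessors(self, uid: int) -> list[int]:
        node = self.unitigs[uid].seq[:self.k]
        return [self._last_edge[e] for e in self._in_edges(node)
                if e in self._last_edge]

    def is_tip(self, uid: int) -> bool:
        """Dead end on either side."""
        return not self.successors(uid) or not self.predecessors(uid)

    def is_long_tip(self, uid: int, min_len: int) -> bool:
        return len(self.unitigs[uid]) >= min_len and self.is_tip(uid)

    def incident_unitigs(self, node: str) -> set[int]:
        """Unitigs whose endpoint is ``node`` or an immediate neighbor."""
        nodes = {node}
        for e in self._out_edges(node):
            nodes.add(e[1:])
        for e in self._in_edges(node):
            nodes.add(e[:self.k])
        uids: set[int] = set()
        for n in nodes:
            for e in self._out_edges(n):
                if e in self._first_edge:
                    uids.add(self._first_edge[e])
            for e in self._in_edges(n):
                if e in self._last_edge:
                    uids.add(self._last_edge[e])
        return uids

    # -- spec-level canonical views ---------------------------------------

    @property
    def canonical_nodes(self) -> set[str]:
        nodes = set()
        for e in self.edges:
            for km in (e[:self.k], e[1:]):
                nodes.add(min(km, revcomp(km)))
        return nodes

    @property
    def canonical_edges(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e, cov in self.edges.items():
            out[min(e, revcomp(e))] = cov
        return out

    def remove_unitig_edges(self, uid: int) -> None:
        """Delete a unitig's edges (and its twin's) from the edge set."""
        k = self.k
        for u in {uid, self._twin[uid]}:
            seq = self.unitigs[u].seq
            for i in range(len(seq) - k):
                self.edges.pop(seq[i:i + k + 1], None)

    def to_gfa(self, path: str) -> str:
        """Optional GFA 1.0 dump for debugging."""
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for u in self.unitigs.values():
                fh.write(f"S\t{u.uid}\t{u.seq}\tdp:f:{u.cov:.1f}\n")
            for u in self.unitigs.values():
                for v in self.successors(u.uid):
                    fh.write(f"L\t{u.uid}\t+\t{v}\t+\t{self.k}M\n")
        return path


def build_graph(short_read_sequences: Iterable[str],
                long_read_sequences: Iterable[str],
                config: Config) -> AssemblyGraph:
    """Count (k+1)-mers and build the compacted graph.

    Short-read k-mers must reach ``solid_coverage`` (default 2) to enter the
    graph; long-read k-mers are admitted with corroboration only — present
    in the short-read spectrum at all, or seen in at least two distinct long
    reads — because even HiFi-grade error rates flood a 55-mer spectrum
    with singleton artifacts.
    """
    from ._kmers import count_solid_kmers, decode_kmers

    k = config.kmer_size
    km = k + 1
    shorts = _clean_sequences(short_read_sequences)
    longs = _clean_sequences(long_read_sequences)
    # strand-naive counting over explicit both-strand buffers; long reads
    # interleave read/rc so distinct-read counts treat them as one molecule
    short_both = shorts + [revcomp(s) for s in shorts]
    long_both: list[str] = []
    for s in longs:
        long_both.append(s)
        long_both.append(revcomp(s))
    his, los, covs = count_solid_kmers(short_both, long_both, km,
                                       config.solid_coverage)
    kmers = decode_kmers(his, los, km)
    edges = dict(zip(kmers, (int(c) for c in covs)))
    if not edges:
        log.warning("no solid k-mers: all reads shorter than k+1 or too sparse")
    return AssemblyGraph(k, edges)


def _weighted_median_coverage(graph: AssemblyGraph) -> float:
    items = sorted(((u.cov, len(u)) for u in graph.unitigs.values()))
    if not items:
        return 0.0
    total = sum(w for _, w in items)
    acc = 0
    for cov, w in items:
        acc += w
        if acc * 2 >= total:
            return cov
    return items[-1][0]


def simplify_graph(graph: AssemblyGraph, config: Config) -> AssemblyGraph:
    """Conservative cleanup that keeps diploid structure.

    Removes (i) short (< k+10) coverage-1 dead ends — sequencing-error
    tips — and (ii) bulge branches whose coverage falls below the
    heterozygous floor (a fraction of the median coverage) while a parallel
    branch stays above it.  Long tips survive regardless of coverage: they
    mark coverage drops that the path-extension rule must see.  In a k-mer
    graph two parallel paths cannot spell identical sequence (edges are a
    set), so exact-duplicate removal is vacuous here and duplicate contigs
    are collapsed at path level instead.
    """
    k = graph.k
    changed = False
    # (i) sequencing-error tips
    for uid, unitig in list(graph.unitigs.items()):
        if len(unitig) < k + 10 and unitig.cov < 2.0 and graph.is_tip(uid):
            graph.remove_unitig_edges(uid)
            changed = True
    if changed:
        graph = AssemblyGraph(k, graph.edges)
    # (ii) sub-floor bulge branches
    floor = config.het_coverage_floor_frac * _weighted_median_coverage(graph)
    ends: dict[tuple[str, str], list[int]] = {}
    for uid, unitig in graph.unitigs.items():
        ends.setdefault((unitig.seq[:k], unitig.seq[-k:]), []).append(uid)
    changed = False
    for (_, _), uids in ends.items():
        if len(uids) < 2:
            continue
        covs = {u: graph.unitigs[u].cov for u in uids}
        strongest = max(covs.values())
        if strongest < floor:
            continue
        for u in uids:
            if covs[u] < floor and covs[u] < strongest:
                graph.remove_unitig_edges(u)
                changed = True
    if changed:
        graph = AssemblyGraph(k, graph.edges)
    return graph


@dataclass
class ContigPath:
    """A spelled path through the unitig graph."""

    unitig_ids: list[int]
    sequence: str
    mean_coverage: float
    terminated_by_tip_rule: bool = False
    contig_id: str = ""

    def __len__(self):
        return len(self.sequence)


def _spell(graph: AssemblyGraph, uids: list[int]) -> str:
    k = graph.k
    seq = graph.unitigs[uids[0]].seq
    for uid in uids[1:]:
        seq += graph.unitigs[uid].seq[k:]
    return seq


def _mean_cov(graph: AssemblyGraph, uids: list[int]) -> float:
    total = sum(len(graph.unitigs[u]) for u in uids)
    if not total:
        return 0.0
    return sum(graph.unitigs[u].cov * len(graph.unitigs[u]) for u in uids) / total


def _extend_right(graph: AssemblyGraph, path: list[int], used: Counter,
                  config: Config) -> bool:
    """Greedy rightward extension; returns True if tip rule terminated."""
    tip_len = config.tip_vicinity_len
    while True:
        cur = path[-1]
        succs = graph.successors(cur)
        if not succs:
            return False
        avail = [s for s in succs
                 if used[min(s, graph.twin(s))] < 2]
        if not avail:
            return False
        # deterministic choice: highest coverage, then sequence
        chosen = max(avail, key=lambda s: (graph.unitigs[s].cov,
                                           graph.unitigs[s].seq))
        if config.tip_rule_enabled:
            node = graph.unitigs[cur].seq[-graph.k:]
            exclude = set()
            for u in path + [chosen]:
                exclude.add(u)
                exclude.add(graph.twin(u))
            for u in graph.incident_unitigs(node):
                if u in exclude:
                    continue
                if graph.is_long_tip(u, tip_len):
                    return True
        path.append(chosen)
        used[min(chosen, graph.twin(chosen))] += 1


def _rc_path(graph: AssemblyGraph, path: list[int]) -> list[int]:
    return [graph.twin(u) for u in reversed(path)]


def extend_paths(graph: AssemblyGraph, config: Config) -> list[ContigPath]:
    """Spell contigs from the simplified graph.

    Paths are seeded from every still-unused unitig in descending length
    order and extended greedily in both directions.  Each unitig (jointly
    with its reverse-complement twin) may appear in at most two paths, which
    lets a bulge's two branches each be spelled through the shared flanks —
    the relaxed-deduplication behavior — while guaranteeing termination.
    """
    used: Counter = Counter()
    seeds = sorted(graph.unitigs.values(),
                   key=lambda u: (-len(u), u.seq))
    out: list[ContigPath] = []
    seen_seqs: set[str] = set()
    for seed in seeds:
        canon = min(seed.uid, graph.twin(seed.uid))
        if used[canon] > 0:
            continue
        path = [seed.uid]
        used[canon] += 1
        tip_flag = _extend_right(graph, path, used, config)
        path = _rc_path(graph, path)
        tip_flag |= _extend_right(graph, path, used, config)
        path = _rc_path(graph, path)
        seq = _spell(graph, path)
        key = min(seq, revcomp(seq))
        if key in seen_seqs:
            continue
        seen_seqs.add(key)
        out.append(ContigPath(path, seq, _mean_cov(graph, path), tip_flag))
    out.sort(key=lambda c: (-len(c), c.sequence))
    for i, contig in enumerate(out):
        contig.contig_id = f"contig_{i}"
    return out


# -- hybrid-mode gap closing ---------------------------------------------


def _end_anchor_hit(anchor: str, read_seq: str, config: Config):
    """Locate ``anchor`` inside ``read_seq`` (infix alignment).

    Returns (read_start, read_end, identity) or None.  Identity is over the
    anchor length; acceptance requires the configured anchor identity.
    """
    import edlib

    if len(anchor) < config.gap_anchor_len:
        return None
    max_ed = int(len(anchor) * (1.0 - config.gap_anchor_identity))
    res = edlib.align(anchor, read_seq, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    identity = 1.0 - res["editDistance"] / len(anchor)
    return (start, end + 1, identity)


def close_gaps_with_long_reads(paths: list[ContigPath], graph: AssemblyGraph,
                               long_reads: list[ReadRecord],
                               config: Config) -> list[ContigPath]:
    """Join contig ends bridged by long reads.

    A long read supports the join A→B when it carries an end-anchored match
    to A's suffix followed by one to B's prefix (each at least
    ``gap_anchor_len`` bp at ``gap_anchor_identity``).  Joins are applied
    greedily by descending support; each contig end is used at most once.
    The whole seam — A's anchor, the gap, B's anchor — is spelled from the
    best-identity supporting read, so anchor overlaps need no ad hoc
    trimming and seam artifacts stay at read-error scale.
    """
    if not long_reads or len(paths) < 2:
        return paths
    # only contigs long enough to carry an informative anchor on each end
    # participate; joining sub-anchor fragments mostly chains artifacts
    min_join_len = 2 * config.gap_anchor_len + 100
    joinable = {i for i, p in enumerate(paths) if len(p) >= min_join_len}
    if len(joinable) < 2:
        return paths
    anchor_len = max(config.gap_anchor_len,
                     min(500, min(len(paths[i]) for i in joinable)))
    # oriented contigs: (index, orientation); orientation '-' is revcomp
    oriented: dict[tuple[int, str], str] = {}
    for i, p in enumerate(paths):
        if i not in joinable:
            continue
        oriented[(i, "+")] = p.sequence
        oriented[(i, "-")] = revcomp(p.sequence)

    def flip(key):
        return (key[0], "-" if key[1] == "+" else "+")

    def canon_join(x, y):
        return min(((x, y), (flip(y), flip(x))))

    def a_len(key):
        return min(anchor_len, len(oriented[key]))

    # support[jkey] = list of (mean anchor identity, splice sequence,
    # suffix-anchor len, prefix-anchor len) in the canonical orientation
    support: dict[tuple, list[tuple[float, str, int, int]]] = {}
    for read in long_reads:
        seq = read.sequence
        suffix_hits = {}
        prefix_hits = {}
        for key, cseq in oriented.items():
            a = a_len(key)
            hit = _end_anchor_hit(cseq[-a:], seq, config)
            if hit:
                suffix_hits[key] = hit
            hit = _end_anchor_hit(cseq[:a], seq, config)
            if hit:
                prefix_hits[key] = hit
        for xkey, (p1, p2, id1) in suffix_hits.items():
            for ykey, (q1, q2, id2) in prefix_hits.items():
                if xkey[0] == ykey[0]:
                    continue
                # B's anchor must end after A's, with a bounded gap;
                # moderate overlap of the matches is fine — the seam is
                # spelled from the read either way
                if q2 <= p2 or q1 <= p1 or q1 - p2 > 50_000:
                    continue
                splice = seq[p1:q2]  # A-anchor + gap + B-anchor as read
                jkey = canon_join(xkey, ykey)
                if jkey != (xkey, ykey):
                    splice = revcomp(splice)
                    sa, sb = a_len(jkey[0]), a_len(jkey[1])
                else:
                    sa, sb = a_len(xkey), a_len(ykey)
                support.setdefault(jkey, []).append(
                    ((id1 + id2) / 2, splice, sa, sb))

    if not support:
        return paths
    ranked = sorted(support.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    used_right: set[tuple[int, str]] = set()
    used_left: set[tuple[int, str]] = set()
    joins: dict[tuple[int, str], tuple] = {}
    for (x, y), sups in ranked:
        # the mirrored join uses the same physical contig ends
        if x in used_right or y in used_left:
            continue
        if flip(x) in used_left or flip(y) in used_right:
            continue
        best = max(sups)
        joins[x] = (y, best[1], best[2], best[3])
        used_right.update([x, flip(y)])
        used_left.update([y, flip(x)])

    # stitch chains deterministically
    targets = {v[0] for v in joins.values()}
    consumed: set[int] = set()
    out: list[ContigPath] = []
    starts = sorted(k for k in joins if k not in targets)
    for start in starts:
        if start[0] in consumed:
            continue
        chain = [start]
        node = start
        while node in joins:
            nxt = joins[node][0]
            if nxt[0] in (c[0] for c in chain):
                break  # cycle guard
            chain.append(nxt)
            node = nxt
        if len(chain) < 2:
            continue
        seq = oriented[chain[0]]
        uids = list(paths[chain[0][0]].unitig_ids)
        flags = paths[chain[0][0]].terminated_by_tip_rule
        for prev, cur in zip(chain, chain[1:]):
            _, splice, sa, sb = joins[prev]
            seq = seq[:-sa] + splice + oriented[cur][sb:]
            uids += paths[cur[0]].unitig_ids
            flags |= paths[cur[0]].terminated_by_tip_rule
        for key in chain:
            consumed.add(key[0])
        covs = [paths[c[0]].mean_coverage for c in chain]
        out.append(ContigPath(uids, seq, sum(covs) / len(covs), flags))
    for i, p in enumerate(paths):
        if i not in consumed:
            out.append(p)
    out.sort(key=lambda c: (-len(c), c.sequence))
    for i, contig in enumerate(out):
        contig.contig_id = f"contig_{i}"
    return out



def assemble_segment(segment, config: Config,
                     gfa_path: Optional[str] = None) -> list[ContigPath]:
    """Full per-segment assembly: graph, simplification, path extension,
    and (hybrid mode) long-read gap closing.  Contigs shorter than
    ``min_contig_len`` are dropped."""
    short_seqs = segment.all_sequences()
    long_seqs = [r.sequence for r in segment.long_reads]
    if not short_seqs and not long_seqs:
        log.info("segment %s: no reads gathered", segment.segment_id)
        return []
    graph = build_graph(short_seqs, long_seqs, config)
    if not graph.edges:
        return []
    graph = simplify_graph(graph, config)
    paths = extend_paths(graph, config)
    if segment.long_reads:
        paths = close_gaps_with_long_reads(paths, graph, segment.long_reads,
                                           config)
    if gfa_path:
        graph.to_gfa(gfa_path)
    paths = [p for p in paths if len(p) >= config.min_contig_len]
    for i, contig in enumerate(paths):
        contig.contig_id = f"{segment.segment_id}|contig_{i}"
    return paths
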