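"""Local assembler: graph construction oracle, diploid-preserving
simplification, tip-aware path extension, and long-read gap closing."""

import random
from collections import Counter

import pytest

from lasv.assembly import (AssemblyGraph, build_graph, close_gaps_with_long_reads,
                           extend_paths, simplify_graph)
from lasv.model import Config, ReadRecord, revcomp

from conftest import random_dna


def tile(seq, read_len=150, step=5):
    return [seq[i:i + read_len] for i in range(0, len(seq) - read_len + 1, step)]


def brute_force_canonical_edges(reads, km, threshold):
    """Independent (k+1)-mer enumeration for the graph oracle."""
    counts = Counter()
    for read in reads:
        for s in (read, revcomp(read)):
            for i in range(len(s) - km + 1):
                counts[s[i:i + km]] += 1
    return {min(e, revcomp(e)) for e, c in counts.items() if c >= threshold}


def assemble(reads, cfg, long_reads=()):
    graph = simplify_graph(build_graph(reads, list(long_reads), cfg), cfg)
    return extend_paths(graph, cfg)


class TestBuildGraph:
    def test_single_read_single_unitig(self):
        cfg = Config(solid_coverage=1)
        read = random_dna(1_000, seed=11)
        graph = build_graph([read], [], cfg)
        seqs = sorted(u.seq for u in graph.unitigs.values())
        assert len(seqs) == 2  # forward + reverse complement
        assert read in seqs or revcomp(read) in seqs

    def test_tiled_reads_reconstruct_string(self, config):
        genome = random_dna(5_000, seed=12)
        graph = build_graph(tile(genome), [], config)
        lengths = sorted(len(u) for u in graph.unitigs.values())
        # a single unitig pair spelling (nearly) the whole string
        assert len(lengths) == 2
        assert lengths[0] > 4_800
        u = max(graph.unitigs.values(), key=len)
        assert u.seq in genome or revcomp(u.seq) in genome

    def test_snv_bulge_structure(self, config):
        h1 = random_dna(2_000, seed=13)
        pos = 1_000
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[h1[pos]]
        h2 = h1[:pos] + alt + h1[pos + 1:]
        graph = build_graph(tile(h1) + tile(h2), [], config)
        # shared flanks + two parallel branches (and their rc twins)
        lengths = sorted(len(u) for u in graph.unitigs.values())
        k = config.kmer_size
        assert len(lengths) == 8
        # the two SNV branches each span k+1 + (k-1) overlap bases... the
        # branch unitigs contain the variant column and are ~2k long
        branch = [u for u in graph.unitigs.values()
                  if len(u) == 2 * k + 1]
        assert len(branch) == 4  # two alleles x two strands

    def test_matches_brute_force_enumeration(self, config):
        rng = random.Random(99)
        for trial in range(5):
            genome = random_dna(rng.randint(500, 3_000), seed=100 + trial)
            reads = tile(genome, step=rng.choice([3, 7, 11]))
            # plant a few error reads
            for _ in range(3):
                read = list(rng.choice(reads))
                read[rng.randrange(len(read))] = rng.choice("ACGT")
                reads.append("".join(read))
            graph = build_graph(reads, [], config)
            expected = brute_force_canonical_edges(
                reads, config.kmer_size + 1, config.solid_coverage)
            assert set(graph.canonical_edges) == expected

    def test_all_reads_shorter_than_k(self, config):
        graph = build_graph(["ACGT" * 10], [], config)  # 40 < k+1
        assert graph.edges == {} and graph.unitigs == {}

    def test_long_read_kmers_need_corroboration(self, config):
        genome = random_dna(2_000, seed=17)
        shorts = tile(genome[:1_000])
        lone = random_dna(500, seed=18)
        graph = build_graph(shorts, [lone], config)
        # a single uncorroborated long read contributes nothing
        assert not any(lone[i:i + 56] in graph.edges for i in range(0, 400, 50))
        graph2 = build_graph(shorts, [lone, lone], config)
        assert any(lone[i:i + 56] in graph2.edges for i in range(0, 400, 50))


class TestSimplify:
    def test_error_tip_removed(self):
        cfg = Config(solid_coverage=1)
        genome = random_dna(3_000, seed=21)
        reads = tile(genome, step=5)
        # one read with an error near its end -> short dead-end at cov 1
        bad = genome[1_000:1_150]
        bad = bad[:-1] + {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[-1]]
        graph = build_graph(reads + [bad], [], cfg)
        assert len(graph.unitigs) > 2
        graph = simplify_graph(graph, cfg)
        assert len(graph.unitigs) == 2  # clean backbone + rc

    def test_het_bulge_retained(self, config):
        h1 = random_dna(4_000, seed=22)
        h2 = h1[:2_000] + h1[2_300:]  # 300 bp deletion allele
        graph = build_graph(tile(h1) + tile(h2), [], config)
        n_before = len(graph.unitigs)
        graph = simplify_graph(graph, config)
        assert len(graph.unitigs) == n_before  # both branches kept

    def test_long_coverage_drop_tip_retained(self, config):
        genome = random_dna(4_000, seed=23)
        # drop all reads overlapping [2500, 4000): long dead-end remains
        reads = [r for r in tile(genome)
                 if not (2_500 < genome.find(r) + 150 and genome.find(r) < 4_000)]
        reads = tile(genome[:2_650])
        graph = simplify_graph(build_graph(reads, [], config), config)
        assert any(len(u) >= 2 * config.kmer_size
                   and graph.is_tip(u.uid)
                   for u in graph.unitigs.values())


def _repeat_gap_reads(seed=31, gap=(8_700, 9_700)):
    """Genome with an interspersed repeat pair and a zero-coverage gap
    between the copies (the false-deletion trap)."""
    rng = random.Random(seed)
    g = list(random_dna(14_000, seed=seed))
    g[11_000:11_300] = g[8_000:8_300]  # identical 300 bp repeat copies
    genome = "".join(g)
    reads = [r for i, r in ((i, genome[i:i + 150])
                            for i in range(0, len(genome) - 150, 4))
             if i + 150 <= gap[0] or i >= gap[1]]
    return genome, reads


class TestExtendPaths:
    def test_linear_graph_single_contig(self, config):
        genome = random_dna(5_000, seed=24)
        paths = assemble(tile(genome), config)
        assert len(paths) == 1
        seq = paths[0].sequence
        assert seq in genome or revcomp(seq) in genome
        assert len(seq) > 4_800

    def test_het_deletion_bulge_spells_both_alleles(self, config):
        h1 = random_dna(5_000, seed=25)
        h2 = h1[:2_400] + h1[2_600:]  # het 200 bp deletion
        paths = assemble(tile(h1) + tile(h2), config)
        seqs = [p.sequence for p in paths]
        def hits(h):
            return any((s in h or revcomp(s) in h) and len(s) > 4_000
                       for s in seqs)
        assert hits(h1) and hits(h2)

    def test_tip_rule_blocks_repeat_shortcut(self):
        genome, reads = _repeat_gap_reads()
        cfg = Config()
        paths = assemble(reads, cfg)
        # no contig may jump the gap: every contig matches the genome
        for p in paths:
            s = p.sequence
            assert s in genome or revcomp(s) in genome
        assert any(p.terminated_by_tip_rule for p in paths)

    def test_ablation_produces_chimeric_join(self):
        genome, reads = _repeat_gap_reads()
        cfg = Config(tip_rule_enabled=False)
        paths = assemble(reads, cfg)
        chimeric = [p for p in paths
                    if len(p) > 500
                    and p.sequence not in genome
                    and revcomp(p.sequence) not in genome]
        assert chimeric  # the rule, not luck, prevents the join

    def test_determinism(self, config):
        h1 = random_dna(4_000, seed=26)
        h2 = h1[:1_500] + h1[1_800:]
        reads = tile(h1) + tile(h2)
        a = [p.sequence for p in assemble(list(reads), config)]
        b = [p.sequence for p in assemble(list(reads), config)]
        assert a == b


def _long_read(seq, name="L0"):
    return ReadRecord(name=name, sequence=seq,
                      base_qualities=[40] * len(seq), is_mapped=True,
                      chrom="c", pos=0, cigar=[("M", len(seq))])


class TestGapClosing:
    def test_no_long_reads_identity(self, config):
        genome = random_dna(3_000, seed=27)
        graph = simplify_graph(build_graph(tile(genome), [], config), config)
        paths = extend_paths(graph, config)
        assert close_gaps_with_long_reads(list(paths), graph, [], config) \
            == paths

    @pytest.mark.parametrize("error", [0.0, 0.01])
    def test_join_across_gap(self, config, error):
        rng = random.Random(41)
        genome = random_dna(12_000, seed=28)
        gap = (4_000, 9_000)
        reads = [genome[i:i + 150] for i in range(0, len(genome) - 150, 4)
                 if i + 150 <= gap[0] or i >= gap[1]]
        graph = simplify_graph(build_graph(reads, [], config), config)
        paths = extend_paths(graph, config)
        assert len(paths) == 2
        long_reads = []
        for j in range(5):
            start = 1_000 + 400 * j
            seq = genome[start:start + 10_000]
            if error:
                seq = list(seq)
                for _ in range(int(len(seq) * error)):
                    p = rng.randrange(len(seq))
                    seq[p] = rng.choice("ACGT")
                seq = "".join(seq)
            long_reads.append(_long_read(seq, f"L{j}"))
        joined = close_gaps_with_long_reads(paths, graph, long_reads, config)
        assert len(joined) == 1
        import edlib
        res = edlib.align(joined[0].sequence, genome, mode="HW")
        assert res["editDistance"] <= max(3, int(0.01 * len(genome)))
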