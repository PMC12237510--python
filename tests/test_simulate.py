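"""Synthetic diploid genomes, barcoded SLR reads, and long reads."""

import numpy as np
import pysam
import pytest

from lasv.io import read_vcf_calls
from lasv.simulate import (SimConfig, TruthSV, apply_svs,
                           simulate_genome_with_svs, simulate_long_reads,
                           simulate_slr_reads)


def _independent_apply(genome, truths):
    """String-surgery oracle for haplotype construction."""
    out = genome
    for t in sorted(truths, key=lambda t: t.pos, reverse=True):
        if t.svtype == "DEL":
            out = out[:t.pos + 1] + out[t.pos + 1 + t.svlen:]
        else:
            out = out[:t.pos + 1] + t.seq + out[t.pos + 1:]
    return out


class TestGenome:
    def test_no_svs_identity(self):
        sim = SimConfig(genome_length=30_000, n_svs=0, seed=1)
        ref, (h0, h1), truths = simulate_genome_with_svs(sim)
        assert h0 == h1 == ref.sequences[sim.chrom_name]
        assert truths == []

    def test_hom_deletion_shortens_both_haplotypes(self, tmp_path):
        sim = SimConfig(genome_length=50_000, n_svs=1, sv_lengths=[500],
                        sv_types=["DEL"], zygosity="hom", seed=2)
        vcf = str(tmp_path / "t.vcf")
        ref, (h0, h1), truths = simulate_genome_with_svs(sim, truth_vcf=vcf)
        g = ref.sequences[sim.chrom_name]
        assert len(h0) == len(h1) == len(g) - 500
        recs = read_vcf_calls(vcf)
        assert len(recs) == 1 and recs[0].svlen == 500
        with pysam.VariantFile(vcf) as v:
            assert next(iter(v)).info["SVLEN"] == -500

    def test_determinism(self):
        sims = [SimConfig(genome_length=40_000, n_svs=3, seed=7)
                for _ in range(2)]
        outs = [simulate_genome_with_svs(s) for s in sims]
        assert outs[0][1] == outs[1][1]
        assert [vars(t) for t in outs[0][2]] == [vars(t) for t in outs[1][2]]

    def test_truth_and_haplotypes_consistent(self):
        """Applying the truth records to the reference reproduces the
        haplotypes byte-exactly (independent oracle)."""
        sim = SimConfig(genome_length=80_000, n_svs=6, zygosity="mixed",
                        seed=11)
        ref, (h0, h1), truths = simulate_genome_with_svs(sim)
        g = ref.sequences[sim.chrom_name]
        assert h0 == _independent_apply(
            g, [t for t in truths if t.haplotype in ("both", "0")])
        assert h1 == _independent_apply(
            g, [t for t in truths if t.haplotype in ("both", "1")])

    def test_spacing_infeasible_raises(self):
        sim = SimConfig(genome_length=20_000, n_svs=50, sv_lengths=[5_000],
                        seed=3)
        with pytest.raises(ValueError, match="spacing"):
            simulate_genome_with_svs(sim)

    def test_apply_svs_matches_oracle_directly(self):
        genome = "ACGTACGTAA" * 100
        truths = [TruthSV("c", 100, "DEL", 50),
                  TruthSV("c", 400, "INS", 30, seq="G" * 30)]
        assert apply_svs(genome, truths) == _independent_apply(genome, truths)


@pytest.fixture(scope="module")
def slr_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("slr")
    sim = SimConfig(genome_length=200_000, n_svs=2, sv_lengths=[300, 1_000],
                    zygosity="het", slr_coverage=20, seed=5)
    ref, haps, truths = simulate_genome_with_svs(sim)
    bam = str(d / "slr.bam")
    stats = simulate_slr_reads(haps, sim, ref, truths, bam,
                               out_fastq=str(d / "slr.fastq"))
    return sim, ref, truths, bam, stats, str(d / "slr.fastq")


class TestSlrReads:
    def test_coverage_accounting(self, slr_dataset):
        sim, ref, _, _, stats, _ = slr_dataset
        target = sim.slr_coverage * sim.genome_length
        assert abs(stats["bases"] - target) <= 0.05 * target

    def test_fragment_lengths_and_barcode_consistency(self, slr_dataset):
        sim, _, _, bam, _, _ = slr_dataset
        lo, hi = sim.fragment_length_range
        by_bx = {}
        with pysam.AlignmentFile(bam) as fh:
            for aln in fh.fetch(until_eof=True):
                assert aln.has_tag("BX")
                if not aln.is_unmapped:
                    by_bx.setdefault(aln.get_tag("BX"), []).append(
                        aln.reference_start)
        # reads sharing a barcode derive from one fragment interval
        for positions in by_bx.values():
            assert max(positions) - min(positions) <= hi

    def test_coverage_reproducible_across_seeds(self, tmp_path):
        """Requested coverage is met within 5% for several seeds."""
        for seed in range(3):
            sim = SimConfig(genome_length=100_000, n_svs=0,
                            slr_coverage=30, seed=seed)
            ref, haps, truths = simulate_genome_with_svs(sim)
            stats = simulate_slr_reads(haps, sim, ref, truths,
                                       str(tmp_path / f"s{seed}.bam"))
            assert abs(stats["bases"] - 3e6) <= 0.05 * 3e6

    def test_bam_is_sorted_and_indexed(self, slr_dataset):
        _, _, _, bam, _, _ = slr_dataset
        with pysam.AlignmentFile(bam) as fh:
            assert fh.header["HD"]["SO"] == "coordinate"
            positions = [a.reference_start for a in fh.fetch("chrS")]
        assert positions == sorted(positions)

    def test_junction_reads_flagged(self, slr_dataset):
        """Reads across SV junctions are clipped or unmapped with AM/BX
        still present, so the badly-aligned filter can recruit them."""
        sim, _, truths, bam, stats, _ = slr_dataset
        clipped = unmapped = 0
        with pysam.AlignmentFile(bam) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    unmapped += 1
                elif any(op == 4 for op, _ in aln.cigartuples):
                    clipped += 1
                    assert aln.get_tag("AM") in (0, 1)
        assert clipped > 0  # junction-spanning reads exist
        ins = [t for t in truths if t.svtype == "INS"]
        if any(t.svlen > 300 for t in ins):
            assert unmapped > 0

    def test_fastq_written(self, slr_dataset):
        *_, fastq = slr_dataset
        lines = open(fastq).read().splitlines()
        assert len(lines) % 4 == 0 and lines[0].startswith("@")


class TestLongReads:
    def _make(self, tmp_path, **kw):
        sim = SimConfig(genome_length=60_000, n_svs=0,
                        long_read_coverage=3, seed=9, **kw)
        ref, haps, truths = simulate_genome_with_svs(sim)
        bam = str(tmp_path / "l.bam")
        stats = simulate_long_reads(haps, sim, ref, truths, bam)
        return sim, ref, bam, stats

    def test_lengths_in_range(self, tmp_path):
        sim, _, bam, _ = self._make(tmp_path)
        lo, hi = sim.long_read_length_range
        with pysam.AlignmentFile(bam) as fh:
            lengths = [len(a.query_sequence) for a in fh.fetch(until_eof=True)]
        assert lengths
        # small indel errors can shift length by a handful of bases
        assert all(lo - 20 <= l <= hi + 20 for l in lengths)

    def test_zero_error_reads_are_exact_substrings(self, tmp_path):
        sim, ref, bam, _ = self._make(
            tmp_path, long_read_error_range=(0.0, 0.0))
        g = ref.sequences[sim.chrom_name]
        with pysam.AlignmentFile(bam) as fh:
            for aln in fh.fetch(until_eof=True):
                assert aln.query_sequence in g

    def test_error_rates_produce_expected_identity(self, tmp_path):
        import edlib
        sim, ref, bam, _ = self._make(tmp_path)
        g = ref.sequences[sim.chrom_name]
        identities = []
        with pysam.AlignmentFile(bam) as fh:
            for aln in fh.fetch(until_eof=True):
                res = edlib.align(aln.query_sequence, g, mode="HW")
                identities.append(1 - res["editDistance"]
                                  / len(aln.query_sequence))
        mean = float(np.mean(identities))
        assert 0.990 <= mean <= 0.999
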