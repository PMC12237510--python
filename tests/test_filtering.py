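"""Badly-aligned pair predicate and the barcode-keyed read map."""

import random

import pytest

from lasv.filtering import (ReadMap, build_read_map, is_badly_aligned,
                            pair_up_records, query_read_map)
from lasv.model import Config, ReadPair

from conftest import make_pair, make_read, write_bam


class TestPredicate:
    """The filter keeps a pair iff it is high quality AND shows a placement
    problem (unmapped / unplaced contig / >20% soft-clip) or a zero AM."""

    def test_low_quality_fails_even_if_unmapped(self, config):
        pair = make_pair(r1_qual=15, r2_mapped=False, r2_mate_mapped=True)
        assert not is_badly_aligned(pair, config)

    def test_unmapped_mate_triggers(self, config):
        pair = make_pair(r2_mapped=False)
        d = is_badly_aligned(pair, config)
        assert d and d.reasons == ("b",)

    def test_softclip_over_20_percent_triggers(self, config):
        seq = "A" * 150
        pair = make_pair(r1_seq=seq, r1_cigar=[("S", 40), ("M", 110)],
                         r2_seq=seq)
        d = is_badly_aligned(pair, config)
        assert d and "b" in d.reasons

    def test_softclip_at_exactly_20_percent_does_not_trigger(self, config):
        seq = "A" * 150
        pair = make_pair(r1_seq=seq, r1_cigar=[("S", 30), ("M", 120)],
                         r2_seq=seq)
        assert not is_badly_aligned(pair, config)

    def test_zero_am_triggers(self, config):
        pair = make_pair(r1_am=0)
        d = is_badly_aligned(pair, config)
        assert d and d.reasons == ("c",)

    def test_clean_pair_with_absent_am_passes_through(self, config):
        assert not is_badly_aligned(make_pair(), config)

    def test_unplaced_contig_triggers(self, config):
        pair = make_pair(r1_unplaced=True)
        assert is_badly_aligned(pair, config)

    def test_quality_boundary_is_strict(self, config):
        # "higher than 20": all bases exactly 21 passes the gate, 20 fails
        assert is_badly_aligned(make_pair(qual=21, r2_mapped=False), config)
        assert not is_badly_aligned(make_pair(qual=20, r2_mapped=False),
                                    config)

    def test_orphan_treated_as_unmapped_mate(self, config):
        pair = ReadPair(make_read(name="solo"))
        assert is_badly_aligned(pair, config)


def _brute_force_filter(pairs, config):
    """Independent restatement of the rule used as an oracle."""
    kept = []
    for pair in pairs:
        reads = pair.reads()
        a = all(min(r.base_qualities) > config.min_base_phred for r in reads)
        def bad(r):
            if r is None or not r.is_mapped or r.is_on_unplaced_contig:
                return True
            clipped = sum(l for op, l in r.cigar if op == "S")
            return clipped / len(r.sequence) > config.max_softclip_fraction
        b = bad(pair.read1) or bad(pair.read2)
        c = any(r.am_value == 0 for r in reads)
        if a and (b or c):
            kept.append(pair)
    return kept


def _random_pair(rng):
    def rand_read(first):
        length = 150
        qual = rng.choice([rng.randint(10, 20), rng.randint(21, 40)])
        mapped = rng.random() > 0.15
        clip = rng.choice([0, 10, 20, 30, 31, 40, 60])
        cigar = ([("S", clip), ("M", length - clip)] if clip else
                 [("M", length)]) if mapped else []
        return make_read(name="p", seq="A" * length, qual=qual,
                         mapped=mapped, pos=rng.randint(0, 1000),
                         cigar=cigar, am=rng.choice([None, 0, 1]),
                         unplaced=rng.random() < 0.05, first=first)
    return ReadPair(rand_read(True), rand_read(False))


class TestPredicateProperties:
    def test_equivalence_with_brute_force_on_random_pairs(self, config):
        rng = random.Random(20240601)
        pairs = [_random_pair(rng) for _ in range(1_000)]
        expected = _brute_force_filter(pairs, config)
        got = [p for p in pairs if is_badly_aligned(p, config)]
        assert got == expected
        assert 0 < len(got) < len(pairs)

    def test_monotonic_in_thresholds(self):
        rng = random.Random(7)
        pairs = [_random_pair(rng) for _ in range(400)]

        def count(min_q, max_clip):
            cfg = Config(min_base_phred=min_q,
                         max_softclip_fraction=max_clip)
            return sum(bool(is_badly_aligned(p, cfg)) for p in pairs)

        base = count(20, 0.20)
        assert count(30, 0.20) <= base      # stricter quality gate
        assert count(20, 0.40) <= base      # laxer clip threshold shrinks R


class TestReadMap:
    def _bam(self, tmp_path):
        """5 pairs: 2 badly aligned with barcodes, 1 badly aligned without
        a barcode, 2 clean."""
        seq = "ACGT" * 25
        specs = []

        def pair(name, bx, bad=False, qual=30):
            specs.append({"name": name, "pos": 100, "bx": bx, "qual": qual,
                          "seq": seq,
                          "mate_unmapped": bad})
            if bad:
                specs.append({"name": name, "read2": True, "unmapped": True,
                              "pos": 100, "bx": bx, "qual": qual,
                              "seq": seq})
            else:
                specs.append({"name": name, "read2": True, "pos": 300,
                              "bx": bx, "qual": qual, "seq": seq,
                              "mate_pos": 100})

        pair("good1", "B1")
        pair("good2", "B2")
        pair("bad1", "B1", bad=True)
        pair("bad2", "B3", bad=True)
        pair("badnobx", None, bad=True)
        return write_bam(tmp_path / "m.bam", specs)

    def test_build_contents(self, tmp_path, config):
        rm = build_read_map(self._bam(tmp_path), config)
        assert rm.total_pairs == 2
        assert set(rm.pairs_by_barcode) == {"B1", "B3"}
        assert rm.dropped_no_barcode == 1

    def test_build_matches_domain_predicate(self, tmp_path, config):
        """Fast-path scan and the pure predicate agree on a real BAM."""
        from lasv.io import read_bam_records

        bam = self._bam(tmp_path)
        rm = build_read_map(bam, config)
        brute = [p for p in pair_up_records(read_bam_records(bam))
                 if is_badly_aligned(p, config) and p.barcode is not None]
        assert rm.total_pairs == len(brute)
        assert sorted(p.read1.name for b in rm.pairs_by_barcode.values()
                      for p in b) == sorted(p.read1.name for p in brute)

    def test_empty_bam(self, tmp_path, config):
        bam = write_bam(tmp_path / "e.bam", [])
        rm = build_read_map(bam, config)
        assert rm.total_pairs == 0

    def test_query_semantics(self):
        rm = ReadMap()
        pairs = [make_pair(name=f"p{i}", barcode="B1") for i in range(3)]
        for p in pairs:
            rm.add(p)
        rm.add(make_pair(name="x", barcode="B2"))
        assert query_read_map(rm, []) == []
        assert query_read_map(rm, ["B1"]) == pairs
        assert query_read_map(rm, ["B1", "B1"]) == pairs  # idempotent
        assert len(query_read_map(rm, ["B1", "B2", "Bmissing"])) == 4
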