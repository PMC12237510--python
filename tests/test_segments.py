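"""Reference tiling, barcode selection, and segment read gathering."""

import random

import pytest

from lasv.filtering import ReadMap
from lasv.model import Config, Reference
from lasv.segments import (Segment, gather_segment_reads, select_barcodes,
                           tile_reference)

from conftest import make_pair, write_bam


class TestTiling:
    @pytest.mark.parametrize("length,expected", [
        (100_000, [(0, 50_000), (40_000, 90_000), (80_000, 100_000)]),
        (30_000, [(0, 30_000)]),
        (50_000, [(0, 50_000)]),
    ])
    def test_window_arithmetic(self, config, length, expected):
        ref = Reference({"c": "A" * length})
        segs = tile_reference(ref, config)
        assert [(s.start, s.end) for s in segs] == expected

    def test_tiling_conservation_random_lengths(self, config):
        rng = random.Random(3)
        for _ in range(100):
            length = rng.randint(1_000, 400_000)
            ref = Reference({"c": "A" * length})
            segs = tile_reference(ref, config)
            # windows cover every base and consecutive windows overlap
            assert segs[0].start == 0 and segs[-1].end == length
            for a, b in zip(segs, segs[1:]):
                assert b.start == a.start + (config.segment_length
                                             - config.segment_overlap)
                assert b.start < a.end  # overlap present
            for s in segs[:-1]:
                assert s.end - s.start == config.segment_length

    def test_custom_window_parameters(self):
        cfg = Config(segment_length=10_000, segment_overlap=2_000)
        ref = Reference({"c": "A" * 25_000})
        segs = tile_reference(ref, cfg)
        assert [(s.start, s.end) for s in segs] == \
            [(0, 10_000), (8_000, 18_000), (16_000, 25_000)]


def _barcode_bam(tmp_path, groups, filename="b.bam"):
    """groups: barcode -> list of (pair_name, pos1, pos2)."""
    specs = []
    seq = "ACGT" * 25
    for bx, pairs in groups.items():
        for name, p1, p2 in pairs:
            specs.append({"name": name, "pos": p1, "bx": bx, "seq": seq,
                          "mate_pos": p2})
            specs.append({"name": name, "read2": True, "pos": p2, "bx": bx,
                          "seq": seq, "mate_pos": p1})
    return write_bam(tmp_path / filename, specs)


class TestSelectBarcodes:
    WINDOW = ("chr1", 0, 50_000)

    def test_three_pairs_wide_span_included(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {
            "OK": [("a", 1_000, 1_400), ("b", 4_000, 4_400),
                   ("c", 6_600, 7_000)],  # span 1,000 -> 7,100 = 6,100
        })
        assert select_barcodes(self.WINDOW, bam, config) == {"OK"}

    def test_two_pairs_excluded_despite_span(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {
            "FEW": [("a", 1_000, 1_300), ("b", 20_000, 21_000)],
        })
        assert select_barcodes(self.WINDOW, bam, config) == set()

    def test_narrow_span_excluded(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {
            "NARROW": [("a", 1_000, 1_200), ("b", 2_000, 2_300),
                       ("c", 4_000, 4_500), ("d", 4_600, 4_800),
                       ("e", 3_000, 3_100)],  # span 1,000 -> 4,900 < 5,000
        })
        assert select_barcodes(self.WINDOW, bam, config) == set()

    def test_span_exactly_5000_excluded_strict(self, tmp_path, config):
        # leftmost start 1,000; rightmost end 5,900 + 100 = 6,000
        bam = _barcode_bam(tmp_path, {
            "EDGE": [("a", 1_000, 1_200), ("b", 3_000, 3_200),
                     ("c", 5_700, 5_900)],
        })
        # reads are 100 bp: extent = 6,000 - 1,000 = 5,000, not > 5,000
        assert select_barcodes(self.WINDOW, bam, config) == set()
        # one base more and it is included
        bam2 = _barcode_bam(tmp_path, {
            "EDGE": [("a", 1_000, 1_200), ("b", 3_000, 3_200),
                     ("c", 5_700, 5_901)],
        }, filename="b2.bam")
        assert select_barcodes(self.WINDOW, bam2, config) == {"EDGE"}


class TestGather:
    def test_empty_barcode_set(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {"B": [("a", 100, 400)]})
        seg = Segment("chr1", 0, 50_000, "s0")
        gather_segment_reads(seg, bam, ReadMap(), None, config)
        assert seg.local_pairs == [] and seg.recruited_pairs == []

    def test_long_read_cap(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {"B": [("a", 100, 400),
                                            ("b", 2_000, 8_000),
                                            ("c", 9_000, 9_300)]})
        long_specs = [{"name": f"L{i}", "pos": 10 * i, "paired": False,
                       "seq": "ACGT" * 250} for i in range(150)]
        long_bam = write_bam(tmp_path / "l.bam", long_specs)
        seg = Segment("chr1", 0, 50_000, "s0", barcodes={"B"})
        gather_segment_reads(seg, bam, ReadMap(), long_bam, config)
        assert len(seg.long_reads) == config.max_long_reads_per_segment
        positions = [r.pos for r in seg.long_reads]
        assert positions == sorted(positions)  # first 100 in coord order

    def test_mate_fetched_for_half_in_window_pair(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {
            "B": [("edge", 49_800, 60_000),  # mate outside window
                  ("a", 100, 400), ("b", 20_000, 20_300)],
        })
        seg = Segment("chr1", 0, 50_000, "s0", barcodes={"B"})
        gather_segment_reads(seg, bam, ReadMap(), None, config)
        edge = [p for p in seg.local_pairs if p.read1.name == "edge"]
        assert len(edge) == 1
        assert edge[0].read2 is not None
        assert edge[0].read2.pos == 60_000

    def test_recruited_pairs_are_m_of_b(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {"B": [("a", 100, 400),
                                            ("b", 7_000, 7_300),
                                            ("c", 9_000, 9_200)]})
        rm = ReadMap()
        recruited = make_pair(name="rec", barcode="B", r2_mapped=False)
        other = make_pair(name="other", barcode="Z", r2_mapped=False)
        rm.add(recruited)
        rm.add(other)
        seg = Segment("chr1", 0, 50_000, "s0", barcodes={"B"})
        gather_segment_reads(seg, bam, rm, None, config)
        assert seg.recruited_pairs == [recruited]

    def test_gather_deterministic(self, tmp_path, config):
        bam = _barcode_bam(tmp_path, {
            "B": [(f"p{i}", 100 * i, 100 * i + 300) for i in range(30)]})
        segs = []
        for _ in range(2):
            seg = Segment("chr1", 0, 50_000, "s0", barcodes={"B"})
            gather_segment_reads(seg, bam, ReadMap(), None, config)
            segs.append([(p.read1.name, p.read1.pos) for p in seg.local_pairs])
        assert segs[0] == segs[1]
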