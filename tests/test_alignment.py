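"""Alignment parsing, six-way classification and gap filtering."""

import io
import itertools

import numpy as np
import pytest

from sharcexo.alignment import (
    ALIGNMENT_CLASSES,
    GappedAlignment,
    Segment,
    SpliceAnnotation,
    classify,
    filter_gaps,
    parse_sam,
    split_by_class,
    write_sam,
)
from conftest import ga

HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:10000\n"


def sam(*lines):
    return io.StringIO(HEADER + "".join(l + "\n" for l in lines))


class TestParseSam:
    def test_simple_match_converts_to_zero_based(self):
        alns = parse_sam(sam("r1\t0\tchr1\t101\t255\t20M\t*\t0\t0\t*\t*"))
        assert alns[0].segments == (Segment("chr1", 100, 120, "+"),)
        assert alns[0].alignment_class == "cont"

    def test_n_gap_splits_segments(self):
        alns = parse_sam(sam("r1\t0\tchr1\t101\t255\t20M50N20M\t*\t0\t0\t*\t*"))
        assert alns[0].segments == (
            Segment("chr1", 100, 120, "+"),
            Segment("chr1", 170, 190, "+"),
        )
        assert alns[0].alignment_class == "gap1"

    def test_short_deletion_absorbed_long_deletion_splits(self):
        absorbed = parse_sam(sam("r1\t0\tchr1\t101\t255\t10M2D10M\t*\t0\t0\t*\t*"))
        assert absorbed[0].segments == (Segment("chr1", 100, 122, "+"),)
        split = parse_sam(sam("r2\t0\tchr1\t101\t255\t10M3D10M\t*\t0\t0\t*\t*"))
        assert len(split[0].segments) == 2

    def test_chimeric_lines_merge_into_trans(self):
        alns = parse_sam(
            sam(
                "r1\t0\tchr1\t101\t255\t20M\t*\t0\t0\t*\t*",
                "r1\t2048\tchr2\t501\t255\t20M\t*\t0\t0\t*\t*",
            )
        )
        assert len(alns) == 1
        assert len(alns[0].segments) == 2
        assert alns[0].alignment_class == "trans"

    def test_soft_clips_do_not_consume_reference(self):
        alns = parse_sam(sam("r1\t0\tchr1\t101\t255\t5S20M5S\t*\t0\t0\t*\t*"))
        assert alns[0].segments == (Segment("chr1", 100, 120, "+"),)

    def test_reverse_strand_flag(self):
        alns = parse_sam(sam("r1\t16\tchr1\t101\t255\t20M\t*\t0\t0\t*\t*"))
        assert alns[0].segments[0].strand == "-"


def oracle_classify(aln):
    """Independent re-statement of the classification rule for cross-checking."""
    segs = list(aln.segments)
    if len(segs) == 1:
        return "cont"
    same_key = len({(s.ref_id, s.strand) for s in segs}) == 1
    overlapping_pairs = [
        (a, b)
        for a, b in itertools.combinations(segs, 2)
        if a.ref_id == b.ref_id
        and a.strand == b.strand
        and min(a.end, b.end) > max(a.start, b.start)
    ]
    if same_key and len(segs) == 2:
        return "homo" if overlapping_pairs else "gap1"
    if overlapping_pairs:
        return "bad"
    return "gapm" if same_key else "trans"


class TestClassify:
    @pytest.mark.parametrize(
        "segs,expected",
        [
            ([("chr1", 100, 120)], "cont"),
            ([("chr1", 100, 120), ("chr1", 170, 190)], "gap1"),
            ([("chr1", 100, 130), ("chr1", 120, 150)], "homo"),
            ([("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 40, 50)], "gapm"),
            ([("chr1", 100, 120), ("chr2", 100, 120)], "trans"),
            ([("chr1", 100, 120), ("chr1", 110, 130, "-")], "trans"),
            ([("chr1", 0, 10), ("chr1", 5, 15), ("chr1", 40, 50)], "bad"),
        ],
    )
    def test_examples(self, segs, expected):
        assert classify(ga("r", *segs)) == expected

    def test_matches_oracle_on_random_geometries(self, rng):
        for _ in range(1500):
            n = int(rng.integers(1, 4))
            segs = []
            for _ in range(n):
                ref = "chr1" if rng.random() < 0.75 else "chr2"
                strand = "+" if rng.random() < 0.75 else "-"
                start = int(rng.integers(0, 60))
                segs.append(Segment(ref, start, start + int(rng.integers(1, 25)), strand))
            aln = ga("r", *segs)
            assert classify(aln) == oracle_classify(aln)

    def test_classification_is_a_partition(self, sim_alns):
        counts = {c: len(v) for c, v in split_by_class(sim_alns).items()}
        assert set(counts) == set(ALIGNMENT_CLASSES)
        assert sum(counts.values()) == len(sim_alns)


class TestFilterGaps:
    def test_short_gap_dropped(self):
        aln = ga("r", ("chr1", 100, 120), ("chr1", 122, 140), cls="gap1")
        kept, dropped = filter_gaps([aln])
        assert kept == [] and dropped == [aln]

    def test_long_gap_kept(self):
        aln = ga("r", ("chr1", 100, 120), ("chr1", 170, 190), cls="gap1")
        kept, dropped = filter_gaps([aln])
        assert kept == [aln]

    def test_junction_gap_dropped_with_tolerance(self):
        splice = SpliceAnnotation({("chr1", 120, 170)})
        exact = ga("r1", ("chr1", 100, 120), ("chr1", 170, 190))
        near = ga("r2", ("chr1", 100, 122), ("chr1", 168, 190))
        far = ga("r3", ("chr1", 100, 125), ("chr1", 170, 190))
        kept, dropped = filter_gaps([exact, near, far], splice)
        assert [a.read_id for a in dropped] == ["r1", "r2"]
        assert [a.read_id for a in kept] == ["r3"]

    def test_one_good_gap_rescues_multigap_read(self):
        aln = ga("r", ("chr1", 0, 10), ("chr1", 12, 20), ("chr1", 80, 90), cls="gapm")
        kept, _ = filter_gaps([aln])
        assert kept == [aln]


class TestRoundTrip:
    def test_parse_write_parse_preserves_segments(self, sim_alns, tmp_path):
        path = tmp_path / "rt.sam"
        write_sam(sim_alns, path, {"toyRNA": 143})
        reparsed = parse_sam(str(path))
        assert {a.read_id: a.segments for a in reparsed} == {
            a.read_id: a.segments for a in sim_alns
        }

    def test_trans_alignment_round_trips(self, tmp_path):
        aln = ga("r1", ("chr1", 100, 120), ("chr2", 500, 530), cls="trans")
        path = tmp_path / "trans.sam"
        write_sam([aln], path, {"chr1": 10000, "chr2": 10000})
        (back,) = parse_sam(str(path))
        assert back.segments == aln.segments
        assert back.alignment_class == "trans"
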