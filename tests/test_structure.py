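"""Structure loading, flexible-nucleotide distances, null model and maps."""

import numpy as np
import pandas as pd
import pytest

from sharcexo.alignment import Segment
from sharcexo.structure import (
    BasePairAnnotation,
    DistanceRecord,
    StructureModel,
    categorize,
    contact_map,
    distance_summary,
    flexible_mask,
    min_arm_distance,
    minpos_heatmap,
    shuffle_reads,
    sqrt_scale,
    window_distance,
)
from sharcexo.simulate import make_toy_structure
from conftest import ga


def model_from_points(points, name="rna"):
    return StructureModel({name: {"O2'": np.asarray(points, float)}})


class TestLoadStructure:
    def test_pdb_round_trip_preserves_coordinates(self, toy, tmp_path):
        pdb = tmp_path / "toy.pdb"
        cmap = tmp_path / "chain_map.tsv"
        toy.to_pdb(pdb)
        toy.write_chain_map(cmap)
        model = StructureModel.from_pdb(pdb, cmap)
        assert model.length(toy.name) == toy.length
        np.testing.assert_allclose(
            model.atom_coords(toy.name), toy.coords["O2'"], atol=1e-3
        )

    def test_two_residue_synthetic_model(self, tmp_path):
        toy = make_toy_structure("helix", length=2)
        pdb = tmp_path / "tiny.pdb"
        toy.to_pdb(pdb)
        toy.write_chain_map(tmp_path / "m.tsv")
        model = StructureModel.from_pdb(pdb, tmp_path / "m.tsv")
        assert model.resolved(toy.name).sum() == 2

    def test_missing_chain_raises(self, toy, tmp_path):
        toy.to_pdb(tmp_path / "t.pdb")
        cmap = toy.chain_map()
        cmap["pdb_chain"] = "Z"
        with pytest.raises(ValueError, match="Z"):
            StructureModel.from_pdb(tmp_path / "t.pdb", cmap)

    def test_unmapped_residue_flagged_unresolved(self, toy, tmp_path):
        toy.to_pdb(tmp_path / "t.pdb")
        cmap = toy.chain_map()
        cmap = cmap[cmap["position"] != 5]  # drop one residue from the map
        model = StructureModel.from_pdb(tmp_path / "t.pdb", cmap)
        resolved = model.resolved(toy.name)
        assert not resolved[5] and resolved.sum() == toy.length - 1

    def test_helix_rise_between_stacked_residues(self):
        helix = make_toy_structure("helix", length=20)
        z = helix.coords["O2'"][:10, 2]
        np.testing.assert_allclose(np.diff(z), 2.81, atol=0.01)


def brute_min(read, coords, mask, window=None):
    """Plain-loop oracle for the flexible-pair minimum distance."""
    best = None
    for arm_l, arm_r in [(read.left_arm, read.right_arm)]:
        for ol in range(1, arm_l.length + 1):
            pl = arm_l.end - ol if arm_l.strand == "+" else arm_l.start + ol - 1
            if not (0 <= pl < len(mask) and mask[pl] and np.isfinite(coords[pl]).all()):
                continue
            if window and not (window[0] <= ol <= window[1]):
                continue
            for orr in range(1, arm_r.length + 1):
                pr = arm_r.end - orr if arm_r.strand == "+" else arm_r.start + orr - 1
                if not (0 <= pr < len(mask) and mask[pr] and np.isfinite(coords[pr]).all()):
                    continue
                if window and not (window[0] <= orr <= window[1]):
                    continue
                d = float(np.linalg.norm(coords[pl] - coords[pr]))
                key = (d, ol, orr)
                if best is None or key < best:
                    best = key
    return best


class TestArmDistances:
    def test_single_flexible_pair(self):
        coords = np.full((40, 3), np.nan)
        coords[5] = (0, 0, 0)
        coords[25] = (3, 0, 0)
        model = model_from_points(coords)
        mask = {"rna": np.ones(40, bool)}
        read = ga("r", ("rna", 0, 10), ("rna", 20, 30), cls="gap1")
        d, minpos = min_arm_distance(read, model, mask)
        assert d == pytest.approx(3.0)
        assert minpos == (5, 5)  # offsets from each arm's 3' end

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            L = 60
            coords = rng.normal(scale=15, size=(L, 3))
            coords[rng.random(L) < 0.15] = np.nan
            mask = rng.random(L) < 0.7
            s1 = int(rng.integers(0, 20))
            s2 = int(rng.integers(25, 45))
            read = ga(
                "r",
                ("rna", s1, s1 + int(rng.integers(3, 12))),
                ("rna", s2, s2 + int(rng.integers(3, 12))),
                cls="gap1",
            )
            model = model_from_points(coords)
            res = min_arm_distance(read, model, {"rna": mask})
            oracle = brute_min(read, coords, mask)
            if oracle is None:
                assert res is None
            else:
                d, minpos = res
                assert d == pytest.approx(oracle[0])
                assert minpos == (oracle[1], oracle[2])
            wres = window_distance(read, model, {"rna": mask}, window=(2, 5))
            woracle = brute_min(read, coords, mask, window=(2, 5))
            if woracle is None:
                assert wres is None
            else:
                assert wres == pytest.approx(woracle[0])

    def test_window_covering_arm_equals_dmin(self):
        coords = np.arange(120).reshape(40, 3).astype(float)
        model = model_from_points(coords)
        mask = {"rna": np.ones(40, bool)}
        read = ga("r", ("rna", 0, 8), ("rna", 20, 28), cls="gap1")
        d, _ = min_arm_distance(read, model, mask)
        assert window_distance(read, model, mask, window=(1, 8)) == pytest.approx(d)

    def test_no_flexible_nt_skips(self):
        model = model_from_points(np.zeros((40, 3)))
        read = ga("r", ("rna", 0, 8), ("rna", 20, 28), cls="gap1")
        assert min_arm_distance(read, model, {"rna": np.zeros(40, bool)}) is None

    def test_dmin_never_exceeds_dwindow(self, sim, sim_alns, toy_model, toy_mask):
        gap1 = [a for a in sim_alns if a.alignment_class == "gap1"][:300]
        for read in gap1:
            d, _ = min_arm_distance(read, toy_model, toy_mask)
            dw = window_distance(read, toy_model, toy_mask)
            if dw is not None:
                assert d <= dw + 1e-9

    def test_simulated_distances_match_crosslinker_reach(self, sim, sim_alns, toy_model, toy_mask):
        """Reach-7Å simulation: window-distance mode near the linker length,
        most minimum distances well under 20 Å."""
        gap1 = [a for a in sim_alns if a.alignment_class == "gap1"]
        dmins, dwins = [], []
        for read in gap1:
            res = min_arm_distance(read, toy_model, toy_mask)
            if res:
                dmins.append(res[0])
            dw = window_distance(read, toy_model, toy_mask)
            if dw is not None:
                dwins.append(dw)
        dmins, dwins = np.array(dmins), np.array(dwins)
        hist, edges = np.histogram(dwins, bins=np.arange(0, 60))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert 5 <= mode <= 11
        assert (dmins <= 20).mean() >= 0.5


class TestShuffle:
    def test_deterministic_and_length_preserving(self, sim_alns):
        reads = [a for a in sim_alns if a.alignment_class == "gap1"][:50]
        a = shuffle_reads(reads, {"toyRNA": 143}, seed=7)
        b = shuffle_reads(reads, {"toyRNA": 143}, seed=7)
        assert [r.segments for r in a] == [r.segments for r in b]
        orig = sorted(s.length for r in reads for s in r.segments)
        shuf = sorted(s.length for r in a for s in r.segments)
        assert orig == shuf

    def test_arms_sorted_by_position(self, sim_alns):
        reads = [a for a in sim_alns if a.alignment_class == "gap1"][:50]
        for r in shuffle_reads(reads, {"toyRNA": 143}, seed=3):
            assert r.segments[0].start <= r.segments[1].start


class TestCategorize:
    def helix_pairs(self):
        # 10-bp helix between [100,110) and [140,150)
        return BasePairAnnotation({(100 + k, 149 - k): "WC" for k in range(10)})

    def test_helix_arms_are_dsrna(self):
        read = ga("r", ("rna", 98, 112), ("rna", 138, 152), cls="gap1")
        assert categorize(read, self.helix_pairs()) == "dsRNA"

    def test_unpaired_core_arms(self):
        read = ga("r", ("rna", 0, 14), ("rna", 40, 54), cls="gap1")
        assert categorize(read, self.helix_pairs()) == "core_tertiary"

    def test_es_overlap_wins_over_core(self):
        read = ga("r", ("rna", 0, 14), ("rna", 40, 54), cls="gap1")
        regions = [("rna", 45, 60)]
        assert categorize(read, self.helix_pairs(), regions) == "es_tertiary"

    def test_min_bp_threshold(self):
        pairs = BasePairAnnotation({(105, 144): "WC"})  # a single bridging pair
        read = ga("r", ("rna", 98, 112), ("rna", 138, 152), cls="gap1")
        assert categorize(read, pairs, min_bp=2) == "core_tertiary"
        assert categorize(read, pairs, min_bp=1) == "dsRNA"

    def test_arm_order_invariant(self, rng):
        pairs = self.helix_pairs()
        regions = [("rna", 200, 260)]
        for _ in range(50):
            a = int(rng.integers(0, 150))
            b = int(rng.integers(160, 300))
            fwd = ga("r", ("rna", a, a + 12), ("rna", b, b + 12), cls="gap1")
            # same arms given in reversed order sort back identically
            rev = ga("r", ("rna", b, b + 12), ("rna", a, a + 12), cls="gap1")
            assert categorize(fwd, pairs, regions) == categorize(rev, pairs, regions)


class TestSummaries:
    def recs(self, ds, cat="core_tertiary"):
        return [DistanceRecord(f"r{k}", None, d, (5, 5), category=cat) for k, d in enumerate(ds)]

    def test_all_close_records(self):
        summary, cdf = distance_summary(self.recs([5.0] * 4))
        all_row = summary[summary.category == "all"].iloc[0]
        assert all_row["frac_le_20A"] == 1.0
        assert cdf["cum_frac"].iloc[-1] == 1.0

    def test_fractions_match_direct_count(self, rng):
        ds = rng.uniform(0, 80, 200)
        summary, _ = distance_summary(self.recs(list(ds)))
        all_row = summary[summary.category == "all"].iloc[0]
        assert all_row["frac_le_20A"] == pytest.approx((ds <= 20).mean())
        assert all_row["frac_le_40A"] == pytest.approx((ds <= 40).mean())

    def test_empty_category_is_nan(self):
        summary, _ = distance_summary(self.recs([5.0], cat="dsRNA"))
        es = summary[summary.category == "es_tertiary"].iloc[0]
        assert es["n"] == 0 and np.isnan(es["frac_le_20A"])


class TestMaps:
    def test_single_read_single_cell(self):
        read = ga("r", ("rna", 10, 20), ("rna", 210, 220), cls="gap1")
        raw, display = contact_map([read], ref_length=300, bin_size=25)
        assert raw.sum() == 1
        assert display[0, 8] == 1.0

    def test_sqrt_scaling(self):
        reads = [ga(f"r{k}", ("rna", 10, 20), ("rna", 210, 220), cls="gap1") for k in range(4)]
        raw, display = contact_map(reads, ref_length=300, bin_size=25)
        assert raw[0, 8] == 4 and display[0, 8] == 2.0

    def test_totals_equal_read_count(self, sim_alns):
        reads = [a for a in sim_alns if a.alignment_class == "gap1"]
        raw, _ = contact_map(reads, ref_length=143, bin_size=25)
        assert raw.sum() == len(reads)

    def test_reference_pairs_fill_lower_triangle(self):
        read = ga("r", ("rna", 10, 20), ("rna", 210, 220), cls="gap1")
        _, display = contact_map([read], 300, 25, reference_pairs=[(5, 290)])
        assert display[11, 0] == 1.0

    def test_minpos_heatmap_counts(self):
        recs = [DistanceRecord(f"r{k}", None, 5.0, (5, 5)) for k in range(9)]
        m = minpos_heatmap(recs)
        assert m[4, 4] == 9 and m.sum() == 9
        assert sqrt_scale(m)[4, 4] == 3.0

    def test_simulated_minpos_mode_at_five(self, sim, sim_alns, toy_model, toy_mask):
        gap1 = [a for a in sim_alns if a.alignment_class == "gap1"]
        recs = []
        for read in gap1:
            res = min_arm_distance(read, toy_model, toy_mask)
            if res:
                recs.append(DistanceRecord(read.read_id, None, res[0], res[1]))
        m = minpos_heatmap(recs)
        i, j = np.unravel_index(np.argmax(m), m.shape)
        assert abs((i + 1) - 5) <= 2 and abs((j + 1) - 5) <= 2


class TestFlexibleMask:
    def test_unpaired_or_reactive(self):
        pairs = BasePairAnnotation({(0, 9): "WC", (1, 8): "WC"})
        react = np.array([0.9, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.8, 0.0])
        mask = flexible_mask(10, pairs, react, reactivity_threshold=0.5)
        # paired-but-reactive positions 0 and 8 stay flexible
        assert mask[0] and mask[8]
        assert not mask[1] and not mask[9]
        assert mask[2:8].all()
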