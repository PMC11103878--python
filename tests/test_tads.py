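"""TAD separation scores, boundary matching, pan sets, events, hotspots."""

import numpy as np
import pandas as pd
import pytest

from chromadapt import tads as td
from chromadapt.core import Condition, InputError
from chromadapt.hic import ContactMatrix


def tad_matrix(boundaries_bins, n=150, bin_size=20_000, tau=2.0,
               depth=50.0):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = depth * (1.0 + d) ** -1.0
    tid = np.searchsorted(boundaries_bins, np.arange(n), side="right")
    m = base * np.where(np.equal.outer(tid, tid), tau, 1.0)
    return ContactMatrix(chrom="A01", bin_size=bin_size, matrix=m)


class TestSeparationScore:
    def test_planted_boundary_is_local_minimum(self):
        cm = tad_matrix([50, 100])
        track = td.separation_score(cm)
        s = track.score
        for b in (50, 100):
            assert s[b] < s[b - 1] and s[b] < s[b + 1]

    def test_uniform_matrix_gives_constant_track(self):
        m = np.full((80, 80), 7.0)
        cm = ContactMatrix(chrom="c", bin_size=20_000, matrix=m)
        s = td.separation_score(cm).score
        assert np.nanstd(s) == 0.0

    def test_scale_invariance_of_z_track(self):
        cm = tad_matrix([60])
        doubled = ContactMatrix(chrom="A01", bin_size=20_000,
                                matrix=2.0 * cm.matrix)
        np.testing.assert_allclose(td.separation_score(cm).score,
                                   td.separation_score(doubled).score,
                                   equal_nan=True)

    def test_oversized_window_rejected(self):
        cm = tad_matrix([10], n=20)
        with pytest.raises(InputError):
            td.separation_score(cm, window_sizes=(400_000,))

    def test_caller_recovers_planted_partition(self):
        cm = tad_matrix([50, 100])
        track = td.separation_score(cm)
        called = td.call_tads_from_score(track, cm.chrom_length)
        bounds = sorted({p for t in called for p in t})
        assert bounds == [0, 50 * 20_000, 100 * 20_000, 150 * 20_000]


class TestBoundaryMatching:
    @staticmethod
    def frame(positions, chrom="A01"):
        return td.boundary_frame([(chrom, p) for p in positions])

    def test_one_bp_overlap_is_conserved(self):
        # [960000, 1040000) vs [1039999, 1119999): overlap exactly 1 bp
        res = td.match_boundaries(self.frame([1_000_000]),
                                  self.frame([1_079_999]))
        assert res.n_matched == 1

    def test_adjacent_regions_do_not_match(self):
        # [960000, 1040000) vs [1040000, 1120000): zero overlap, half-open
        res = td.match_boundaries(self.frame([1_000_000]),
                                  self.frame([1_080_000]))
        assert res.n_matched == 0
        assert res.a_specific == [0] and res.b_specific == [0]

    def test_identical_sets_fully_matched(self):
        a = self.frame([100_000, 500_000, 900_000])
        res = td.match_boundaries(a, a.copy())
        assert res.n_matched == 3
        assert not res.a_specific and not res.b_specific

    def test_reciprocal_best_resolves_one_to_many(self):
        a = self.frame([1_000_000])
        b = self.frame([995_000, 1_050_000])  # both overlap; nearer wins
        res = td.match_boundaries(a, b)
        assert res.pairs == [(0, 0)]
        assert res.b_specific == [1]

    def test_matching_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = self.frame(np.sort(rng.integers(0, 5_000_000, 30)))
            b = self.frame(np.sort(rng.integers(0, 5_000_000, 25)))
            ab = td.match_boundaries(a, b)
            ba = td.match_boundaries(b, a)
            assert ab.n_matched == ba.n_matched
            assert {(i, j) for i, j in ab.pairs} == {
                (i, j) for j, i in ba.pairs}

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(InputError):
            td.match_boundaries(self.frame([1], chrom="Z99"),
                                self.frame([1], chrom="Z99"),
                                chrom_lengths={"A01": 10})


class TestPanBoundaries:
    @staticmethod
    def sets(values):
        return {s: td.boundary_frame([("A01", p) for p in ps])
                for s, ps in values.items()}

    def test_identical_sets_all_conserved4(self):
        base = [200_000, 700_000, 1_500_000]
        pan = td.build_pan_boundaries(self.sets(
            {s: base for s in ("ID", "MD", "SD", "RW")}))
        assert len(pan.entries) == 3
        assert (pan.entries["conservation"] == "conserved-4").all()

    def test_disjoint_sets_all_stage_specific(self):
        pan = td.build_pan_boundaries(self.sets({
            "ID": [100_000], "MD": [1_000_000],
            "SD": [2_000_000], "RW": [3_000_000],
        }))
        assert len(pan.entries) == 4
        assert (pan.entries["conservation"] == "stage-specific").all()

    def test_hand_traced_accretion(self):
        """A boundary present (overlapping) only in ID and SD is
        conserved-2; its representative comes from ID."""
        pan = td.build_pan_boundaries(self.sets({
            "ID": [500_000, 3_000_000],
            "MD": [3_000_000],
            "SD": [530_000, 3_000_000],  # 530k region overlaps 500k region
            "RW": [3_000_000],
        }))
        e = pan.entries.set_index("pos")
        assert len(pan.entries) == 2
        row = e.loc[500_000]
        assert row["origin_stage"] == "ID"
        assert row["conservation"] == "conserved-2"
        assert bool(row["present_ID"]) and bool(row["present_SD"])
        assert not bool(row["present_MD"]) and not bool(row["present_RW"])
        assert e.loc[3_000_000, "conservation"] == "conserved-4"

    def test_every_boundary_maps_to_exactly_one_entry(self):
        rng = np.random.default_rng(9)
        sets = {s: td.boundary_frame(
            [("A01", int(p)) for p in np.sort(
                rng.choice(np.arange(0, 6_000_000, 20_000), 40,
                           replace=False))])
            for s in ("ID", "MD", "SD", "RW")}
        pan = td.build_pan_boundaries(sets)
        sizes = [len(df) for df in sets.values()]
        assert max(sizes) <= len(pan.entries) <= sum(sizes)
        for s, idx in pan.assignments.items():
            assert (idx >= 0).all()  # every input boundary mapped
            assert (idx < len(pan.entries)).all()


class TestDroughtClassification:
    def test_identical_sets_fully_conserved(self):
        a = td.boundary_frame([("A01", p) for p in (1_000_000, 2_000_000)])
        res = td.classify_drought_boundaries(a, a.copy())
        assert res.conserved_fraction == 1.0
        assert res.dg.empty and res.dl.empty

    def test_lost_boundary_labeled_dl(self):
        ctrl = td.boundary_frame([("A01", 1_000_000), ("A01", 2_000_000)])
        drt = td.boundary_frame([("A01", 1_000_000)])
        res = td.classify_drought_boundaries(ctrl, drt)
        assert list(res.dl["pos"]) == [2_000_000]
        assert res.dg.empty

    def test_planted_losses_recovered_from_truth_sets(self, default_study):
        truth = default_study.contacts.truth
        cond_c = Condition("sensitive", "C", "MD")
        cond_d = Condition("sensitive", "D", "MD")
        cb = td.boundaries_of_tads(truth.tads[cond_c])
        db = td.boundaries_of_tads(truth.tads[cond_d])
        res = td.classify_drought_boundaries(cb, db)
        planted_lost = {
            (e.chrom, e.boundary_bp) for e in truth.events
            if e.condition == cond_d and e.type == "fusion"
        }
        # flanked matching can absorb a removed boundary into a close
        # neighbour, so dl must at least cover the planted removals
        dl = {(r.chrom, r.pos) for r in res.dl.itertuples(index=False)}
        assert dl == planted_lost


class TestEvents:
    def test_definitional_fusion_instance(self):
        control = {"A01": [(0, 200_000), (200_000, 400_000)]}
        drought = {"A01": [(0, 400_000)]}
        evs = td.detect_tad_events(control, drought)
        assert len(evs) == 1
        e = evs[0]
        assert e.type == "fusion"
        assert e.changed_boundaries == (200_000,)
        assert e.drought_tads == ((0, 400_000),)
        assert e.control_tads == ((0, 200_000), (200_000, 400_000))

    def test_swapped_inputs_give_the_dual_neo(self):
        control = {"A01": [(0, 200_000), (200_000, 400_000)]}
        drought = {"A01": [(0, 400_000)]}
        evs = td.detect_tad_events(drought, control)
        assert len(evs) == 1
        assert evs[0].type == "neo"
        assert evs[0].changed_boundaries == (200_000,)

    def test_identical_sets_no_events(self):
        t = {"A01": [(0, 200_000), (200_000, 400_000)]}
        assert td.detect_tad_events(t, t) == []

    def test_three_way_fusion(self):
        control = {"A01": [(0, 100_000), (100_000, 250_000),
                           (250_000, 400_000)]}
        drought = {"A01": [(0, 400_000)]}
        evs = td.detect_tad_events(control, drought)
        assert len(evs) == 1
        assert set(evs[0].changed_boundaries) == {100_000, 250_000}

    def test_overlapping_tads_rejected(self):
        bad = {"A01": [(0, 300_000), (200_000, 400_000)]}
        with pytest.raises(InputError):
            td.detect_tad_events(bad, {"A01": [(0, 400_000)]})

    def test_event_type_arity_enforced(self):
        with pytest.raises(InputError):
            td.TADEventCall(type="fusion", chrom="A01",
                            control_tads=((0, 10),),
                            drought_tads=((0, 10),),
                            changed_boundaries=())


class TestHotspots:
    LENGTHS = {"A01": 40_000_000}

    @staticmethod
    def frame(positions, chrom="A01"):
        return td.boundary_frame([(chrom, p) for p in positions])

    def test_nine_boundaries_make_a_hotspot(self):
        pos = np.linspace(1_000_000, 9_000_000, 9, dtype=int)
        hs = td.call_hotspots(self.frame(pos), "dl", self.LENGTHS)
        assert len(hs) == 1
        assert hs[0].count == 9
        assert (hs[0].start, hs[0].end) == (0, 10_000_000)

    def test_eight_boundaries_do_not(self):
        pos = np.linspace(1_000_000, 9_000_000, 8, dtype=int)
        assert td.call_hotspots(self.frame(pos), "dg", self.LENGTHS) == []

    def test_adjacent_qualifying_windows_merge(self):
        pos = np.concatenate([
            np.linspace(500_000, 9_500_000, 9, dtype=int),
            np.linspace(10_500_000, 19_500_000, 9, dtype=int),
        ])
        hs = td.call_hotspots(self.frame(pos), "dl", self.LENGTHS)
        assert len(hs) == 1
        assert (hs[0].start, hs[0].end) == (0, 20_000_000)
        assert hs[0].count == 18

    def test_soundness_every_hotspot_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.integers(0, 40_000_000, 60))
        hs = td.call_hotspots(self.frame(pos), "dg", self.LENGTHS)
        for h in hs:
            assert h.count > td.HOTSPOT_MIN_COUNT

    def test_shared_percentage_rounding(self):
        assert td.shared_percentage(1, 3) == 33.3

    def test_shared_hotspot_overlap_rule(self):
        a = [td.Hotspot("A01", 0, 10_000_000, "dg", 9)]
        b = [td.Hotspot("A01", 9_999_999, 20_000_000, "dg", 10),
             td.Hotspot("A01", 30_000_000, 40_000_000, "dg", 11)]
        assert len(td.shared_hotspots(a, b)) == 1


class TestGenesNearBoundaries:
    GENES = pd.DataFrame({
        "gene_id": ["in_right", "edge_out", "far"],
        "chrom": ["A01"] * 3,
        "start": [1_005_000, 1_020_000, 3_000_000],
        "end": [1_008_000, 1_025_000, 3_005_000],
    })

    def test_window_membership_half_open(self):
        b = td.boundary_frame([("A01", 1_000_000)])
        got = td.genes_near_boundaries(b, self.GENES, window=20_000)
        assert got == {"in_right"}  # [1020000, 1025000) misses [980000, 1020000)

    def test_empty_boundaries_empty_result(self):
        b = td.boundary_frame([])
        assert td.genes_near_boundaries(b, self.GENES) == set()

    def test_boundary_genes_expressed_higher(self, default_study):
        genes = default_study.genome.genes
        expr = np.log2(default_study.expression.fpkm.mean(axis=1) + 1)
        near = expr[genes.loc[genes["near_boundary"], "gene_id"]]
        far = expr[genes.loc[~genes["near_boundary"], "gene_id"]]
        assert near.mean() > far.mean()


class TestCrossSamplePan:
    @staticmethod
    def frame(positions, chrom="A01"):
        return td.boundary_frame([(chrom, p) for p in positions])

    def test_identical_sets_full_presence(self):
        base = [200_000, 900_000, 2_500_000]
        sets = [(f"s{i}", self.frame(base)) for i in range(16)]
        pan = td.build_cross_sample_pan(sets)
        assert len(pan) == 3
        assert (pan["n_samples"] == 16).all()

    def test_disjoint_set_contributes_singletons(self):
        sets = [("a", self.frame([200_000])), ("b", self.frame([210_000])),
                ("c", self.frame([5_000_000]))]
        pan = td.build_cross_sample_pan(sets)
        assert len(pan) == 2
        lone = pan[pan["pos"] == 5_000_000].iloc[0]
        assert lone["n_samples"] == 1 and lone["present_c"]

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        sets = [
            (f"s{i}", self.frame(np.sort(
                rng.choice(np.arange(0, 4_000_000, 20_000), 20,
                           replace=False))))
            for i in range(6)
        ]
        pan1 = td.build_cross_sample_pan(sets)
        shuffled = [sets[i] for i in rng.permutation(len(sets))]
        pan2 = td.build_cross_sample_pan(shuffled)
        cols = sorted(pan1.columns)
        pd.testing.assert_frame_equal(
            pan1[cols].sort_values(["chrom", "pos"], ignore_index=True),
            pan2[cols].sort_values(["chrom", "pos"], ignore_index=True),
        )

    def test_duplicate_sample_keys_rejected(self):
        with pytest.raises(InputError):
            td.build_cross_sample_pan([("a", self.frame([1])),
                                       ("a", self.frame([2]))])
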