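"""Edge filtering, hubs, module profiles, enrichment, target screen."""

import math

import numpy as np
import pandas as pd
import pytest

from chromadapt import network as net
from chromadapt.core import InputError


def edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


class TestFilterEdges:
    def test_strictly_greater_than_threshold(self):
        g = net.filter_edges(edges([("a", "b", 0.19), ("b", "c", 0.20),
                                    ("c", "d", 0.21)]))
        assert set(g.edges) == {("c", "d")}
        assert g.graph["n_nodes"] == 2 and g.graph["n_edges"] == 1

    def test_empty_edge_list(self):
        g = net.filter_edges(edges([]))
        assert g.number_of_nodes() == 0

    def test_threshold_zero_keeps_positive_weights(self):
        g = net.filter_edges(edges([("a", "b", 0.0), ("b", "c", 0.01)]),
                             threshold=0.0)
        assert set(g.edges) == {("b", "c")}

    def test_self_edge_rejected(self):
        with pytest.raises(InputError):
            net.filter_edges(edges([("a", "a", 0.5)]))

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(InputError):
            net.filter_edges(edges([("a", "b", 1.5)]))


class TestHubs:
    def test_star_center_is_hub(self):
        g = net.filter_edges(edges([("hub", x, 0.5)
                                    for x in ("a", "b", "c")]))
        modules = pd.Series("m1", index=["hub", "a", "b", "c"])
        assert net.find_hubs(g, modules) == {"m1": ["hub"]}

    def test_tie_breaks_lexicographically(self):
        g = net.filter_edges(edges([("a", "b", 0.5)]))
        modules = pd.Series("m1", index=["a", "b"])
        assert net.find_hubs(g, modules) == {"m1": ["a"]}
        # swap test: renaming does not change the rule
        g2 = net.filter_edges(edges([("b", "a", 0.5)]))
        assert net.find_hubs(g2, modules) == {"m1": ["a"]}

    def test_k_exceeding_module_size_warns_and_returns_all(self):
        g = net.filter_edges(edges([("a", "b", 0.5)]))
        modules = pd.Series("m1", index=["a", "b"])
        with pytest.warns(UserWarning):
            assert net.find_hubs(g, modules, k=5) == {"m1": ["a", "b"]}

    def test_unlabeled_node_rejected(self):
        g = net.filter_edges(edges([("a", "b", 0.5)]))
        with pytest.raises(InputError, match="b"):
            net.find_hubs(g, pd.Series({"a": "m1"}))

    def test_intra_module_weights_only(self):
        g = net.filter_edges(edges([
            ("a", "b", 0.9),   # intra m1
            ("b", "x", 0.95),  # inter-module: must not count for b
            ("a", "c", 0.3),
        ]))
        modules = pd.Series({"a": "m1", "b": "m1", "c": "m1", "x": "m2"})
        assert net.find_hubs(g, modules)["m1"] == ["a"]


class TestModuleProfile:
    def test_single_gene_profile_is_its_zscore(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [5.0]},
                            index=["g"])
        prof = net.module_expression_profile(["g"], expr)
        x = expr.loc["g"].to_numpy()
        np.testing.assert_allclose(prof.to_numpy(),
                                   (x - x.mean()) / x.std())

    def test_constant_gene_masked(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 4.0]},
                            index=["flat", "var"])
        prof = net.module_expression_profile(["flat", "var"], expr)
        x = expr.loc["var"].to_numpy()
        np.testing.assert_allclose(prof.to_numpy(),
                                   (x - x.mean()) / x.std())

    def test_no_overlap_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["g"])
        with pytest.raises(InputError):
            net.module_expression_profile(["other"], expr)

    def test_drought_module_profile_tracks_treatment(self, default_study):
        """Planted down-regulated genes: module profile sits lower under
        drought than control at MD and SD."""
        resp = default_study.expression.truth.response
        down = list(resp.index[(resp == -1).to_numpy()])[:50]
        prof = net.module_expression_profile(
            down, default_study.expression.fpkm)
        meta = default_study.expression.sample_meta.set_index("sample_id")
        for stage in ("MD", "SD"):
            d = prof[(meta["treatment"] == "D")
                     & (meta["stage"] == stage)].mean()
            c = prof[(meta["treatment"] == "C")
                     & (meta["stage"] == stage)].mean()
            assert d < c


class TestFisherEnrichment:
    def test_term_equal_to_set_has_minimal_p(self):
        universe = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(5)}
        res = net.fisher_enrichment(gene_set, universe, {
            "hit": set(gene_set),
            "half": {"g0", "g1", "g10", "g11"},
            "miss": {f"g{i}" for i in range(30, 40)},
        })
        assert res[0].term == "hit"
        assert res[0].p == min(r.p for r in res)

    def test_disjoint_term_has_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = net.fisher_enrichment({"g0", "g1"}, universe,
                                    {"t": {"g10", "g11"}})
        assert res[0].overlap == 0
        assert res[0].p == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_by_summation(self):
        # 2x2 (a=5, b=5, c=5, d=85): set 10, term 10, universe 100
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = net.fisher_enrichment(gene_set, universe, {"t": term})
        tail = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert res[0].p == pytest.approx(tail, rel=1e-10)
        assert res[0].overlap == 5

    def test_relabeling_invariance(self):
        universe = {f"g{i}" for i in range(40)}
        gene_set = {f"g{i}" for i in range(8)}
        term = {f"g{i}" for i in range(4, 16)}
        p1 = net.fisher_enrichment(gene_set, universe, {"t": term})[0].p
        ren = {g: f"x{g}" for g in universe}
        p2 = net.fisher_enrichment(
            {ren[g] for g in gene_set}, set(ren.values()),
            {"t": {ren[g] for g in term}},
        )[0].p
        assert p1 == pytest.approx(p2)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(InputError):
            net.fisher_enrichment({"alien"}, {"g0"}, {})


class TestTargetScreen:
    def test_three_set_intersection(self):
        report = net.screen_target_genes({"v1": {
            "induced": {"a", "b", "c"},
            "module": {"b", "c", "d"},
            "tad_change": {"c", "d", "e"},
        }})
        assert report.targets["v1"] == {"c"}

    def test_shared_and_specific_partition(self):
        report = net.screen_target_genes({
            "v1": {"induced": {"c", "f"}, "module": {"c", "f"},
                   "tad_change": {"c", "f"}},
            "v2": {"induced": {"c", "g"}, "module": {"c", "g"},
                   "tad_change": {"c", "g"}},
        })
        assert report.shared == {"c"}
        assert report.specific == {"v1": {"f"}, "v2": {"g"}}
        union = report.targets["v1"] | report.targets["v2"]
        assert (len(report.shared) + len(report.specific["v1"])
                + len(report.specific["v2"])) == len(union)

    def test_monotone_in_evidence(self):
        base = {"induced": {"a", "b"}, "module": {"b"}, "tad_change": {"b"}}
        small = net.screen_target_genes({"v": base}).targets["v"]
        grown = net.screen_target_genes({"v": {
            **base, "module": {"a", "b"},
        }}).targets["v"]
        assert small <= grown

    def test_empty_evidence_warns_not_raises(self):
        with pytest.warns(UserWarning):
            report = net.screen_target_genes({"v": {
                "induced": set(), "module": {"a"}, "tad_change": {"a"},
            }})
        assert report.targets["v"] == set()

    def test_missing_evidence_key_rejected(self):
        with pytest.raises(InputError):
            net.screen_target_genes({"v": {"induced": {"a"},
                                           "module": {"a"}}})

    def test_planted_targets_recovered_exactly(self):
        """Genes planted to satisfy all three criteria are exactly the
        screen's output."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        planted = set(rng.choice(genes, 10, replace=False))
        induced = planted | set(rng.choice(genes, 40))
        module = planted | (set(rng.choice(genes, 40)) - induced)
        tad = planted | (set(rng.choice(genes, 40)) - induced - module)
        report = net.screen_target_genes({"v": {
            "induced": induced, "module": module, "tad_change": tad,
        }})
        assert report.targets["v"] == planted
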