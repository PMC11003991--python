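"""Dynamic network assembly, core nodes, loop motifs, static expansion, joins."""

from __future__ import annotations

import numpy as np
import pytest

from imad import (CoreNodeSet, DynamicNetwork, OrthologMap, PPIGraph,
                  build_dynamic_network, connect_networks,
                  connection_frequency_scan, core_nodes, detect_loops,
                  static_expand)
from imad.dynnet import target_counts

from conftest import (HAND_DEG, HAND_EDGE_LIST, HAND_IMPACTFUL, HAND_STAGES,
                      make_deg_table)


class TestBuild:
    def test_hand_drawn_edge_list(self, hand_network):
        assert hand_network.edge_records() == HAND_EDGE_LIST

    def test_node_classes(self, hand_network):
        assert hand_network.node_class("A", "S1") == "both"  # DEG and impactful
        assert hand_network.node_class("B", "S2") == "both"
        assert hand_network.node_class("E", "S2") == "deg"
        assert hand_network.node_class("C", "S3") == "both"

    def test_all_deg_genes_present_even_without_edges(self, hand_network):
        assert hand_network.nodes_at("S3") == {"C", "E"}

    def test_no_impactful_gives_deg_only_network(self, hand_ppi, hand_tables):
        net = build_dynamic_network(hand_tables, {}, hand_ppi)
        assert net.n_edges == 0
        assert net.nodes_at("S2") == HAND_DEG["S2"]

    def test_allow_skip_adds_stage_skipping_edges(self, hand_ppi, hand_tables):
        net = build_dynamic_network(hand_tables, HAND_IMPACTFUL, hand_ppi,
                                    allow_skip=True)
        skips = {rec for rec in net.edge_records() if rec[4] == "skip"}
        assert skips == {("A", "S1", "C", "S3", "skip"),
                         ("D", "S1", "E", "S3", "skip"),
                         ("B", "S2", "A", "S4", "skip")}
        assert [r for r in net.edge_records() if r[4] == "consecutive"] == HAND_EDGE_LIST

    def test_unknown_stage_in_impactful_errors(self, hand_ppi, hand_tables):
        with pytest.raises(ValueError, match="unknown"):
            build_dynamic_network(hand_tables, {"BOGUS": {"A"}}, hand_ppi)

    def test_edge_contracts_validated(self, hand_network, hand_ppi):
        hand_network.validate(hand_ppi)  # no assertion error

    def test_target_counts_at_final_stage(self, hand_ppi, hand_tables):
        net = build_dynamic_network(hand_tables, HAND_IMPACTFUL, hand_ppi,
                                    allow_skip=True)
        counts = target_counts(net, "S2", "S4").set_index("gene")["targets"]
        assert counts.to_dict() == {"B": 1, "F": 0}  # B@S2 -> A@S4 only


class TestCoreNodes:
    def test_hand_network_core(self, hand_network):
        core = core_nodes(hand_network, "S1")
        # A reaches the S4 DEG via B@S2 -> C@S3 -> A@S4; D's paths dead-end
        assert core.genes == ("A",)

    def test_empty_network(self):
        net = DynamicNetwork(layers=["S1", "S2"])
        assert core_nodes(net, "S1").genes == ()

    def test_dead_end_gene_excluded(self, hand_network):
        assert "D" not in core_nodes(hand_network, "S1").genes


class TestLoops:
    def core(self, genes):
        return CoreNodeSet(stage="S1", genes=tuple(genes), provenance="manual")

    def test_hand_network_has_one_cycle_and_one_feedforward(self, hand_network):
        loops = detect_loops(hand_network, self.core("ABCDEF"))
        assert loops.feedback == (("A", "B", "C"),)
        assert loops.feedforward == (("D", "E", ("D", "F", "E")),)

    def test_acyclic_core_has_no_feedback(self, hand_network):
        loops = detect_loops(hand_network, self.core("DEF"))
        assert loops.feedback == ()
        assert loops.feedforward == (("D", "E", ("D", "F", "E")),)

    def test_three_gene_cycle_only(self, hand_network):
        loops = detect_loops(hand_network, self.core("ABC"))
        assert loops.feedback == (("A", "B", "C"),)
        assert loops.feedforward == ()

    def test_max_cycle_len_bounds_enumeration(self, hand_network):
        loops = detect_loops(hand_network, self.core("ABCDEF"), max_cycle_len=2)
        assert loops.feedback == ()

    def test_invariant_under_order_preserving_stage_relabel(self, hand_ppi, hand_tables):
        renamed = []
        mapping = dict(zip(HAND_STAGES, ["T1", "T2", "T3", "T4"]))
        for t in hand_tables:
            renamed.append(make_deg_table(mapping[t.stage], set(t.universe), t.deg_genes))
        imp = {mapping[s]: v for s, v in HAND_IMPACTFUL.items()}
        net2 = build_dynamic_network(renamed, imp, hand_ppi)
        loops2 = detect_loops(net2, self.core("ABCDEF"))
        net1_loops = detect_loops(
            build_dynamic_network(hand_tables, HAND_IMPACTFUL, hand_ppi),
            self.core("ABCDEF"))
        assert loops2 == net1_loops


class TestStaticExpand:
    def test_all_changed_degenerate_null(self, hand_ppi):
        with pytest.warns(UserWarning, match="degenerate"):
            out = static_expand(["A"], hand_ppi, hand_ppi.nodes, max_hops=2,
                                n_perm=100, rng_seed=0)
        assert np.allclose(out["observed_ratio"], 1.0)
        assert out["z"].isna().all()

    def test_default_hop_range_is_one_to_six(self, hand_ppi):
        out = static_expand(["A"], hand_ppi, {"B"}, n_perm=100, rng_seed=0)
        assert list(out["hop"]) == [1, 2, 3, 4, 5, 6]

    def test_frontier_sizes_monotone(self):
        from imad import generate_ppi_synthetic

        ppi = generate_ppi_synthetic(300, 2, rng_seed=4)
        changed = {g for i, g in enumerate(sorted(ppi.nodes)) if i % 5 == 0}
        out = static_expand(["G00000"], ppi, changed, max_hops=4, n_perm=100, rng_seed=0)
        sizes = out["frontier_size"].to_numpy()
        assert (np.diff(sizes) >= 0).all()

    def test_parameter_validation(self, hand_ppi):
        with pytest.raises(ValueError):
            static_expand(["A"], hand_ppi, {"B"}, max_hops=0, n_perm=100)
        with pytest.raises(ValueError):
            static_expand(["A"], hand_ppi, {"B"}, n_perm=10)


def b_dataset():
    """Second dataset for joins: 4-gene PPI sharing symbol A with the hand data."""
    ppi_b = PPIGraph.from_edges([("A", "P"), ("A", "Q"), ("P", "Q"), ("Q", "R")])
    m1 = make_deg_table("M1", {"A", "P", "Q", "R"}, {"P", "Q"})
    m2 = make_deg_table("M2", {"A", "P", "Q", "R"}, {"R"})
    return ppi_b, [(m1, {"Q"}), (m2, None)]


class TestConnect:
    def test_connect_mode_bridges_via_shared_symbols(self, hand_network):
        ppi_b, stages_b = b_dataset()
        combined, records = connect_networks(hand_network, stages_b, ppi_b,
                                             mode="connect", alpha=0.4)
        assert combined.layers == HAND_STAGES + ["M1", "M2"]
        bridge = [r for r in combined.edge_records() if r[1] == "S4"]
        # A@S4 is the only final-stage gene; its PPI-B neighbors P,Q are M1 DEGs
        assert bridge == [("A", "S4", "P", "M1", "consecutive"),
                          ("A", "S4", "Q", "M1", "consecutive")]
        # dataset-B internal edge from its impactful set survives
        assert ("Q", "M1", "R", "M2", "consecutive") in combined.edge_records()
        assert len(records) == 1 and records[0].gene == "A"

    def test_empty_idmap_intersection_preserves_both_networks(self, hand_network):
        ppi_b, stages_b = b_dataset()
        idmap = OrthologMap.from_pairs([("ZZZ", "YYY")])  # maps nothing relevant
        combined, records = connect_networks(hand_network, stages_b, ppi_b,
                                             mode="connect", idmap=idmap, alpha=0.4)
        assert records == []
        assert not [r for r in combined.edge_records() if r[1] == "S4"]
        for rec in hand_network.edge_records():
            assert rec in combined.edge_records()
        assert combined.nodes_at("M2") == {"R"}

    def test_insert_mode_splices_before_final_stage(self, hand_ppi, hand_network,
                                                    hand_tables):
        m1 = make_deg_table("M1", {"A", "B", "C"}, {"B"})
        combined, records = connect_networks(
            hand_network, [(m1, None)], hand_ppi, mode="insert",
            a_final_table=hand_tables[-1], alpha=0.6)
        assert combined.layers == ["S1", "S2", "S3", "M1", "S4"]
        bridge = sorted(r for r in combined.edge_records() if r[1] == "M1")
        assert bridge == [("B", "M1", "A", "S4", "consecutive"),
                          ("C", "M1", "A", "S4", "consecutive")]
        # pre-existing edge into the final stage is now stage-skipping
        assert ("C", "S3", "A", "S4", "skip") in combined.edge_records()
        combined.validate()

    def test_insert_mode_requires_final_table(self, hand_network, hand_ppi):
        m1 = make_deg_table("M1", {"A"}, set())
        with pytest.raises(ValueError, match="a_final_table"):
            connect_networks(hand_network, [(m1, None)], hand_ppi, mode="insert")

    def test_stage_name_collision_rejected(self, hand_network, hand_ppi):
        s2 = make_deg_table("S2", {"A"}, set())
        with pytest.raises(ValueError, match="collision"):
            connect_networks(hand_network, [(s2, None)], hand_ppi)


class TestConnectionFrequencyScan:
    def test_zero_shared_symbols(self, hand_network):
        ppi = PPIGraph.from_edges([("P", "Q")])
        t = make_deg_table("W5", {"P", "Q"}, {"P"})
        out = connection_frequency_scan(hand_network, [t], ppi)
        assert out.loc[0, "connected_nodes"] == 0

    def test_constructed_ordering(self, hand_network, hand_ppi):
        # final stage of the hand network holds only gene A (neighbors B, C, H)
        richer = make_deg_table("W28", set("ABCDEFGH"), {"B", "C"})
        poorer = make_deg_table("W05", set("ABCDEFGH"), {"G"})
        out = connection_frequency_scan(hand_network, [poorer, richer], hand_ppi)
        assert list(out["candidate_stage"]) == ["W28", "W05"]
        assert list(out["rank"]) == [1, 2]
        assert list(out["connected_nodes"]) == [1, 0]
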