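"""Impact statistic, Fisher test, BH correction and impactful-gene selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from imad import (PPIGraph, bh_adjust, fisher_two_sided, impact_scores,
                  relevant_genes, select_impactful)

from conftest import HAND_ADJACENCY, HAND_EDGES, MICRO_DEG, MICRO_UNIVERSE
from oracles import bh_stepup, fisher_enumeration


class TestRelevantGenes:
    def test_star_center(self):
        ppi = PPIGraph.from_edges([("HUB", f"L{i}") for i in range(5)])
        assert relevant_genes(ppi, "HUB") == {f"L{i}" for i in range(5)}
        assert relevant_genes(ppi, "L0") == {"HUB"}

    def test_absent_gene_empty(self):
        ppi = PPIGraph.from_edges([("A", "B")])
        assert relevant_genes(ppi, "ZZZ") == set()

    def test_hand_fixture_matches_adjacency(self):
        ppi = PPIGraph.from_edges(HAND_EDGES)
        for gene, nbrs in HAND_ADJACENCY.items():
            assert relevant_genes(ppi, gene) == nbrs


class TestFisher:
    def test_degenerate_margins(self):
        assert fisher_two_sided(0, 0, 0, 0) == 1.0

    def test_printed_example_matches_enumeration(self):
        assert fisher_two_sided(3, 1, 2, 14) == pytest.approx(
            fisher_enumeration(3, 1, 2, 14), abs=1e-9)

    def test_equal_proportions_give_one(self):
        assert fisher_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_two_sided(1, -1, 2, 3)

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_enumeration(a, b, c, d), abs=1e-9)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_definitional_oracle_exactly(self, pvals):
        assert np.array_equal(bh_adjust(pvals), bh_stepup(pvals))

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                           atol=1e-12)


class TestImpactScores:
    def test_micro_example(self, micro_ppi):
        records = impact_scores(micro_ppi, MICRO_UNIVERSE, MICRO_DEG, ["X"])
        (rec,) = records
        assert (rec.n_neighbors, rec.n_deg_neighbors) == (4, 3)
        assert rec.r == pytest.approx(0.75)
        assert (rec.background_deg, rec.background_total) == (5, 20)
        assert rec.fisher_p == pytest.approx(fisher_enumeration(3, 1, 2, 14), abs=1e-9)
        assert rec.q == pytest.approx(rec.fisher_p)  # single test: q = p

    def test_no_degs_means_nothing_impactful(self, micro_ppi):
        records = impact_scores(micro_ppi, MICRO_UNIVERSE, set(), ["X"])
        (rec,) = records
        assert rec.r == 0 and rec.fisher_p == pytest.approx(1.0)
        assert not rec.impactful

    def test_deg_outside_universe_rejected(self, micro_ppi):
        with pytest.raises(ValueError, match="subset"):
            impact_scores(micro_ppi, {"A"}, {"A", "ZZ"}, ["X"])

    def test_zero_neighbor_candidates_untested_and_excluded_from_m(self, micro_ppi):
        records = impact_scores(micro_ppi, MICRO_UNIVERSE, MICRO_DEG, ["X", "LONER"])
        by_gene = {r.gene: r for r in records}
        assert math.isnan(by_gene["LONER"].fisher_p)
        assert math.isnan(by_gene["LONER"].q)
        assert not by_gene["LONER"].impactful
        # X remains a single-hypothesis family: q equals its raw p
        assert by_gene["X"].q == pytest.approx(by_gene["X"].fisher_p)

    def test_candidate_order_and_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        genes = [f"N{i}" for i in range(30)]
        edges = [(genes[i], genes[j]) for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.15]
        ppi = PPIGraph.from_edges(edges)
        universe = set(genes)
        deg = {g for g in genes if rng.random() < 0.3}
        fwd = impact_scores(ppi, universe, deg, genes)
        rev = impact_scores(ppi, universe, deg, genes[::-1])
        import pandas.testing as pdt

        from imad.impact import records_to_frame
        pdt.assert_frame_equal(records_to_frame(fwd), records_to_frame(rev))
        # relabeling nodes permutes results consistently
        relabel = {g: f"Z{i}" for i, g in enumerate(genes)}
        ppi2 = PPIGraph.from_edges([(relabel[a], relabel[b]) for a, b in edges])
        out2 = impact_scores(ppi2, {relabel[g] for g in universe},
                             {relabel[g] for g in deg}, [relabel[g] for g in genes])
        back = {rec.gene: rec for rec in fwd}
        for rec in out2:
            orig = back[[g for g, z in relabel.items() if z == rec.gene][0]]
            assert rec.n_neighbors == orig.n_neighbors
            assert rec.fisher_p == pytest.approx(orig.fisher_p, nan_ok=True)

    def test_select_impactful_ordering_and_alpha(self):
        records = impact_scores(
            PPIGraph.from_edges([("X", "A"), ("X", "B"), ("Y", "A"), ("Y", "B")]),
            {"A", "B", "C", "D"}, {"A", "B"}, ["X", "Y"])
        # both candidates identical -> tie broken lexicographically
        sel = select_impactful(records, alpha=1.0)
        assert sel == ["X", "Y"]
        assert select_impactful(records, alpha=1e-6) == []


def test_permutation_null_controls_false_discoveries():
    """Shuffling DEG labels keeps the mean false-discovery proportion near alpha."""
    from imad import generate_ppi_synthetic

    ppi = generate_ppi_synthetic(200, 3, rng_seed=7)
    genes = sorted(ppi.nodes)
    rng = np.random.default_rng(7)
    alpha, fdps = 0.05, []
    for _ in range(25):
        deg = set(rng.choice(genes, size=30, replace=False))
        records = impact_scores(ppi, genes, deg, genes, alpha=alpha)
        hits = select_impactful(records, alpha)
        fdps.append(1.0 if hits else 0.0)  # every hit is false under the null
    se = math.sqrt(alpha * (1 - alpha) / len(fdps))
    assert np.mean(fdps) <= alpha + 3 * se
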