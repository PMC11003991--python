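"""Shared fixtures: hand-enumerable micro graphs and a small synthetic bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from imad import DEGTable, PPIGraph, build_dynamic_network

# 8-gene PPI used across modules; 10 edges, hand-countable degrees.
HAND_EDGES = [
    ("A", "B"), ("B", "C"), ("C", "A"),
    ("D", "E"), ("D", "F"), ("E", "F"),
    ("D", "G"), ("G", "E"),
    ("A", "H"), ("B", "H"),
]
HAND_ADJACENCY = {
    "A": {"B", "C", "H"}, "B": {"A", "C", "H"}, "C": {"A", "B"},
    "D": {"E", "F", "G"}, "E": {"D", "F", "G"}, "F": {"D", "E"},
    "G": {"D", "E"}, "H": {"A", "B"},
}

# Four-stage dynamic-network fixture on the same 8 genes.  Hand-drawn edges:
#   A@S1->B@S2, D@S1->E@S2, D@S1->F@S2, B@S2->C@S3, F@S2->E@S3, C@S3->A@S4
# Collapsed over cores {A..F}: A->B->C->A (one 3-cycle) and D->E, D->F,
# F->E (one feed-forward motif D->E via F).
HAND_STAGES = ["S1", "S2", "S3", "S4"]
HAND_DEG = {"S1": {"A", "D"}, "S2": {"B", "E", "F"}, "S3": {"C", "E"}, "S4": {"A"}}
HAND_IMPACTFUL = {"S1": {"A", "D"}, "S2": {"B", "F"}, "S3": {"C"}}
HAND_EDGE_LIST = sorted([
    ("A", "S1", "B", "S2", "consecutive"),
    ("D", "S1", "E", "S2", "consecutive"),
    ("D", "S1", "F", "S2", "consecutive"),
    ("B", "S2", "C", "S3", "consecutive"),
    ("F", "S2", "E", "S3", "consecutive"),
    ("C", "S3", "A", "S4", "consecutive"),
])


def make_deg_table(stage: str, universe, deg_genes) -> DEGTable:
    """DEG table whose |log2fc| > 0.5 flags reproduce the given gene set."""
    genes = sorted(universe)
    table = pd.DataFrame(
        {"log2fc": [1.0 if g in deg_genes else 0.1 for g in genes],
         "pvalue": np.nan, "padj": np.nan},
        index=pd.Index(genes, name="gene"))
    table["is_deg"] = table["log2fc"].abs() > 0.5
    return DEGTable(stage=stage, table=table, criterion="abs_log2fc>0.5")


@pytest.fixture
def hand_ppi() -> PPIGraph:
    return PPIGraph.from_edges(HAND_EDGES)


@pytest.fixture
def hand_tables() -> list[DEGTable]:
    universe = set(HAND_ADJACENCY)
    return [make_deg_table(s, universe, HAND_DEG[s]) for s in HAND_STAGES]


@pytest.fixture
def hand_network(hand_ppi, hand_tables):
    return build_dynamic_network(hand_tables, HAND_IMPACTFUL, hand_ppi)


# Micro impact example: 20-gene universe, 5 DEGs, candidate X with neighbors
# {A,B,C,D} of which 3 are DEG -> 2x2 table (3,1,2,14), r = 0.75.
MICRO_UNIVERSE = frozenset({"A", "B", "C", "D"} | {f"U{i:02d}" for i in range(5, 21)})
MICRO_DEG = frozenset({"A", "B", "C", "U05", "U06"})


@pytest.fixture
def micro_ppi() -> PPIGraph:
    return PPIGraph.from_edges([("X", n) for n in ("A", "B", "C", "D")])
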