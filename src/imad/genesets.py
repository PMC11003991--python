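"""Gene-set over-representation and keyword-defined sub-network annotation.

Over-representation analysis (ORA) tests a query gene list against named gene
sets (GMT) with a one-sided Fisher / hypergeometric tail and BH correction —
the enrichment-only direction used for pathway bar plots.  Term annotations
(gene → GO term) support keyword-filtered term sets, e.g. selecting
"cytokine" terms while excluding look-alikes such as "cytokinesis", and the
resulting gene sets can annotate dynamic-network edges: an edge is relevant
when its *target* gene belongs to the relevant set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dynnet import DynamicNetwork
from .impact import bh_adjust
from .io_formats import normalize_symbol, _data_rows

__all__ = [
    "GeneSetCollection",
    "TermAnnotation",
    "read_gmt",
    "read_term_annotation",
    "ora",
    "keyword_terms",
    "relevant_gene_set",
    "edge_relevance_fraction",
]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with normalized symbols."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {', '.join(sorted(empty))}")

    @property
    def names(self) -> list[str]:
        return sorted(self.sets)


@dataclass
class TermAnnotation:
    """Flat gene → term mapping plus term id → name lookup (no ancestor closure)."""

    gene_to_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def genes_for_terms(self, terms: Iterable[str]) -> frozenset[str]:
        wanted = set(terms)
        return frozenset(g for g, ts in self.gene_to_terms.items() if ts & wanted)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> member symbols."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT rows need ≥3 columns")
        name = fields[0].strip()
        if name in sets:
            raise ValueError(f"{path}: duplicate gene set {name!r}")
        sets[name] = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
    return GeneSetCollection(sets)


def read_term_annotation(path: str | Path) -> TermAnnotation:
    """Gene → term TSV (columns: gene, term id, optional term name)."""
    gene_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected ≥2 columns")
        gene, term = normalize_symbol(fields[0]), fields[1].strip()
        gene_to_terms.setdefault(gene, set()).add(term)
        if len(fields) >= 3 and fields[2].strip():
            name = fields[2].strip()
            if term_names.get(term, name) != name:
                raise ValueError(f"{path}: conflicting names for term {term}")
            term_names[term] = name
    return TermAnnotation({g: frozenset(ts) for g, ts in gene_to_terms.items()},
                          term_names)


def ora(query: Iterable[str], collection: GeneSetCollection,
        universe: Iterable[str]) -> pd.DataFrame:
    """One-sided (enrichment) over-representation of ``query`` in each gene set.

    Gene sets are restricted to the universe before testing.  Columns:
    set_name, overlap, set_size, ratio (overlap/set size), p (hypergeometric
    upper tail), q (BH over the tested sets).  Sets with no universe members
    are dropped.
    """
    uni = frozenset(normalize_symbol(g) for g in universe)
    qry = frozenset(normalize_symbol(g) for g in query)
    if not qry <= uni:
        extra = sorted(qry - uni)[:5]
        raise ValueError(f"query genes outside the universe (e.g. {extra})")
    rows = []
    for name in collection.names:
        s = collection.sets[name] & uni
        if not s:
            continue
        a = len(qry & s)
        # hypergeometric upper tail: P(X >= a) drawing |query| from universe
        p = float(stats.hypergeom.sf(a - 1, len(uni), len(s), len(qry)))
        rows.append({"set_name": name, "overlap": a, "set_size": len(s),
                     "ratio": a / len(s), "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "ratio", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def keyword_terms(ann: TermAnnotation, include: str,
                  exclude: Sequence[str] = ()) -> list[str]:
    """Term ids whose names contain ``include`` but no exclusion pattern.

    Matching is case-insensitive substring on term names; e.g. include
    "cytokine" with exclude ["cytokinesis"] keeps "cytokine production" and
    drops "cytokinesis".  Returns sorted term ids.
    """
    if not include:
        raise ValueError("empty include keyword")
    inc = include.lower()
    exc = [e.lower() for e in exclude]
    hits = [tid for tid, name in ann.term_names.items()
            if inc in name.lower() and not any(e in name.lower() for e in exc)]
    return sorted(hits)


def relevant_gene_set(ann: TermAnnotation, include: str,
                      exclude: Sequence[str] = ()) -> frozenset[str]:
    """Genes annotated to any keyword-selected term."""
    return ann.genes_for_terms(keyword_terms(ann, include, exclude))


def edge_relevance_fraction(net: DynamicNetwork, relevant_genes: Iterable[str],
                            origin: str) -> float:
    """Percentage of edges in the sub-network rooted at ``origin`` whose
    target gene is in ``relevant_genes``.

    The sub-network comprises every edge reachable from any (origin, stage)
    node by directed traversal.  Returns a value in [0, 100]; NaN (with a
    warning) when the sub-network has no edges.
    """
    origin_nodes = [(g, s) for g, s in net.graph.nodes if g == origin]
    if not origin_nodes:
        raise ValueError(f"{origin!r} is not a node of the network")
    reach: set = set(origin_nodes)
    for node in origin_nodes:
        reach |= nx.descendants(net.graph, node)
    edges = [(u, v) for u, v in net.graph.edges if u in reach]
    if not edges:
        warnings.warn(f"sub-network at {origin} has no edges; fraction undefined")
        return float("nan")
    rel = frozenset(relevant_genes)
    hit = sum(1 for _, (gene, _) in edges if gene in rel)
    return 100.0 * hit / len(edges)
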