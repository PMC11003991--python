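"""Readers, writers and validated containers for the external formats the pipeline touches.

Gene identifiers throughout the package are uppercased symbol strings.  The PPI
graph is an undirected symbol graph (STRING-style edge-list exports load
directly); expression inputs are plain TSV count matrices or DESeq2-style
results tables.  Dynamic networks are exported/imported as GraphML or TSV edge
lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("imad")

__all__ = [
    "normalize_symbol",
    "PPIGraph",
    "CountMatrix",
    "OrthologMap",
    "load_ppi",
    "load_counts",
    "load_ortholog_map",
    "export_network",
    "load_network_graphml",
    "load_config",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene identifier: stripped, uppercased symbol. Idempotent."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


@dataclass
class PPIGraph:
    """Undirected protein–protein interaction graph over gene symbols.

    Invariants: no self-loops, no duplicate edges, uppercase non-empty
    symbols, optional non-negative edge weights.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]) -> "PPIGraph":
        g = nx.Graph()
        for edge in edges:
            a, b = normalize_symbol(edge[0]), normalize_symbol(edge[1])
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if a == b:
                continue
            if w < 0:
                raise ValueError(f"negative edge weight on {a}-{b}: {w}")
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return gene in self.graph

    def neighbors(self, gene: str) -> set[str]:
        """One-hop neighborhood, excluding the gene itself; empty if absent."""
        if gene not in self.graph:
            return set()
        return set(self.graph[gene]) - {gene}

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()


@dataclass
class CountMatrix:
    """Genes × samples raw count matrix for one stage, with case/control labels."""

    counts: pd.DataFrame  # index = gene symbols, columns = sample ids
    groups: dict[str, str]  # sample id -> "case" | "control"
    stage: str

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {', '.join(dups)}")
        missing = [s for s in self.groups if s not in self.counts.columns]
        if missing:
            raise ValueError(f"samples in group map absent from matrix: {', '.join(missing)}")
        labels = set(self.groups.values())
        if not labels <= {"case", "control"}:
            raise ValueError(f"group labels must be case/control, got {sorted(labels)}")
        for lab in ("case", "control"):
            if lab not in labels:
                raise ValueError(f"no samples labeled {lab!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class OrthologMap:
    """Many-to-many symbol translation (e.g. human SYMBOL ↔ mouse Symbol).

    The default (empty) map is a case-insensitive identity: a normalized symbol
    maps to itself.  Lookups return sorted tuples, so iteration order is
    deterministic.
    """

    pairs: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        return cls(frozenset((normalize_symbol(a), normalize_symbol(b)) for a, b in pairs))

    def lookup(self, symbol: str) -> tuple[str, ...]:
        symbol = normalize_symbol(symbol)
        if not self.pairs:
            return (symbol,)
        hits = sorted(b for a, b in self.pairs if a == symbol)
        return tuple(hits)


def _data_rows(path: str | Path):
    """Yield (line_number, fields) for non-comment, non-blank TSV rows."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_ppi(path: str | Path, min_weight: float = 0.0) -> PPIGraph:
    """Load an undirected PPI edge list (two columns, optional score column).

    Self-loops are dropped, duplicate edges collapsed keeping the maximum
    weight, symbols uppercased, and edges with weight < ``min_weight``
    discarded.  A header row (non-numeric score column on the first row) is
    skipped automatically, so raw STRING exports load as-is.
    """
    edges: list[tuple[str, str, float]] = []
    first = True
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected ≥2 tab-separated columns")
        weight = 1.0
        if len(fields) >= 3 and fields[2].strip():
            try:
                weight = float(fields[2])
            except ValueError:
                if first:
                    first = False
                    continue  # header row
                raise ValueError(f"{path}: line {lineno}: non-numeric weight {fields[2]!r}")
        first = False
        if weight >= min_weight:
            edges.append((fields[0], fields[1], weight))
    ppi = PPIGraph.from_edges(edges)
    if ppi.n_edges == 0:
        raise ValueError(f"{path}: no edges remain after filtering (min_weight={min_weight})")
    logger.info("loaded PPI %s: %d nodes, %d edges", path, ppi.n_nodes, ppi.n_edges)
    return ppi


def load_counts(path: str | Path, groups: Mapping[str, str], stage: str) -> CountMatrix:
    """Load a genes × samples TSV count matrix and attach case/control labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = [normalize_symbol(g) for g in df.index]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from None
    cm = CountMatrix(counts=df, groups=dict(groups), stage=stage)
    logger.info("loaded counts %s: %d genes × %d samples", path, len(df), df.shape[1])
    return cm


def load_ortholog_map(path: str | Path) -> OrthologMap:
    pairs = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return OrthologMap.from_pairs(pairs)


# -- dynamic network export / import ---------------------------------------

_NODE_SEP = "||"


def export_network(net, path: str | Path, format: str = "graphml") -> None:
    """Write a DynamicNetwork as GraphML (round-trips) or a TSV edge list."""
    from .dynnet import DynamicNetwork  # local import avoids a cycle

    assert isinstance(net, DynamicNetwork)
    if format == "graphml":
        g = nx.DiGraph(layers="\t".join(net.layers))
        for (gene, stage), data in net.graph.nodes(data=True):
            g.add_node(f"{gene}{_NODE_SEP}{stage}", gene=gene, stage=stage,
                       node_class=data.get("node_class", "deg"))
        for (g1, s1), (g2, s2), data in net.graph.edges(data=True):
            g.add_edge(f"{g1}{_NODE_SEP}{s1}", f"{g2}{_NODE_SEP}{s2}",
                       edge_class=data.get("edge_class", "consecutive"))
        nx.write_graphml(g, str(path))
    elif format == "tsv":
        rows = ["source\tsource_stage\ttarget\ttarget_stage\tedge_class"]
        for (g1, s1), (g2, s2), data in sorted(net.graph.edges(data=True)):
            rows.append(f"{g1}\t{s1}\t{g2}\t{s2}\t{data.get('edge_class', 'consecutive')}")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown network export format {format!r} (use graphml or tsv)")


def load_network_graphml(path: str | Path):
    from .dynnet import DynamicNetwork

    g = nx.read_graphml(str(path))
    layers = g.graph.get("layers", "")
    net = DynamicNetwork(layers=layers.split("\t") if layers else [])
    for node, data in g.nodes(data=True):
        net.graph.add_node((data["gene"], data["stage"]),
                           node_class=data.get("node_class", "deg"))
    for u, v, data in g.edges(data=True):
        du, dv = g.nodes[u], g.nodes[v]
        net.graph.add_edge((du["gene"], du["stage"]), (dv["gene"], dv["stage"]),
                           edge_class=data.get("edge_class", "consecutive"))
    return net


def load_config(path: str | Path) -> dict:
    """Read a YAML (or flat ``key=value`` / ``key: value``) config file."""
    text = Path(path).read_text(encoding="utf-8")
    body = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if body and all("=" in ln and ":" not in ln.split("=")[0] for ln in body):
        cfg = {}
        for line in body:
            k, _, v = line.partition("=")
            cfg[k.strip()] = yaml.safe_load(v.strip())
        return cfg
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must map keys to values")
    return data
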