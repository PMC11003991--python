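"""Stage-layered dynamic networks, core nodes, loops and cross-dataset joins.

The dynamic network is a digraph over (gene, stage) nodes: each edge runs from
a gene called impactful at one stage to a PPI neighbor that is differentially
expressed at a strictly later stage.  Collapsing the layered edges among a
core gene set yields a gene-level digraph whose simple cycles are feedback
loops and whose (direct edge + indirect path) pairs are feed-forward motifs.

A "static" companion analysis expands an undirected neighborhood hop by hop
from a seed DEG set and scores the changed-gene fraction of each frontier
against a uniform random-node null (z-scores).

Two layouts join a second dataset's time series to an existing network:
*connect* appends the new stages after the final stage (bridging transition
scored from the final-stage genes into the new dataset), *insert* splices a
new stage in front of the final stage (bridging scored from the new stage's
genes onto the final-stage DEG set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .deg import DEGTable
from .impact import ImpactRecord, impact_scores, select_impactful
from .io_formats import OrthologMap, PPIGraph

logger = logging.getLogger("imad")

__all__ = [
    "DynamicNetwork",
    "CoreNodeSet",
    "LoopSet",
    "build_dynamic_network",
    "core_nodes",
    "detect_loops",
    "static_expand",
    "connect_networks",
    "connection_frequency_scan",
]


@dataclass
class DynamicNetwork:
    """Directed multi-stage network over (gene, stage) nodes.

    Node attribute ``node_class`` ∈ {impactful, deg, both}; edge attribute
    ``edge_class`` ∈ {consecutive, skip}.  Stage order strictly increases
    along every edge.
    """

    layers: list[str] = field(default_factory=list)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def stage_index(self, stage: str) -> int:
        return self.layers.index(stage)

    def nodes_at(self, stage: str) -> set[str]:
        return {g for g, s in self.graph.nodes if s == stage}

    def node_class(self, gene: str, stage: str) -> str:
        return self.graph.nodes[(gene, stage)]["node_class"]

    def _tag(self, gene: str, stage: str, cls: str) -> None:
        node = (gene, stage)
        if node in self.graph:
            old = self.graph.nodes[node]["node_class"]
            if old != cls:
                self.graph.nodes[node]["node_class"] = "both"
        else:
            self.graph.add_node(node, node_class=cls)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_records(self) -> list[tuple[str, str, str, str, str]]:
        return sorted((g1, s1, g2, s2, d.get("edge_class", "consecutive"))
                      for (g1, s1), (g2, s2), d in self.graph.edges(data=True))

    def validate(self, ppi: PPIGraph | None = None) -> None:
        """Assert every edge contract; raises AssertionError on violation."""
        order = {s: i for i, s in enumerate(self.layers)}
        for (g1, s1), (g2, s2), data in self.graph.edges(data=True):
            assert order[s1] < order[s2], f"edge {g1}@{s1}->{g2}@{s2} not stage-increasing"
            assert self.node_class(g1, s1) in ("impactful", "both"), \
                f"edge source {g1}@{s1} not impactful"
            assert self.node_class(g2, s2) in ("deg", "both"), \
                f"edge target {g2}@{s2} not DEG"
            expected = "consecutive" if order[s2] == order[s1] + 1 else "skip"
            assert data.get("edge_class") == expected
            if ppi is not None:
                assert ppi.graph.has_edge(g1, g2), f"edge {g1}->{g2} not PPI-backed"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DynamicNetwork):
            return NotImplemented
        mine = {(n, d["node_class"]) for n, d in self.graph.nodes(data=True)}
        theirs = {(n, d["node_class"]) for n, d in other.graph.nodes(data=True)}
        return (self.layers == other.layers and mine == theirs
                and self.edge_records() == other.edge_records())


@dataclass(frozen=True)
class CoreNodeSet:
    stage: str
    genes: tuple[str, ...]
    provenance: str


@dataclass(frozen=True)
class LoopSet:
    feedback: tuple[tuple[str, ...], ...]  # canonicalized simple cycles
    feedforward: tuple[tuple[str, str, tuple[str, ...]], ...]  # (src, tgt, indirect path)


def build_dynamic_network(stages: Sequence[DEGTable],
                          impactful_per_transition: Mapping[str, Iterable[str]],
                          ppi: PPIGraph, allow_skip: bool = False) -> DynamicNetwork:
    """Assemble the layered digraph from per-stage DEG tables and impactful sets.

    ``impactful_per_transition`` maps a source stage name to the genes called
    impactful there (scored against the following stage).  Edges run from each
    impactful gene to its PPI neighbors that are DEG at the next stage, and —
    with ``allow_skip`` — at every later stage as well.  All DEG genes appear
    as nodes even when untargeted.
    """
    if len(stages) < 2:
        raise ValueError("need ≥2 stages to build a dynamic network")
    names = [t.stage for t in stages]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate stage names: {names}")
    unknown = set(impactful_per_transition) - set(names[:-1])
    if unknown:
        raise ValueError(f"impactful sets reference unknown/final stages: {sorted(unknown)}")

    net = DynamicNetwork(layers=list(names))
    deg_sets = {t.stage: t.deg_genes for t in stages}
    for stage, degs in deg_sets.items():
        for g in sorted(degs):
            net._tag(g, stage, "deg")
    for i, stage in enumerate(names[:-1]):
        for gene in sorted(set(impactful_per_transition.get(stage, ()))):
            net._tag(gene, stage, "impactful")
            neighbors = ppi.neighbors(gene)
            targets = [(i + 1, "consecutive")]
            if allow_skip:
                targets += [(j, "skip") for j in range(i + 2, len(names))]
            for j, cls in targets:
                for nb in sorted(neighbors & deg_sets[names[j]]):
                    net.graph.add_edge((gene, stage), (nb, names[j]), edge_class=cls)
    net.validate(ppi)
    return net


def target_counts(net: DynamicNetwork, origin_stage: str, final_stage: str | None = None
                  ) -> pd.DataFrame:
    """Per impactful origin-stage gene, its number of final-stage DEG targets."""
    final_stage = final_stage or net.layers[-1]
    rows = []
    for gene in sorted(net.nodes_at(origin_stage)):
        if net.node_class(gene, origin_stage) not in ("impactful", "both"):
            continue
        n = sum(1 for (_, s) in net.graph.successors((gene, origin_stage)) if s == final_stage)
        rows.append({"gene": gene, "targets": n})
    return pd.DataFrame(rows, columns=["gene", "targets"])


def core_nodes(net: DynamicNetwork, origin_stage: str) -> CoreNodeSet:
    """Impactful origin-stage genes with ≥1 directed path to a final-stage DEG."""
    final = net.layers[-1] if net.layers else None
    genes = []
    for gene in sorted(net.nodes_at(origin_stage)):
        if net.node_class(gene, origin_stage) not in ("impactful", "both"):
            continue
        reach = nx.descendants(net.graph, (gene, origin_stage))
        if any(s == final and net.node_class(g, s) in ("deg", "both") for g, s in reach):
            genes.append(gene)
    return CoreNodeSet(stage=origin_stage, genes=tuple(genes),
                       provenance=f"impactful at {origin_stage} with a path to a "
                                  f"DEG at {final}")


def collapse_core(net: DynamicNetwork, core: CoreNodeSet) -> nx.DiGraph:
    """Gene-level digraph: A→B iff any layered edge runs from A to B at a later stage."""
    core_set = set(core.genes)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(core_set))
    for (g1, _), (g2, _) in net.graph.edges:
        if g1 in core_set and g2 in core_set and g1 != g2:
            g.add_edge(g1, g2)
    return g


def _canonical_cycle(cycle: Sequence[str]) -> tuple[str, ...]:
    i = cycle.index(min(cycle))
    return tuple(cycle[i:]) + tuple(cycle[:i])


def detect_loops(net: DynamicNetwork, core: CoreNodeSet, max_cycle_len: int = 5) -> LoopSet:
    """Feedback cycles and feed-forward motifs among core genes.

    The layered network is collapsed to a gene-level digraph.  Feedback loops
    are its simple cycles up to ``max_cycle_len``; a feed-forward motif is a
    pair (A, B) with a direct edge A→B plus an indirect path avoiding that
    edge (reported with one shortest such path).
    """
    collapsed = collapse_core(net, core)
    feedback = sorted(_canonical_cycle(c)
                      for c in nx.simple_cycles(collapsed, length_bound=max_cycle_len))
    feedforward = []
    for a, b in sorted(collapsed.edges):
        collapsed.remove_edge(a, b)
        try:
            path = nx.shortest_path(collapsed, a, b)
            feedforward.append((a, b, tuple(path)))
        except nx.NetworkXNoPath:
            pass
        finally:
            collapsed.add_edge(a, b)
    return LoopSet(feedback=tuple(feedback), feedforward=tuple(feedforward))


def static_expand(seed_genes: Iterable[str], ppi: PPIGraph, changed: Iterable[str],
                  max_hops: int = 6, n_perm: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """Hop-by-hop expansion z-scores of the changed-gene ratio around a seed set.

    For hop k = 1..max_hops the frontier is every gene within k edges of any
    seed; the observed changed fraction is compared with ``n_perm`` uniformly
    drawn node sets of the same size.  Columns: hop, frontier_size,
    observed_ratio, null_mean, null_sd, z (NaN when the null is degenerate).
    """
    if max_hops < 1:
        raise ValueError("max_hops must be ≥ 1")
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100")
    seeds = sorted(set(seed_genes) & ppi.nodes)
    changed_set = frozenset(changed)
    rng = np.random.default_rng(rng_seed)
    all_nodes = np.array(sorted(ppi.nodes))
    is_changed = np.isin(all_nodes, sorted(changed_set))

    dist = nx.multi_source_dijkstra_path_length(ppi.graph, seeds, cutoff=max_hops,
                                                weight=None) if seeds else {}
    rows = []
    for k in range(1, max_hops + 1):
        frontier = {g for g, d in dist.items() if d <= k}
        size = len(frontier)
        if size == 0:
            rows.append({"hop": k, "frontier_size": 0, "observed_ratio": np.nan,
                         "null_mean": np.nan, "null_sd": np.nan, "z": np.nan})
            continue
        obs = len(frontier & changed_set) / size
        draws = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(all_nodes.size, size=size, replace=False)
            draws[i] = is_changed[idx].mean()
        mu, sd = draws.mean(), draws.std(ddof=1)
        if sd == 0:
            warnings.warn(f"hop {k}: degenerate null (sd=0); z undefined")
            z = np.nan
        else:
            z = (obs - mu) / sd
        rows.append({"hop": k, "frontier_size": size, "observed_ratio": obs,
                     "null_mean": mu, "null_sd": sd, "z": z})
    return pd.DataFrame(rows)


def _map_genes(genes: Iterable[str], idmap: OrthologMap) -> dict[str, list[str]]:
    return {g: list(idmap.lookup(g)) for g in sorted(set(genes))}


def connect_networks(net_a: DynamicNetwork,
                     stages_b: Sequence[tuple[DEGTable, Iterable[str] | None]],
                     ppi_b: PPIGraph, mode: str = "connect",
                     idmap: OrthologMap | None = None, *,
                     ppi_a: PPIGraph | None = None,
                     a_final_table: DEGTable | None = None,
                     alpha: float = 0.05) -> tuple[DynamicNetwork, list[ImpactRecord]]:
    """Join a second dataset's stages onto an existing dynamic network.

    ``stages_b`` is an ordered list of (DEGTable, impactful gene set or None)
    for the second dataset.  In *connect* mode the new stages are appended
    after ``net_a``'s final stage and the bridging transition (final-stage
    genes → first new stage) is scored with the impact statistic on
    ``ppi_b``.  In *insert* mode the new stages are spliced in front of the
    final stage and the bridge (last new stage → final stage) is scored on
    ``ppi_a`` (default: ``ppi_b``) against ``a_final_table``'s universe.
    Symbol translation uses ``idmap`` (default: case-insensitive identity).
    All pre-existing nodes and edges of both inputs are preserved.

    Returns the combined network and the bridging impact records.
    """
    if mode not in ("connect", "insert"):
        raise ValueError(f"mode must be connect or insert, got {mode!r}")
    if not stages_b:
        raise ValueError("stages_b is empty")
    idmap = idmap or OrthologMap()
    b_names = [t.stage for t, _ in stages_b]
    clash = set(b_names) & set(net_a.layers)
    if clash:
        raise ValueError(f"stage name collision between datasets: {sorted(clash)}")

    a_final = net_a.layers[-1]
    if mode == "connect":
        layers = list(net_a.layers) + b_names
    else:
        if a_final_table is None:
            raise ValueError("insert mode needs a_final_table (final-stage DEG table)")
        layers = list(net_a.layers[:-1]) + b_names + [a_final]

    combined = DynamicNetwork(layers=layers)
    combined.graph = net_a.graph.copy()
    # dataset-B internal layers: DEG nodes plus any provided impactful edges
    b_tables = [t for t, _ in stages_b]
    b_impactful = {t.stage: set(imp) for t, imp in stages_b if imp is not None}
    for t in b_tables:
        for g in sorted(t.deg_genes):
            combined._tag(g, t.stage, "deg")
    for i, t in enumerate(b_tables[:-1]):
        nxt = b_tables[i + 1]
        for gene in sorted(b_impactful.get(t.stage, ())):
            combined._tag(gene, t.stage, "impactful")
            for nb in sorted(ppi_b.neighbors(gene) & nxt.deg_genes):
                combined.graph.add_edge((gene, t.stage), (nb, nxt.stage),
                                        edge_class="consecutive")

    # bridging transition
    if mode == "connect":
        b_first = b_tables[0]
        sources = sorted(net_a.nodes_at(a_final))
        mapped = _map_genes(sources, idmap)
        candidates = sorted({m for ms in mapped.values() for m in ms
                             if ppi_b.has_node(m)})
        records = impact_scores(ppi_b, b_first.universe, b_first.deg_genes, candidates,
                                stage_from=a_final, stage_to=b_first.stage, alpha=alpha)
        hits = set(select_impactful(records, alpha))
        for src in sources:
            if not any(m in hits for m in mapped[src]):
                continue
            combined._tag(src, a_final, "impactful")
            for m in mapped[src]:
                if m in hits:
                    for nb in sorted(ppi_b.neighbors(m) & b_first.deg_genes):
                        combined.graph.add_edge((src, a_final), (nb, b_first.stage),
                                                edge_class="consecutive")
    else:
        bridge_ppi = ppi_a or ppi_b
        b_last = b_tables[-1]
        mapped = _map_genes(b_last.universe, idmap)
        candidates = sorted({m for ms in mapped.values() for m in ms
                             if bridge_ppi.has_node(m)})
        records = impact_scores(bridge_ppi, a_final_table.universe,
                                a_final_table.deg_genes, candidates,
                                stage_from=b_last.stage, stage_to=a_final, alpha=alpha)
        hits = set(select_impactful(records, alpha))
        for src in sorted(mapped):
            src_hits = [m for m in mapped[src] if m in hits]
            if not src_hits:
                continue
            combined._tag(src, b_last.stage, "impactful")
            for m in src_hits:
                for nb in sorted(bridge_ppi.neighbors(m) & a_final_table.deg_genes):
                    combined.graph.add_edge((src, b_last.stage), (nb, a_final),
                                            edge_class="consecutive")

    # re-derive edge classes for layer distances that changed with the splice
    order = {s: i for i, s in enumerate(layers)}
    for u, v in combined.graph.edges:
        combined.graph.edges[u, v]["edge_class"] = (
            "consecutive" if order[v[1]] == order[u[1]] + 1 else "skip")
    combined.validate()
    logger.info("%s mode: %d bridging candidates, %d impactful", mode,
                len(records), len(select_impactful(records, alpha)))
    return combined, records


def connection_frequency_scan(net_a: DynamicNetwork,
                              candidate_stages: Sequence[DEGTable],
                              ppi: PPIGraph,
                              idmap: OrthologMap | None = None) -> pd.DataFrame:
    """Count, per candidate stage, the final-stage genes with ≥1 bridging edge.

    A final-stage gene of ``net_a`` connects to a candidate stage when any of
    its translated symbols has a PPI neighbor in that stage's DEG set.
    Ranked by count (descending) then stage name.
    """
    if not candidate_stages:
        raise ValueError("need ≥1 candidate stage")
    idmap = idmap or OrthologMap()
    final_genes = sorted(net_a.nodes_at(net_a.layers[-1]))
    rows = []
    for table in candidate_stages:
        deg = table.deg_genes
        n = sum(1 for g in final_genes
                if any(ppi.neighbors(m) & deg for m in idmap.lookup(g)))
        rows.append({"candidate_stage": table.stage, "connected_nodes": n})
    df = pd.DataFrame(rows).sort_values(
        ["connected_nodes", "candidate_stage"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
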