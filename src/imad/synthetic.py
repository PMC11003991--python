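"""Synthetic benchmarks with the statistical structure the impact analysis assumes.

The generator emulates a short differentiation time course measured as bulk
RNA-seq triplicates: a scale-free (preferential-attachment) PPI graph over
``n_genes`` symbols, a handful of planted "impactful" genes whose one-hop
neighbors are differentially expressed at the following stage with elevated
probability ``p_hi`` against a background rate ``p_bg``, and per-stage
negative-binomial count matrices in which labeled DEGs carry a
``effect_log2fc`` fold change between case and control.

All randomness flows from the single integer seed stored in
:class:`SyntheticTruth`; identical seeds give identical label sets, counts and
downstream selections.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import CountMatrix, PPIGraph

__all__ = [
    "SyntheticTruth",
    "generate_ppi_synthetic",
    "choose_planted",
    "plant_and_label",
    "labels_to_counts",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic experiment.

    ``planted_impactful`` maps each scored transition's source stage to the
    planted gene tuple.  ``p_hi`` is the DEG probability of planted genes'
    neighbors at the next stage, ``p_bg`` the background DEG probability.
    The planted fold change must exceed the 0.5 DEG threshold, otherwise the
    signal is undetectable by construction.
    """

    rng_seed: int
    planted_impactful: dict[str, tuple[str, ...]]
    p_hi: float = 0.6
    p_bg: float = 0.05
    effect_log2fc: float = 2.0
    n_genes: int = 2000
    n_replicates: int = 3
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.p_bg < self.p_hi <= 1):
            raise ValueError(f"need 0 ≤ p_bg < p_hi ≤ 1, got {self.p_bg}, {self.p_hi}")
        if self.effect_log2fc <= 0.5:
            raise ValueError("effect_log2fc must exceed the 0.5 DEG threshold")
        if self.n_replicates < 2:
            raise ValueError("need ≥2 replicates per group")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_impactful"] = {k: list(v) for k, v in d["planted_impactful"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["planted_impactful"] = {k: tuple(v) for k, v in d["planted_impactful"].items()}
        return cls(**d)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_ppi_synthetic(n_genes: int, attach_m: int, rng_seed: int) -> PPIGraph:
    """Scale-free PPI graph by preferential attachment (Barabási–Albert).

    Starts from ``attach_m`` unconnected nodes and attaches every further node
    with ``attach_m`` edges, giving exactly ``attach_m · (n_genes − attach_m)``
    edges and a connected graph.  Deterministic for a fixed seed.
    """
    if not n_genes > attach_m >= 1:
        raise ValueError(f"need n_genes > attach_m ≥ 1, got {n_genes}, {attach_m}")
    g = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(rng_seed))
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return PPIGraph(g)


def choose_planted(ppi: PPIGraph, stages: Sequence[str], n_planted: int,
                   min_degree: int, rng_seed: int, **truth_kwargs) -> SyntheticTruth:
    """Pick ``n_planted`` genes of degree ≥ ``min_degree`` as the impactful
    set at every scored transition and freeze them into a SyntheticTruth."""
    eligible = sorted(g for g in ppi.nodes if ppi.degree(g) >= min_degree)
    if len(eligible) < n_planted:
        raise ValueError(f"only {len(eligible)} genes have degree ≥ {min_degree}")
    rng = np.random.default_rng(rng_seed)
    planted = tuple(sorted(str(g) for g in rng.choice(eligible, size=n_planted, replace=False)))
    per_transition = {s: planted for s in stages[:-1]}
    return SyntheticTruth(rng_seed=int(rng_seed), planted_impactful=per_transition,
                          n_genes=ppi.n_nodes, **truth_kwargs)


def plant_and_label(ppi: PPIGraph, truth: SyntheticTruth,
                    stages: Sequence[str]) -> dict[str, frozenset[str]]:
    """Per-stage DEG label sets with planted neighborhood enrichment.

    The first stage is labeled at the background rate.  At every transition,
    neighbors of that transition's planted genes are DEG at the next stage
    with probability ``p_hi``; every other gene with ``p_bg``.  Draws follow
    a fixed gene-sorted order, so labels are fully seed-determined.
    """
    rng = np.random.default_rng(truth.rng_seed)
    genes = sorted(ppi.nodes)
    labels: dict[str, frozenset[str]] = {}
    draws = rng.random(len(genes))
    labels[stages[0]] = frozenset(g for g, u in zip(genes, draws) if u < truth.p_bg)
    for i, stage in enumerate(stages[:-1]):
        planted = truth.planted_impactful.get(stage, ())
        boosted: set[str] = set()
        for p in planted:
            if not ppi.has_node(p):
                raise ValueError(f"planted gene {p} absent from graph")
            boosted |= ppi.neighbors(p)
        draws = rng.random(len(genes))
        nxt = frozenset(
            g for g, u in zip(genes, draws)
            if u < (truth.p_hi if g in boosted else truth.p_bg))
        labels[stages[i + 1]] = nxt
    return labels


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
               size: tuple[int, int]) -> np.ndarray:
    """Gamma–Poisson negative binomial: var = mu + dispersion · mu²."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion, size=size)
    return rng.poisson(lam).astype(float)


def labels_to_counts(labels: Mapping[str, frozenset[str]], truth: SyntheticTruth,
                     genes: Sequence[str]) -> dict[str, CountMatrix]:
    """Per-stage case/control count matrices realizing the DEG labels.

    Baseline means are log-normal (median ≈ 100 counts) and shared across
    stages; at each stage, labeled DEGs have their case-group mean scaled by
    2^±effect_log2fc with a seed-determined random sign.  Counts are
    negative-binomial with the stated gene-level dispersion.
    """
    genes = sorted(genes)
    rng = np.random.default_rng(truth.rng_seed + 1)
    base = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=len(genes))
    fold = 2.0 ** truth.effect_log2fc
    out: dict[str, CountMatrix] = {}
    n_rep = truth.n_replicates
    for stage in labels:
        deg = labels[stage]
        sign = rng.random(len(genes)) < 0.5
        case_mean = np.array([
            m * (fold if up else 1.0 / fold) if g in deg else m
            for g, m, up in zip(genes, base, sign)])
        shape = (len(genes), n_rep)
        case = _nb_counts(rng, case_mean[:, None], truth.dispersion, shape)
        ctrl = _nb_counts(rng, base[:, None], truth.dispersion, shape)
        samples = [f"{stage}_case_{i+1}" for i in range(n_rep)] + \
                  [f"{stage}_ctrl_{i+1}" for i in range(n_rep)]
        df = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
        groups = {s: ("case" if "_case_" in s else "control") for s in samples}
        out[stage] = CountMatrix(counts=df, groups=groups, stage=stage)
    return out


def evaluate_recovery(selected: Sequence[str] | set[str], truth: SyntheticTruth,
                      stage_from: str) -> dict[str, float]:
    """Precision / recall / observed false-discovery proportion of a selection
    against the planted impactful set at ``stage_from``.

    Precision (and FDR) are NaN for an empty selection.
    """
    planted = set(truth.planted_impactful.get(stage_from, ()))
    sel = set(selected)
    tp = len(sel & planted)
    recall = tp / len(planted) if planted else math.nan
    precision = tp / len(sel) if sel else math.nan
    fdr = 1.0 - precision if sel else math.nan
    return {"precision": precision, "recall": recall, "fdr": fdr,
            "n_selected": float(len(sel)), "n_planted": float(len(planted))}
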