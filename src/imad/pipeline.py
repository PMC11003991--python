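"""End-to-end orchestration: config validation, staged run, manifest capture."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx
import numpy
import pandas
import scipy

import imad

from .deg import Criterion, DEGTable, ingest_deg_table
from .dynnet import (DynamicNetwork, build_dynamic_network, core_nodes,
                     detect_loops, target_counts)
from .impact import impact_scores, select_impactful, write_impact_tsv
from .io_formats import PPIGraph, export_network, load_config, load_ppi

logger = logging.getLogger("imad")

__all__ = ["RunConfig", "run_pipeline", "score_transitions"]


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    stages: list[str]
    deg_tables: dict[str, str]  # stage -> DESeq2-style TSV path
    ppi: str
    out_dir: str
    criterion: str = "abs_log2fc>0.5"
    alpha: float = 0.05
    min_weight: float = 0.0
    allow_skip: bool = False
    candidates: str = "all"  # "all" = every measured gene in the PPI; "deg" restricts
    max_cycle_len: int = 5
    n_perm: int = 1000
    rng_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = load_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if len(self.stages) < 2:
            raise ValueError("need ≥2 stages")
        if self.candidates not in ("all", "deg"):
            raise ValueError(f"candidates must be all|deg, got {self.candidates!r}")
        Criterion.parse(self.criterion)
        missing = [s for s in self.stages if s not in self.deg_tables]
        if missing:
            raise ValueError(f"no DEG table configured for stages: {missing}")
        for p in [self.ppi, *self.deg_tables.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def score_transitions(ppi: PPIGraph, universes: Mapping[str, frozenset[str]],
                      deg_sets: Mapping[str, frozenset[str]], stages: Sequence[str],
                      alpha: float = 0.05, candidates: str = "all") -> dict[str, list]:
    """Impact records for every consecutive stage transition.

    Candidates at each source stage are the genes measured there that appear
    in the PPI graph (``candidates="deg"`` restricts to that stage's DEGs).
    Returns {stage_from: [ImpactRecord, ...]}.
    """
    out = {}
    for i, stage in enumerate(stages[:-1]):
        nxt = stages[i + 1]
        pool = deg_sets[stage] if candidates == "deg" else universes[stage]
        cand = sorted(g for g in pool if ppi.has_node(g))
        out[stage] = impact_scores(ppi, universes[nxt], deg_sets[nxt], cand,
                                   stage_from=stage, stage_to=nxt, alpha=alpha)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run DEG ingestion → impact scoring → network → core nodes → loops.

    Writes per-stage DEG tables, per-transition impact TSVs, GraphML and TSV
    network exports, the core-node list, a loop report and a machine-readable
    manifest into ``config.out_dir``.  Returns a summary dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ppi = load_ppi(config.ppi, min_weight=config.min_weight)
    tables: list[DEGTable] = []
    for stage in config.stages:
        t = ingest_deg_table(config.deg_tables[stage], config.criterion, stage=stage)
        t.to_tsv(out / f"deg_{stage}.tsv")
        tables.append(t)

    universes = {t.stage: t.universe for t in tables}
    deg_sets = {t.stage: t.deg_genes for t in tables}
    records = score_transitions(ppi, universes, deg_sets, config.stages,
                                alpha=config.alpha, candidates=config.candidates)
    impactful = {}
    for stage, recs in records.items():
        write_impact_tsv(recs, out / f"impact_{stage}_to_next.tsv")
        impactful[stage] = select_impactful(recs, config.alpha)

    net = build_dynamic_network(tables, impactful, ppi, allow_skip=config.allow_skip)
    export_network(net, out / "network.graphml", "graphml")
    export_network(net, out / "network.tsv", "tsv")

    core = core_nodes(net, config.stages[0])
    (out / "core_nodes.tsv").write_text(
        "gene\n" + "".join(f"{g}\n" for g in core.genes), encoding="utf-8")
    target_counts(net, config.stages[0]).to_csv(out / "target_counts.tsv",
                                                sep="\t", index=False)
    loops = detect_loops(net, core, config.max_cycle_len)
    (out / "loops.json").write_text(json.dumps({
        "feedback": [list(c) for c in loops.feedback],
        "feedforward": [{"source": a, "target": b, "indirect_path": list(p)}
                        for a, b, p in loops.feedforward],
    }, indent=1, sort_keys=True), encoding="utf-8")

    summary = {
        "stages": config.stages,
        "n_deg_per_stage": {s: len(deg_sets[s]) for s in config.stages},
        "n_impactful_per_transition": {s: len(v) for s, v in impactful.items()},
        "n_network_edges": net.n_edges,
        "core_nodes": list(core.genes),
        "n_feedback_loops": len(loops.feedback),
        "n_feedforward_motifs": len(loops.feedforward),
    }
    manifest = {
        "parameters": dataclasses.asdict(config),
        "summary": summary,
        "versions": {"imad": imad.__version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "pandas": pandas.__version__,
                     "networkx": networkx.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                       encoding="utf-8")
    logger.info("pipeline complete: %s", summary)
    return summary
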