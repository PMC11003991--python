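"""Impactful-gene selection: neighborhood DEG enrichment at the next time point.

A candidate gene at stage *t* is scored by its one-hop PPI neighbors measured
at stage *t+1*: the impact ratio ``r`` is the fraction of those neighbors that
are differentially expressed at *t+1*, and a two-tailed Fisher's exact test
compares that fraction against the transcriptome-wide DEG fraction.  Genes
with Benjamini–Hochberg q < α (default 0.05) are called impactful.

The 2×2 table for a candidate with neighbor set N inside the stage-*t+1*
universe U and DEG set D is::

              DEG      not DEG
    neighbor   a = |N∩D|   b = |N\\D|
    other      c = |D\\N|   d = |U\\N\\D|

Candidates with no measured neighbors carry no evidence: they get missing
p/q, are never impactful, and are excluded from the multiple-testing family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PPIGraph

__all__ = [
    "ImpactRecord",
    "relevant_genes",
    "fisher_two_sided",
    "bh_adjust",
    "impact_scores",
    "select_impactful",
    "records_to_frame",
]


@dataclass(frozen=True)
class ImpactRecord:
    """Per-candidate impact statistics for one stage transition."""

    gene: str
    stage_from: str
    stage_to: str
    n_neighbors: int
    n_deg_neighbors: int
    r: float  # NaN when the candidate has no measured neighbors
    background_deg: int
    background_total: int
    fisher_p: float  # NaN when untested
    q: float  # NaN when untested
    impactful: bool


def relevant_genes(ppi: PPIGraph, gene: str) -> set[str]:
    """Genes connected to ``gene`` by a single PPI edge (the gene excluded)."""
    return ppi.neighbors(gene)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact test p for the 2×2 table [[a, b], [c, d]].

    Uses the point-probability rule: the p-value sums the probabilities of all
    tables with the observed margins whose probability does not exceed that of
    the observed table.  Degenerate margins give p = 1.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2×2 table: {cells}")
    if any(x != int(x) for x in cells):
        raise ValueError(f"non-integer cell in 2×2 table: {cells}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (clipped at 1), input order preserved.

    q(i) = min_{j : rank(j) ≥ rank(i)} m · p(j) / rank(j), with m the number
    of hypotheses.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def impact_scores(ppi: PPIGraph, universe_t2: Iterable[str], deg_t2: Iterable[str],
                  candidates: Iterable[str], *, stage_from: str = "t1",
                  stage_to: str = "t2", alpha: float = 0.05) -> list[ImpactRecord]:
    """Score every candidate's impact on the stage-``t2`` DEG set.

    ``universe_t2`` is the set of genes measured at the following stage (the
    testable background); ``deg_t2`` must be a subset of it.  Returns records
    sorted by gene symbol, with BH q computed over the tested candidates and
    ``impactful`` set where q < ``alpha``.
    """
    universe = frozenset(universe_t2)
    deg = frozenset(deg_t2)
    if not deg <= universe:
        extra = sorted(deg - universe)[:5]
        raise ValueError(f"DEG set not a subset of the stage universe (e.g. {extra})")
    records: list[ImpactRecord] = []
    for gene in sorted(set(candidates)):
        neighbors = relevant_genes(ppi, gene) & universe
        a = len(neighbors & deg)
        b = len(neighbors) - a
        c = len(deg) - a
        d = len(universe) - len(neighbors) - c
        if a + b == 0:
            rec = ImpactRecord(gene, stage_from, stage_to, 0, 0, math.nan,
                               len(deg), len(universe), math.nan, math.nan, False)
        else:
            rec = ImpactRecord(gene, stage_from, stage_to, a + b, a, a / (a + b),
                               len(deg), len(universe),
                               fisher_two_sided(a, b, c, d), math.nan, False)
        records.append(rec)
    tested = [i for i, rec in enumerate(records) if not math.isnan(rec.fisher_p)]
    if tested:
        qvals = bh_adjust([records[i].fisher_p for i in tested])
        for i, q in zip(tested, qvals):
            records[i] = replace(records[i], q=float(q), impactful=bool(q < alpha))
    return records


def select_impactful(records: Sequence[ImpactRecord], alpha: float = 0.05) -> list[str]:
    """Impactful genes (q < alpha), ordered by q then symbol."""
    hits = [r for r in records if not math.isnan(r.q) and r.q < alpha]
    return [r.gene for r in sorted(hits, key=lambda r: (r.q, r.gene))]


def records_to_frame(records: Sequence[ImpactRecord]) -> pd.DataFrame:
    cols = ["gene", "stage_from", "stage_to", "n_neighbors", "n_deg_neighbors",
            "r", "fisher_p", "q", "impactful"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_impact_tsv(records: Sequence[ImpactRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    for col in ("r", "fisher_p", "q"):
        df[col] = df[col].map(lambda v: "" if math.isnan(v) else f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)
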