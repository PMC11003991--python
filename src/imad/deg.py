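"""Differential-expression tables and DEG criteria.

Two routes produce a :class:`DEGTable` for a stage: ingesting a DESeq2-style
results TSV (the intended path for real data), or the built-in fallback caller
— a documented stand-in, not DESeq2 — which normalizes raw counts to CPM,
computes log2 fold changes with a pseudocount, and tests with Welch's t-test.

DEG criteria are strict ``|log2FC| > θ`` (default θ = 0.5) for the fold-change
mode, ``Welch p ≤ α`` (default α = 0.05) for the p-value mode used in
cross-dataset meta-analysis, and a combined fold-change + adjusted-p mode.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, normalize_symbol

logger = logging.getLogger("imad")

__all__ = ["Criterion", "DEGTable", "ingest_deg_table", "call_degs_fallback"]


@dataclass(frozen=True)
class Criterion:
    """A DEG selection rule, parseable from a compact descriptor string.

    Descriptors::

        abs_log2fc>0.5            |log2FC| strictly greater than 0.5
        welch_p<=0.05             Welch p-value at most 0.05
        abs_log2fc>0.5 AND padj<0.05
    """

    kind: str  # "abs_log2fc" | "welch_p" | "combined"
    log2fc_threshold: float | None = None
    p_threshold: float | None = None

    _PATTERNS = {
        "abs_log2fc": re.compile(r"^abs_log2fc>([\d.eE+-]+)$"),
        "welch_p": re.compile(r"^welch_p<=([\d.eE+-]+)$"),
        "combined": re.compile(r"^abs_log2fc>([\d.eE+-]+) AND padj<([\d.eE+-]+)$"),
    }

    @classmethod
    def parse(cls, descriptor: str) -> "Criterion":
        descriptor = descriptor.strip()
        for kind, pat in cls._PATTERNS.items():
            m = pat.match(descriptor)
            if m:
                if kind == "abs_log2fc":
                    return cls(kind, log2fc_threshold=float(m.group(1)))
                if kind == "welch_p":
                    return cls(kind, p_threshold=float(m.group(1)))
                return cls(kind, log2fc_threshold=float(m.group(1)),
                           p_threshold=float(m.group(2)))
        raise ValueError(f"unparseable DEG criterion {descriptor!r}")

    def describe(self) -> str:
        if self.kind == "abs_log2fc":
            return f"abs_log2fc>{self.log2fc_threshold:g}"
        if self.kind == "welch_p":
            return f"welch_p<={self.p_threshold:g}"
        return f"abs_log2fc>{self.log2fc_threshold:g} AND padj<{self.p_threshold:g}"

    def apply(self, table: pd.DataFrame) -> pd.Series:
        """Boolean DEG flags; raises if a needed column is absent or all-missing."""
        if self.kind in ("abs_log2fc", "combined"):
            flags = table["log2fc"].abs() > self.log2fc_threshold  # strict >
        if self.kind == "welch_p":
            if "pvalue" not in table or table["pvalue"].isna().all():
                raise ValueError("criterion welch_p needs a pvalue column")
            flags = table["pvalue"] <= self.p_threshold
        if self.kind == "combined":
            if "padj" not in table or table["padj"].isna().all():
                raise ValueError("combined criterion needs a padj column")
            flags = flags & (table["padj"] < self.p_threshold)
        return flags.fillna(False).astype(bool)


DEFAULT_CRITERION = Criterion.parse("abs_log2fc>0.5")


@dataclass
class DEGTable:
    """Per-gene differential-expression statistics for one stage.

    ``table`` is indexed by gene symbol with columns ``log2fc``, ``pvalue``,
    ``padj`` and ``is_deg``; the flag is always recomputable from the stored
    statistics and ``criterion``.
    """

    stage: str
    table: pd.DataFrame
    criterion: str

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols in DEG table: {', '.join(dups)}")
        both = self.table[["pvalue", "padj"]].dropna()
        if ((both["padj"] - both["pvalue"]) < -1e-12).any():
            raise ValueError("padj < pvalue in DEG table")

    @property
    def universe(self) -> frozenset[str]:
        """Genes measured at this stage."""
        return frozenset(self.table.index)

    @property
    def deg_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_deg"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        for col in ("log2fc", "pvalue", "padj"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
        out.to_csv(path, sep="\t")


_COLUMN_ALIASES = {"log2foldchange": "log2fc", "log2fc": "log2fc",
                   "pvalue": "pvalue", "p.value": "pvalue",
                   "padj": "padj", "qvalue": "padj", "is_deg": "is_deg"}


def ingest_deg_table(path: str | Path, criterion: str | Criterion = DEFAULT_CRITERION,
                     stage: str | None = None) -> DEGTable:
    """Read a DESeq2-style results TSV (gene, log2FoldChange, pvalue, padj).

    Extra columns are ignored; genes with missing log2FC are excluded (count
    logged).  DEG flags are recomputed from ``criterion`` regardless of any
    flag column in the file.
    """
    crit = criterion if isinstance(criterion, Criterion) else Criterion.parse(criterion)
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c: _COLUMN_ALIASES[c.lower()] for c in df.columns if c.lower() in _COLUMN_ALIASES}
    gene_col = df.columns[0]
    df = df.rename(columns=cols)
    if "log2fc" not in df.columns:
        raise ValueError(f"{path}: no log2FoldChange column")
    df[gene_col] = df[gene_col].map(normalize_symbol)
    n_missing = int(df["log2fc"].isna().sum())
    if n_missing:
        logger.info("%s: excluding %d genes with missing log2FC", path, n_missing)
        df = df[df["log2fc"].notna()]
    table = pd.DataFrame(index=pd.Index(df[gene_col], name="gene"))
    table["log2fc"] = df["log2fc"].to_numpy(dtype=float)
    for col in ("pvalue", "padj"):
        table[col] = df[col].to_numpy(dtype=float) if col in df.columns else np.nan
    table["is_deg"] = crit.apply(table)
    return DEGTable(stage=stage or Path(path).stem, table=table, criterion=crit.describe())


def _welch_p(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch p; zero-variance rows resolved by mean equality."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(case[degenerate].mean(axis=1), ctrl[degenerate].mean(axis=1))
        p[degenerate] = np.where(same, 1.0, 0.0)
    return p


def call_degs_fallback(cm: CountMatrix, pseudocount: float = 1.0,
                       criterion: str | Criterion = DEFAULT_CRITERION) -> DEGTable:
    """Simple DEG caller: CPM normalization, pseudocount log2FC, Welch's t-test.

    This is a transparent stand-in for a dedicated differential-expression
    package — no dispersion estimation or shrinkage — adequate for synthetic
    benchmarks and for the p-value-based meta-analysis mode.  ``padj`` is the
    Benjamini–Hochberg adjustment of the Welch p-values.
    """
    crit = criterion if isinstance(criterion, Criterion) else Criterion.parse(criterion)
    case_ids, ctrl_ids = cm.samples("case"), cm.samples("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("Welch mode needs ≥2 samples per group")
    libsize = cm.counts.sum(axis=0)
    if (libsize == 0).any():
        zeros = ", ".join(libsize.index[libsize == 0])
        raise ValueError(f"zero library size in sample(s): {zeros}")
    cpm = cm.counts / libsize * 1e6
    case = cpm[case_ids].to_numpy()
    ctrl = cpm[ctrl_ids].to_numpy()
    log2fc = np.log2((case.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount))
    pvals = _welch_p(case, ctrl)
    from .impact import bh_adjust

    table = pd.DataFrame({"log2fc": log2fc, "pvalue": pvals, "padj": bh_adjust(pvals)},
                         index=pd.Index(cm.genes, name="gene"))
    table["is_deg"] = crit.apply(table)
    return DEGTable(stage=cm.stage, table=table, criterion=crit.describe())
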