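# imad — dynamic molecular network analysis of time-ordered expression data

`imad` identifies the genes that *drive* transcriptome change during a
staged biological process — for example the differentiation of patient
iPSCs toward a terminal neuronal fate — rather than the genes that merely
*show* change. Given time-ordered differential-expression results and an
undirected protein–protein interaction (PPI) graph, it selects **impactful
genes**: genes whose one-hop PPI neighbors are significantly enriched for
differential expression at the *following* time point. From the impactful
genes it assembles a stage-layered directed network, converges it to core
regulatory nodes, detects feedback and feed-forward loops among them,
annotates keyword-defined (e.g. cytokine-relevant) sub-networks, and joins
networks across datasets and species.

## The statistic

For a candidate gene *g* at stage *t*, let *N* be its one-hop PPI neighbors
measured at stage *t+1*, *U* the genes measured at *t+1* and *D ⊆ U* the
differentially expressed genes (DEGs) there. The impact ratio is

    r = |N ∩ D| / |N|

and the 2×2 table

    a = |N ∩ D|   b = |N \ D|
    c = |D \ N|   d = |U \ N \ D|

is tested with a two-tailed Fisher's exact test (point-probability rule),
followed by Benjamini–Hochberg correction across candidates; genes with
q < 0.05 are impactful. DEGs are defined by |log2FC| > 0.5 (strict) for
DESeq2-style tables, or Welch's t-test p ≤ 0.05 for the count-level
meta-analysis mode. Edges of the dynamic network run from each impactful
gene at stage *t* to its PPI neighbors that are DEG at stage *t+1* (or any
later stage with `allow_skip`); core nodes are origin-stage impactful genes
whose edges reach the final stage.

## Worked example

`examples/01_impact_scoring.py` scores one candidate with four measured
neighbors, three of them DEG, against a 5/20 background:

```
neighbors measured at next stage: 4
of which differentially expressed: 3
impact ratio r = 0.75  (background 5/20 = 0.25)
two-tailed Fisher p = 0.0320, BH q = 0.0320
impactful at FDR < 5%: True
```

The neighborhood is three-fold enriched over the background DEG rate and
unlikely to be so by chance (p ≈ 0.032), so the candidate is called
impactful. `examples/03_synthetic_benchmark.py` runs the full pipeline on a
2000-gene scale-free graph with 10 planted driver hubs and prints

```
recall 1.00, precision 1.00, observed FDR 0.00
```

— the selection recovers exactly the planted genes. The other examples
cover network assembly with loop detection, gene-set over-representation
with cytokine-keyword annotation, and cross-dataset connected/inserted
network layouts.

A thin CLI wraps the same functions (`imad --help`): subcommands `deg`,
`impact`, `run`, `loops`, `ora`, `connect`, `simulate`, `evaluate`.

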