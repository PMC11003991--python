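# Methods

## Model and procedure

The package operates on a short ordered sequence of biological stages, each
carrying a differential-expression table (case vs control), plus one
undirected PPI graph shared by all stages. The working assumption is that a
regulator acting at stage *t* leaves its signature not in its own expression
at *t* but in the expression of its interaction partners at *t+1*: candidate
genes are therefore scored by the DEG enrichment of their one-hop PPI
neighborhood at the following stage, not by their own fold change. The
candidate pool at a stage defaults to *every* gene measured there that is
present in the PPI graph; a `candidates="deg"` mode restricts the pool to
that stage's DEGs for the stricter reading in which origins must themselves
be differentially expressed.

The 2×2 test partitions the stage-*t+1* measured universe into neighbor /
non-neighbor × DEG / non-DEG. Using the measured transcriptome as the
universe keeps the rows disjoint and makes the background rate the
transcriptome-wide DEG fraction. Candidates whose neighborhoods contain no
measured gene carry no evidence: they receive missing p and q, are never
called impactful, and are excluded from the Benjamini–Hochberg family so
that untestable hypotheses do not deflate the power of the step-up
procedure.

The two-sided Fisher p-value follows the point-probability convention (sum
over all tables with the observed margins whose probability does not exceed
the observed table's); this is the convention implemented by
`scipy.stats.fisher_exact`, which backs `fisher_two_sided`. BH adjustment is
implemented directly from the step-up definition
q(i) = min over rank(j) ≥ rank(i) of m·p(j)/rank(j), clipped at 1, because
the package treats exact reproducibility of q-values as part of its
contract; the test suite cross-checks it against `statsmodels`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| DEG criterion | `abs_log2fc>0.5` | strict fold-change threshold (dimensionless log2 units) |
| meta-analysis criterion | `welch_p<=0.05` | inclusive Welch p threshold for count-level cross-dataset work |
| alpha | 0.05 | BH FDR level for impactful selection (and ORA q reporting) |
| allow_skip | off | also draw edges to DEGs at all later stages, not only t+1 |
| max_cycle_len | 5 | bound on feedback-cycle enumeration in the collapsed core digraph |
| max_hops | 6 | static-expansion range, one to six hops |
| n_perm | 1000 | random node sets per hop for the expansion null |
| min_weight | 0 | PPI edge-score filter at load time (keep all) |

The fold-change boundary is strict (0.5 is not a DEG); the Welch p boundary
is inclusive (p = 0.05 is significant). Selection output is ordered by q
then symbol, so ties are deterministic.

## The fallback DEG caller

`call_degs_fallback` is a transparent stand-in for a dedicated
differential-expression package, intended for synthetic data and for
p-value-mode meta-analysis: counts-per-million normalization, group means,
log2FC = log2((mean_case + 1)/(mean_ctrl + 1)), two-sided Welch's t-test on
the normalized values. It performs no dispersion estimation, shrinkage or
multi-factor modeling; analyses meant to mirror a DESeq2 workflow should
ingest DESeq2 result tables instead (`ingest_deg_table`). When both groups
of a gene have zero variance the Welch statistic is undefined; the caller
reports p = 1 when the group means are equal and p = 0 otherwise.

## Dynamic network, core nodes, loops

Nodes are (gene, stage) pairs classed impactful / deg / both; every edge
runs from an impactful node to a PPI-backed DEG node at a strictly later
stage. All four edge contracts are asserted on every build. Core nodes at
the origin stage are impactful genes with at least one directed path to a
final-stage DEG. Loop analysis collapses layered edges among a core gene
set to a gene-level digraph (A→B iff any layered A-to-later-B edge);
feedback loops are its simple cycles up to `max_cycle_len`, and a
feed-forward motif is a pair with a direct edge plus an indirect path that
avoids that edge — the direct edge has no intermediates, so any simple
indirect path is node-disjoint from it, and each motif reports one shortest
indirect path to avoid double counting.

## Static expansion

The static companion statistic grows an undirected frontier from a seed DEG
set hop by hop (1–6) and compares each frontier's changed-gene fraction
against uniformly drawn node sets of the same size (seeded; z-score). The
null is uniform over nodes, not degree-preserving: a degree-aware null is a
documented non-default that is not implemented. When the frontier covers
genes whose changed fraction the null reproduces exactly (sd = 0, e.g. the
whole graph), z is reported missing with a warning rather than inflated.

## Cross-dataset joins

`connect_networks` supports two layouts: *connect* appends dataset B's
stages after A's final stage and scores the bridging transition (A
final-stage genes, translated by the ortholog map, against B's first-stage
DEG set on B's PPI); *insert* splices B's stages before A's final stage and
scores B's last stage against A's final-stage universe. The default symbol
translation is case-insensitive identity (human SYMBOL ↔ mouse Symbol
capitalization collapses under normalization), overridable with a
two-column ortholog TSV. Both modes preserve every pre-existing node and
edge; edge classes (consecutive/skip) are re-derived after splicing.
`connection_frequency_scan` ranks candidate B stages by the number of A
final-stage genes with at least one bridging edge, descending, ties broken
by stage name.

## Synthetic generator

The generator emulates the study design the method targets: a scale-free
PPI (preferential attachment; PPI degree distributions are heavy-tailed), a
three-stage course, and bulk RNA-seq triplicates. Planted "impactful" hub
genes (degree ≥ 20 by default) have their neighbors labeled DEG at the next
stage with probability `p_hi` = 0.6 against a background `p_bg` = 0.05;
counts are negative-binomial (gene-level dispersion 0.1) around log-normal
baseline means, with labeled DEGs scaled by 2^±2 in the case group
(direction random, magnitude above the 0.5 threshold by construction).
What it does **not** emulate: correlated co-regulation, library-size and
batch effects, lowly-expressed-gene count sparsity, annotation errors in
the PPI, or stage-to-stage autocorrelation of expression. Passing the
recovery benchmarks therefore demonstrates the statistical machinery works
as specified under its own assumptions — not that real differentiation data
will yield networks of any particular quality.

All randomness flows from a single integer seed through named
`numpy.random.Generator` instances drawn in fixed gene-sorted order; there
is no global RNG state, and fixed seeds give identical label sets,
count matrices and selections across runs.

## Numerical and design choices

- Gene identifiers are uppercased symbols; normalization is idempotent and
  applied at every ingestion boundary. Symbol-keyed STRING-style edge lists
  are the expected PPI source; duplicate edges collapse keeping the
  maximum score.
- Benchmark problem sizes: the planted benchmark uses 2000 genes /
  attachment 3 / 10 planted hubs, the null calibration 50 replicates of 500
  genes, and the expansion calibration 100 draws at 300 permutations —
  sizes at which every statistic is stable yet a full run completes in
  seconds.
- Output TSVs use fixed column orders and 6-significant-digit floats so
  reruns diff cleanly; the run manifest records parameters, seed and
  library versions.
- Degenerate inputs: empty DEG sets give p = 1 everywhere and no impactful
  genes; empty networks are valid and export as headers-only files;
  an all-zero 2×2 table has p = 1.

## Known limitations

- One-hop neighborhoods only; no multi-hop impact scoring and no
  edge-weight-aware scoring (weights act only as a load-time filter).
- The PPI graph is treated as stage-invariant and error-free.
- GO-style annotations are used as flat term lists; no ancestor-closure
  propagation over the ontology graph.
- The impact test assumes candidate neighborhoods are exchangeable with
  the background; heavy hub overlap between candidates makes the BH family
  positively dependent, which BH tolerates but does not exploit.
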