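"""Gene-set over-representation and keyword-defined sub-network relevance.

First an ORA of a query list against named gene sets (hypergeometric upper
tail, BH-corrected); then a "cytokine" keyword filter over GO-style term
names (excluding look-alikes such as cytokinesis) whose gene set annotates
the edges of a small dynamic network.
"""

from imad import (DEGTable, PPIGraph, TermAnnotation, build_dynamic_network,
                  edge_relevance_fraction, ora, relevant_gene_set)
from imad.genesets import GeneSetCollection

import pandas as pd

universe = [f"G{i}" for i in range(30)]
collection = GeneSetCollection({
    "immune_response": frozenset(universe[:8]),
    "metabolism": frozenset(universe[20:28])})
query = universe[:6] + universe[25:27]  # heavily overlaps immune_response

result = ora(query, collection, universe)
print(result.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# 'immune_response' captures 6/8 of its members -> small p; metabolism does not.

ann = TermAnnotation(
    gene_to_terms={"G0": frozenset({"T1"}), "G1": frozenset({"T1"}),
                   "G5": frozenset({"T2"}), "G9": frozenset({"T3"})},
    term_names={"T1": "cytokine production", "T2": "cytokinesis",
                "T3": "ion transport"})
cyto = relevant_gene_set(ann, "cytokine", exclude=["cytokinesis"])
print(f"cytokine-relevant genes (cytokinesis excluded): {sorted(cyto)}")

ppi = PPIGraph.from_edges([("HUB", g) for g in ("G0", "G1", "G5", "G9")])
genes = sorted(["HUB", "G0", "G1", "G5", "G9"])
t1 = pd.DataFrame({"log2fc": [1.0 if g == "HUB" else 0.0 for g in genes]},
                  index=pd.Index(genes, name="gene")).assign(
                      pvalue=float("nan"), padj=float("nan"))
t2 = pd.DataFrame({"log2fc": [0.0 if g == "HUB" else 1.0 for g in genes]},
                  index=pd.Index(genes, name="gene")).assign(
                      pvalue=float("nan"), padj=float("nan"))
for t in (t1, t2):
    t["is_deg"] = t["log2fc"].abs() > 0.5
net = build_dynamic_network(
    [DEGTable("T1", t1, "abs_log2fc>0.5"), DEGTable("T2", t2, "abs_log2fc>0.5")],
    {"T1": {"HUB"}}, ppi)
pct = edge_relevance_fraction(net, cyto, "HUB")
print(f"cytokine-relevant edges from HUB: {pct:.0f}%")
# 2 of HUB's 4 downstream edges point at cytokine genes -> 50%.
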