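"""Score one candidate gene's impact on the next time point.

Candidate X has four PPI neighbors measured at the following stage, three of
which are differentially expressed there, against a background of 5 DEGs
among 20 measured genes.  The impact ratio r is the DEG fraction of the
neighborhood; the two-tailed Fisher p compares it with the background rate.
"""

from imad import PPIGraph, impact_scores

ppi = PPIGraph.from_edges([("X", n) for n in ("A", "B", "C", "D")])
universe = {"A", "B", "C", "D"} | {f"U{i:02d}" for i in range(5, 21)}
deg_next_stage = {"A", "B", "C", "U05", "U06"}

(record,) = impact_scores(ppi, universe, deg_next_stage, ["X"])
print(f"neighbors measured at next stage: {record.n_neighbors}")
print(f"of which differentially expressed: {record.n_deg_neighbors}")
print(f"impact ratio r = {record.r:.2f}  (background {record.background_deg}"
      f"/{record.background_total} = {record.background_deg / record.background_total:.2f})")
print(f"two-tailed Fisher p = {record.fisher_p:.4f}, BH q = {record.q:.4f}")
print(f"impactful at FDR < 5%: {record.impactful}")
# r = 0.75 vs a 0.25 background rate: X's neighborhood is three-fold enriched,
# and p ~= 0.032 quantifies how unlikely that is by chance.
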