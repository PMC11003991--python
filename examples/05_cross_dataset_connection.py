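"""Join two datasets' time series: connected and inserted network layouts.

Dataset A is a two-stage human-like series ending at stage PC; dataset B is a
mouse-like series (stages W05, W28).  'connect' appends B after A's final
stage and scores the bridging transition; the connection-frequency scan ranks
candidate B stages by how many A final-stage genes they connect to.
"""

import pandas as pd

from imad import (DEGTable, PPIGraph, build_dynamic_network, connect_networks,
                  connection_frequency_scan)


def table(stage, universe, deg):
    genes = sorted(universe)
    df = pd.DataFrame({"log2fc": [1.0 if g in deg else 0.0 for g in genes],
                       "pvalue": float("nan"), "padj": float("nan")},
                      index=pd.Index(genes, name="gene"))
    df["is_deg"] = df["log2fc"].abs() > 0.5
    return DEGTable(stage=stage, table=df, criterion="abs_log2fc>0.5")


ppi_a = PPIGraph.from_edges([("TP53", "MDM2"), ("TP53", "ATM"), ("MDM2", "ATM")])
net_a = build_dynamic_network(
    [table("IPSC", {"TP53", "MDM2", "ATM"}, {"TP53"}),
     table("PC", {"TP53", "MDM2", "ATM"}, {"MDM2", "ATM"})],
    {"IPSC": {"TP53"}}, ppi_a)
print(f"dataset A network: {net_a.n_edges} edges, final stage {net_a.layers[-1]}")

# dataset B shares symbols with A (case-insensitive identity mapping)
ppi_b = PPIGraph.from_edges([("ATM", "CDKN1A"), ("MDM2", "BAX")])
w05 = table("W05", {"MDM2", "ATM", "CDKN1A", "BAX"}, {"CDKN1A"})
w28 = table("W28", {"MDM2", "ATM", "CDKN1A", "BAX"}, {"CDKN1A", "BAX"})

combined, bridge = connect_networks(net_a, [(w05, None)], ppi_b,
                                    mode="connect", alpha=0.9)
print(f"connected network layers: {combined.layers}")
for g1, s1, g2, s2, _ in combined.edge_records():
    print(f"  {g1}@{s1} -> {g2}@{s2}")

scan = connection_frequency_scan(net_a, [w05, w28], ppi_b)
print(scan.to_string(index=False))
# W28 connects both final-stage genes (ATM via CDKN1A, MDM2 via BAX) while
# W05 connects only ATM, so W28 ranks first as the best-matching mouse age.
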