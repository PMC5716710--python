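"""Build and export the tripartite ceRNA-miRNA network for a small call set.

Two called ceRNA pairs share a hub lncRNA; the shared miRNAs attach with
"binds" edges (weight = correlation r) while the lncRNA-mRNA "competes"
edges carry the ceRNA score. The degree report ranks nodes by how many
competing partners they have — the hub lncRNA tops the list.
"""

from pathlib import Path

import pandas as pd

import cerna_triad as ct

calls = [
    ct.CeRNACandidate("lnc-01", "FASN", 24, 5, 4, 3, frozenset({"miR-a", "miR-b", "miR-c"}),
                      cerna_score=0.75, pval=0.004, source="shared"),
    ct.CeRNACandidate("lnc-01", "LPL", 24, 4, 4, 2, frozenset({"miR-a", "miR-b"}),
                      cerna_score=0.5, pval=0.03, source="shared"),
]
binds_mrna = [ct.CorrelationEdge("miR-a", "FASN", "miRNA", "mRNA", -0.93, 0.007, 6),
              ct.CorrelationEdge("miR-b", "LPL", "miRNA", "mRNA", -0.88, 0.02, 6)]
binds_lnc = [ct.CorrelationEdge("miR-a", "lnc-01", "miRNA", "lncRNA", -0.91, 0.012, 6)]
annotations = pd.DataFrame({"feature_id": ["lnc-01", "FASN", "LPL", "miR-a", "miR-b"],
                            "direction": ["Up", "Up", "Up", "Down", "Down"]})

net = ct.build_tripartite_network(calls, binds_mrna, binds_lnc, annotations)
outdir = Path("scratch/example_network")
node_path, edge_path = ct.write_network(net, outdir)
print(f"wrote {node_path} and {edge_path}")
print(ct.degree_report(net).to_string(index=False))
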