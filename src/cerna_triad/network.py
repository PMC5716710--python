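"""Assembly and export of ceRNA networks.

Two views are produced: the bipartite competing network, whose nodes are
mRNAs and lncRNAs and whose edges ("competes") are called ceRNA pairs
weighted by ceRNA score; and the tripartite view that adds the shared
miRNAs with "binds" edges (weighted by correlation r) to every target that
participates in at least one called pair. Nodes carry their RNA class and
differential direction so viewers can colour by regulation. Exports are a
two-file node/edge TSV convention with deterministic (lexicographic)
ordering, importable by common network viewers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

EDGE_TYPES = ("competes", "binds")


@dataclass
class CeRNANetwork:
    """Wrapper around an undirected :class:`networkx.Graph`.

    Node attributes: ``cls`` (mRNA | lncRNA | miRNA), ``direction``
    (Up | Down | NotSignificant | Unknown). Edge attributes: ``edge_type``
    (competes | binds) and ``weight``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on {u}")
            cu = self.graph.nodes[u]["cls"]
            cv = self.graph.nodes[v]["cls"]
            et = d["edge_type"]
            if et == "competes" and {cu, cv} != {"mRNA", "lncRNA"}:
                raise ValidationError(f"competes edge {u}-{v} must join lncRNA and mRNA")
            if et == "binds" and ("miRNA" not in {cu, cv} or {cu, cv} == {"miRNA"}):
                raise ValidationError(f"binds edge {u}-{v} must join a miRNA and a target")
            if et not in EDGE_TYPES:
                raise ValidationError(f"unknown edge type {et!r}")

    # -- tabular views ---------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": n, "class": d["cls"], "direction": d.get("direction", "Unknown")}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["id", "class", "direction"])

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            s, t = d.get("source", u), d.get("target", v)
            rows.append(
                {"source": s, "target": t, "edge_type": d["edge_type"], "weight": round(d["weight"], 6)}
            )
        rows.sort(key=lambda r: (r["edge_type"], r["source"], r["target"]))
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "weight"])

    def equals(self, other: "CeRNANetwork") -> bool:
        return self.node_table().equals(other.node_table()) and self.edge_table().equals(other.edge_table())


def _direction_map(annotations) -> dict[str, str]:
    if annotations is None:
        return {}
    if isinstance(annotations, pd.DataFrame):
        return dict(zip(annotations["feature_id"], annotations["direction"]))
    return dict(annotations)


def _add_node(g: nx.Graph, node: str, cls: str, directions: dict[str, str], warned: set) -> None:
    if node not in directions and node not in warned:
        warned.add(node)
        logger.warning("no differential annotation for %s; marked Unknown", node)
    g.add_node(node, cls=cls, direction=directions.get(node, "Unknown"))


def build_cerna_network(cernas, annotations=None) -> CeRNANetwork:
    """Bipartite competing network: one de-duplicated competes edge per
    called candidate, weighted by its ceRNA score."""
    g = nx.Graph()
    directions = _direction_map(annotations)
    warned: set = set()
    for c in cernas:
        _add_node(g, c.lncrna_id, "lncRNA", directions, warned)
        _add_node(g, c.mrna_id, "mRNA", directions, warned)
        g.add_edge(
            c.lncrna_id, c.mrna_id, edge_type="competes", weight=float(c.cerna_score),
            source=c.lncrna_id, target=c.mrna_id,
        )
    net = CeRNANetwork(g)
    net.validate()
    return net


def build_tripartite_network(
    cernas, shared_mirna_mrna_pairs, shared_mirna_lncrna_pairs, annotations=None
) -> CeRNANetwork:
    """Competing network plus binds edges for shared miRNA pairs.

    A binds edge is added only when its target participates in at least one
    called ceRNA pair; miRNAs paired solely with uncalled targets are
    excluded. Pair inputs may be CorrelationEdge objects (weight = r) or
    bare (mirna_id, target_id) tuples (weight = NaN).
    """
    net = build_cerna_network(cernas, annotations)
    g = net.graph
    participants = {n for n, d in g.nodes(data=True) if d["cls"] in ("mRNA", "lncRNA")}
    directions = _direction_map(annotations)
    warned: set = set()
    for pairs, cls in ((shared_mirna_mrna_pairs, "mRNA"), (shared_mirna_lncrna_pairs, "lncRNA")):
        for p in pairs:
            if hasattr(p, "source_id"):
                mir, tgt, w = p.source_id, p.target_id, float(p.r)
            elif hasattr(p, "mirna_id"):
                mir, tgt, w = p.mirna_id, p.target_id, math.nan
            else:
                mir, tgt, w = p[0], p[1], math.nan
            if tgt not in participants:
                continue
            _add_node(g, mir, "miRNA", directions, warned)
            g.add_edge(mir, tgt, edge_type="binds", weight=w, source=mir, target=tgt)
    net.validate()
    return net


def degree_report(net: CeRNANetwork) -> pd.DataFrame:
    """Per-node degree split by edge type, sorted by descending competes
    degree then id. The handshake identity holds per type: the column sums
    equal twice the corresponding edge counts."""
    g = net.graph
    rows = []
    for n, d in g.nodes(data=True):
        competes = sum(1 for _, _, e in g.edges(n, data=True) if e["edge_type"] == "competes")
        binds = sum(1 for _, _, e in g.edges(n, data=True) if e["edge_type"] == "binds")
        rows.append({"node": n, "class": d["cls"], "competes_degree": competes, "binds_degree": binds})
    rows.sort(key=lambda r: (-r["competes_degree"], r["node"]))
    return pd.DataFrame(rows, columns=["node", "class", "competes_degree", "binds_degree"])


def write_network(net: CeRNANetwork, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    node_path = outdir / "nodes.tsv"
    edge_path = outdir / "edges.tsv"
    net.node_table().to_csv(node_path, sep="\t", index=False)
    net.edge_table().to_csv(edge_path, sep="\t", index=False, float_format="%.6f")
    return node_path, edge_path


def read_network(outdir) -> CeRNANetwork:
    outdir = Path(outdir)
    nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t")
    edges = pd.read_csv(outdir / "edges.tsv", sep="\t")
    g = nx.Graph()
    for r in nodes.itertuples():
        g.add_node(str(r.id), cls=r._2, direction=r.direction)
    for r in edges.itertuples():
        g.add_edge(
            str(r.source), str(r.target), edge_type=r.edge_type, weight=float(r.weight),
            source=str(r.source), target=str(r.target),
        )
    net = CeRNANetwork(g)
    net.validate()
    return net
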