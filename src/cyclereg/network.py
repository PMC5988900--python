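"""Assembly and export of the regulator -> ncRNA -> target network.

Nodes are master-regulator proteins (CtrA, DnaA, CcrM, GcrA), ncRNAs, and
target transcripts.  Protein and transcript identities of the same factor
are distinct nodes ("CtrA" the protein regulating an ncRNA promoter versus
"ctrA" the transcript an ncRNA silences), keeping the graph acyclic where
the biology is a feed-forward loop.

Edge types carry the evidence class: ctra_full / ctra_half (binding sites),
ccrm_site (methylation sites), dnaa_box, gcra_peak (ChIP-seq), and
ncrna_target (integrated prediction).  When a promoter carries a full CtrA
site, its half sites are not drawn (a full site implies direct regulation;
half-site edges would only restate it).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MASTER_REGULATORS",
    "EDGE_TYPES",
    "build_network",
    "multiregulated",
    "export_network",
]

MASTER_REGULATORS = ("CtrA", "DnaA", "CcrM", "GcrA")

EDGE_TYPES = ("ctra_full", "ctra_half", "ccrm_site", "dnaa_box", "gcra_peak", "ncrna_target")

# site-count column -> (regulator protein, edge type)
_MOTIF_EDGE = {
    "ccrm": ("CcrM", "ccrm_site"),
    "dnaa": ("DnaA", "dnaa_box"),
    "gcra_peaks": ("GcrA", "gcra_peak"),
}


def build_network(
    site_counts: pd.DataFrame,
    confirmed_targets: list[tuple[str, str]] | None = None,
    catalog_ids: set[str] | None = None,
) -> nx.MultiDiGraph:
    """Build the regulatory network from per-promoter site counts and
    confirmed ncRNA->target pairs.

    ``site_counts`` has one row per TSS (columns ccna, ctra_full, ctra_half,
    ccrm, dnaa, gcra_peaks); rows of the same ncRNA are summed.  A positive
    count becomes one typed regulator->ncRNA edge weighted by the count,
    with the CtrA full/half collapse applied per ncRNA.
    """
    g = nx.MultiDiGraph()
    per_ncrna = (
        site_counts.groupby("ccna")[["ctra_full", "ctra_half", "ccrm", "dnaa", "gcra_peaks"]]
        .sum()
        .sort_index()
    )
    for reg in MASTER_REGULATORS:
        g.add_node(reg, node_type="master_protein")
    for ncrna_id, row in per_ncrna.iterrows():
        g.add_node(ncrna_id, node_type="ncrna")
        if row["ctra_full"] > 0:
            g.add_edge("CtrA", ncrna_id, edge_type="ctra_full", weight=int(row["ctra_full"]))
        elif row["ctra_half"] > 0:
            g.add_edge("CtrA", ncrna_id, edge_type="ctra_half", weight=int(row["ctra_half"]))
        for col, (reg, etype) in _MOTIF_EDGE.items():
            if row[col] > 0:
                g.add_edge(reg, ncrna_id, edge_type=etype, weight=int(row[col]))
    for ncrna_id, locus in confirmed_targets or []:
        if ncrna_id not in g:
            if catalog_ids is not None and ncrna_id not in catalog_ids:
                logger.warning("target pair for %s absent from catalog; node created", ncrna_id)
            g.add_node(ncrna_id, node_type="ncrna")
        if locus not in g:
            g.add_node(locus, node_type="target_transcript")
        if not any(
            d["edge_type"] == "ncrna_target" for d in g.get_edge_data(ncrna_id, locus, default={}).values()
        ):
            g.add_edge(ncrna_id, locus, edge_type="ncrna_target", weight=1)
    return g


def multiregulated(network: nx.MultiDiGraph, k: int = 2) -> list[str]:
    """ncRNA nodes with at least ``k`` distinct incoming master regulators,
    sorted by descending regulator count then name."""
    out = []
    for node, data in network.nodes(data=True):
        if data.get("node_type") != "ncrna":
            continue
        regs = {u for u, _, d in network.in_edges(node, data=True)
                if network.nodes[u].get("node_type") == "master_protein"}
        if len(regs) >= k:
            out.append((len(regs), node))
    return [n for c, n in sorted(out, key=lambda x: (-x[0], x[1]))]


def _sorted_edges(network: nx.MultiDiGraph) -> list[tuple[str, str, str, int]]:
    edges = [
        (u, d["edge_type"], v, int(d.get("weight", 1)))
        for u, v, d in network.edges(data=True)
    ]
    return sorted(edges)


def export_network(network: nx.MultiDiGraph, fmt: str, path: str | Path) -> None:
    """Write the network as SIF, GraphML or TSV with deterministic ordering."""
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, etype, v, _w in _sorted_edges(network):
                fh.write(f"{u}\t{etype}\t{v}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\tedge_type\ttarget\tweight\n")
            for u, etype, v, w in _sorted_edges(network):
                fh.write(f"{u}\t{etype}\t{v}\t{w}\n")
    elif fmt == "graphml":
        # rebuild in sorted order so the XML is byte-stable across runs
        g = nx.MultiDiGraph()
        for node in sorted(network.nodes):
            g.add_node(node, **network.nodes[node])
        for u, etype, v, w in _sorted_edges(network):
            g.add_edge(u, v, edge_type=etype, weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
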