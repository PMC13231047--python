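"""miRNA-mRNA regulatory network: shared disease miRNAs, hub-gene targets,
and a typed tripartite (disease -> miRNA -> gene) graph exportable to SIF
and GraphML.

miRNA identifiers are normalized by lowercasing and whitespace trimming
only; no miRBase version mapping is attempted.
"""

from __future__ import annotations

import networkx as nx

from . import io as chio

__all__ = [
    "normalize_mirna",
    "shared_mirnas",
    "hub_targets",
    "build_network",
    "export_network",
]


def normalize_mirna(name: str) -> str:
    return name.strip().lower()


def shared_mirnas(list_a, list_b) -> list[str]:
    """Case-normalized sorted intersection of two disease miRNA lists."""
    a = {normalize_mirna(m) for m in list_a}
    b = {normalize_mirna(m) for m in list_b}
    return sorted(a & b)


def hub_targets(
    shared, target_map: dict[str, list[str]], hubs
) -> tuple[list[tuple[str, str]], list[str]]:
    """Edges (miRNA, gene) for targets that are common hub genes.

    Returns (edge list, miRNAs with no hub target). Gene ids are matched
    exactly; miRNA ids are case-normalized.
    """
    hubs = set(hubs)
    norm_map: dict[str, set] = {}
    for m, genes in target_map.items():
        norm_map.setdefault(normalize_mirna(m), set()).update(genes)
    edges = []
    unconnected = []
    for m in sorted(normalize_mirna(x) for x in shared):
        targets = sorted(norm_map.get(m, set()) & hubs)
        if targets:
            edges.extend((m, g) for g in targets)
        else:
            unconnected.append(m)
    return edges, unconnected


def build_network(
    disease_a: str,
    disease_b: str,
    shared,
    mirna_gene_edges,
) -> nx.Graph:
    """Typed regulatory network: both disease nodes link to every shared
    miRNA; miRNAs link to the hub genes they target."""
    g = nx.Graph()
    g.add_node(disease_a, node_type="disease")
    g.add_node(disease_b, node_type="disease")
    for m in sorted(normalize_mirna(x) for x in shared):
        g.add_node(m, node_type="mirna")
        g.add_edge(disease_a, m, relation="disease-mirna")
        g.add_edge(disease_b, m, relation="disease-mirna")
    for m, gene in mirna_gene_edges:
        g.add_node(normalize_mirna(m), node_type="mirna")
        g.add_node(gene, node_type="gene")
        g.add_edge(normalize_mirna(m), gene, relation="mirna-gene")
    return g


def export_network(net: nx.Graph, path, fmt: str) -> None:
    if fmt == "sif":
        chio.write_sif(net, path)
    elif fmt == "graphml":
        chio.write_graphml(net, path)
    else:
        raise ValueError(f"unknown format: {fmt!r} (use 'sif' or 'graphml')")
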