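"""Signed coordination graphs: assembly, condition diffs, import/export.

A coordination graph for a gene set and condition has one node per gene
(isolated genes retained, annotated with their regulation status UP/DOWN/NC)
and one edge per significantly coordinated pair, signed "+" or "-" by the
sign of rho; IND and UNCLASSIFIED pairs contribute no edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .coordination import NEG, POS, CorrelationRecord, pair_key
from .expression_stats import RegulationCall

__all__ = ["EdgeDiff", "build_network", "diff_networks", "export_graph", "load_graphml"]


@dataclass
class EdgeDiff:
    """Pair-level changes between two conditions' graphs (A -> B)."""

    gained: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    sign_reversed: set = field(default_factory=set)
    unchanged: set = field(default_factory=set)


def build_network(
    records: list[CorrelationRecord],
    geneset,
    condition: str,
    regulation: list[RegulationCall] | None = None,
) -> nx.Graph:
    """Assemble the signed graph of a gene set in one condition.

    Records touching genes outside the set are skipped (collected in
    ``graph.graph["skipped_records"]``).  Node regulation defaults to NC.
    """
    genes = list(geneset)
    if not genes:
        raise ValueError("empty gene set")
    status = {c.transcript_id: c.status for c in (regulation or [])}
    g = nx.Graph(condition=condition, skipped_records=0)
    for gene in genes:
        g.add_node(gene, regulation=status.get(gene, "NC"))
    members = set(genes)
    for r in records:
        if r.classification not in (POS, NEG):
            continue
        if r.gene_a not in members or r.gene_b not in members:
            g.graph["skipped_records"] += 1
            continue
        g.add_edge(r.gene_a, r.gene_b, sign="+" if r.rho > 0 else "-", rho=float(r.rho))
    return g


def diff_networks(graph_a: nx.Graph, graph_b: nx.Graph) -> EdgeDiff:
    """Partition pairs into gained/lost/sign-reversed/unchanged from A to B."""
    if set(graph_a.nodes) != set(graph_b.nodes):
        raise ValueError("graphs have different node universes")
    diff = EdgeDiff()
    edges_a = {pair_key(u, v): d["sign"] for u, v, d in graph_a.edges(data=True)}
    edges_b = {pair_key(u, v): d["sign"] for u, v, d in graph_b.edges(data=True)}
    for pair, sign in edges_a.items():
        if pair not in edges_b:
            diff.lost.add(pair)
        elif edges_b[pair] == sign:
            diff.unchanged.add(pair)
        else:
            diff.sign_reversed.add(pair)
    diff.gained = {p for p in edges_b if p not in edges_a}
    return diff


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML (round-trip safe), TSV edge list or DOT."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tsign\trho\n")
            for u, v, d in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['sign']}\t{d['rho']:.6f}\n")
    elif format == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_dot(graph: nx.Graph, path) -> None:
    # minimal DOT writer: node fill by regulation, edge color by sign
    colors = {"UP": "red", "DOWN": "green", "NC": "yellow"}
    with open(path, "w") as fh:
        fh.write(f'graph "{graph.graph.get("condition", "coordination")}" {{\n')
        for node, d in sorted(graph.nodes(data=True)):
            fill = colors.get(d.get("regulation", "NC"), "yellow")
            fh.write(f'  "{node}" [style=filled, fillcolor={fill}];\n')
        for u, v, d in sorted(graph.edges(data=True)):
            color = "red" if d.get("sign") == "+" else "blue"
            fh.write(f'  "{u}" -- "{v}" [color={color}, label="{d.get("rho", 0):.3f}"];\n')
        fh.write("}\n")


def load_graphml(path) -> nx.Graph:
    """Read back a GraphML export (rho restored as float)."""
    g = nx.read_graphml(path)
    for _, _, d in g.edges(data=True):
        d["rho"] = float(d["rho"])
    return g
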