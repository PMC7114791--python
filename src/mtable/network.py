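"""Protein-interaction subnetworks and node centralities.

Graphs are simple and undirected: duplicate and reversed interactor pairs
collapse to one edge, self-interactions are dropped (and counted). Five
per-node centralities are computed: degree, degree normalized by N−1,
closeness restricted to the node's connected component ((r−1)/Σd over the
r nodes reachable), closeness with the Wasserman–Faust (r−1)/(N−1) scaling
so values are comparable across components, and Freeman betweenness
(endpoints excluded) normalized by (N−1)(N−2)/2.
"""

from __future__ import annotations

import json
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError
from .genesets import GeneSet

CENTRALITY_COLUMNS = (
    "degree",
    "degree_norm",
    "closeness",
    "closeness_norm",
    "betweenness",
)


def read_interactions(path) -> nx.Graph:
    """Read a 2-column TSV of interactor pairs into an undirected graph.

    (a, b) and (b, a) merge; self-pairs are dropped, with the count stored
    in ``graph.graph['n_self_loops_dropped']``. Extra columns (as in
    BioGRID tab exports reduced upstream) are ignored.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 2 fields"
                )
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    graph.graph["n_self_loops_dropped"] = n_self
    return graph


def induced_subgraph(
    graph: nx.Graph, genes, include_neighbors: bool = False
) -> nx.Graph:
    """Subgraph on a gene set, optionally expanded by first neighbors.

    Genes absent from the graph are listed in
    ``subgraph.graph['unmapped']``.
    """
    if isinstance(genes, GeneSet):
        genes = genes.genes
    genes = set(genes)
    present = genes & set(graph.nodes)
    unmapped = sorted(genes - present)
    nodes = set(present)
    if include_neighbors:
        for node in present:
            nodes.update(graph.neighbors(node))
    sub = nx.Graph(graph.subgraph(nodes))
    sub.graph["unmapped"] = unmapped
    sub.graph["seed_genes"] = sorted(present)
    return sub


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Per-node centrality table (see module docstring for definitions).

    On graphs with fewer than two nodes all centralities are 0.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return pd.DataFrame(columns=list(CENTRALITY_COLUMNS))
    if n == 1:
        return pd.DataFrame(
            0.0, index=pd.Index(nodes, name="node"),
            columns=list(CENTRALITY_COLUMNS),
        )
    degree = dict(graph.degree())
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    closeness_wf = nx.closeness_centrality(graph, wf_improved=True)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    frame = pd.DataFrame(
        {
            "degree": [float(degree[v]) for v in nodes],
            "degree_norm": [degree[v] / (n - 1) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "closeness_norm": [closeness_wf[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return frame


def annotate_centralities(graph: nx.Graph) -> nx.Graph:
    """Attach the five centralities as node attributes, in place."""
    frame = centralities(graph)
    for column in frame.columns:
        nx.set_node_attributes(graph, frame[column].to_dict(), column)
    return graph


def export_graph(graph: nx.Graph, path, format: str = "cytoscape_json") -> None:
    """Export as Cytoscape.js elements JSON or a 2-column edge TSV."""
    if format == "cytoscape_json":
        document = nx.cytoscape_data(graph)
        with open(path, "wt") as fh:
            json.dump(document, fh, indent=2)
            fh.write("\n")
    elif format == "edge_tsv":
        with open(path, "wt") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{a}\t{b}\n")
    else:
        raise ValidationError(
            f"unknown export format {format!r}; use 'cytoscape_json' or "
            f"'edge_tsv'"
        )


def read_cytoscape_json(path) -> nx.Graph:
    with open(path, "rt") as fh:
        document = json.load(fh)
    return nx.cytoscape_graph(document)


def write_centralities_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6f", index_label="node")
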