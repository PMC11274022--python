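"""Shared-DEG networks over selected GO terms.

For one comparison, each selected term becomes a node carrying the
number of DEGs it contains (node size grows logarithmically with the
count), the signed sum of those DEGs' log2 fold changes (node colour:
red above zero, green below, white for balanced deregulation), and two
terms are linked whenever they share at least one DEG, the edge weighted
by how many DEGs are deregulated in both terms at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import SeedgoError
from .ego_network import DegInteractorSet
from .io_formats import AnnotationMap

GRAPH_FORMATS = ("graphml", "gml", "tsv")


@dataclass
class TermGraph:
    """Undirected term-similarity graph for one comparison."""

    comparison_id: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def classify_node_direction(sum_fc: float, balance_tol: float = 0.0) -> str:
    """"up" / "down" / "balanced" from the signed fold-change sum."""
    if balance_tol < 0:
        raise SeedgoError("balance_tol must be >= 0")
    if sum_fc > balance_tol:
        return "up"
    if sum_fc < -balance_tol:
        return "down"
    return "balanced"


def build_term_graph(
    terms,
    deg_set: DegInteractorSet,
    annot: AnnotationMap,
    universe: set[str] | None = None,
    size_coeff: float = 1.0,
    balance_tol: float = 0.0,
) -> TermGraph:
    """Build the shared-DEG graph over ``terms`` for one comparison.

    Node attributes: ``name``, ``n_degs``, ``sum_fc``,
    ``size_attr = size_coeff * log(n_degs + 1)`` and ``direction``.
    Edge attributes: ``shared_count`` and the sorted ``shared_genes``.
    """
    term_list = sorted(terms.terms if hasattr(terms, "terms") else terms)
    graph = nx.Graph(comparison_id=deg_set.comparison_id)
    term_degs: dict[str, set[str]] = {}
    for term in term_list:
        if term not in annot:
            raise SeedgoError(f"term {term!r} absent from annotation map")
        genes = annot[term]
        if universe is not None:
            genes = genes & universe
        if not genes:
            raise SeedgoError(f"term {term!r} has zero annotated genes")
        hits = deg_set.genes & genes
        term_degs[term] = hits
        sum_fc = sum(deg_set.log2fc[g] for g in hits)
        graph.add_node(
            term,
            name=annot.name_of(term),
            n_degs=len(hits),
            sum_fc=float(sum_fc),
            size_attr=size_coeff * math.log(len(hits) + 1),
            direction=classify_node_direction(sum_fc, balance_tol),
        )
    for i, ta in enumerate(term_list):
        for tb in term_list[i + 1:]:
            shared = term_degs[ta] & term_degs[tb]
            if shared:
                graph.add_edge(
                    ta, tb,
                    shared_count=len(shared),
                    shared_genes="|".join(sorted(shared)),
                )
    return TermGraph(deg_set.comparison_id, graph)


def export_graph(tg: TermGraph, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize a term graph with all node and edge attributes.

    ``tsv`` writes an edge list plus a sibling ``*.nodes.tsv`` attribute
    table; ``graphml``/``gml`` are single-file and round-trippable via
    :func:`load_graph`.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(tg.graph, path)
    elif fmt == "gml":
        nx.write_gml(tg.graph, path)
    elif fmt == "tsv":
        edges = pd.DataFrame(
            [
                (a, b, d["shared_count"], d["shared_genes"])
                for a, b, d in sorted(tg.graph.edges(data=True))
            ],
            columns=["term_a", "term_b", "shared_count", "shared_genes"],
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [
                (t, d["name"], d["n_degs"], d["sum_fc"], d["size_attr"], d["direction"])
                for t, d in sorted(tg.graph.nodes(data=True))
            ],
            columns=["term_id", "name", "n_degs", "sum_fc", "size_attr", "direction"],
        )
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    else:
        raise SeedgoError(f"unknown graph format {fmt!r}; use one of {GRAPH_FORMATS}")


def load_graph(path: str | Path, fmt: str = "graphml") -> TermGraph:
    """Re-read an exported graphml/gml term graph."""
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.relabel_nodes(graph, str)
    elif fmt == "gml":
        graph = nx.read_gml(path, label="label")
    else:
        raise SeedgoError(f"cannot load format {fmt!r}")
    return TermGraph(graph.graph.get("comparison_id", "unknown"), nx.Graph(graph))
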