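"""Readers and writers for the external formats the pipeline touches.

Formats handled
---------------
* per-comparison gene statistics tables (TSV: gene id, log2 fold change,
  raw p-value, BH-adjusted q-value), typically exported from a DESeq2 run;
* protein-interaction edge lists in the STRING ``protein.links`` dialect
  (whitespace separated ``protein1 protein2 combined_score``, score on a
  0-1000 integer scale);
* GO annotations in GAF 2.2 and a minimal OBO 1.2 ontology subset
  (``id``, ``name``, ``namespace``, ``is_a``, ``is_obsolete``).

Everything is validated strictly on load; malformed input raises
:class:`~seedgo.errors.FormatError` rather than propagating silently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: mapping from OBO namespace values to single-letter GAF aspects
NAMESPACE_TO_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}

DEFAULT_COLUMN_MAP = {
    "gene_id": "gene_id",
    "log2fc": "log2fc",
    "p_value": "p_value",
    "q_value": "q_value",
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneStatTable:
    """Per-comparison gene statistics (log2FC, p, BH q) for one contrast.

    ``comparison_id`` labels the contrast, conventionally
    ``"<dose>uM_<timepoint>h"`` so comparisons sort by dose then timepoint.
    """

    comparison_id: str
    data: pd.DataFrame  # columns: gene_id, log2fc, p_value, q_value

    def __post_init__(self) -> None:
        missing = set(DEFAULT_COLUMN_MAP) - set(self.data.columns)
        if missing:
            raise FormatError(f"gene table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    def log2fc_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene_id"], self.data["log2fc"]))

    def q_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene_id"], self.data["q_value"]))


@dataclass
class Interactome:
    """Undirected weighted interaction network with scores in [0, 1].

    The seed protein (the ego of the downstream filter) is designated
    after loading via :meth:`with_seed`; the loader itself is agnostic.
    """

    graph: nx.Graph
    seed_node: str | None = None

    def with_seed(self, seed: str) -> "Interactome":
        return Interactome(self.graph, seed_node=seed)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_set(self) -> set[tuple[str, str, float]]:
        return {
            (*sorted((a, b)), d["score"]) for a, b, d in self.graph.edges(data=True)
        }


@dataclass
class AnnotationMap:
    """term id -> gene-id set, with term metadata where known.

    ``term_meta`` maps term ids to ``(name, aspect)`` tuples; terms
    annotated in a GAF but absent from the ontology stay unknown
    (``name_of`` returns ``"unknown"``).
    """

    term_to_genes: dict[str, set[str]]
    term_meta: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.term_to_genes.items() if not g]
        if empty:
            raise FormatError(f"terms with empty gene sets: {sorted(empty)[:5]}")

    def genes(self) -> set[str]:
        """The annotated universe: every gene carrying >=1 annotation."""
        out: set[str] = set()
        for gs in self.term_to_genes.values():
            out |= gs
        return out

    def name_of(self, term: str) -> str:
        return self.term_meta.get(term, ("unknown", "?"))[0]

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_genes

    def __getitem__(self, term: str) -> set[str]:
        return self.term_to_genes[term]

    def __len__(self) -> int:
        return len(self.term_to_genes)

    def attach_ontology(self, ontology: "OntologyGraph") -> None:
        """Fill term metadata from an ontology in place."""
        for term in self.term_to_genes:
            if term in ontology.graph:
                node = ontology.graph.nodes[term]
                self.term_meta[term] = (
                    node.get("name", "unknown"),
                    NAMESPACE_TO_ASPECT.get(node.get("namespace", ""), "?"),
                )


@dataclass
class OntologyGraph:
    """Directed acyclic is_a graph, edges child -> parent."""

    graph: nx.DiGraph

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (descendants along child->parent edges)."""
        return nx.descendants(self.graph, term)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


# ---------------------------------------------------------------------------
# gene statistics tables
# ---------------------------------------------------------------------------

def read_gene_stat_table(
    path: str | Path,
    comparison_id: str,
    column_map: dict[str, str] | None = None,
) -> GeneStatTable:
    """Read one comparison's gene statistics from a tab-separated file.

    ``column_map`` maps the canonical field names (``gene_id``, ``log2fc``,
    ``p_value``, ``q_value``) to the column headers actually present.
    Rows with unparseable numeric fields are dropped with their indices
    logged; duplicate gene ids or out-of-range p/q are fatal.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["gene_id"]: str})
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df[[cmap[k] for k in DEFAULT_COLUMN_MAP]].copy()
    df.columns = list(DEFAULT_COLUMN_MAP)

    if df.empty:
        logger.warning("%s: gene table is empty (header only)", path)
        return GeneStatTable(comparison_id, df)

    for col in ("log2fc", "p_value", "q_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[["log2fc", "p_value", "q_value"]].isna().any(axis=1)]
    if len(bad):
        logger.warning(
            "%s: dropped %d rows with unparseable numerics (row indices %s)",
            path, len(bad), list(bad[:10]),
        )
        df = df.drop(index=bad).reset_index(drop=True)

    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene ids: {sorted(dupes)[:10]}")
    for col in ("p_value", "q_value"):
        out = df[(df[col] < 0) | (df[col] > 1)]
        if len(out):
            raise FormatError(
                f"{path}: {col} outside [0,1] for genes {list(out['gene_id'][:5])}"
            )
    return GeneStatTable(comparison_id, df.reset_index(drop=True))


def write_gene_stat_table(table: GeneStatTable, path: str | Path) -> None:
    """Write a gene table as TSV at full (round-trippable) float precision."""
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# STRING-dialect interaction links
# ---------------------------------------------------------------------------

def read_string_links(
    path: str | Path,
    score_scale: str = "raw_0_1000",
    aliases: dict[str, str] | str | Path | None = None,
) -> Interactome:
    """Read a STRING ``protein.links``-dialect edge list.

    Scores on the raw 0-1000 integer scale are divided by 1000; an
    optional alias table (two-column TSV or mapping) translates node
    tokens (e.g. STRING protein ids) to gene symbols before edges are
    collapsed. Duplicate undirected edges keep the maximum score;
    self-loops are dropped and counted.
    """
    if score_scale not in ("raw_0_1000", "unit"):
        raise FormatError(f"unknown score_scale {score_scale!r}")
    alias_map: dict[str, str] = {}
    if aliases is not None:
        if isinstance(aliases, (str, Path)):
            adf = pd.read_csv(aliases, sep="\t", header=None, dtype=str)
            alias_map = dict(zip(adf[0], adf[1]))
        else:
            alias_map = dict(aliases)

    graph = nx.Graph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header line auto-detect
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric score {raw!r}")
            if score_scale == "raw_0_1000":
                if not 0 <= score <= 1000:
                    raise FormatError(
                        f"{path}:{lineno}: score {score} outside 0-1000 scale"
                    )
                score /= 1000.0
            elif not 0 <= score <= 1:
                raise FormatError(f"{path}:{lineno}: score {score} outside [0,1]")
            a = alias_map.get(a, a)
            b = alias_map.get(b, b)
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    if n_self:
        logger.warning("%s: dropped %d self-loop lines", path, n_self)
    return Interactome(graph)


def write_string_links(net: Interactome, path: str | Path) -> None:
    """Write edges back to the raw 0-1000 STRING dialect (canonical order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, score in sorted(net.edge_set()):
            fh.write(f"{a} {b} {round(score * 1000)}\n")


# ---------------------------------------------------------------------------
# GAF 2.2 annotations
# ---------------------------------------------------------------------------

def read_gaf(
    path: str | Path,
    aspect_filter: frozenset[str] | set[str] = frozenset({"P"}),
    exclude_not: bool = True,
) -> AnnotationMap:
    """Read GO annotations from a GAF 2.2 file.

    Only rows whose aspect (column 9) is in ``aspect_filter`` survive;
    rows whose qualifier contains ``NOT`` are excluded when
    ``exclude_not``. Gene ids are taken from DB Object ID (column 2).
    """
    term_to_genes: dict[str, set[str]] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                logger.warning("%s:%d: short GAF row skipped", path, lineno)
                continue
            gene, qualifier, go_id, aspect = cols[1], cols[3], cols[4], cols[8]
            if not GO_ID_RE.match(go_id):
                logger.warning("%s:%d: malformed GO id %r skipped", path, lineno, go_id)
                continue
            if aspect not in aspect_filter:
                continue
            if exclude_not and "NOT" in qualifier.split("|"):
                continue
            term_to_genes.setdefault(go_id, set()).add(gene)
            n_rows += 1
    if not term_to_genes:
        raise FormatError(f"{path}: zero annotations survive filtering")
    logger.info("%s: %d annotations over %d terms", path, n_rows, len(term_to_genes))
    return AnnotationMap(term_to_genes)


def write_gaf(annot: AnnotationMap, path: str | Path, db: str = "SEEDGO") -> None:
    """Write an AnnotationMap as minimal GAF 2.2 (aspect from metadata, default P)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(annot.term_to_genes):
            aspect = annot.term_meta.get(term, ("", "P"))[1]
            if aspect == "?":
                aspect = "P"
            for gene in sorted(annot.term_to_genes[term]):
                cols = [
                    db, gene, gene, "involved_in", term, "SEEDGO:ref", "IEA", "",
                    aspect, "", "", "gene", "taxon:10090", "20240101", db, "", "",
                ]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------

def read_obo_minimal(path: str | Path) -> OntologyGraph:
    """Read the minimal OBO subset: id, name, namespace, is_a, is_obsolete.

    Obsolete terms are dropped; any is_a cycle is fatal. Relations other
    than is_a (part_of, regulates, ...) are ignored.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if not GO_ID_RE.match(node):
            logger.warning("%s: non-GO term id %r skipped", path, node)
            continue
        graph.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    n_other = 0
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            n_other += 1
            continue
        if child in graph and parent in graph:
            graph.add_edge(child, parent)
    if n_other:
        logger.info("%s: ignored %d non-is_a relations", path, n_other)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise FormatError(f"is_a cycle involving term {cycle[0][0]}")
    return OntologyGraph(graph)


def write_obo_minimal(onto: OntologyGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: seedgo-synthetic\n")
        for term in sorted(onto.graph.nodes):
            node = onto.graph.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {node.get('name', term)}\n")
            fh.write(f"namespace: {node.get('namespace', 'biological_process')}\n")
            for parent in sorted(onto.graph.successors(term)):
                pname = onto.graph.nodes[parent].get("name", parent)
                fh.write(f"is_a: {parent} ! {pname}\n")


def propagate_annotations(annot: AnnotationMap, ontology: OntologyGraph) -> AnnotationMap:
    """Apply the true-path rule: annotate each gene to all is_a ancestors.

    Propagation stays within the annotated term's namespace. Terms absent
    from the ontology are kept unpropagated with a warning. Idempotent.
    """
    new: dict[str, set[str]] = {t: set(g) for t, g in annot.term_to_genes.items()}
    meta = dict(annot.term_meta)
    for term, genes in annot.term_to_genes.items():
        if term not in ontology:
            logger.warning("term %s not in ontology; kept unpropagated", term)
            continue
        ns = ontology.graph.nodes[term].get("namespace", "")
        for anc in ontology.ancestors(term):
            if ontology.graph.nodes[anc].get("namespace", "") != ns:
                continue
            new.setdefault(anc, set()).update(genes)
            if anc not in meta:
                node = ontology.graph.nodes[anc]
                meta[anc] = (
                    node.get("name", "unknown"),
                    NAMESPACE_TO_ASPECT.get(node.get("namespace", ""), "?"),
                )
    return AnnotationMap(new, meta)
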