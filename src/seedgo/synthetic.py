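"""Seeded synthetic study generator with planted enrichment.

Emulates the inputs the pipeline consumes — a gene universe, a term
system of overlapping gene sets under a shallow is_a hierarchy, an
interactome centred on a high-degree seed protein, and six comparison
tables (three doses by two timepoints) — with a known ground truth:
a handful of planted terms whose interactor genes are differentially
expressed at an elevated rate. Every output is a pure function of
(config, seed), and the on-disk bundle uses exactly the external formats
the readers in :mod:`seedgo.io_formats` validate.

The generator produces the gene statistics tables directly (q-values by
construction below/above the DEG threshold) rather than simulating read
counts: the pipeline's contract starts at the gene table, so the
simulation targets that table's semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import SeedgoError
from .io_formats import (
    AnnotationMap,
    GeneStatTable,
    Interactome,
    OntologyGraph,
    write_gaf,
    write_gene_stat_table,
    write_obo_minimal,
    write_string_links,
)

import networkx as nx
import pandas as pd

SEED_NODE = "SEED"

DEFAULT_COMPARISONS = (
    (0.5, 48.0), (5.0, 48.0), (10.0, 48.0),
    (0.5, 96.0), (5.0, 96.0), (10.0, 96.0),
)


def comparison_label(dose: float, timepoint: float) -> str:
    return f"{dose:g}uM_{timepoint:g}h"


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults encode the emulated design: a 2,000-gene universe, 120
    overlapping BP-like terms (sizes log-uniform in 5-200), 5 planted
    terms enriched five-fold over a 10% baseline DEG probability, a seed
    protein with 400 interactors, and the 3-dose x 2-timepoint layout.
    """

    rng_seed: int = 0
    n_genes: int = 2000
    n_terms: int = 120
    term_size_range: tuple[int, int] = (5, 200)
    n_parents: int = 10
    n_planted_terms: int = 5
    enrichment_factor: float = 5.0       # rho: DEG-probability multiplier in planted terms
    deg_fraction: float = 0.10           # pi0: baseline P(gene is DEG)
    seed_degree: int = 400
    n_background_edges: int = 4000
    min_planted_overlap: int = 20        # planted terms must carry >= this many interactors
    fc_mu: float = 1.0                   # mean |log2FC| of DEGs
    fc_sigma: float = 0.5
    null_fc_sigma: float = 0.1
    fc_mu_scale: dict[str, float] = field(default_factory=dict)  # per-comparison multiplier
    comparisons: tuple[tuple[float, float], ...] = DEFAULT_COMPARISONS

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_terms", "n_parents", "n_planted_terms", "seed_degree"):
            if getattr(self, name) <= 0:
                raise SeedgoError(f"{name} must be positive")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise SeedgoError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise SeedgoError("term size bound exceeds the gene universe")
        if self.enrichment_factor < 1:
            raise SeedgoError("enrichment_factor must be >= 1")
        if not 0 < self.deg_fraction < 1:
            raise SeedgoError("deg_fraction must be in (0,1)")
        if self.seed_degree >= self.n_genes:
            raise SeedgoError("seed_degree must be below n_genes")
        labels = [comparison_label(d, t) for d, t in self.comparisons]
        if len(set(labels)) != len(labels):
            raise SeedgoError("comparison labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [comparison_label(d, t) for d, t in self.comparisons]

    @classmethod
    def scaled(cls, rng_seed: int = 0, n_genes: int = 2000,
               n_terms: int = 120, **overrides) -> "SyntheticConfig":
        """A config with size-dependent defaults rescaled to ``n_genes``.

        Keeps the default proportions (20% of genes interact with the
        seed, two background edges per gene, term sizes up to a tenth of
        the universe) so small universes stay internally consistent.
        """
        defaults = dict(
            rng_seed=rng_seed,
            n_genes=n_genes,
            n_terms=n_terms,
            seed_degree=max(10, n_genes // 5),
            n_background_edges=2 * n_genes,
            term_size_range=(5, max(10, n_genes // 10)),
            min_planted_overlap=max(3, n_genes // 100),
            n_planted_terms=min(5, max(1, n_terms // 6)),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Ground truth: what was planted, who is a DEG, who interacts."""

    planted_terms: list[str]
    interactors: list[str]
    boosted_genes: list[str]              # planted-term genes that are interactors
    deg_sets: dict[str, list[str]]        # comparison -> true DEG ids


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    annotations: AnnotationMap
    ontology: OntologyGraph
    interactome: Interactome
    tables: dict[str, GeneStatTable]
    truth: SyntheticTruth
    paths: dict[str, str] | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_annotations(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationMap, OntologyGraph]:
    """Sample the term system and its shallow is_a hierarchy.

    Term sizes are log-uniform within ``term_size_range``; each term's
    genes are drawn without replacement from the universe. Leaf terms are
    grouped under ``n_parents`` parent terms (plus one root) so the
    true-path propagation path is exercisable.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    genes = np.array(_gene_ids(config.n_genes))
    lo, hi = config.term_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), config.n_terms)).astype(int)
    sizes = np.clip(sizes, lo, hi)

    term_to_genes: dict[str, set[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    graph = nx.DiGraph()
    root = "GO:0900000"
    graph.add_node(root, name="synthetic biological process root",
                   namespace="biological_process")
    parents = [f"GO:{900001 + j:07d}" for j in range(config.n_parents)]
    for j, pid in enumerate(parents):
        graph.add_node(pid, name=f"synthetic parent process {j + 1}",
                       namespace="biological_process")
        graph.add_edge(pid, root)
    for i in range(config.n_terms):
        term = f"GO:{i + 1:07d}"
        members = rng.choice(genes, size=int(sizes[i]), replace=False)
        term_to_genes[term] = set(members.tolist())
        meta[term] = (f"synthetic process {i + 1}", "P")
        graph.add_node(term, name=meta[term][0], namespace="biological_process")
        graph.add_edge(term, parents[i % config.n_parents])
    return AnnotationMap(term_to_genes, meta), OntologyGraph(graph)


def generate_interactome(
    config: SyntheticConfig,
    universe: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> Interactome:
    """Build the seed-centred interactome.

    The seed node gets exactly ``seed_degree`` interactors with
    confidence scores uniform on the 400-1000 STRING grid (all at or
    above the default 0.4 threshold, so thresholding recovers the planted
    set exactly); ``n_background_edges`` random gene-gene edges with
    scores on the 150-1000 grid exercise the threshold downstream.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    genes = np.array(_gene_ids(config.n_genes) if universe is None else universe)
    graph = nx.Graph()
    interactors = rng.choice(genes, size=config.seed_degree, replace=False)
    for g, s in zip(interactors, rng.integers(400, 1001, config.seed_degree)):
        graph.add_edge(SEED_NODE, str(g), score=s / 1000.0)
    n_bg = 0
    while n_bg < config.n_background_edges:
        a, b = rng.choice(genes, size=2, replace=False)
        score = int(rng.integers(150, 1001)) / 1000.0
        if graph.has_edge(str(a), str(b)):
            graph[str(a)][str(b)]["score"] = max(graph[str(a)][str(b)]["score"], score)
        else:
            graph.add_edge(str(a), str(b), score=score)
        n_bg += 1
    return Interactome(graph, seed_node=SEED_NODE)


def _choose_planted(
    config: SyntheticConfig,
    annot: AnnotationMap,
    interactors: set[str],
    rng: np.random.Generator,
) -> list[str]:
    """Pick planted terms among those with enough interactor members.

    A planted effect on a term sharing almost no genes with the seed's
    interactors would be invisible to the interactor-filtered query, so
    eligibility requires ``min_planted_overlap`` interactor members;
    if too few terms qualify, the largest-overlap terms are taken.
    """
    overlap = {t: len(annot[t] & interactors) for t in sorted(annot.term_to_genes)}
    eligible = [t for t, o in overlap.items() if o >= config.min_planted_overlap]
    if len(eligible) >= config.n_planted_terms:
        chosen = rng.choice(np.array(eligible), size=config.n_planted_terms, replace=False)
        return sorted(str(t) for t in chosen)
    ranked = sorted(overlap, key=lambda t: (-overlap[t], t))
    return sorted(ranked[: config.n_planted_terms])


def generate_deg_table(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    comparison: str,
    rng: np.random.Generator,
) -> GeneStatTable:
    """Simulate one comparison's gene statistics table.

    Genes in a planted term that are also interactors are DEGs with
    probability min(1, rho * pi0); everyone else with pi0. DEG q-values
    are uniform below 0.05, non-DEG q-values uniform above; raw p is
    q times an independent uniform so p <= q always. DEG log2FCs are
    Normal(sign * mu, sigma) with Bernoulli(1/2) sign; non-DEG log2FCs
    are tight noise around zero.
    """
    n = config.n_genes
    genes = _gene_ids(n)
    boosted = np.isin(genes, truth.boosted_genes)
    p_deg = np.where(boosted, min(1.0, config.enrichment_factor * config.deg_fraction),
                     config.deg_fraction)
    is_deg = rng.random(n) < p_deg
    q = np.where(is_deg, rng.uniform(0.0, 0.05, n), rng.uniform(0.05, 1.0, n))
    p = q * rng.random(n)
    mu = config.fc_mu * config.fc_mu_scale.get(comparison, 1.0)
    sign = rng.integers(0, 2, n) * 2 - 1
    fc_deg = sign * mu + rng.normal(0.0, config.fc_sigma, n)
    fc_null = rng.normal(0.0, config.null_fc_sigma, n)
    fc = np.where(is_deg, fc_deg, fc_null)
    df = pd.DataFrame({"gene_id": genes, "log2fc": fc, "p_value": p, "q_value": q})
    truth.deg_sets[comparison] = sorted(np.array(genes)[is_deg].tolist())
    return GeneStatTable(comparison, df)


def generate_study(
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> SyntheticStudy:
    """Generate the full input bundle (optionally written to ``out_dir``).

    The draw order is fixed (annotations, interactome, planted-term
    choice, then tables in configured comparison order), so the bundle is
    a pure function of (config, rng_seed) and two runs are byte-identical.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.rng_seed)
    annot, onto = generate_annotations(config, rng)
    net = generate_interactome(config, _gene_ids(config.n_genes), rng)
    interactors = set(net.graph[SEED_NODE])
    planted = _choose_planted(config, annot, interactors, rng)
    boosted: set[str] = set()
    for t in planted:
        boosted |= annot[t] & interactors
    truth = SyntheticTruth(
        planted_terms=planted,
        interactors=sorted(interactors),
        boosted_genes=sorted(boosted),
        deg_sets={},
    )
    tables = {
        label: generate_deg_table(config, truth, label, rng)
        for label in config.labels
    }
    study = SyntheticStudy(config, annot, onto, net, tables, truth)
    if out_dir is not None:
        study.paths = write_study(study, out_dir, force=force)
    return study


def write_study(study: SyntheticStudy, out_dir: str | Path, force: bool = False) -> dict[str, str]:
    """Write the bundle in the pipeline's external formats plus truth JSON."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise SeedgoError(f"output directory {out} is not empty (use force=True)")
    (out / "tables").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for label, table in study.tables.items():
        p = out / "tables" / f"{label}.tsv"
        write_gene_stat_table(table, p)
        paths[f"table:{label}"] = str(p)
    write_string_links(study.interactome, out / "links.txt")
    paths["links"] = str(out / "links.txt")
    write_gaf(study.annotations, out / "annotations.gaf")
    paths["gaf"] = str(out / "annotations.gaf")
    write_obo_minimal(study.ontology, out / "ontology.obo")
    paths["obo"] = str(out / "ontology.obo")
    truth_path = out / "truth.json"
    cfg = asdict(study.config)
    cfg["comparisons"] = [list(c) for c in study.config.comparisons]
    cfg["term_size_range"] = list(study.config.term_size_range)
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump({"config": cfg, **asdict(study.truth)}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = str(truth_path)
    return paths
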