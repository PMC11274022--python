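"""End-to-end orchestration: DEG calls -> ego filter -> enrichment ->
common terms -> score matrices -> clustering -> term networks.

Deterministic results live under ``<out>/results/``; the run manifest
(config echo, input checksums, per-stage counts, timestamps) and log go
under ``<out>/meta/`` so that two runs on identical inputs produce
byte-identical results trees even though the manifest records wall-clock
times. Stages read their inputs from the previous stage's files, so each
is individually re-runnable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import choose_cluster_count, fit_glm_log_link, hcluster_rows
from .config import PipelineConfig
from .ego_network import (
    DegInteractorSet,
    call_degs,
    extract_ego_interactors,
    intersect_deg_interactors,
)
from .enrichment import (
    common_terms,
    overrepresent,
    read_enrichment_table,
    write_enrichment_table,
)
from .errors import SeedgoError
from .io_formats import (
    propagate_annotations,
    read_gaf,
    read_gene_stat_table,
    read_obo_minimal,
    read_string_links,
)
from .scoring import SCORE_KINDS, build_score_matrix
from .term_network import build_term_graph, export_graph

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _apply_fc_scale(deg_sets: dict[str, DegInteractorSet], fc_scale: str):
    """Optionally move log2 fold changes to a signed linear scale.

    ``linear`` maps l to sign(l) * 2**|l| (a 2-fold change becomes +/-2).
    """
    if fc_scale == "log2":
        return deg_sets
    out = {}
    for label, dis in deg_sets.items():
        fc = {g: (1 if v >= 0 else -1) * 2 ** abs(v) for g, v in dis.log2fc.items()}
        out[label] = DegInteractorSet(label, set(dis.genes), fc)
    return out


def _timepoint_groups(config: PipelineConfig) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for c in config.comparisons:
        groups.setdefault(f"{c.timepoint:g}h", []).append(c.label)
    return groups


class PipelineRun:
    """Stage-by-stage execution with a manifest accumulated along the way."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path, force: bool = False):
        self.config = config
        self.out = Path(out_dir)
        self.results = self.out / "results"
        self.meta = self.out / "meta"
        if self.results.exists() and any(self.results.iterdir()) and not force:
            raise SeedgoError(
                f"output directory {self.results} already has results (use --force)"
            )
        self.results.mkdir(parents=True, exist_ok=True)
        self.meta.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "config": {
                k: v for k, v in vars(config).items() if k != "comparisons"
            },
            "comparisons": [vars(c) for c in config.comparisons],
            "inputs": {},
            "stages": {},
            "started": _dt.datetime.now().isoformat(),
        }
        for c in config.comparisons:
            self.manifest["inputs"][c.label] = _sha256(c.path)
        for key in ("interactome_path", "gaf_path", "obo_path"):
            self.manifest["inputs"][key] = _sha256(getattr(config, key))

    # -- stage 1: DEG calling + ego filter ---------------------------------

    def stage_degs(self) -> dict[str, DegInteractorSet]:
        cfg = self.config
        net = read_string_links(cfg.interactome_path, cfg.score_scale, cfg.alias_path)
        net = net.with_seed(cfg.seed_node)
        interactors = extract_ego_interactors(net, cfg.seed_node, cfg.min_score)
        deg_dir = self.results / "deg_interactors"
        deg_dir.mkdir(exist_ok=True)
        counts = {}
        out: dict[str, DegInteractorSet] = {}
        for c in cfg.comparisons:
            table = read_gene_stat_table(c.path, c.label)
            call = call_degs(table, cfg.alpha)
            dis = intersect_deg_interactors(call, interactors, table)
            out[c.label] = dis
            rows = sorted(dis.genes)
            pd.DataFrame(
                {"gene_id": rows, "log2fc": [dis.log2fc[g] for g in rows]}
            ).to_csv(deg_dir / f"{c.label}.tsv", sep="\t", index=False)
            counts[c.label] = {
                "degs": len(call.degs), "up": len(call.up), "down": len(call.down),
                "deg_interactors": len(dis),
            }
            logger.info(
                "%s: %d DEGs (%d up / %d down), %d DEG-interactors",
                c.label, len(call.degs), len(call.up), len(call.down), len(dis),
            )
        self.manifest["stages"]["degs"] = {
            "interactors": len(interactors.members), "per_comparison": counts,
        }
        logger.info("seed %s: %d interactors at score >= %g; network %d nodes / %d edges",
                    cfg.seed_node, len(interactors.members), cfg.min_score,
                    net.n_nodes, net.n_edges)
        return out

    def _load_deg_interactors(self) -> dict[str, DegInteractorSet]:
        deg_dir = self.results / "deg_interactors"
        out = {}
        for c in self.config.comparisons:
            p = deg_dir / f"{c.label}.tsv"
            if not p.exists():
                raise SeedgoError(f"missing intermediate {p}; run the ego stage first")
            df = pd.read_csv(p, sep="\t", dtype={"gene_id": str})
            fc = dict(zip(df["gene_id"], df["log2fc"]))
            out[c.label] = DegInteractorSet(c.label, set(fc), fc)
        return out

    def _load_annotations(self):
        cfg = self.config
        annot = read_gaf(cfg.gaf_path)
        onto = read_obo_minimal(cfg.obo_path)
        annot.attach_ontology(onto)
        if cfg.propagate:
            annot = propagate_annotations(annot, onto)
        return annot

    def _universe(self, annot) -> set[str] | None:
        if self.config.universe_mode == "custom":
            with open(self.config.custom_universe_path, encoding="utf-8") as fh:
                return {line.strip() for line in fh if line.strip()}
        return None

    # -- stage 2: enrichment + common terms --------------------------------

    def stage_enrichment(self, deg_sets=None):
        cfg = self.config
        deg_sets = deg_sets or self._load_deg_interactors()
        annot = self._load_annotations()
        universe = self._universe(annot)
        enr_dir = self.results / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        tables = {}
        for label, dis in deg_sets.items():
            et = overrepresent(dis, annot, universe, cfg.alpha, cfg.min_term_size)
            write_enrichment_table(et, enr_dir / f"{label}.tsv")
            tables[label] = et
            logger.info("%s: %d terms tested, %d significant at q < %g",
                        label, len(et), len(et.significant_terms()), cfg.alpha)
        groups = {"all": [c.label for c in cfg.comparisons]}
        groups.update(_timepoint_groups(cfg))
        common_dir = self.results / "common_terms"
        common_dir.mkdir(exist_ok=True)
        commons = {}
        for gname, labels in groups.items():
            cts = common_terms([tables[l] for l in labels], gname)
            commons[gname] = cts
            pd.DataFrame({"term_id": sorted(cts.terms)}).to_csv(
                common_dir / f"{gname}.tsv", sep="\t", index=False
            )
            logger.info("grouping %s (%s): %d common terms",
                        gname, ",".join(labels), len(cts.terms))
        self.manifest["stages"]["enrichment"] = {
            "tested": {l: len(t) for l, t in tables.items()},
            "significant": {l: len(t.significant_terms()) for l, t in tables.items()},
            "common_terms": {g: len(c.terms) for g, c in commons.items()},
        }
        return tables, commons

    def _load_common(self) -> dict[str, set[str]]:
        common_dir = self.results / "common_terms"
        if not common_dir.exists():
            raise SeedgoError("missing common-term outputs; run the enrich stage first")
        out = {}
        for p in sorted(common_dir.glob("*.tsv")):
            df = pd.read_csv(p, sep="\t", dtype=str)
            out[p.stem] = set(df["term_id"]) if len(df) else set()
        return out

    # -- stage 3: score matrices -------------------------------------------

    def stage_scores(self, deg_sets=None, commons=None):
        deg_sets = _apply_fc_scale(deg_sets or self._load_deg_interactors(),
                                   self.config.fc_scale)
        commons = commons or self._load_common()
        annot = self._load_annotations()
        universe = self._universe(annot)
        score_dir = self.results / "scores"
        score_dir.mkdir(exist_ok=True)
        matrices = {}
        counts = {}
        for gname, terms in commons.items():
            term_set = terms.terms if hasattr(terms, "terms") else terms
            if not term_set:
                logger.warning("grouping %s has no common terms; no score matrix", gname)
                continue
            for kind in SCORE_KINDS:
                sm = build_score_matrix(term_set, deg_sets, annot, kind, universe)
                sm.values.to_csv(score_dir / f"{gname}_{kind}.tsv", sep="\t",
                                 index_label="term_id")
                sm.to_long().to_csv(score_dir / f"{gname}_{kind}_long.tsv",
                                    sep="\t", index=False)
                matrices[(gname, kind)] = sm
            counts[gname] = len(term_set)
        self.manifest["stages"]["scores"] = counts
        return matrices

    # -- stage 4: clustering ------------------------------------------------

    def stage_clustering(self, matrices=None):
        cfg = self.config
        if matrices is None:
            matrices = {}
            score_dir = self.results / "scores"
            if not score_dir.exists():
                raise SeedgoError("missing score matrices; run the score stage first")
            for p in sorted(score_dir.glob("*_*.tsv")):
                if p.stem.endswith("_long"):
                    continue
                gname, kind = p.stem.rsplit("_", 1)
                df = pd.read_csv(p, sep="\t", index_col="term_id")
                matrices[(gname, kind)] = df
        clus_dir = self.results / "clusters"
        clus_dir.mkdir(exist_ok=True)
        chosen = {}
        for (gname, kind), matrix in sorted(matrices.items()):
            df = matrix.values if hasattr(matrix, "kind") else matrix
            if len(df) < 2:
                logger.warning("matrix %s_%s has <2 rows; clustering skipped", gname, kind)
                continue
            dend = hcluster_rows(df, cfg.distance, cfg.linkage)
            n_merges = dend.n_leaves - 1
            if n_merges >= 2 and dend.heights.max() > 0:
                fit = fit_glm_log_link(dend.heights)
                assign = choose_cluster_count(dend, fit, cfg.tol_rel)
                diag = {
                    "beta0": fit.beta0, "beta1": fit.beta1,
                    "converged": fit.converged, "n_iter": fit.n_iter,
                    "i_star": assign.i_star, "k": assign.k,
                }
            else:
                assign = choose_cluster_count(dend, _trivial_fit(dend), cfg.tol_rel)
                diag = {"beta0": None, "beta1": None, "converged": True,
                        "n_iter": 0, "i_star": assign.i_star, "k": assign.k}
            pd.DataFrame(
                sorted(assign.assignment.items()), columns=["term_id", "cluster"]
            ).to_csv(clus_dir / f"{gname}_{kind}.tsv", sep="\t", index=False)
            with open(clus_dir / f"{gname}_{kind}.json", "w", encoding="utf-8") as fh:
                json.dump(diag, fh, indent=1, sort_keys=True)
                fh.write("\n")
            chosen[f"{gname}_{kind}"] = assign.k
            logger.info("clustering %s_%s: k = %d (i* = %s)", gname, kind,
                        assign.k, assign.i_star)
        self.manifest["stages"]["clustering"] = chosen
        return chosen

    # -- stage 5: term networks ---------------------------------------------

    def stage_networks(self, deg_sets=None, commons=None):
        cfg = self.config
        deg_sets = _apply_fc_scale(deg_sets or self._load_deg_interactors(),
                                   cfg.fc_scale)
        commons = commons or self._load_common()
        annot = self._load_annotations()
        universe = self._universe(annot)
        terms = commons.get("all")
        term_set = terms.terms if hasattr(terms, "terms") else (terms or set())
        net_dir = self.results / "network"
        net_dir.mkdir(exist_ok=True)
        sizes = {}
        if not term_set:
            logger.warning("no common terms across all comparisons; no term networks")
            self.manifest["stages"]["networks"] = sizes
            return {}
        graphs = {}
        for c in cfg.comparisons:
            tg = build_term_graph(term_set, deg_sets[c.label], annot, universe,
                                  cfg.size_coeff, cfg.balance_tol)
            export_graph(tg, net_dir / f"{c.label}.graphml", "graphml")
            export_graph(tg, net_dir / f"{c.label}.tsv", "tsv")
            graphs[c.label] = tg
            sizes[c.label] = {"nodes": tg.n_nodes, "edges": tg.n_edges}
            logger.info("term graph %s: %d nodes, %d edges", c.label,
                        tg.n_nodes, tg.n_edges)
        self.manifest["stages"]["networks"] = sizes
        return graphs

    def finish(self) -> None:
        self.manifest["finished"] = _dt.datetime.now().isoformat()
        with open(self.meta / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def _trivial_fit(dend):
    """Degenerate-fit stand-in for matrices too small (or flat) to model."""
    import numpy as np
    from .clustering import GlmFit
    h = dend.heights
    return GlmFit(0.0, 0.0, np.asarray(h, float), np.zeros(len(h)), True, 0)


def run_pipeline(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Run every stage in order; write the manifest even on failure."""
    run = PipelineRun(config, out_dir, force=force)
    try:
        deg_sets = run.stage_degs()
        _, commons = run.stage_enrichment(deg_sets)
        matrices = run.stage_scores(deg_sets, commons)
        run.stage_clustering(matrices)
        run.stage_networks(deg_sets, commons)
    except Exception as exc:
        run.manifest["error"] = f"{type(exc).__name__}: {exc}"
        run.finish()
        raise
    run.finish()
    return run.out
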