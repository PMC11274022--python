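import json
import logging
import math

import numpy as np
import pytest

from seedgo.io_formats import read_gaf, read_gene_stat_table, read_obo_minimal, \
    read_string_links
from seedgo.synthetic import SyntheticConfig, generate_annotations, \
    generate_interactome, generate_study


class TestAnnotations:
    def test_sizes_within_bounds(self, small_cfg):
        annot, onto = generate_annotations(small_cfg)
        lo, hi = small_cfg.term_size_range
        sizes = [len(g) for g in annot.term_to_genes.values()]
        leaf_sizes = [len(annot[t]) for t in annot.term_to_genes]
        assert len(annot) == small_cfg.n_terms
        assert min(leaf_sizes) >= lo and max(leaf_sizes) <= hi

    def test_same_seed_same_map(self, small_cfg):
        a1, _ = generate_annotations(small_cfg)
        a2, _ = generate_annotations(small_cfg)
        assert a1.term_to_genes == a2.term_to_genes

    def test_size_distribution_tracks_log_uniform(self):
        """Across seeds, sizes stay in range and centre near the geometric
        mean of the bounds (log-uniform sampling)."""
        sizes = []
        for s in range(30):
            cfg = SyntheticConfig(rng_seed=s, n_genes=400, n_terms=40,
                                  term_size_range=(5, 200), seed_degree=80)
            annot, _ = generate_annotations(cfg)
            sizes += [len(g) for g in annot.term_to_genes.values()]
        gm = math.sqrt(5 * 200)
        assert min(sizes) >= 5 and max(sizes) <= 200
        assert gm / 2 <= np.median(sizes) <= gm * 2

    def test_hierarchy_supports_propagation(self, small_cfg):
        from seedgo.io_formats import propagate_annotations

        annot, onto = generate_annotations(small_cfg)
        prop = propagate_annotations(annot, onto)
        assert len(prop) > len(annot)  # parents gained annotations
        again = propagate_annotations(prop, onto)
        assert prop.term_to_genes == again.term_to_genes


class TestInteractome:
    def test_seed_degree_exact(self, small_cfg):
        net = generate_interactome(small_cfg)
        assert net.graph.degree("SEED") == small_cfg.seed_degree

    def test_all_seed_edges_above_default_threshold(self, small_cfg):
        net = generate_interactome(small_cfg)
        scores = [net.graph["SEED"][n]["score"] for n in net.graph["SEED"]]
        assert min(scores) >= 0.4

    def test_impossible_threshold_empty(self, small_cfg):
        from seedgo.ego_network import extract_ego_interactors

        net = generate_interactome(small_cfg)
        assert extract_ego_interactors(net, "SEED", 1.0).members <= set(
            net.graph["SEED"]
        )
        high = [n for n in net.graph["SEED"] if net.graph["SEED"][n]["score"] >= 1.0]
        assert len(extract_ego_interactors(net, "SEED", 1.0).members) == len(high)


class TestDegTables:
    def test_q_separates_degs_by_construction(self, small_cfg):
        study = generate_study(small_cfg)
        for label, table in study.tables.items():
            degs = set(study.truth.deg_sets[label])
            df = table.data
            is_deg = df["gene_id"].isin(degs)
            assert (df.loc[is_deg, "q_value"] < 0.05).all()
            assert (df.loc[~is_deg, "q_value"] >= 0.05).all()
            assert (df["p_value"] <= df["q_value"]).all()

    def test_deg_count_matches_binomial_mixture(self):
        """DEG count within 3 sigma of the two-group binomial expectation."""
        cfg = SyntheticConfig(rng_seed=2)
        study = generate_study(cfg)
        b = len(study.truth.boosted_genes)
        n0 = cfg.n_genes - b
        p0, p1 = cfg.deg_fraction, min(1, cfg.enrichment_factor * cfg.deg_fraction)
        mean = n0 * p0 + b * p1
        sd = math.sqrt(n0 * p0 * (1 - p0) + b * p1 * (1 - p1))
        for label in study.config.labels:
            count = len(study.truth.deg_sets[label])
            assert abs(count - mean) < 3 * sd

    def test_null_enrichment_factor_gives_equal_rates(self):
        """rho = 1: planted and background DEG rates indistinguishable
        (pooled two-proportion z over seeds)."""
        k_b = n_b = k_o = n_o = 0
        for s in range(10):
            cfg = SyntheticConfig(rng_seed=s, enrichment_factor=1.0,
                                  n_genes=500, n_terms=30, term_size_range=(5, 100),
                                  seed_degree=100, min_planted_overlap=5)
            study = generate_study(cfg)
            boosted = set(study.truth.boosted_genes)
            for label in study.config.labels:
                degs = set(study.truth.deg_sets[label])
                k_b += len(degs & boosted)
                n_b += len(boosted)
                k_o += len(degs - boosted)
                n_o += cfg.n_genes - len(boosted)
        p_pool = (k_b + k_o) / (n_b + n_o)
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / n_b + 1 / n_o))
        z = (k_b / n_b - k_o / n_o) / se
        assert abs(z) < 3

    def test_effect_size_monotone_in_rho(self):
        """Planted-term -log10 q grows with the enrichment factor.

        The mean is used as the location summary: BH caps most
        planted-cell q-values at exactly 1 under weak or null effects, so
        a median saturates at 0 and cannot order the effect sizes.
        """
        from seedgo.ego_network import call_degs, extract_ego_interactors, \
            intersect_deg_interactors
        from seedgo.enrichment import overrepresent

        loc = []
        for rho in (1.0, 2.0, 5.0):
            qs = []
            for s in range(6):
                cfg = SyntheticConfig(rng_seed=s, enrichment_factor=rho)
                study = generate_study(cfg)
                ia = extract_ego_interactors(study.interactome, "SEED", 0.4)
                table = study.tables["10uM_96h"]
                dis = intersect_deg_interactors(call_degs(table), ia, table)
                et = overrepresent(dis, study.annotations)
                rec = et.records.set_index("term_id")
                qs += (-np.log10(rec.loc[study.truth.planted_terms, "q"] + 1e-300)).tolist()
            loc.append(np.mean(qs))
        assert loc[0] < loc[1] < loc[2]


class TestBundle:
    def test_bundle_is_byte_deterministic(self, small_cfg, tmp_path):
        p1, p2 = tmp_path / "b1", tmp_path / "b2"
        generate_study(small_cfg, out_dir=p1)
        generate_study(small_cfg, out_dir=p2)
        files1 = sorted(f.relative_to(p1) for f in p1.rglob("*") if f.is_file())
        files2 = sorted(f.relative_to(p2) for f in p2.rglob("*") if f.is_file())
        assert files1 == files2
        for f in files1:
            assert (p1 / f).read_bytes() == (p2 / f).read_bytes()

    def test_six_tables_named_by_design(self, tmp_path):
        cfg = SyntheticConfig(rng_seed=0, n_genes=200, n_terms=10,
                              term_size_range=(5, 40), seed_degree=40,
                              n_background_edges=100, min_planted_overlap=3,
                              n_planted_terms=2)
        study = generate_study(cfg, out_dir=tmp_path / "b")
        names = sorted(p.stem for p in (tmp_path / "b" / "tables").glob("*.tsv"))
        assert names == sorted(cfg.labels)
        assert "48h" in names[0] or "96h" in names[0]

    def test_refuses_nonempty_dir_without_force(self, small_cfg, tmp_path):
        from seedgo.errors import SeedgoError

        out = tmp_path / "b"
        generate_study(small_cfg, out_dir=out)
        with pytest.raises(SeedgoError, match="force"):
            generate_study(small_cfg, out_dir=out)
        generate_study(small_cfg, out_dir=out, force=True)  # explicit force ok

    def test_bundle_parses_through_readers_without_warnings(
        self, small_cfg, tmp_path, caplog
    ):
        """Format fidelity: every generated file round-trips through the
        strict readers with zero warnings, reproducing the in-memory study."""
        study = generate_study(small_cfg, out_dir=tmp_path / "b")
        with caplog.at_level(logging.WARNING):
            net = read_string_links(study.paths["links"])
            annot = read_gaf(study.paths["gaf"])
            onto = read_obo_minimal(study.paths["obo"])
            tables = {
                label: read_gene_stat_table(study.paths[f"table:{label}"], label)
                for label in study.config.labels
            }
        assert not caplog.records
        assert net.edge_set() == study.interactome.edge_set()
        assert annot.term_to_genes == study.annotations.term_to_genes
        assert set(study.annotations.term_to_genes) <= set(onto.graph.nodes)
        for label, table in tables.items():
            assert list(table.data["gene_id"]) == list(study.tables[label].data["gene_id"])

    def test_truth_json_consistent(self, small_cfg, tmp_path):
        study = generate_study(small_cfg, out_dir=tmp_path / "b")
        truth = json.loads((tmp_path / "b" / "truth.json").read_text())
        assert truth["planted_terms"] == study.truth.planted_terms
        assert set(truth["deg_sets"]) == set(study.config.labels)
        assert set(truth["boosted_genes"]) <= set(truth["interactors"]) | set()
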