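"""Generators: construction guarantees, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest

from rhizotox.architecture import architecture_table, parse_gene_models
from rhizotox.biomarker import ddct_fold_change, leave_one_out_panels
from rhizotox.expression import per_stress_fc_table
from rhizotox.motifs import BUILTIN_MOTIFS, gene_fraction_with_motif, has_motif
from rhizotox.stats import kruskal_wallis
from rhizotox.synthetic import (ConfigurationError, SyntheticConfig,
                                default_planted_counts, edge_list_lines,
                                generate_ct_table, generate_expression,
                                generate_gene_models, generate_network,
                                generate_ortholog_pairs, generate_promoters)


class TestExpressionGenerator:
    def test_truth_table_counts_exact(self):
        config = SyntheticConfig(n_genes=500, planted_counts={"GSR_up": 50},
                                 seed=1)
        _, truth = generate_expression(config)
        assert (truth["label"] == "GSR_up").sum() == 50
        assert (truth["label"] == "filler").sum() == 450

    def test_noise_free_background_fc_within_bounds(self):
        config = SyntheticConfig(n_genes=50, planted_counts={"background": 20},
                                 noise_sd=0.0, seed=3)
        dataset, truth = generate_expression(config)
        table = per_stress_fc_table(dataset)
        fc = table.pivot(index="gene", columns="stress", values="fc")
        bg = truth.index[truth["label"] == "background"]
        assert (fc.loc[bg].abs().to_numpy() <= 1.2).all()

    def test_planted_counts_exceeding_n_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_genes=10, planted_counts={"GSR_up": 11})

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(replicates=1)

    def test_determinism_byte_identical(self, tmp_path):
        config = SyntheticConfig(n_genes=80, noise_sd=0.05,
                                 planted_counts={"GSR_up": 10}, seed=9)
        for run in ("a", "b"):
            dataset, _ = generate_expression(config)
            dataset.write(tmp_path / f"{run}.tsv", tmp_path / f"{run}_meta.tsv")
        assert ((tmp_path / "a.tsv").read_bytes()
                == (tmp_path / "b.tsv").read_bytes())
        assert ((tmp_path / "a_meta.tsv").read_bytes()
                == (tmp_path / "b_meta.tsv").read_bytes())

    def test_different_seeds_differ(self):
        base = dict(n_genes=50, planted_counts={"GSR_up": 5}, noise_sd=0.05)
        a, _ = generate_expression(SyntheticConfig(seed=1, **base))
        b, _ = generate_expression(SyntheticConfig(seed=2, **base))
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())


class TestPromoterGenerator:
    def test_full_and_zero_planting(self):
        wbox = BUILTIN_MOTIFS["W-box"]
        gsr, background, truth = generate_promoters(10, 10, wbox, 1.0, 0.0,
                                                    length=1000, seed=3)
        assert gene_fraction_with_motif(gsr, wbox) == 100.0
        assert gene_fraction_with_motif(background, wbox) == 0.0
        assert truth["planted"].sum() == 10

    def test_scanner_measured_fractions_match_request(self):
        cgcg = BUILTIN_MOTIFS["CGCG box"]
        gsr, background, _ = generate_promoters(50, 50, cgcg, 0.52, 0.31,
                                                length=1000, seed=11)
        assert gene_fraction_with_motif(gsr, cgcg) == pytest.approx(52.0)
        assert gene_fraction_with_motif(background, cgcg) == pytest.approx(32.0)

    def test_unplanted_sequences_clean_on_both_strands(self):
        wbox = BUILTIN_MOTIFS["W-box"]
        _, background, _ = generate_promoters(0, 20, wbox, 0.0, 0.0,
                                              length=500, seed=4)
        assert not any(has_motif(s, wbox, "both") for s in background.values())

    def test_motif_longer_than_promoter_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_promoters(5, 5, BUILTIN_MOTIFS["ABRE-like"], 0.5, 0.5,
                               length=4, seed=0)


class TestGeneModelGenerator:
    def test_intronless_group_is_fully_intronless(self):
        gff3, truth = generate_gene_models(
            {"flat": {"n": 30, "intron_count": {"fixed": 0},
                      "intron_length": {"fixed": 100}}}, seed=1)
        assert (truth["intron_count"] == 0).all()
        models = parse_gene_models(gff3_text=gff3)
        assert all(m.intronless for m in models)

    def test_round_trip_matches_truth(self):
        gff3, truth = generate_gene_models(
            {"a": {"n": 40, "intron_count": {"poisson": 2.5},
                   "intron_length": {"uniform_int": (60, 800)}}}, seed=7)
        table = architecture_table(parse_gene_models(gff3_text=gff3))
        table = table.loc[truth.index]
        assert (table["intron_count"] == truth["intron_count"]).all()
        assert (table["total_intron_length"] == truth["total_intron_length"]).all()

    def test_groups_with_contrasting_intron_length_separate(self):
        """Mean total intron length 400 vs 1200 must reject at p < 0.01."""
        gff3, truth = generate_gene_models(
            {"short": {"n": 200, "intron_count": {"fixed": 2},
                       "intron_length": {"uniform_int": (150, 250)}},
             "long": {"n": 200, "intron_count": {"fixed": 2},
                      "intron_length": {"uniform_int": (450, 750)}}}, seed=5)
        models = {m.gene_id: m for m in parse_gene_models(gff3_text=gff3)}
        groups = {label: [models[g].total_intron_length
                          for g in truth.index[truth["group"] == label]]
                  for label in ("short", "long")}
        _, p = kruskal_wallis(groups["short"], groups["long"])
        assert p < 0.01


class TestOrthologGenerator:
    def test_omega_zero_forbids_amino_acid_changes(self):
        _, proteins, truth = generate_ortholog_pairs(20, 120, omega=0.0, seed=2)
        for pair in truth.index:
            assert proteins[f"{pair}_a"] == proteins[f"{pair}_b"]

    def test_zero_branch_mutations_gives_identical_pair(self):
        cds, _, truth = generate_ortholog_pairs(5, 100, omega=1.0,
                                                branch_mutations=0.0, seed=2)
        for pair in truth.index:
            assert cds[f"{pair}_a"] == cds[f"{pair}_b"]
        assert (truth["codon_differences"] == 0).all()

    def test_no_internal_stops_emitted(self):
        from rhizotox.evolution import STOP_CODONS
        cds, _, _ = generate_ortholog_pairs(10, 200, omega=1.0, seed=6)
        for seq in cds.values():
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)


class TestNetworkGenerator:
    def test_star_graph(self):
        graph, truth = generate_network(11, planted_hubs=1, hub_degree=10,
                                        background_degree_mean=0.0, seed=1)
        hub = truth.index[truth["is_hub"]][0]
        assert graph.degree(hub) == 10
        assert all(graph.degree(n) == 1 for n in graph.nodes if n != hub)

    def test_no_planting_no_background_is_empty(self):
        graph, _ = generate_network(5, planted_hubs=0,
                                    background_degree_mean=0.0, seed=1)
        assert graph.number_of_edges() == 0
        assert all(d == 0 for _, d in graph.degree)

    def test_simple_graph_invariants(self):
        graph, _ = generate_network(200, planted_hubs=5, hub_degree=25,
                                    background_degree_mean=3.0, seed=8)
        assert all(a != b for a, b in graph.edges)
        lines = edge_list_lines(graph)
        assert len(lines) == len(set(lines)) == graph.number_of_edges()

    def test_hub_degree_not_exceeding_background_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_network(50, planted_hubs=2, hub_degree=3,
                             background_degree_mean=5.0, seed=0)


class TestCtGenerator:
    def test_eight_fold_is_three_cycles_below_control(self):
        panels = {"p1": {"Cd"}}
        table, _ = generate_ct_table(panels, {"g": {"p1": 8.0}}, seed=1)
        drop = table.mean_ct("g", "water") - table.mean_ct("g", "p1")
        assert drop == pytest.approx(3.0)
        assert ddct_fold_change(table, "g", "p1", "water") == pytest.approx(8.0)

    def test_fold_one_gives_zero_ddct(self):
        panels = {"p1": {"Cu"}}
        table, _ = generate_ct_table(panels, {"g": {"p1": 1.0}}, seed=1)
        assert ddct_fold_change(table, "g", "p1", "water") == pytest.approx(1.0)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_ct_table({"p1": {"Cd"}}, {"g": {"p1": 0.0}}, seed=1)

    def test_round_trip_through_files(self, tmp_path):
        from rhizotox.biomarker import CtTable, panel_folds
        panels = leave_one_out_panels()
        profiles = {"g": {p: (4.0 if "Cd" in c else 1.5)
                          for p, c in panels.items()}}
        table, truth = generate_ct_table(panels, profiles, seed=5)
        table.write(tmp_path / "ct.csv", tmp_path / "samples.tsv")
        loaded = CtTable.read(tmp_path / "ct.csv", tmp_path / "samples.tsv",
                              table.reference_gene)
        folds = panel_folds(loaded)
        for _, row in truth.iterrows():
            assert folds.loc[row["gene_id"], row["panel"]] == pytest.approx(
                row["fold"], rel=1e-9)
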