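"""GFF3 parsing and compactness comparisons."""

import numpy as np
import pandas as pd
import pytest

from rhizotox.architecture import (GeneModel, compare_intron_metrics,
                                   intronless_fraction_test, parse_gene_models,
                                   split_by_fc_test)
from rhizotox.stats import kruskal_wallis, two_proportion_ztest
from rhizotox.synthetic import generate_gene_models


def gff3_for(exon_sets):
    """Minimal GFF3 text with one gene per exon list."""
    lines = ["##gff-version 3"]
    for i, exons in enumerate(exon_sets):
        start, end = exons[0][0], exons[-1][1]
        lines.append(f"chr1\tt\tgene\t{start}\t{end}\t.\t+\t.\tID=gene{i}")
        lines.append(f"chr1\tt\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                     f"ID=gene{i}.1;Parent=gene{i}")
        for k, (s, e) in enumerate(exons):
            lines.append(f"chr1\tt\texon\t{s}\t{e}\t.\t+\t.\t"
                         f"ID=gene{i}.1.e{k};Parent=gene{i}.1")
    return "\n".join(lines) + "\n"


def models_with_lengths(lengths, prefix="m"):
    """Gene models with one intron of the requested length (0 = intronless)."""
    out = []
    for i, length in enumerate(lengths):
        if length == 0:
            exons = [(1, 100)]
        else:
            exons = [(1, 100), (101 + length, 200 + length)]
        out.append(GeneModel(gene_id=f"{prefix}{i}", strand="+", exons=exons))
    return out


class TestParser:
    def test_single_intron_coordinates(self):
        models = parse_gene_models(gff3_for([[(1, 100), (201, 300)]]))
        assert models[0].intron_count == 1
        assert models[0].intron_lengths == [100]

    def test_single_exon_is_intronless(self):
        models = parse_gene_models(gff3_for([[(10, 500)]]))
        assert models[0].intronless and models[0].total_intron_length == 0

    def test_two_introns_hand_arithmetic(self):
        models = parse_gene_models(gff3_for([[(1, 10), (12, 20), (100, 120)]]))
        assert models[0].intron_lengths == [1, 79]
        assert models[0].total_intron_length == 80

    def test_overlapping_exons_rejected_with_warning(self):
        text = gff3_for([[(1, 100), (50, 150)], [(1, 50), (101, 130)]])
        with pytest.warns(UserWarning, match="overlapping"):
            models = parse_gene_models(text)
        assert [m.gene_id for m in models] == ["gene1"]

    def test_gene_without_transcript_skipped_with_warning(self):
        text = ("##gff-version 3\n"
                "chr1\tt\tgene\t1\t100\t.\t+\t.\tID=lonely\n")
        with pytest.warns(UserWarning, match="no mRNA"):
            assert parse_gene_models(text) == []

    def test_first_mrna_is_representative(self):
        text = ("##gff-version 3\n"
                "chr1\tt\tgene\t1\t400\t.\t+\t.\tID=g\n"
                "chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=g.1;Parent=g\n"
                "chr1\tt\texon\t1\t100\t.\t+\t.\tID=g.1.e1;Parent=g.1\n"
                "chr1\tt\texon\t201\t300\t.\t+\t.\tID=g.1.e2;Parent=g.1\n"
                "chr1\tt\tmRNA\t1\t400\t.\t+\t.\tID=g.2;Parent=g\n"
                "chr1\tt\texon\t1\t400\t.\t+\t.\tID=g.2.e1;Parent=g.2\n")
        models = parse_gene_models(text)
        assert len(models) == 1
        assert models[0].intron_count == 1


class TestIntronlessFraction:
    def test_hand_computed_z(self):
        group_a = models_with_lengths([0] * 60 + [100] * 40, "a")
        group_b = models_with_lengths([0] * 40 + [100] * 60, "b")
        res = intronless_fraction_test(group_a, group_b)
        assert res.z == pytest.approx(2.828, abs=5e-4)

    def test_equal_fractions(self):
        group = models_with_lengths([0, 0, 100, 100])
        res = intronless_fraction_test(group, group)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_all_introned(self):
        group = models_with_lengths([100] * 50)
        res = intronless_fraction_test(group, group)
        assert res.degenerate


class TestIntronMetricComparisons:
    def test_three_identical_groups(self):
        group = models_with_lengths([100, 200, 300])
        (h, p), _, _ = compare_intron_metrics(
            {"a": group, "b": group, "c": group})
        assert (h, p) == (0.0, 1.0)

    def test_intronless_excluded_before_testing(self):
        groups = {"a": models_with_lengths([0, 0, 100, 110, 120], "a"),
                  "b": models_with_lengths([0, 1000, 1100, 1200], "b")}
        _, _, usable = compare_intron_metrics(groups)
        assert len(usable["a"]) == 3 and len(usable["b"]) == 3

    def test_separated_groups_match_rank_expectation(self):
        groups = {"short": models_with_lengths([100, 110, 120], "s"),
                  "long": models_with_lengths([1000, 1100, 1200], "l")}
        (h, p), dunn, _ = compare_intron_metrics(groups)
        # complete separation: the exact rank-sum oracle makes this the most
        # extreme of the 20 configurations
        assert h > 3.8
        assert dunn.loc[0, "z"] != 0

    def test_emptied_group_omitted_with_warning(self):
        groups = {"a": models_with_lengths([100, 200, 300], "a"),
                  "b": models_with_lengths([150, 250, 350], "b"),
                  "empty": models_with_lengths([0, 0, 0], "e")}
        with pytest.warns(UserWarning, match="omitted"):
            (_, _), _, usable = compare_intron_metrics(groups)
        assert "empty" not in usable

    def test_null_calibration_z_and_kruskal(self, rng):
        """Same-distribution groups reject at alpha=0.05 within [0.03, 0.07]."""
        nsim = 1000
        rej_z = rej_k = 0
        for _ in range(nsim):
            a, b = rng.binomial(100, 0.4, size=2)
            z, p = two_proportion_ztest(int(a), 100, int(b), 100)
            rej_z += np.isfinite(z) and p < 0.05
            x = rng.lognormal(6, 0.8, 50)
            y = rng.lognormal(6, 0.8, 50)
            rej_k += kruskal_wallis(x, y)[1] < 0.05
        assert 0.03 <= rej_z / nsim <= 0.07
        assert 0.03 <= rej_k / nsim <= 0.07


class TestFcSplit:
    def test_exact_small_sample(self):
        # higher-FC genes have the shorter introns (1, 2): U(top, bottom) = 0
        models = models_with_lengths([1, 2, 3, 4])
        fc = pd.Series([4.0, 3.5, 3.0, 2.5], index=[m.gene_id for m in models])
        res = split_by_fc_test(models, fc)
        assert res.u == 0.0
        assert res.p == pytest.approx(0.333, abs=5e-4)

    def test_identical_halves_p_one(self):
        models = models_with_lengths([7, 7, 7, 7])
        fc = pd.Series([2.0, 2.5, 3.0, 3.5], index=[m.gene_id for m in models])
        assert split_by_fc_test(models, fc).p == pytest.approx(1.0, abs=1e-9)

    def test_odd_count_median_gene_dropped(self):
        models = models_with_lengths([1, 2, 3, 4, 5])
        fc = pd.Series(np.arange(2.0, 4.5, 0.5), index=[m.gene_id for m in models])
        res = split_by_fc_test(models, fc)
        assert res.n_top == res.n_bottom == 2

    def test_too_few_genes_returns_none(self):
        models = models_with_lengths([1, 2, 0, 0])
        fc = pd.Series([2, 3, 4, 5.0], index=[m.gene_id for m in models])
        assert split_by_fc_test(models, fc) is None

    def test_planted_compactness_signal_detected(self, rng):
        """Top-FC genes given systematically shorter introns: p < 0.01 at n=200."""
        lengths = np.concatenate([rng.integers(100, 400, 100),    # short
                                  rng.integers(800, 2000, 100)])  # long
        models = models_with_lengths(lengths)
        fc_values = np.concatenate([rng.uniform(4, 8, 100),   # high FC, short
                                    rng.uniform(2, 3, 100)])  # low FC, long
        fc = pd.Series(fc_values, index=[m.gene_id for m in models])
        assert split_by_fc_test(models, fc).p < 0.01


class TestWholeFileContrast:
    def test_generated_contrast_detected_from_gff3(self):
        gff3, truth = generate_gene_models(
            {"compact": {"n": 120, "intron_count": {"poisson": 0.8},
                         "intron_length": {"uniform_int": (60, 300)}},
             "sprawling": {"n": 120, "intron_count": {"poisson": 4.0},
                           "intron_length": {"uniform_int": (300, 1500)}}},
            seed=17)
        by_id = {m.gene_id: m for m in parse_gene_models(gff3_text=gff3)}
        groups = {label: [by_id[g] for g in truth.index[truth["group"] == label]]
                  for label in ("compact", "sprawling")}
        res = intronless_fraction_test(groups["compact"], groups["sprawling"])
        assert res.fraction_a > res.fraction_b
        (h, p), _, _ = compare_intron_metrics(groups, "total_intron_length")
        assert p < 0.01
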