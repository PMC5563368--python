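"""Expression normalization, fold-change testing, and the class taxonomy."""

import numpy as np
import pandas as pd
import pytest

from rhizotox import reference
from rhizotox.expression import (ExpressionDataset, assemble_summary,
                                 classify_genes, compare_basal_expression,
                                 filter_low_intensity, joint_quantile_normalize,
                                 per_stress_fc_table, signed_fold_change,
                                 summarize_counts, SUM_ROW)
from rhizotox.stats import kruskal_wallis

from conftest import tiny_dataset


def _two_sample_ds(col_a, col_b, stress="Cu"):
    return tiny_dataset(
        {"s1": col_a, "s2": col_b},
        [("s1", stress, 1, 1, "control"), ("s2", stress, 1, 1, "treated")],
        [f"g{i}" for i in range(len(col_a))],
    )


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        ds = _two_sample_ds([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = joint_quantile_normalize([ds])
        assert np.allclose(out.values.to_numpy(), ds.values.to_numpy())

    def test_rank_wise_row_means(self):
        ds = _two_sample_ds([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = joint_quantile_normalize([ds])
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.values.to_numpy(), expected)

    def test_all_columns_share_sorted_vector(self, rng):
        values = {f"s{i}": rng.lognormal(5, 1, 40) for i in range(6)}
        meta = [(f"s{i}", "Cu", 1, i + 1, "control") for i in range(6)]
        ds = tiny_dataset(values, meta, [f"g{i}" for i in range(40)])
        out = joint_quantile_normalize([ds]).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])

    def test_mismatched_gene_sets_error(self):
        a = _two_sample_ds([1.0], [2.0])
        b = tiny_dataset({"s3": [1.0]}, [("s3", "Cd", 1, 1, "control")], ["other"])
        with pytest.raises(ValueError, match="mismatched ids"):
            joint_quantile_normalize([a, b])


class TestIntensityFilter:
    def test_all_low_gene_removed_and_induced_gene_kept(self):
        ds = tiny_dataset(
            {"s1": [50.0, 20.0], "s2": [50.0, 150.0]},
            [("s1", "Cu", 1, 1, "control"), ("s2", "Cu", 1, 1, "treated")],
            ["quiet", "induced"],
        )
        out = filter_low_intensity(ds, threshold=100)
        assert list(out.values.index) == ["induced"]

    def test_zero_threshold_is_identity(self, noise_free_run):
        _, dataset, _ = noise_free_run
        out = filter_low_intensity(dataset, threshold=0)
        assert out.values.shape == dataset.values.shape


class TestSignedFoldChange:
    @pytest.mark.parametrize("treated,control,expected",
                             [(200, 100, 2.0), (50, 100, -2.0), (100, 100, 1.0)])
    def test_sign_convention(self, treated, control, expected):
        assert signed_fold_change(treated, control) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 10.0)


def _timepoint_dataset():
    """One gene, one stress, FC +1.1 at 1 h and +2.6 at 3 h."""
    cols, meta = {}, []
    for tp, fc in ((1, 1.1), (3, 2.6)):
        for rep in (1, 2, 3):
            jitter = 0.01 * rep
            cols[f"c{tp}_{rep}"] = [100.0 + jitter]
            cols[f"t{tp}_{rep}"] = [100.0 * fc + jitter]
            meta.append((f"c{tp}_{rep}", "Cd", tp, rep, "control"))
            meta.append((f"t{tp}_{rep}", "Cd", tp, rep, "treated"))
    return tiny_dataset(cols, meta, ["g0"])


class TestPerStressFcTable:
    def test_max_abs_fc_timepoint_rule(self):
        table = per_stress_fc_table(_timepoint_dataset())
        assert table.loc[0, "fc"] == pytest.approx(2.6, abs=0.01)

    def test_sample_order_invariance(self):
        ds = _timepoint_dataset()
        shuffled = ExpressionDataset(
            values=ds.values[ds.values.columns[::-1]],
            samples=ds.samples.iloc[::-1],
        )
        a = per_stress_fc_table(ds)
        b = per_stress_fc_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_gsr_gene_has_fc_at_least_two_everywhere(self, noise_free_run):
        _, dataset, truth = noise_free_run
        table = per_stress_fc_table(dataset)
        gsr = truth.index[truth["label"] == "GSR_up"]
        fc = table.pivot(index="gene", columns="stress", values="fc").loc[gsr]
        assert (fc.to_numpy() >= 2.0).all()

    def test_missing_control_group_errors(self):
        ds = tiny_dataset({"t1": [5.0], "t2": [6.0]},
                          [("t1", "Cu", 1, 1, "treated"),
                           ("t2", "Cu", 1, 2, "treated")], ["g0"])
        with pytest.raises(ValueError, match="control"):
            per_stress_fc_table(ds)


def _fc_frame(fc_by_stress: dict, q: float = 0.01) -> pd.DataFrame:
    rows = [("g0", s, v, q, q) for s, v in fc_by_stress.items()]
    return pd.DataFrame(rows, columns=["gene", "stress", "fc", "p", "q"])


STRESSES = ["Cu", "As(V)", "Cd", "Hg", "Cr", "V", "FA", "juglone"]


class TestClassifyGenes:
    def test_gsr_up(self):
        res = classify_genes(_fc_frame({s: 2.5 for s in STRESSES}))
        assert res.labels["g0"] == "GSR_up"

    def test_unique_up_cadmium(self):
        fc = {s: 1.1 for s in STRESSES}
        fc["Cd"] = 3.0
        res = classify_genes(_fc_frame(fc))
        assert res.labels["g0"] == "unique_up:Cd"
        assert res.unique_stress["g0"] == "Cd"

    def test_between_class_gap_is_unclassified(self):
        fc = {s: 1.0 for s in STRESSES}
        fc["Cu"] = 1.5
        res = classify_genes(_fc_frame(fc))
        assert res.labels["g0"] == "unclassified"

    def test_fdr_gate_blocks_gsr_but_not_background(self):
        res = classify_genes(_fc_frame({s: 2.5 for s in STRESSES}, q=0.2))
        assert res.labels["g0"] == "unclassified"
        res = classify_genes(_fc_frame({s: 1.1 for s in STRESSES}, q=0.9))
        assert res.labels["g0"] == "background"

    def test_mutual_exclusivity_on_random_tables(self, rng):
        """The class predicates partition every random FC table (the
        classifier asserts exclusivity internally)."""
        genes = [f"g{i}" for i in range(300)]
        rows = []
        for g in genes:
            for s in STRESSES:
                r = float(np.exp(rng.normal(0, 0.7)))
                fc = r if r >= 1 else -1.0 / r
                rows.append((g, s, fc, 0.01, float(rng.choice([0.01, 0.2]))))
        table = pd.DataFrame(rows, columns=["gene", "stress", "fc", "p", "q"])
        res = classify_genes(table)  # no assertion error = predicates disjoint
        assert set(res.labels.index) == set(genes)


class TestSummaries:
    def test_reference_unique_totals_are_column_sums(self):
        table = assemble_summary(reference.PER_STRESS_COUNTS,
                                 reference.GLOBAL_CLASS_COUNTS)
        assert table.loc[SUM_ROW, "uniquely_up"] == 219
        assert table.loc[SUM_ROW, "uniquely_down"] == 370
        assert table.loc[SUM_ROW, "generally_regulated"] == 577

    def test_empty_classification_gives_zero_table(self):
        empty = classify_genes(pd.DataFrame(
            columns=["gene", "stress", "fc", "p", "q"]).astype(
                {"fc": float, "p": float, "q": float}))
        assert len(empty.labels) == 0

    def test_summary_internal_identities_on_synthetic_run(self, noise_free_run):
        _, dataset, _ = noise_free_run
        res = classify_genes(per_stress_fc_table(filter_low_intensity(dataset)))
        table = summarize_counts(res)
        per_stress = table.drop(index=SUM_ROW)
        assert (per_stress["DEGs"]
                == per_stress["up_regulated"] + per_stress["down_regulated"]).all()
        assert (per_stress["uniquely_regulated"]
                == per_stress["uniquely_up"] + per_stress["uniquely_down"]).all()
        assert table.loc[SUM_ROW, "uniquely_up"] == per_stress["uniquely_up"].sum()


class TestBasalExpression:
    def test_planted_high_basal_class_ranks_highest(self, rng):
        meta = [(f"c{r}", "Cu", 1, r, "control") for r in (1, 2, 3)]
        genes = [f"g{i}" for i in range(60)]
        base = np.concatenate([np.full(30, 1000.0), np.full(30, 100.0)])
        cols = {f"c{r}": base * np.exp(0.05 * rng.standard_normal(60))
                for r in (1, 2, 3)}
        ds = tiny_dataset(cols, meta, genes)
        labels = pd.Series(["background"] * 30 + ["GSR_up"] * 30, index=genes)
        from rhizotox.expression import ClassificationResult
        res = ClassificationResult(labels=labels,
                                   unique_stress=pd.Series(index=genes, dtype=object),
                                   deg_up=pd.DataFrame(index=genes),
                                   deg_down=pd.DataFrame(index=genes))
        levels, omnibus, _ = compare_basal_expression(
            ds, res, classes=("background", "GSR_up"))
        assert levels["background"].mean() > levels["GSR_up"].mean()
        assert omnibus[1] < 0.01

    def test_single_class_descriptive_only(self, rng):
        meta = [(f"c{r}", "Cu", 1, r, "control") for r in (1, 2)]
        genes = [f"g{i}" for i in range(10)]
        cols = {f"c{r}": rng.lognormal(6, 1, 10) for r in (1, 2)}
        ds = tiny_dataset(cols, meta, genes)
        labels = pd.Series(["GSR_up"] * 10, index=genes)
        from rhizotox.expression import ClassificationResult
        res = ClassificationResult(labels=labels,
                                   unique_stress=pd.Series(index=genes, dtype=object),
                                   deg_up=pd.DataFrame(index=genes),
                                   deg_down=pd.DataFrame(index=genes))
        with pytest.warns(UserWarning):
            levels, omnibus, dunn = compare_basal_expression(
                ds, res, classes=("background", "GSR_up"))
        assert omnibus is None and dunn is None

    def test_null_calibration(self, rng):
        """Omnibus p is calibrated: classes drawn from one distribution
        reject at alpha = 0.05 between 3% and 7% of the time."""
        nsim, rejections = 500, 0
        for _ in range(nsim):
            groups = [rng.lognormal(7, 1, 60) for _ in range(3)]
            rejections += kruskal_wallis(*groups)[1] < 0.05
        assert 0.03 <= rejections / nsim <= 0.07
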