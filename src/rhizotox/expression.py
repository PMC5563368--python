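"""Multi-stress expression classification.

Classifies rice root genes by their expression pattern across eight
rhizotoxin treatments (Cu, As(V), Cd, Hg, Cr, V, ferulic acid, juglone),
each profiled at 1 h and 3 h with triplicate control and treated samples.

Workflow: joint quantile normalization across datasets, a detection
filter (signal intensity >= 100 in at least one sample), a per-stress
signed fold change (treated/control ratio r, reported as r when r >= 1
and -1/r otherwise) with a control-vs-treated Kruskal-Wallis test and
per-stress Benjamini-Hochberg FDR, and finally the four-class taxonomy:

* ``GSR_up`` — general stress response, FC >= 2 under all stresses (FDR-passing)
* ``generally_down`` — FC <= -2 under all stresses (FDR-passing)
* ``unique_up:<s>`` / ``unique_down:<s>`` — |FC| >= 2 under exactly one
  stress (FDR-passing there) and |FC| <= 1.4 under the others
* ``background`` — |FC| <= 1.2 under all stresses
* ``low_regulated`` — 1.2 < FC < 2 under all stresses
* anything else — ``unclassified``

Background and low-regulated membership is defined purely by fold-change
bounds; the FDR gate applies to DEG/GSR/unique calls only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, kruskal_dunn, kruskal_two_group_rows

logger = logging.getLogger(__name__)

STRESSORS = ("Cu", "As(V)", "Cd", "Hg", "Cr", "V", "FA", "juglone")

DEFAULT_THRESHOLDS = {"deg": 2.0, "unique_other": 1.4, "background": 1.2}

SAMPLE_COLUMNS = ("stress", "timepoint", "replicate", "condition")


@dataclass
class ExpressionDataset:
    """Intensity matrix (genes x samples) plus per-sample metadata.

    ``values``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns
    stress, timepoint (hours), replicate (int), condition in {control, treated}.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.samples.index):
            extra = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(f"sample ids of matrix and metadata disagree: {sorted(extra)}")
        bad = set(self.samples["condition"]) - {"control", "treated"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def stressors(self) -> list[str]:
        return list(pd.unique(self.samples["stress"]))

    def sample_ids(self, stress=None, timepoint=None, condition=None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if stress is not None:
            mask &= self.samples["stress"] == stress
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def write(self, values_path, samples_path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(values_path, sep="\t", index=False, float_format="%.6f")
        meta = self.samples.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, values_path, samples_path) -> "ExpressionDataset":
        values = pd.read_csv(values_path, sep="\t").set_index("gene_id")
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        return cls(values=values, samples=samples)


@dataclass
class ClassificationResult:
    """Per-gene class labels plus per-stress DEG flags."""

    labels: pd.Series                # gene -> class label (unique_* carry ":<stress>")
    unique_stress: pd.Series         # gene -> stress for unique_* labels, else NA
    deg_up: pd.DataFrame             # genes x stresses, bool
    deg_down: pd.DataFrame

    def genes_in_class(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def write(self, path) -> None:
        out = pd.DataFrame({
            "gene_id": self.labels.index,
            "class": self.labels.values,
            "unique_stress": self.unique_stress.reindex(self.labels.index).values,
        })
        out.to_csv(path, sep="\t", index=False)


def joint_quantile_normalize(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Quantile-normalize all sample columns of all datasets together.

    After normalization every column shares the same marginal
    distribution: the mean of the sorted columns.  Tied intensities get
    the mean reference value of their rank span.  Gene and sample order
    are preserved; datasets must share one gene universe.
    """
    if not datasets:
        raise ValueError("no datasets given")
    genes = datasets[0].values.index
    for ds in datasets[1:]:
        if set(ds.values.index) != set(genes):
            missing = set(genes) ^ set(ds.values.index)
            raise ValueError(f"gene universes differ; mismatched ids: {sorted(missing)[:10]}")
    matrix = pd.concat([ds.values.reindex(genes) for ds in datasets], axis=1)
    x = matrix.to_numpy(dtype=float)
    n_genes = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    ranks = sps.rankdata(x, axis=0)  # midranks, 1-based
    normalized = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    norm_df = pd.DataFrame(normalized, index=genes, columns=matrix.columns)
    samples = pd.concat([ds.samples for ds in datasets], axis=0)
    return ExpressionDataset(values=norm_df, samples=samples)


def filter_low_intensity(dataset: ExpressionDataset, threshold: float = 100.0
                         ) -> ExpressionDataset:
    """Drop genes whose intensity is below ``threshold`` in every sample.

    The max-across-samples rule keeps genes silenced in control but
    induced by stress, which the general-stress-response classes need.
    """
    keep = dataset.values.max(axis=1) >= threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("intensity filter (<%g in all samples): dropped %d of %d genes",
                    threshold, dropped, len(keep))
    if keep.sum() == 0:
        warnings.warn("intensity filter removed every gene", stacklevel=2)
    return ExpressionDataset(values=dataset.values.loc[keep],
                             samples=dataset.samples.copy())


def signed_fold_change(treated_mean: float, control_mean: float) -> float:
    """Signed FC: ratio r = treated/control, reported r if r >= 1 else -1/r."""
    if treated_mean <= 0 or control_mean <= 0:
        raise ValueError("means must be positive")
    r = treated_mean / control_mean
    return r if r >= 1.0 else -1.0 / r


def _signed_fc_array(treated_mean: np.ndarray, control_mean: np.ndarray) -> np.ndarray:
    if np.any(treated_mean <= 0) or np.any(control_mean <= 0):
        raise ValueError("means must be positive")
    r = treated_mean / control_mean
    return np.where(r >= 1.0, r, -1.0 / r)


def per_stress_fc_table(dataset: ExpressionDataset, stressors=None) -> pd.DataFrame:
    """Signed FC, Kruskal-Wallis p and BH q per gene x stress.

    Per stress, FC is taken from the timepoint with the larger |FC|
    (means over replicates).  The test pools the replicates of both
    timepoints per condition (control vs treated), and BH is applied per
    stress across genes.  Returns a tidy frame: gene, stress, fc, p, q.
    """
    if stressors is None:
        stressors = dataset.stressors
    genes = dataset.values.index
    frames = []
    for stress in stressors:
        timepoints = sorted(pd.unique(
            dataset.samples.loc[dataset.samples["stress"] == stress, "timepoint"]))
        if not timepoints:
            raise ValueError(f"no samples for stress {stress!r}")
        fc_by_tp = []
        control_cols_all, treated_cols_all = [], []
        for tp in timepoints:
            control_cols = dataset.sample_ids(stress, tp, "control")
            treated_cols = dataset.sample_ids(stress, tp, "treated")
            if not control_cols:
                raise ValueError(f"missing control group for {stress!r} at {tp} h")
            if not treated_cols:
                raise ValueError(f"missing treated group for {stress!r} at {tp} h")
            control_cols_all += control_cols
            treated_cols_all += treated_cols
            fc_by_tp.append(_signed_fc_array(
                dataset.values[treated_cols].mean(axis=1).to_numpy(),
                dataset.values[control_cols].mean(axis=1).to_numpy()))
        fc_matrix = np.column_stack(fc_by_tp)
        pick = np.argmax(np.abs(fc_matrix), axis=1)
        fc = fc_matrix[np.arange(len(genes)), pick]
        _, p = kruskal_two_group_rows(dataset.values[control_cols_all].to_numpy(),
                                      dataset.values[treated_cols_all].to_numpy())
        q = bh_fdr(p)
        frames.append(pd.DataFrame({"gene": genes, "stress": stress,
                                    "fc": fc, "p": p, "q": q}))
    return pd.concat(frames, ignore_index=True)


def _pivot(fc_table: pd.DataFrame, column: str) -> pd.DataFrame:
    return fc_table.pivot(index="gene", columns="stress", values=column)


def classify_genes(fc_table: pd.DataFrame,
                   thresholds: dict | None = None,
                   fdr_cutoff: float = 0.05,
                   stressors=None) -> ClassificationResult:
    """Assign each gene to the four-class taxonomy (or ``unclassified``).

    ``thresholds``: {"deg": 2, "unique_other": 1.4, "background": 1.2}.
    DEG flags (and the GSR / generally-down / unique calls built on them)
    require |FC| >= deg AND q < fdr_cutoff; the background and
    low-regulated classes are bounded by FC alone.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    fc = _pivot(fc_table, "fc")
    q = _pivot(fc_table, "q")
    if stressors is not None:
        missing = set(stressors) - set(fc.columns)
        if missing:
            raise ValueError(f"fold-change table lacks stresses: {sorted(missing)}")
        fc, q = fc[list(stressors)], q[list(stressors)]
    fcv, qv = fc.to_numpy(), q.to_numpy()
    sig = qv < fdr_cutoff
    up = (fcv >= thr["deg"]) & sig
    down = (fcv <= -thr["deg"]) & sig
    absfc = np.abs(fcv)

    gsr_up = up.all(axis=1)
    gen_down = down.all(axis=1)
    background = (absfc <= thr["background"]).all(axis=1)
    low_reg = ((fcv > thr["background"]) & (fcv < thr["deg"])).all(axis=1)

    other_ok_up = np.empty_like(up)
    other_ok_down = np.empty_like(up)
    n_stress = fcv.shape[1]
    for j in range(n_stress):
        others = [k for k in range(n_stress) if k != j]
        other_ok_up[:, j] = (absfc[:, others] <= thr["unique_other"]).all(axis=1)
        other_ok_down[:, j] = other_ok_up[:, j]
    unique_up = up & other_ok_up
    unique_down = down & other_ok_down
    uu_any = unique_up.any(axis=1)
    ud_any = unique_down.any(axis=1)

    stacked = np.column_stack([gsr_up, gen_down, background, low_reg, uu_any, ud_any])
    assert (stacked.sum(axis=1) <= 1).all(), "class predicates must be mutually exclusive"

    labels = np.full(len(fc.index), "unclassified", dtype=object)
    unique_stress = np.full(len(fc.index), None, dtype=object)
    labels[background] = "background"
    labels[low_reg] = "low_regulated"
    labels[gsr_up] = "GSR_up"
    labels[gen_down] = "generally_down"
    for j, stress in enumerate(fc.columns):
        sel_u = unique_up[:, j]
        labels[sel_u] = f"unique_up:{stress}"
        unique_stress[sel_u] = stress
        sel_d = unique_down[:, j]
        labels[sel_d] = f"unique_down:{stress}"
        unique_stress[sel_d] = stress

    return ClassificationResult(
        labels=pd.Series(labels, index=fc.index, name="class"),
        unique_stress=pd.Series(unique_stress, index=fc.index, name="unique_stress"),
        deg_up=pd.DataFrame(up, index=fc.index, columns=fc.columns),
        deg_down=pd.DataFrame(down, index=fc.index, columns=fc.columns),
    )


SUMMARY_COLUMNS = ["DEGs", "up_regulated", "down_regulated", "uniquely_regulated",
                   "uniquely_up", "uniquely_down", "generally_regulated",
                   "generally_up_GSR", "generally_down", "background_genes",
                   "low_regulated"]

SUM_ROW = "Sum (non-redundant)"


def assemble_summary(per_stress: pd.DataFrame,
                     global_counts: dict,
                     nonredundant: dict | None = None) -> pd.DataFrame:
    """Build the per-stress summary table plus its non-redundant Sum row.

    ``per_stress`` needs columns up_regulated, down_regulated,
    uniquely_up, uniquely_down (index = stress).  Derived columns:
    DEGs = up + down, uniquely_regulated = uniquely_up + uniquely_down,
    generally_regulated = generally_up + generally_down.  Unique classes
    are disjoint across stresses, so their non-redundant totals are plain
    column sums; the non-redundant DEG/up/down totals cannot be derived
    from per-stress counts (genes overlap between stresses) and must be
    supplied via ``nonredundant`` when known.
    """
    table = per_stress.copy().reindex(
        columns=["up_regulated", "down_regulated", "uniquely_up", "uniquely_down"]
        + [c for c in per_stress.columns
           if c not in ("up_regulated", "down_regulated",
                        "uniquely_up", "uniquely_down")],
        fill_value=0)
    table["DEGs"] = table["up_regulated"] + table["down_regulated"]
    table["uniquely_regulated"] = table["uniquely_up"] + table["uniquely_down"]
    gu = int(global_counts["generally_up_GSR"])
    gd = int(global_counts["generally_down"])
    table["generally_up_GSR"] = gu
    table["generally_down"] = gd
    table["generally_regulated"] = gu + gd
    table["background_genes"] = int(global_counts["background_genes"])
    table["low_regulated"] = int(global_counts["low_regulated"])

    totals = {
        "uniquely_up": int(table["uniquely_up"].sum()),
        "uniquely_down": int(table["uniquely_down"].sum()),
        "uniquely_regulated": int(table["uniquely_regulated"].sum()),
        "generally_up_GSR": gu,
        "generally_down": gd,
        "generally_regulated": gu + gd,
        "background_genes": int(global_counts["background_genes"]),
        "low_regulated": int(global_counts["low_regulated"]),
    }
    for key in ("DEGs", "up_regulated", "down_regulated"):
        totals[key] = int(nonredundant[key]) if nonredundant and key in nonredundant else pd.NA
    table.loc[SUM_ROW] = pd.Series(totals)
    return table[SUMMARY_COLUMNS]


def summarize_counts(result: ClassificationResult) -> pd.DataFrame:
    """Per-stress and non-redundant global counts from a classification."""
    stresses = list(result.deg_up.columns)
    labels = result.labels
    rows = {}
    for s in stresses:
        rows[s] = {
            "up_regulated": int(result.deg_up[s].sum()),
            "down_regulated": int(result.deg_down[s].sum()),
            "uniquely_up": int((labels == f"unique_up:{s}").sum()),
            "uniquely_down": int((labels == f"unique_down:{s}").sum()),
        }
    per_stress = pd.DataFrame.from_dict(rows, orient="index")
    global_counts = {
        "generally_up_GSR": int((labels == "GSR_up").sum()),
        "generally_down": int((labels == "generally_down").sum()),
        "background_genes": int((labels == "background").sum()),
        "low_regulated": int((labels == "low_regulated").sum()),
    }
    up_any = result.deg_up.any(axis=1)
    down_any = result.deg_down.any(axis=1)
    nonredundant = {
        "DEGs": int((up_any | down_any).sum()),
        "up_regulated": int(up_any.sum()),
        "down_regulated": int(down_any.sum()),
    }
    return assemble_summary(per_stress, global_counts, nonredundant)


def compare_basal_expression(dataset: ExpressionDataset,
                             result: ClassificationResult,
                             classes=("background", "low_regulated", "GSR_up"),
                             min_genes: int = 2):
    """Compare basal (mean control-intensity) levels across gene classes.

    Returns (per-class basal Series dict, omnibus (H, p) or None,
    Dunn pairwise DataFrame or None).  Classes with fewer than
    ``min_genes`` members are excluded with a warning; with fewer than
    two usable classes only the descriptive levels are returned.
    """
    control_cols = dataset.sample_ids(condition="control")
    basal = dataset.values[control_cols].mean(axis=1)
    groups = {}
    for label in classes:
        genes = result.genes_in_class(label)
        genes = genes.intersection(basal.index)
        if len(genes) < min_genes:
            warnings.warn(f"class {label!r} has <{min_genes} genes; excluded", stacklevel=2)
            continue
        groups[label] = basal.loc[genes].to_numpy()
    if len(groups) < 2:
        return {k: pd.Series(v) for k, v in groups.items()}, None, None
    h, p, dunn = kruskal_dunn(groups)
    return {k: pd.Series(v) for k, v in groups.items()}, (h, p), dunn
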