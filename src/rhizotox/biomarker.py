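"""qPCR quantification (comparative Ct) and biomarker specificity screen.

Relative expression is quantified with the comparative threshold-cycle
method: dCt = Ct_target - Ct_reference per sample, ddCt = dCt_treated -
dCt_control, fold = 2^(-ddCt), assuming 100% amplification efficiency.
Technical replicate Ct values are averaged before ddCt.

The two-stage specificity screen mirrors the combined-stress biomarker
design: (1) candidates are genes uniquely induced by exactly one
(non-excluded) stressor in single-stress measurements; (2) a candidate
is validated when, across combined panels (each a subset of stressors,
canonically 4-of-5 metal leave-one-out mixes), it stays induced in every
panel containing its target stressor and its specificity ratio
(minimum fold over panels with the target / maximum fold over panels
without it) reaches the configured minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRESS_SEPARATOR = "+"


@dataclass
class CtTable:
    """Long-format Ct measurements plus per-sample panel metadata.

    ``ct``: DataFrame with columns gene_id, sample_id, ct (technical
    replicates may repeat rows).  ``samples``: DataFrame indexed by
    sample_id with columns panel, stresses (``+``-joined stressor
    labels, empty for water control), condition in {control, treated}.
    """

    ct: pd.DataFrame
    samples: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        need = {"gene_id", "sample_id", "ct"}
        if not need <= set(self.ct.columns):
            raise ValueError(f"ct table needs columns {sorted(need)}")
        if (self.ct["ct"] <= 0).any():
            raise ValueError("Ct values must be positive cycles")
        per_sample = set(self.ct.loc[self.ct["gene_id"] == self.reference_gene,
                                     "sample_id"])
        missing = set(self.ct["sample_id"]) - per_sample
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing in samples: "
                f"{sorted(missing)}")

    def mean_ct(self, gene: str, sample: str) -> float:
        sel = self.ct[(self.ct["gene_id"] == gene)
                      & (self.ct["sample_id"] == sample)]
        if sel.empty:
            raise KeyError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(sel["ct"].mean())

    def stresses_of(self, sample: str) -> frozenset[str]:
        raw = self.samples.loc[sample, "stresses"]
        if pd.isna(raw) or raw == "":
            return frozenset()
        return frozenset(str(raw).split(STRESS_SEPARATOR))

    def write(self, ct_path, samples_path) -> None:
        self.ct.to_csv(ct_path, index=False)  # full precision: ddCt recovery is exact
        meta = self.samples.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, ct_path, samples_path, reference_gene: str) -> "CtTable":
        ct = pd.read_csv(ct_path)
        samples = pd.read_csv(samples_path, sep="\t", keep_default_na=False,
                              na_values=[]).set_index("sample_id")
        return cls(ct=ct, samples=samples, reference_gene=reference_gene)


def ddct_fold_change(table: CtTable, gene: str, treated_sample: str,
                     control_sample: str) -> float:
    """Fold induction 2^(-ddCt) of ``gene`` vs the reference gene."""
    dct_treated = (table.mean_ct(gene, treated_sample)
                   - table.mean_ct(table.reference_gene, treated_sample))
    dct_control = (table.mean_ct(gene, control_sample)
                   - table.mean_ct(table.reference_gene, control_sample))
    return float(2.0 ** (-(dct_treated - dct_control)))


def panel_folds(table: CtTable, genes=None) -> pd.DataFrame:
    """Fold induction per (gene, treated panel) against the control sample.

    Expects exactly one condition == control sample; every treated
    sample is one panel.  Returns genes x panels.
    """
    controls = table.samples.index[table.samples["condition"] == "control"]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control sample, got {len(controls)}")
    control = controls[0]
    treated = table.samples.index[table.samples["condition"] == "treated"]
    if genes is None:
        genes = sorted(set(table.ct["gene_id"]) - {table.reference_gene})
    data = {
        table.samples.loc[s, "panel"]: [
            ddct_fold_change(table, g, s, control) for g in genes]
        for s in treated
    }
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def uniqueness_screen(folds: pd.DataFrame, exclude_stressors=(),
                      up_threshold: float = 2.0,
                      other_threshold: float = 1.4) -> pd.DataFrame:
    """Stage 1: genes uniquely induced by exactly one non-excluded stressor.

    ``folds``: genes x single-stress fold inductions (or signed FC — the
    magnitude is used for the "quiet elsewhere" bound).  A candidate has
    fold >= up_threshold under exactly one stressor and |fold| <=
    other_threshold under all the others; candidates whose stressor is
    excluded (e.g. vanadate, whose assay concentration is unrealistic in
    the field) are dropped.
    """
    records = []
    stressors = list(folds.columns)
    for gene, row in folds.iterrows():
        above = [s for s in stressors if row[s] >= up_threshold]
        if len(above) != 1:
            continue
        target = above[0]
        others = [s for s in stressors if s != target]
        if any(abs(row[s]) > other_threshold for s in others):
            continue
        if target in exclude_stressors:
            continue
        records.append((gene, target, float(row[target])))
    return pd.DataFrame(records, columns=["gene_id", "target_stressor", "fold"]
                        ).set_index("gene_id")


@dataclass
class BiomarkerVerdict:
    gene_id: str
    target_stressor: str
    min_fold_with_target: float
    max_fold_without_target: float
    specificity_ratio: float
    induced_everywhere_with_target: bool
    verdict: str  # "validated" | "rejected" | "unassessable"


def combined_panel_validation(candidates: pd.DataFrame,
                              folds: pd.DataFrame,
                              panel_composition: dict[str, frozenset | set],
                              induced_threshold: float = 2.0,
                              specificity_ratio_min: float = 2.0
                              ) -> pd.DataFrame:
    """Stage 2: validate candidates against combined-stress panel folds.

    ``candidates``: output of :func:`uniqueness_screen` (index gene_id,
    column target_stressor).  ``folds``: genes x panels fold inductions.
    ``panel_composition``: panel -> set of stressors.  A candidate whose
    target stressor appears in every panel cannot be assessed and is
    flagged ``unassessable``.
    """
    rows = []
    for gene, cand in candidates.iterrows():
        target = cand["target_stressor"]
        with_target = [p for p, comp in panel_composition.items() if target in comp]
        without = [p for p, comp in panel_composition.items() if target not in comp]
        if gene not in folds.index:
            raise KeyError(f"candidate {gene!r} missing from panel folds")
        missing = set(panel_composition) - set(folds.columns)
        if missing:
            raise KeyError(f"panels without measurements: {sorted(missing)}")
        if not without:
            rows.append(BiomarkerVerdict(gene, target, float("nan"), float("nan"),
                                         float("nan"), False, "unassessable"))
            continue
        fw = folds.loc[gene, with_target].astype(float)
        fo = folds.loc[gene, without].astype(float)
        min_with = float(fw.min())
        max_without = float(fo.max())
        ratio = min_with / max_without if max_without > 0 else float("inf")
        induced = bool((fw >= induced_threshold).all())
        ok = induced and ratio >= specificity_ratio_min
        rows.append(BiomarkerVerdict(gene, target, min_with, max_without,
                                     ratio, induced,
                                     "validated" if ok else "rejected"))
    return pd.DataFrame(
        [(r.gene_id, r.target_stressor, r.min_fold_with_target,
          r.max_fold_without_target, r.specificity_ratio,
          r.induced_everywhere_with_target, r.verdict) for r in rows],
        columns=["gene_id", "target_stressor", "min_fold_with_target",
                 "max_fold_without_target", "specificity_ratio",
                 "induced_everywhere_with_target", "verdict"],
    ).set_index("gene_id")


def leave_one_out_panels(stressors=("As(V)", "Cd", "Hg", "Cu", "Cr")
                         ) -> dict[str, frozenset]:
    """The canonical 4-of-5 design: each panel omits exactly one metal."""
    return {f"minus_{s}": frozenset(set(stressors) - {s}) for s in stressors}
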