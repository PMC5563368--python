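"""Gene-architecture (intron compactness) statistics from GFF3 models.

Rapidly stress-induced genes tend to be compact: a larger intronless
fraction, fewer introns, and shorter total intron length.  This module
derives intron architecture from GFF3 gene models (1-based inclusive
coordinates; introns are the gaps between consecutive exons of the
representative transcript, length = next_start - prev_end - 1) and runs
the class comparisons: a pooled two-proportion z-test on intronless
fractions, Kruskal-Wallis + Dunn on intron number and total intron
length (intronless genes excluded), and a Mann-Whitney test on total
intron length between the top and bottom 50% of genes ranked by fold
change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

from .stats import kruskal_dunn, mann_whitney, two_proportion_ztest

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """Exon/intron architecture of one gene's representative transcript."""

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.introns = [(e1 + 1, s2 - 1)
                        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:])]

    @property
    def intron_count(self) -> int:
        return len(self.introns)

    @property
    def intron_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.introns]

    @property
    def total_intron_length(self) -> int:
        return sum(self.intron_lengths)

    @property
    def intronless(self) -> bool:
        return self.intron_count == 0


def parse_gene_models(gff3_text: str | None = None, path=None) -> list[GeneModel]:
    """Parse gene models from GFF3, one representative transcript per gene.

    The representative transcript is the first mRNA child per gene in
    file order.  Genes whose representative transcript has overlapping
    exons are rejected with a warning; exon features without a resolvable
    parent are skipped with a warning.
    """
    if (gff3_text is None) == (path is None):
        raise ValueError("give exactly one of gff3_text or path")
    if path is not None:
        with open(path) as fh:
            gff3_text = fh.read()
    db = gffutils.create_db(gff3_text, dbfn=":memory:", from_string=True,
                            keep_order=True, merge_strategy="error")
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            warnings.warn(f"gene {gene.id} has no mRNA child; skipped", stacklevel=2)
            continue
        rep = mrnas[0]
        exons = [(e.start, e.end) for e in db.children(rep, featuretype="exon")]
        if not exons:
            warnings.warn(f"transcript {rep.id} has no exons; skipped", stacklevel=2)
            continue
        try:
            models.append(GeneModel(gene_id=gene.id, strand=gene.strand, exons=exons))
        except ValueError as exc:
            warnings.warn(f"model rejected: {exc}", stacklevel=2)
    return models


def architecture_table(models: list[GeneModel]) -> pd.DataFrame:
    """Tidy per-gene architecture: intron_count, total_intron_length."""
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "intron_count": [m.intron_count for m in models],
            "total_intron_length": [m.total_intron_length for m in models],
        }
    ).set_index("gene_id")


@dataclass
class ProportionTestResult:
    fraction_a: float
    fraction_b: float
    n_a: int
    n_b: int
    z: float
    p: float
    degenerate: bool


def intronless_fraction_test(group_a: list[GeneModel], group_b: list[GeneModel]
                             ) -> ProportionTestResult:
    """Two-proportion z-test on intronless fractions of two gene groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ka = sum(m.intronless for m in group_a)
    kb = sum(m.intronless for m in group_b)
    na, nb = len(group_a), len(group_b)
    z, p = two_proportion_ztest(ka, na, kb, nb)
    return ProportionTestResult(fraction_a=ka / na, fraction_b=kb / nb,
                                n_a=na, n_b=nb, z=z, p=p,
                                degenerate=not np.isfinite(z))


def compare_intron_metrics(groups: dict[str, list[GeneModel]],
                           metric: str = "total_intron_length"):
    """Kruskal-Wallis + Dunn on an intron metric across gene classes.

    ``metric``: "intron_count" or "total_intron_length".  Intronless
    genes are excluded before testing; groups emptied (or left with < 2
    genes) by the exclusion are omitted with a warning.  Returns
    (omnibus (H, p), Dunn DataFrame, per-group value arrays).
    """
    if metric not in ("intron_count", "total_intron_length"):
        raise ValueError(f"unknown metric {metric!r}")
    usable = {}
    for label, models in groups.items():
        values = np.array([getattr(m, metric) for m in models if not m.intronless],
                          dtype=float)
        if values.size < 2:
            warnings.warn(f"group {label!r} has <2 intron-bearing genes; omitted",
                          stacklevel=2)
            continue
        usable[label] = values
    if len(usable) < 2:
        raise ValueError("need at least two usable groups after intronless exclusion")
    h, p, dunn = kruskal_dunn(usable)
    return (h, p), dunn, usable


@dataclass
class SplitTestResult:
    u: float
    p: float
    n_top: int
    n_bottom: int
    mean_top: float
    mean_bottom: float


def split_by_fc_test(models: list[GeneModel], fc_by_gene: pd.Series
                     ) -> SplitTestResult | None:
    """Mann-Whitney on total intron length, top vs bottom 50% by FC.

    Intronless genes are excluded; genes are ranked by ``fc_by_gene``
    (ascending); with an odd count the median gene joins neither half.
    Returns None when fewer than 4 genes remain.
    """
    usable = [(m.gene_id, m.total_intron_length) for m in models
              if not m.intronless and m.gene_id in fc_by_gene.index]
    if len(usable) < 4:
        return None
    frame = pd.DataFrame(usable, columns=["gene_id", "total_intron_length"])
    frame["fc"] = fc_by_gene.loc[frame["gene_id"]].to_numpy()
    frame = frame.sort_values(["fc", "gene_id"], kind="mergesort")
    half = len(frame) // 2
    bottom = frame.iloc[:half]
    top = frame.iloc[len(frame) - half:]
    u, p = mann_whitney(top["total_intron_length"], bottom["total_intron_length"])
    return SplitTestResult(u=u, p=p, n_top=half, n_bottom=half,
                           mean_top=float(top["total_intron_length"].mean()),
                           mean_bottom=float(bottom["total_intron_length"].mean()))
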