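"""Nonparametric statistical kernels shared across the pipeline.

Every downstream comparison in the pipeline is rank-based: per-gene
treated-vs-control testing uses the Kruskal-Wallis test, multiplicity is
controlled with Benjamini-Hochberg FDR, multi-group architecture and
Ka/Ks contrasts use Kruskal-Wallis with Dunn's post-hoc test, and the
top-vs-bottom fold-change split uses the Mann-Whitney U test.  Intronless
proportions are compared with a pooled two-proportion z-test.

The scalar kernels delegate to scipy/statsmodels; ``kruskal_two_group_rows``
is a vectorized row-wise two-group Kruskal-Wallis (with midrank tie
correction) used to test thousands of genes at once, and is kept exactly
equivalent to :func:`scipy.stats.kruskal` per row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "bh_fdr",
    "kruskal_wallis",
    "kruskal_two_group_rows",
    "mann_whitney",
    "two_proportion_ztest",
    "dunn_posthoc",
    "kruskal_dunn",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * n / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p for >= 2 groups of observations.

    Ties are handled by midranks with the standard tie correction.  The
    degenerate all-identical case (tie correction divisor 0) is reported
    as no evidence at all: H = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and groups[0] and \
            hasattr(groups[0][0], "__len__"):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _tie_term(sorted_rows: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row of a row-sorted matrix."""
    g, n = sorted_rows.shape
    out = np.zeros(g)
    for i in range(g):
        row = sorted_rows[i]
        # run-length encode equal neighbours
        boundaries = np.flatnonzero(row[1:] != row[:-1]) + 1
        lengths = np.diff(np.concatenate(([0], boundaries, [n])))
        out[i] = np.sum(lengths.astype(float) ** 3 - lengths)
    return out


def kruskal_two_group_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group Kruskal-Wallis.

    Parameters
    ----------
    a, b:
        2-D arrays of shape (rows, n_a) and (rows, n_b); each row is one
        gene, columns are replicate observations of the two conditions.

    Returns
    -------
    (H, p) arrays of length ``rows``.  Rows whose values are all identical
    get H = 0, p = 1 (matching :func:`kruskal_wallis`).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ")
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    x = np.concatenate([a, b], axis=1)
    ranks = sps.rankdata(x, axis=1)
    ra = ranks[:, :na].sum(axis=1)
    rb = ranks[:, na:].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (ra**2 / na + rb**2 / nb) - 3.0 * (n + 1)
    tie = _tie_term(np.sort(x, axis=1))
    denom = 1.0 - tie / float(n**3 - n)
    degenerate = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, denom))
    h = np.clip(h, 0.0, None)
    p = sps.chi2.sf(h, df=1)
    p = np.where(degenerate, 1.0, p)
    return h, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample) and p.

    Exact null distribution for combined n <= 20 with no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 20 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_proportion_ztest(count_a: int, n_a: int, count_b: int, n_b: int
                         ) -> tuple[float, float]:
    """Pooled two-sample z-test for proportions.

    Returns (z, two-sided p).  The degenerate pooled proportion (0 or 1)
    has an undefined z; (nan, nan) is returned so callers can report it.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    pooled = (count_a + count_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        return float("nan"), float("nan")
    z, p = proportions_ztest([count_a, count_b], [n_a, n_b])
    return float(z), float(p)


@dataclass
class DunnResult:
    """One pairwise Dunn comparison (Bonferroni-adjusted)."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


def dunn_posthoc(groups: dict[str, np.ndarray]) -> list[DunnResult]:
    """Dunn's post-hoc z-tests on pooled midranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups in the pooled sample.
    """
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate([arrays[k] for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, offset = {}, {}, 0
    for k in labels:
        m = arrays[k].size
        mean_ranks[k] = ranks[offset:offset + m].mean()
        sizes[k] = m
        offset += m
    tie = _tie_term(np.sort(pooled)[None, :])[0]
    variance_core = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(labels, 2))
    results = []
    for ka, kb in pairs:
        se = np.sqrt(variance_core * (1.0 / sizes[ka] + 1.0 / sizes[kb]))
        z = (mean_ranks[ka] - mean_ranks[kb]) / se if se > 0 else float("nan")
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
        results.append(DunnResult(ka, kb, float(z), float(p),
                                  float(min(1.0, p * len(pairs))) if np.isfinite(z) else float("nan")))
    return results


def kruskal_dunn(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus over named groups plus Dunn pairwise table."""
    h, p = kruskal_wallis(*[groups[k] for k in groups])
    table = pd.DataFrame(
        [(r.group_a, r.group_b, r.z, r.p_raw, r.p_adjusted) for r in dunn_posthoc(groups)],
        columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"],
    )
    return h, p, table
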