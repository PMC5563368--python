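"""Pairwise Ka/Ks estimation on codon alignments (Nei-Gojobori counting).

Protein alignments are back-translated onto their coding sequences to
give codon alignments; synonymous and nonsynonymous sites and
differences are then counted with the NG86 scheme (equal-weight pathway
averaging for multi-difference codons, mutations to stop codons counted
as nonsynonymous sites, evolutionary paths through stop codons
excluded), and the proportions are corrected for multiple hits with the
Jukes-Cantor formula K = -(3/4) ln(1 - 4p/3).

Category comparisons are rank-based (Kruskal-Wallis + Dunn against a
pooled reference set), so the counting estimator's rank behavior, not
its absolute calibration against likelihood methods, is what downstream
conclusions rest on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .stats import kruskal_dunn

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
GAP_CODON = "---"

_AA = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Amino acid of a sense codon; '*' for stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _AA[codon]


@dataclass
class CodonAlignment:
    """A pair of gap-aligned codon sequences.

    ``codons_a`` / ``codons_b`` are equal-length lists of 3-mers or the
    all-gap codon '---'.  No internal stop codons are allowed in
    ungapped columns.
    """

    pair_id: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(f"{self.pair_id}: column counts differ")
        for codon in self.codons_a + self.codons_b:
            if codon == GAP_CODON:
                continue
            if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
                raise ValueError(f"{self.pair_id}: bad codon {codon!r}")
            if codon in STOP_CODONS:
                raise ValueError(f"{self.pair_id}: internal stop codon {codon}")

    @property
    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in zip(self.codons_a, self.codons_b)
                if a != GAP_CODON and b != GAP_CODON]


def back_translate_alignment(protein_a: str, protein_b: str,
                             cds_a: str, cds_b: str,
                             pair_id: str = "pair") -> CodonAlignment:
    """Map an aligned protein pair back onto its coding sequences.

    Each amino-acid column becomes its source codon; gap columns become
    gap codons.  Each CDS must translate (standard code) to its ungapped
    protein; a terminal stop codon on the CDS is allowed and stripped.
    """

    def codons_for(protein: str, cds: str, label: str) -> list[str]:
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{pair_id}/{label}: CDS length not divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        ungapped = protein.replace("-", "")
        if len(codons) != len(ungapped):
            raise ValueError(f"{pair_id}/{label}: CDS codes {len(codons)} residues, "
                             f"protein has {len(ungapped)}")
        out, k = [], 0
        for col, aa in enumerate(protein):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            codon = codons[k]
            if codon in STOP_CODONS:
                raise ValueError(f"{pair_id}/{label}: internal stop at codon {k + 1}")
            if translate_codon(codon) != aa.upper():
                raise ValueError(
                    f"{pair_id}/{label}: residue {k + 1} is {aa!r} but codon "
                    f"{codon} codes {translate_codon(codon)!r}")
            out.append(codon)
            k += 1
        return out

    if len(protein_a) != len(protein_b):
        raise ValueError(f"{pair_id}: aligned proteins differ in length")
    return CodonAlignment(pair_id=pair_id,
                          codons_a=codons_for(protein_a, cds_a, "a"),
                          codons_b=codons_for(protein_b, cds_b, "b"))


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) mutational sites of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    mutants that are synonymous; mutants to stop codons count as
    nonsynonymous.  n + s = 3 for every sense codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_difference_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences of a codon pair.

    For k differing positions, all k! orderings of single-nucleotide
    steps are enumerated; each step is classified against the standard
    code and the per-path (Nd, Sd) are averaged.  Paths crossing a stop
    codon are excluded; if every path is blocked, all paths are used.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        nd = sd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if translate_codon(current) == translate_codon(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return nd, sd

    def walk_through_stops(order: tuple[int, ...]) -> tuple[float, float]:
        nd = sd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            ca = translate_codon(current)
            cb = translate_codon(nxt)
            if ca == cb:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return nd, sd

    paths = [r for r in (walk(o) for o in permutations(diff_positions)) if r is not None]
    if not paths:
        paths = [walk_through_stops(o) for o in permutations(diff_positions)]
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def ng86_pair_counts(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) over the ungapped columns of a codon alignment.

    Sites are the per-codon NG86 site counts averaged across the two
    sequences and summed over columns; differences are pathway-averaged
    per column and summed.
    """
    n_sites = s_sites = nd = sd = 0.0
    for codon_a, codon_b in alignment.ungapped_columns:
        na, sa = ng86_site_counts(codon_a)
        nb, sb = ng86_site_counts(codon_b)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = ng86_difference_counts(codon_a, codon_b)
        nd += d_n
        sd += d_s
    return n_sites, s_sites, nd, sd


def jukes_cantor(p: float) -> float:
    """JC69 distance K = -(3/4) ln(1 - 4p/3); nan when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """Per-pair NG86 counts, JC-corrected rates, and their ratio."""

    pair_id: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float
    ks: float
    ratio: float          # nan when undefined (Ks = 0, 0/0, or correction diverged)
    defined: bool


def kaks(alignment: CodonAlignment) -> KaKsResult:
    """Estimate Ka, Ks and Ka/Ks for one codon alignment."""
    if not alignment.ungapped_columns:
        raise ValueError(f"{alignment.pair_id}: no ungapped codon columns")
    n_sites, s_sites, nd, sd = ng86_pair_counts(alignment)
    pn = nd / n_sites if n_sites > 0 else float("nan")
    ps = sd / s_sites if s_sites > 0 else float("nan")
    ka = jukes_cantor(pn) if not math.isnan(pn) else float("nan")
    ks = jukes_cantor(ps) if not math.isnan(ps) else float("nan")
    defined = (not math.isnan(ka)) and (not math.isnan(ks)) and ks > 0
    ratio = ka / ks if defined else float("nan")
    return KaKsResult(pair_id=alignment.pair_id, n_sites=n_sites, s_sites=s_sites,
                      nd=nd, sd=sd, pn=pn, ps=ps, ka=ka, ks=ks,
                      ratio=ratio, defined=defined)


def kaks_table(results: list[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "N": [r.n_sites for r in results],
            "S": [r.s_sites for r in results],
            "Nd": [r.nd for r in results],
            "Sd": [r.sd for r in results],
            "Ka": [r.ka for r in results],
            "Ks": [r.ks for r in results],
            "ratio": [r.ratio for r in results],
            "defined": [r.defined for r in results],
        }
    ).set_index("pair_id")


def compare_category_ratios(categories: dict[str, list[float]],
                            reference: list[float],
                            min_defined: int = 3):
    """Compare each category's Ka/Ks ratios against a pooled reference set.

    Undefined (nan) ratios are excluded; categories left with fewer than
    ``min_defined`` ratios are flagged and omitted from testing.  Returns
    a DataFrame with each category's n, median, Kruskal-Wallis p versus
    the reference, and Dunn-adjusted p (Bonferroni over the tested
    categories).
    """
    ref = np.asarray([x for x in reference if np.isfinite(x)], dtype=float)
    if ref.size < 2:
        raise ValueError("reference set too small")
    rows, tested = [], []
    for label, values in categories.items():
        vals = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
        if vals.size < min_defined:
            warnings.warn(f"category {label!r} has <{min_defined} defined ratios; "
                          "flagged and not tested", stacklevel=2)
            rows.append((label, vals.size, float(np.median(vals)) if vals.size else
                         float("nan"), float("nan"), float("nan"), False))
            continue
        h, p, _ = kruskal_dunn({label: vals, "reference": ref})
        rows.append((label, vals.size, float(np.median(vals)), float(h), float(p), True))
        tested.append(label)
    frame = pd.DataFrame(rows, columns=["category", "n", "median_ratio", "H",
                                        "p", "tested"]).set_index("category")
    n_tested = max(1, len(tested))
    frame["p_adjusted"] = np.where(frame["tested"],
                                   np.minimum(1.0, frame["p"] * n_tested),
                                   np.nan)
    return frame
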