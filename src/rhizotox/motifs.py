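"""IUPAC promoter-motif scanning and permutation enrichment.

Scans 1 kb upstream promoter sets for degenerate (IUPAC) consensus
motifs and compares the per-gene presence fraction between two promoter
sets (typically general-stress-response vs background genes) with a
label-permutation test.

The enrichment statistic is the difference of per-gene presence
percentages (a gene counts once no matter how many occurrences its
promoter holds).  The null is built by shuffling group labels over the
pooled promoters, preserving group sizes; the one-sided p-value uses the
add-one rule p = (1 + #{permuted >= observed}) / (1 + n_permutations), so
p is never zero.  Motifs are matched on both strands by default.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus motif."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif")
        for i, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {ch!r} at position {i + 1}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.iupac))
        return MotifPattern(self.name, rc)


#: Built-in motif set reported enriched in GSR promoters.
BUILTIN_MOTIFS = {
    "W-box": MotifPattern("W-box", "TTGACY"),
    "ABRE-like": MotifPattern("ABRE-like", "BACGTGKM"),
    "RWRE": MotifPattern("RWRE", "CGCGTT"),
    "CGCG box": MotifPattern("CGCG box", "SCGCGCS"),
}


def resolve_motif(spec: str) -> MotifPattern:
    """Look up a built-in motif by name, or build one from an IUPAC string."""
    if spec in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[spec]
    return MotifPattern(spec, spec)


def expand_iupac(pattern: MotifPattern) -> int:
    """Number of concrete sequences the consensus matches."""
    count = 1
    for ch in pattern.iupac:
        count *= len(IUPAC_CODES[ch])
    return count


def _regex(pattern: MotifPattern) -> re.Pattern:
    # N in the *sequence* never matches, so the classes list only ACGT.
    return re.compile("".join(f"[{IUPAC_CODES[c]}]" if len(IUPAC_CODES[c]) > 1
                              else IUPAC_CODES[c] for c in pattern.iupac))


def scan_sequence(seq: str, pattern: MotifPattern, strands: str = "both"
                  ) -> list[tuple[int, str]]:
    """All match start positions (1-based on the forward sequence).

    Returns sorted (position, strand) tuples; overlapping matches are
    reported.  A reverse-strand hit is recorded at the forward-strand
    start of the matching window.  ``strands``: "forward" or "both".
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    s = seq.upper()
    hits = []
    fwd = _regex(pattern)
    pos = 0
    while True:
        m = fwd.search(s, pos)
        if m is None:
            break
        hits.append((m.start() + 1, "+"))
        pos = m.start() + 1
    if strands == "both":
        rev = _regex(pattern.reverse_complement())
        pos = 0
        while True:
            m = rev.search(s, pos)
            if m is None:
                break
            hits.append((m.start() + 1, "-"))
            pos = m.start() + 1
    return sorted(hits)


def has_motif(seq: str, pattern: MotifPattern, strands: str = "both") -> bool:
    """True if the sequence holds at least one motif instance."""
    s = seq.upper()
    if _regex(pattern).search(s):
        return True
    if strands == "both" and _regex(pattern.reverse_complement()).search(s):
        return True
    return False


def read_promoters(path) -> dict[str, str]:
    """Read a promoter FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def gene_fraction_with_motif(promoters: dict[str, str], pattern: MotifPattern,
                             strands: str = "both") -> float:
    """Percentage of promoters containing >= 1 motif instance."""
    if not promoters:
        raise ValueError("empty promoter set")
    n_hit = sum(has_motif(seq, pattern, strands) for seq in promoters.values())
    return 100.0 * n_hit / len(promoters)


@dataclass
class EnrichmentResult:
    """Permutation-test enrichment of a motif between two promoter sets."""

    motif: str
    name: str
    fraction_in_group_a: float  # percent of genes with >= 1 hit
    fraction_in_group_b: float
    observed_difference: float  # percentage points, A - B
    p_value: float
    n_permutations: int
    seed: int


def permutation_enrichment(group_a: dict[str, str], group_b: dict[str, str],
                           pattern: MotifPattern, n_permutations: int = 10_000,
                           seed: int = 0, strands: str = "both") -> EnrichmentResult:
    """One-sided permutation test for motif enrichment in group A over B.

    Per-gene presence is computed once; the group labels are then
    shuffled ``n_permutations`` times over the pooled genes, preserving
    group sizes.  p uses the add-one rule and the ">= observed" tail.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    presence_a = np.array([has_motif(s, pattern, strands)
                           for s in group_a.values()], dtype=float)
    presence_b = np.array([has_motif(s, pattern, strands)
                           for s in group_b.values()], dtype=float)
    frac_a = 100.0 * presence_a.mean()
    frac_b = 100.0 * presence_b.mean()
    observed = frac_a - frac_b
    # canonical order: presence is exchangeable, and sorting makes the
    # Monte-Carlo p invariant to gene order within each group
    pooled = np.concatenate([np.sort(presence_a)[::-1], np.sort(presence_b)[::-1]])
    n_a = presence_a.size
    rng = np.random.default_rng(seed)
    exceed = 0
    # Vectorized label shuffles in blocks to bound memory.
    block = 1000
    done = 0
    while done < n_permutations:
        k = min(block, n_permutations - done)
        perms = np.argsort(rng.random((k, pooled.size)), axis=1)
        shuffled = pooled[perms]
        diff = 100.0 * (shuffled[:, :n_a].mean(axis=1)
                        - shuffled[:, n_a:].mean(axis=1))
        exceed += int(np.sum(diff >= observed - 1e-12))
        done += k
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return EnrichmentResult(motif=pattern.iupac, name=pattern.name,
                            fraction_in_group_a=frac_a, fraction_in_group_b=frac_b,
                            observed_difference=observed, p_value=p,
                            n_permutations=n_permutations, seed=seed)
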