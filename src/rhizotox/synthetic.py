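"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the eight-rhizotoxin rice root study design: for each stressor
(Cu, As(V), Cd, Hg, Cr, V, ferulic acid, juglone) an intensity matrix
with two timepoints (1 h, 3 h), three biological replicates and paired
control/treated samples on a shared gene universe — plus matching
promoter FASTA sets, GFF3 gene models, ortholog CDS/protein-alignment
pairs, an interaction edge list, and qPCR Ct tables.

Every generator takes an explicit seed (substreams are derived
deterministically from one master seed) and returns a truth table
recording what was planted, so recovery tests can score the pipeline
against ground truth.  Intensities are log-normal around a per-gene
baseline with multiplicative treatment effects, so the noise-free limit
reproduces the class-defining fold-change inequalities exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .biomarker import STRESS_SEPARATOR, CtTable
from .evolution import (NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, translate_codon)
from .expression import STRESSORS, ExpressionDataset
from .motifs import IUPAC_CODES, MotifPattern, has_motif

CLASS_LABELS = ("GSR_up", "generally_down", "background", "low_regulated")

#: Multiplicative treatment-effect ranges per planted class (per stress
#: and timepoint).  GSR/unique inductions sit comfortably above the
#: 2-fold call threshold; low-regulated effects stay inside (1.2, 2).
GSR_EFFECT_RANGE = (2.5, 6.0)
LOW_REGULATED_EFFECT_RANGE = (1.3, 1.9)

#: Planted regulated genes draw baselines log-uniformly in this range:
#: stress-inducible genes tend to have low basal expression, and the
#: range keeps every planted gene clear of the 100-intensity detection
#: filter.  Filler genes are log-normal around the configured baseline
#: and may fall below the filter.
PLANTED_BASELINE_RANGE = (200.0, 2000.0)

#: Planted background genes sit higher: genes flat across all eight
#: stresses are the constitutively expressed bulk.
BACKGROUND_BASELINE_RANGE = (2000.0, 20000.0)


def substream(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-generator random substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Design of the synthetic expression experiment."""

    n_genes: int = 2000
    stressors: tuple = STRESSORS
    timepoints: int = 2
    replicates: int = 3
    planted_counts: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    baseline_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates for testing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.baseline_intensity <= 0:
            raise ConfigurationError("baseline_intensity must be positive")
        for label, count in self.planted_counts.items():
            if count < 0:
                raise ConfigurationError(f"negative count for {label!r}")
            base = label.split(":")[0]
            if base not in CLASS_LABELS + ("unique_up", "unique_down"):
                raise ConfigurationError(f"unknown class label {label!r}")
            if base in ("unique_up", "unique_down"):
                stress = label.split(":", 1)[1] if ":" in label else None
                if stress not in self.stressors:
                    raise ConfigurationError(
                        f"unique label {label!r} must name one of the stressors")
        if sum(self.planted_counts.values()) > self.n_genes:
            raise ConfigurationError("planted counts exceed n_genes")

    @property
    def timepoint_hours(self) -> list[int]:
        hours = [1, 3]
        if self.timepoints <= 2:
            return hours[: self.timepoints]
        return hours + list(range(5, 5 + 2 * (self.timepoints - 2), 2))


def default_planted_counts(stressors=STRESSORS, n_genes: int = 2000) -> dict:
    """The study-scale planting: 100 GSR-up, 20 generally down, 10
    uniquely-up per stress, 100 background, 50 low-regulated (at the
    canonical 2000-gene universe; smaller universes scale down
    proportionally, keeping at least one gene per class)."""
    factor = min(1.0, n_genes / 2000.0)
    counts = {"GSR_up": 100, "generally_down": 20,
              "background": 100, "low_regulated": 50}
    for s in stressors:
        counts[f"unique_up:{s}"] = 10
    return {label: max(1, int(round(count * factor)))
            for label, count in counts.items()}


def generate_expression(config: SyntheticConfig
                        ) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate the intensity matrix + metadata and its truth table.

    Control replicate intensities are ``baseline * exp(noise_sd * Z)``;
    treated replicates multiply in the class effect for that (stress,
    timepoint).  With ``noise_sd = 0`` the per-stress signed fold change
    equals the planted effect exactly.
    """
    rng = substream(config.seed, 0)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    labels = []
    for label, count in config.planted_counts.items():
        labels += [label] * count
    labels += ["filler"] * (config.n_genes - len(labels))

    n_planted = sum(config.planted_counts.values())
    baselines = np.empty(config.n_genes)
    lo, hi = np.log(PLANTED_BASELINE_RANGE[0]), np.log(PLANTED_BASELINE_RANGE[1])
    baselines[:n_planted] = np.exp(rng.uniform(lo, hi, size=n_planted))
    baselines[n_planted:] = np.exp(
        rng.normal(math.log(config.baseline_intensity), 1.0,
                   size=config.n_genes - n_planted))
    blo, bhi = (np.log(BACKGROUND_BASELINE_RANGE[0]),
                np.log(BACKGROUND_BASELINE_RANGE[1]))
    for i, label in enumerate(labels[:n_planted]):
        if label == "background":
            baselines[i] = np.exp(rng.uniform(blo, bhi))

    hours = config.timepoint_hours
    n_s, n_t = len(config.stressors), len(hours)
    effects = np.ones((config.n_genes, n_s, n_t))
    for i, label in enumerate(labels):
        base = label.split(":")[0]
        if base == "GSR_up":
            effects[i] = rng.uniform(*GSR_EFFECT_RANGE, size=(n_s, n_t))
        elif base == "generally_down":
            effects[i] = 1.0 / rng.uniform(*GSR_EFFECT_RANGE, size=(n_s, n_t))
        elif base == "low_regulated":
            effects[i] = rng.uniform(*LOW_REGULATED_EFFECT_RANGE, size=(n_s, n_t))
        elif base in ("unique_up", "unique_down"):
            stress = label.split(":", 1)[1]
            j = list(config.stressors).index(stress)
            draw = rng.uniform(*GSR_EFFECT_RANGE, size=n_t)
            effects[i, j, :] = draw if base == "unique_up" else 1.0 / draw
        # background / filler keep effect 1

    columns, meta_rows = [], []
    values = {}
    for j, stress in enumerate(config.stressors):
        for t, hour in enumerate(hours):
            for condition in ("control", "treated"):
                eff = effects[:, j, t] if condition == "treated" else 1.0
                for rep in range(1, config.replicates + 1):
                    sample_id = f"{stress}_{hour}h_{condition}_{rep}"
                    noise = (np.exp(config.noise_sd
                                    * rng.standard_normal(config.n_genes))
                             if config.noise_sd > 0 else 1.0)
                    values[sample_id] = baselines * eff * noise
                    meta_rows.append((sample_id, stress, hour, rep, condition))
                    columns.append(sample_id)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=columns)
    samples = pd.DataFrame(meta_rows, columns=["sample_id", "stress", "timepoint",
                                               "replicate", "condition"]
                           ).set_index("sample_id")
    truth = pd.DataFrame({"gene_id": genes, "label": labels,
                          "baseline": baselines}).set_index("gene_id")
    return ExpressionDataset(values=matrix, samples=samples), truth


def _concrete_instance(motif: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))]
                   for c in motif.iupac)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def generate_promoters(n_gsr: int, n_background: int, motif: MotifPattern,
                       planted_fraction_gsr: float, planted_fraction_bg: float,
                       length: int = 1000, seed: int = 0
                       ) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Two promoter sets with exact planted per-gene motif fractions.

    Exactly ``round(fraction * n)`` promoters per group carry >= 1 exact
    motif instance; the rest are rejection-sampled to contain no
    instance on either strand, so scanner-measured fractions match the
    request exactly.
    """
    for frac in (planted_fraction_gsr, planted_fraction_bg):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError("fractions must lie in [0, 1]")
    if length < len(motif):
        raise ConfigurationError("motif longer than the promoter")
    rng = substream(seed, 1)

    def build_group(prefix: str, n: int, fraction: float) -> tuple[dict, list]:
        planted_n = round(fraction * n)
        sequences, rows = {}, []
        for i in range(n):
            name = f"{prefix}{i:04d}"
            planted = i < planted_n
            if planted:
                seq = _random_sequence(length, rng)
                instance = _concrete_instance(motif, rng)
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + instance + seq[pos + len(motif):]
            else:
                while True:
                    seq = _random_sequence(length, rng)
                    if not has_motif(seq, motif, strands="both"):
                        break
            sequences[name] = seq
            rows.append((name, prefix.rstrip("_"), planted))
        return sequences, rows

    gsr, rows_a = build_group("gsr_", n_gsr, planted_fraction_gsr)
    background, rows_b = build_group("bg_", n_background, planted_fraction_bg)
    truth = pd.DataFrame(rows_a + rows_b,
                         columns=["gene_id", "group", "planted"]).set_index("gene_id")
    return gsr, background, truth


def _draw(dist: dict, rng: np.random.Generator, minimum: int) -> int:
    """Sample one integer from a distribution spec dict."""
    if len(dist) != 1:
        raise ConfigurationError(f"bad distribution spec {dist!r}")
    (kind, param), = dist.items()
    if kind == "fixed":
        value = int(param)
    elif kind == "poisson":
        value = int(rng.poisson(float(param)))
    elif kind == "uniform_int":
        lo, hi = param
        value = int(rng.integers(int(lo), int(hi) + 1))
    elif kind == "geometric_mean":
        # geometric with the given mean (support >= 0)
        value = int(rng.geometric(1.0 / (float(param) + 1.0)) - 1)
    else:
        raise ConfigurationError(f"unknown distribution kind {kind!r}")
    return max(minimum, value)


def generate_gene_models(groups: dict[str, dict], seed: int = 0
                         ) -> tuple[str, pd.DataFrame]:
    """GFF3 gene models with per-group intron architecture.

    ``groups``: label -> {"n": count, "intron_count": dist spec,
    "intron_length": dist spec}; dist specs are single-key dicts like
    {"fixed": 0}, {"poisson": 4}, {"uniform_int": (50, 500)}.  Returns
    the GFF3 text (version 3, 1-based inclusive) and a truth table with
    each gene's intron count and total intron length.
    """
    rng = substream(seed, 2)
    lines = ["##gff-version 3"]
    rows = []
    cursor = 1
    idx = 0
    for label, spec in groups.items():
        for _ in range(int(spec["n"])):
            gene_id = f"syn{idx:05d}"
            idx += 1
            n_introns = _draw(spec["intron_count"], rng, minimum=0)
            intron_lengths = [_draw(spec["intron_length"], rng, minimum=1)
                              for _ in range(n_introns)]
            exon_lengths = [int(rng.integers(80, 301)) for _ in range(n_introns + 1)]
            exons = []
            pos = cursor
            for k, exon_len in enumerate(exon_lengths):
                exons.append((pos, pos + exon_len - 1))
                pos += exon_len
                if k < n_introns:
                    pos += intron_lengths[k]
            gene_start, gene_end = exons[0][0], exons[-1][1]
            mrna_id = f"{gene_id}.1"
            lines.append("\t".join(["chr1", "synthetic", "gene", str(gene_start),
                                    str(gene_end), ".", "+", ".", f"ID={gene_id}"]))
            lines.append("\t".join(["chr1", "synthetic", "mRNA", str(gene_start),
                                    str(gene_end), ".", "+", ".",
                                    f"ID={mrna_id};Parent={gene_id}"]))
            for k, (s, e) in enumerate(exons, start=1):
                lines.append("\t".join(["chr1", "synthetic", "exon", str(s), str(e),
                                        ".", "+", ".",
                                        f"ID={mrna_id}.exon{k};Parent={mrna_id}"]))
            rows.append((gene_id, label, n_introns, sum(intron_lengths)))
            cursor = gene_end + 500
    truth = pd.DataFrame(rows, columns=["gene_id", "group", "intron_count",
                                        "total_intron_length"]).set_index("gene_id")
    return "\n".join(lines) + "\n", truth


def _random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    codons = np.array(SENSE_CODONS)
    return list(codons[rng.integers(0, len(codons), size=n)])


def _mutate_sequence(codons: list[str], n_proposals: int, omega: float,
                     rng: np.random.Generator) -> list[str]:
    """Propose single-nucleotide changes; reject stops; accept
    nonsynonymous proposals with probability min(1, omega)."""
    codons = list(codons)
    for _ in range(n_proposals):
        i = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        current = codons[i]
        alternatives = [n for n in NUCLEOTIDES if n != current[pos]]
        nt = alternatives[int(rng.integers(3))]
        mutant = current[:pos] + nt + current[pos + 1:]
        if mutant in STOP_CODONS:
            continue
        if translate_codon(mutant) != translate_codon(current):
            if rng.random() >= min(1.0, omega):
                continue
        codons[i] = mutant
    return codons


def generate_ortholog_pairs(n_pairs: int, codons_per_gene: int = 500,
                            omega: float = 0.2, branch_mutations: float = 0.15,
                            seed: int = 0
                            ) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Simulated ortholog pairs evolved under a fixed dN/dS (omega).

    Each pair descends from a random stop-free ancestor; each of the two
    lineages receives ``Poisson(branch_mutations * codons_per_gene)``
    proposed single-nucleotide mutations (uniform position and change),
    stop-creating proposals are rejected, and nonsynonymous proposals
    are accepted with probability min(1, omega) — the neutral limit
    (omega = 1) therefore has dN/dS = 1.

    Returns (CDS sequences, aligned protein sequences, truth table);
    ids are ``pair####_a`` / ``pair####_b``.
    """
    if omega < 0:
        raise ConfigurationError("omega must be nonnegative")
    if branch_mutations < 0:
        raise ConfigurationError("branch_mutations must be nonnegative")
    rng = substream(seed, 3)
    cds, proteins, rows = {}, {}, []
    for i in range(n_pairs):
        ancestor = _random_sense_codons(codons_per_gene, rng)
        pair = {}
        for suffix in ("a", "b"):
            n_prop = int(rng.poisson(branch_mutations * codons_per_gene))
            pair[suffix] = _mutate_sequence(ancestor, n_prop, omega, rng)
        name = f"pair{i:04d}"
        for suffix in ("a", "b"):
            codons = pair[suffix]
            cds[f"{name}_{suffix}"] = "".join(codons)
            proteins[f"{name}_{suffix}"] = "".join(translate_codon(c) for c in codons)
        n_diff = sum(ca != cb for ca, cb in zip(pair["a"], pair["b"]))
        rows.append((name, omega, n_diff))
    truth = pd.DataFrame(rows, columns=["pair_id", "omega", "codon_differences"]
                         ).set_index("pair_id")
    return cds, proteins, truth


def generate_network(n_nodes: int, planted_hubs: int = 0, hub_degree: int = 30,
                     background_degree_mean: float = 3.0,
                     regulator_labels=(), seed: int = 0
                     ) -> tuple[nx.Graph, pd.DataFrame]:
    """Erdos-Renyi background graph with planted high-degree hubs.

    The first ``planted_hubs`` nodes get extra edges to random non-hub
    partners until they reach ``hub_degree``.  Requires ``hub_degree >
    background_degree_mean`` so planted hubs dominate the degree ranking.
    """
    if planted_hubs > n_nodes:
        raise ConfigurationError("more hubs than nodes")
    if planted_hubs and hub_degree <= background_degree_mean:
        raise ConfigurationError("hub_degree must exceed background_degree_mean")
    rng = substream(seed, 4)
    names = [f"n{i:04d}" for i in range(n_nodes)]
    p = min(1.0, background_degree_mean / max(1, n_nodes - 1))
    graph = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))
    graph.add_nodes_from(names)
    hubs = names[:planted_hubs]
    non_hubs = names[planted_hubs:]
    for hub in hubs:
        candidates = [n for n in non_hubs if not graph.has_edge(hub, n)]
        need = hub_degree - graph.degree(hub)
        if need > len(candidates):
            raise ConfigurationError("not enough nodes to reach hub_degree")
        if need > 0:
            chosen = rng.choice(len(candidates), size=need, replace=False)
            graph.add_edges_from((hub, candidates[k]) for k in chosen)
    regulators = set(regulator_labels)
    truth = pd.DataFrame({
        "node": names,
        "is_hub": [n in set(hubs) for n in names],
        "role": ["regulator" if n in regulators else "other" for n in names],
    }).set_index("node")
    return graph, truth


def edge_list_lines(graph: nx.Graph) -> list[str]:
    """Deterministic TSV edge-list serialization (sorted endpoints)."""
    return [f"{a}\t{b}" for a, b in sorted(tuple(sorted(e)) for e in graph.edges)]


def generate_ct_table(stressor_panels: dict[str, set],
                      biomarker_profiles: dict[str, dict[str, float]],
                      reference_gene: str = "tubulin_alpha",
                      seed: int = 0) -> tuple[CtTable, pd.DataFrame]:
    """qPCR Ct table whose ddCt quantification recovers planted folds exactly.

    ``stressor_panels``: panel label -> stress subset.  ``biomarker_profiles``:
    gene -> {panel -> fold induction vs the water control}.  The reference
    gene is held at a constant Ct; each target's treated Ct drops by one
    cycle per 2-fold planted induction.  Technical triplicate rows are
    emitted (identical Ct, so recovery is to machine precision).
    """
    for gene, profile in biomarker_profiles.items():
        for panel, fold in profile.items():
            if panel not in stressor_panels:
                raise ConfigurationError(f"unknown panel {panel!r} for {gene!r}")
            if fold <= 0:
                raise ConfigurationError("fold inductions must be positive")
    rng = substream(seed, 5)
    reference_ct = 20.0
    samples = [("water", "water", "", "control")]
    samples += [(panel, panel,
                 STRESS_SEPARATOR.join(sorted(stressor_panels[panel])), "treated")
                for panel in stressor_panels]
    rows = []
    truth_rows = []
    for gene, profile in biomarker_profiles.items():
        base_ct = float(rng.uniform(26.0, 30.0))
        ct_by_sample = {"water": base_ct}
        for panel in stressor_panels:
            fold = profile.get(panel, 1.0)
            ct_by_sample[panel] = base_ct - math.log2(fold)
            truth_rows.append((gene, panel, fold))
        for sample_id, ct_value in ct_by_sample.items():
            rows += [(gene, sample_id, ct_value)] * 3
    for sample_id, *_ in samples:
        rows += [(reference_gene, sample_id, reference_ct)] * 3
    ct = pd.DataFrame(rows, columns=["gene_id", "sample_id", "ct"])
    meta = pd.DataFrame(samples, columns=["sample_id", "panel", "stresses",
                                          "condition"]).set_index("sample_id")
    table = CtTable(ct=ct, samples=meta, reference_gene=reference_gene)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "panel", "fold"])
    return table, truth
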