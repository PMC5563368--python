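"""End-to-end orchestration of the analysis stages from one configuration.

Stage order: simulate (synthetic mode) -> classify -> {motifs,
architecture, kaks, network, biomarker}.  Each stage writes its tables
under the output directory and records its status, output paths and
SHA-256 checksums in a JSON run manifest; a failed stage marks its
dependents skipped.  All randomness flows from ``PipelineConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import (architecture_table, compare_intron_metrics,
                           intronless_fraction_test, parse_gene_models)
from .biomarker import (combined_panel_validation, leave_one_out_panels,
                        panel_folds)
from .evolution import back_translate_alignment, kaks, kaks_table
from .expression import (ExpressionDataset, classify_genes, filter_low_intensity,
                         joint_quantile_normalize, per_stress_fc_table,
                         summarize_counts, STRESSORS)
from .motifs import (BUILTIN_MOTIFS, permutation_enrichment, read_promoters,
                     write_fasta)
from .network import hubs_table, load_edge_list, terminal_regulators
from .synthetic import (SyntheticConfig, default_planted_counts, edge_list_lines,
                        generate_ct_table, generate_expression,
                        generate_gene_models, generate_network,
                        generate_ortholog_pairs, generate_promoters)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "motifs", "architecture", "kaks",
          "network", "biomarker")

DEPENDENCIES = {
    "classify": ("simulate",),
    "motifs": (),
    "architecture": (),
    "kaks": (),
    "network": (),
    "biomarker": (),
}


@dataclass
class PipelineConfig:
    """Thresholds, inputs and run options for a pipeline run."""

    output_dir: str = "results/run"
    seed: int = 0
    synthetic: bool = True
    n_genes: int = 2000
    noise_sd: float = 0.05
    stressors: tuple = STRESSORS
    intensity_min: float = 100.0
    # joint quantile normalization is for integrating separately scaled
    # datasets; a single jointly generated matrix is already on one scale
    quantile_normalize: bool = False
    deg_fc: float = 2.0
    unique_other: float = 1.4
    background: float = 1.2
    fdr: float = 0.05
    n_permutations: int = 10_000
    excluded_stressors: tuple = ("V",)
    # input paths (used when synthetic=False, or to override)
    expression_tsv: str | None = None
    samples_tsv: str | None = None
    promoters_gsr: str | None = None
    promoters_background: str | None = None
    gff3: str | None = None
    edge_list: str | None = None
    ct_csv: str | None = None
    ct_samples: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stressors", "excluded_stressors"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Invariant violations of a config; empty list when valid."""
    violations = []
    for name in ("intensity_min", "deg_fc", "unique_other", "background", "fdr"):
        if getattr(config, name) <= 0:
            violations.append(f"{name} must be positive")
    if not (config.deg_fc > config.unique_other > config.background > 1.0):
        violations.append("threshold ordering deg_fc > unique_other > background > 1 "
                          "violated")
    if config.fdr >= 1.0:
        violations.append("fdr must be < 1")
    if config.n_permutations < 1:
        violations.append("n_permutations must be >= 1")
    if not config.stressors:
        violations.append("stressor list is empty")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest dict."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}
    state: dict = {}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "ok"}
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    def run_stage(stage: str, fn) -> None:
        for dep in DEPENDENCIES.get(stage, ()):
            if manifest["stages"].get(dep, {}).get("status") != "ok":
                manifest["stages"][stage] = {"status": "skipped",
                                             "reason": f"dependency {dep} failed"}
                logger.warning("stage %s skipped (dependency %s)", stage, dep)
                return
        try:
            record(stage, fn())
        except Exception as exc:  # stage isolation: later stages still run
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc),
                                         "traceback": traceback.format_exc()}

    thresholds = {"deg": config.deg_fc, "unique_other": config.unique_other,
                  "background": config.background}

    # --- simulate -----------------------------------------------------
    def stage_simulate() -> list[Path]:
        paths = []
        if config.synthetic:
            syn = SyntheticConfig(n_genes=config.n_genes,
                                  stressors=tuple(config.stressors),
                                  planted_counts=default_planted_counts(
                                      tuple(config.stressors), config.n_genes),
                                  noise_sd=config.noise_sd, seed=config.seed)
            dataset, truth = generate_expression(syn)
            ev, sv = out / "expression.tsv", out / "samples.tsv"
            dataset.write(ev, sv)
            truth.to_csv(out / "expression_truth.tsv", sep="\t")
            state["dataset"] = dataset
            paths += [ev, sv, out / "expression_truth.tsv"]
        else:
            if not (config.expression_tsv and config.samples_tsv):
                raise FileNotFoundError("expression_tsv and samples_tsv required "
                                        "when synthetic=False")
            state["dataset"] = ExpressionDataset.read(config.expression_tsv,
                                                      config.samples_tsv)
        return paths

    # --- classify -----------------------------------------------------
    def stage_classify() -> list[Path]:
        dataset = state["dataset"]
        if config.quantile_normalize:
            dataset = joint_quantile_normalize([dataset])
        dataset = filter_low_intensity(dataset, config.intensity_min)
        fc = per_stress_fc_table(dataset, stressors=list(config.stressors))
        result = classify_genes(fc, thresholds=thresholds, fdr_cutoff=config.fdr)
        summary = summarize_counts(result)
        state["fc"], state["classification"] = fc, result
        fc_path = out / "fold_changes.tsv"
        fc.to_csv(fc_path, sep="\t", index=False, float_format="%.6g")
        cls_path = out / "classification.tsv"
        result.write(cls_path)
        sum_path = out / "summary_table.tsv"
        summary.to_csv(sum_path, sep="\t")
        return [fc_path, cls_path, sum_path]

    # --- motifs -------------------------------------------------------
    def stage_motifs() -> list[Path]:
        if config.promoters_gsr and config.promoters_background:
            gsr = read_promoters(config.promoters_gsr)
            background = read_promoters(config.promoters_background)
        elif config.synthetic:
            motif = BUILTIN_MOTIFS["CGCG box"]
            gsr, background, truth = generate_promoters(
                60, 60, motif, 0.5, 0.2, length=1000, seed=config.seed)
            write_fasta(out / "promoters_gsr.fasta", gsr)
            write_fasta(out / "promoters_background.fasta", background)
            truth.to_csv(out / "promoter_truth.tsv", sep="\t")
        else:
            raise FileNotFoundError("promoter FASTA paths required")
        rows = []
        for name, motif in BUILTIN_MOTIFS.items():
            res = permutation_enrichment(gsr, background, motif,
                                         n_permutations=config.n_permutations,
                                         seed=config.seed)
            rows.append((motif.iupac, name, res.fraction_in_group_a,
                         res.fraction_in_group_b, res.observed_difference,
                         res.p_value))
        table = pd.DataFrame(rows, columns=["motif", "name", "pct_gsr",
                                            "pct_background", "difference", "p"])
        path = out / "motif_enrichment.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return [path]

    # --- architecture -------------------------------------------------
    def stage_architecture() -> list[Path]:
        if config.gff3:
            models = parse_gene_models(path=config.gff3)
            groups = {"all": models}
        elif config.synthetic:
            gff3, truth = generate_gene_models(
                {"gsr": {"n": 150, "intron_count": {"poisson": 1.2},
                         "intron_length": {"uniform_int": (60, 400)}},
                 "background": {"n": 150, "intron_count": {"poisson": 4.0},
                                "intron_length": {"uniform_int": (200, 1500)}}},
                seed=config.seed)
            (out / "gene_models.gff3").write_text(gff3)
            truth.to_csv(out / "gene_model_truth.tsv", sep="\t")
            models = parse_gene_models(gff3_text=gff3)
            by_id = {m.gene_id: m for m in models}
            groups = {label: [by_id[g] for g in truth.index[truth["group"] == label]]
                      for label in ("gsr", "background")}
        else:
            raise FileNotFoundError("gff3 path required")
        arch = architecture_table([m for ms in groups.values() for m in ms])
        path = out / "architecture.tsv"
        arch.to_csv(path, sep="\t")
        paths = [path]
        if len(groups) >= 2:
            labels = list(groups)
            prop = intronless_fraction_test(groups[labels[0]], groups[labels[1]])
            (omnibus, dunn, _) = compare_intron_metrics(groups,
                                                        "total_intron_length")
            report = pd.DataFrame({
                "test": ["intronless_z", "kruskal_total_intron_length"],
                "statistic": [prop.z, omnibus[0]],
                "p": [prop.p, omnibus[1]],
            })
            rpath = out / "architecture_tests.tsv"
            report.to_csv(rpath, sep="\t", index=False, float_format="%.6g")
            paths.append(rpath)
        return paths

    # --- kaks ---------------------------------------------------------
    def stage_kaks() -> list[Path]:
        cds, proteins, truth = generate_ortholog_pairs(
            n_pairs=40, codons_per_gene=300, omega=0.2, seed=config.seed)
        results = []
        for pair in truth.index:
            aln = back_translate_alignment(proteins[f"{pair}_a"],
                                           proteins[f"{pair}_b"],
                                           cds[f"{pair}_a"], cds[f"{pair}_b"],
                                           pair_id=pair)
            results.append(kaks(aln))
        table = kaks_table(results)
        path = out / "kaks.tsv"
        table.to_csv(path, sep="\t", float_format="%.6g")
        return [path]

    # --- network ------------------------------------------------------
    def stage_network() -> list[Path]:
        if config.edge_list:
            graph = load_edge_list(path=config.edge_list)
            regulators = ()
        elif config.synthetic:
            graph, truth = generate_network(400, planted_hubs=10, hub_degree=30,
                                            background_degree_mean=3.0,
                                            seed=config.seed)
            regulators = tuple(truth.index[:20])
            (out / "network_edges.tsv").write_text(
                "\n".join(edge_list_lines(graph)) + "\n")
        else:
            raise FileNotFoundError("edge_list path required")
        hubs = hubs_table(graph, k=10)
        hpath = out / "network_hubs.tsv"
        hubs.to_csv(hpath, sep="\t", index=False)
        paths = [hpath]
        if regulators:
            terms = terminal_regulators(graph, regulators)
            tpath = out / "terminal_regulators.tsv"
            pd.DataFrame([(k, ",".join(v)) for k, v in terms.items()],
                         columns=["regulator", "neighbors"]
                         ).to_csv(tpath, sep="\t", index=False)
            paths.append(tpath)
        return paths

    # --- biomarker ----------------------------------------------------
    def stage_biomarker() -> list[Path]:
        panels = leave_one_out_panels()
        profiles = {
            "cd_marker": {p: (32.0 if "Cd" in comp else 2.0)
                          for p, comp in panels.items()},
            "decoy": {p: 10.0 for p in panels},
        }
        table, truth = generate_ct_table(panels, profiles, seed=config.seed)
        folds = panel_folds(table)
        candidates = pd.DataFrame({"target_stressor": ["Cd", "Cd"],
                                   "fold": [32.0, 10.0]},
                                  index=pd.Index(["cd_marker", "decoy"],
                                                 name="gene_id"))
        report = combined_panel_validation(candidates, folds, panels)
        path = out / "biomarker_report.tsv"
        report.to_csv(path, sep="\t", float_format="%.6g")
        return [path]

    run_stage("simulate", stage_simulate)
    run_stage("classify", stage_classify)
    run_stage("motifs", stage_motifs)
    run_stage("architecture", stage_architecture)
    run_stage("kaks", stage_kaks)
    run_stage("network", stage_network)
    run_stage("biomarker", stage_biomarker)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
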