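"""End-to-end orchestration: simulate -> preprocess -> DE -> dosage ->
annotate -> scan -> integrate, with deterministic seeding and a run manifest.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``; each stage receives one child, so
toggling stages never perturbs another stage's stream.  Every stage writes its
outputs to ``outdir`` and contributes record counts and SHA-256 checksums to
``manifest.json``; re-running with the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential_expression import call_de, de_frame
from .dosage_classifier import classify_all, dosage_profiles, group_summary
from .io_formats import (read_bed, read_expression_table, read_fasta,
                         read_gene_models, read_meme_motif, read_sample_design,
                         write_bed, write_expression_table, write_fasta,
                         write_gene_models, write_meme_motif,
                         write_sample_design, write_table)
from .motif_scan import central_enrichment, pax9_consensus_pwm, scan, trim_central
from .peak_annotation import (annotate_peaks, annotation_frame,
                              category_distribution)
from .preprocess import preprocess_pipeline
from .synthetic_data import (SimulationConfig, simulate_expression,
                             simulate_genome)
from .target_integration import bound_fraction, dosage_direct_summary, integrate

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

STAGES = ("simulate", "preprocess", "de", "dosage", "annotate", "scan", "integrate")


@dataclass
class PipelineConfig:
    outdir: str = "dosereg_run"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    # simulation
    n_genes: int = 2000
    replicates_per_genotype: int = 3
    noise_sd_log2: float = 0.15
    n_peak_genes: int = 100
    category_plan: dict = field(default_factory=lambda: {
        "TSS": 100, "promoter": 100, "intragenic": 100,
        "proximal": 100, "distal": 100, "others": 100})
    # thresholds
    fc_threshold: float = 1.5
    alpha: float = 0.05
    p_mode: str = "bh"
    motif_p: float = 0.001
    central_window: int = 100
    # optional external inputs (used when the simulate stage is off)
    expression_path: str | None = None
    design_path: str | None = None
    peaks_path: str | None = None
    genes_path: str | None = None
    fasta_path: str | None = None
    motif_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.fc_threshold <= 0 or cfg.alpha <= 0 or cfg.motif_p <= 0:
            raise ValueError("thresholds must be positive")
        return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2^31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": seeds, "stages": {}, "checksums": {}}

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = counts
        for f in files:
            manifest["checksums"][f.name] = _sha256(f)

    def require(path: str | None, producer: str, what: str) -> str:
        if path is None or not Path(path).exists():
            raise RuntimeError(
                f"stage dependency error: {what} not available "
                f"(enable the '{producer}' stage or provide the input path)")
        return path

    paths = {
        "expression": config.expression_path, "design": config.design_path,
        "peaks": config.peaks_path, "genes": config.genes_path,
        "fasta": config.fasta_path, "motif": config.motif_path,
    }

    pwm = None
    try:
        if "simulate" in config.stages:
            sim_cfg = SimulationConfig(
                n_genes=config.n_genes,
                replicates_per_genotype=config.replicates_per_genotype,
                noise_sd_log2=config.noise_sd_log2,
                seed=seeds["simulate"],
            )
            matrix, design, truth = simulate_expression(sim_cfg)
            pwm = pax9_consensus_pwm()
            seqs, genes, peaks, gtruth = simulate_genome(
                config.n_peak_genes, None, pwm, config.category_plan,
                seed=seeds["simulate"],
                gene_ids=[f"G{i + 1:05d}" for i in range(config.n_peak_genes)])
            paths["expression"] = str(outdir / "expression.tsv")
            paths["design"] = str(outdir / "samples.tsv")
            paths["peaks"] = str(outdir / "peaks.bed")
            paths["genes"] = str(outdir / "genes.tsv")
            paths["fasta"] = str(outdir / "genome.fa")
            paths["motif"] = str(outdir / "motif.meme")
            write_expression_table(matrix, paths["expression"])
            write_sample_design(design, paths["design"])
            write_bed(peaks, paths["peaks"])
            write_gene_models(genes, paths["genes"])
            write_fasta(seqs, paths["fasta"])
            write_meme_motif(pwm, paths["motif"])
            write_table(truth.genes, outdir / "truth_genes.tsv")
            write_table(gtruth.peaks, outdir / "truth_peaks.tsv")
            record("simulate", {"n_genes": config.n_genes, "n_peaks": len(peaks)},
                   [Path(paths[k]) for k in ("expression", "design", "peaks",
                                             "genes", "fasta", "motif")])

        processed = None
        design = None
        if "preprocess" in config.stages:
            matrix = read_expression_table(require(paths["expression"], "simulate",
                                                   "expression table"))
            design = read_sample_design(require(paths["design"], "simulate",
                                                "sample sheet"))
            processed, report = preprocess_pipeline(matrix)
            write_expression_table(processed, outdir / "expression.normalized.tsv")
            record("preprocess", {"input_probes": report.n_input,
                                  "after_flag_filter": report.n_after_flags,
                                  "after_percentile_filter": report.n_after_percentile},
                   [outdir / "expression.normalized.tsv"])

        de_results = None
        if "de" in config.stages:
            if processed is None:
                raise RuntimeError("stage dependency error: 'de' needs the "
                                   "'preprocess' stage output")
            de_results = call_de(processed, design, ("WT", "Pax1KO_Pax9KO"),
                                 fc_threshold=config.fc_threshold,
                                 alpha=config.alpha, p_mode=config.p_mode)
            df = de_frame(de_results)
            write_table(df, outdir / "de_overall.tsv")
            record("de", {"n_genes": len(df),
                          "n_significant": int(df["significant"].sum())},
                   [outdir / "de_overall.tsv"])

        assignments = None
        if "dosage" in config.stages:
            if processed is None:
                raise RuntimeError("stage dependency error: 'dosage' needs the "
                                   "'preprocess' stage output")
            profiles = dosage_profiles(processed, design)
            assignments = classify_all(profiles, config.fc_threshold)
            adf = pd.DataFrame([a.__dict__ for a in assignments])
            write_table(adf, outdir / "dosage_assignments.tsv")
            summary = group_summary(assignments, profiles)
            write_table(summary, outdir / "dosage_group_summary.tsv")
            in_uni = [a for a in assignments if a.in_universe]
            record("dosage", {"universe": len(in_uni),
                              **{g: sum(1 for a in in_uni if a.group == g)
                                 for g in ("group1", "group2", "group3", "unclassified")}},
                   [outdir / "dosage_assignments.tsv",
                    outdir / "dosage_group_summary.tsv"])

        annotations = None
        if "annotate" in config.stages:
            peaks = read_bed(require(paths["peaks"], "simulate", "peak BED"))
            genes = read_gene_models(require(paths["genes"], "simulate",
                                             "gene models"))
            annotations = annotate_peaks(peaks, genes)
            write_table(annotation_frame(annotations), outdir / "peak_annotations.tsv")
            write_table(category_distribution(annotations),
                        outdir / "peak_category_distribution.tsv")
            record("annotate", {"n_peaks": len(annotations)},
                   [outdir / "peak_annotations.tsv",
                    outdir / "peak_category_distribution.tsv"])

        if "scan" in config.stages:
            seqs = read_fasta(require(paths["fasta"], "simulate", "genome FASTA"))
            if pwm is None:
                pwm = read_meme_motif(require(paths["motif"], "simulate",
                                              "MEME motif"))
            peaks = read_bed(require(paths["peaks"], "simulate", "peak BED"))
            peak_seqs = {p.name or f"peak{i + 1}":
                         trim_central(seqs[p.chrom][p.start:p.end])
                         for i, p in enumerate(peaks)}
            hits = scan(peak_seqs, pwm, config.motif_p)
            hdf = pd.DataFrame([h.__dict__ for h in hits])
            write_table(hdf, outdir / "motif_hits.tsv")
            enr = central_enrichment(peak_seqs, pwm, config.motif_p,
                                     config.central_window)
            (outdir / "central_enrichment.json").write_text(json.dumps({
                "n_central": enr.n_central, "n_total": enr.n_total,
                "null_prob": enr.null_prob, "binomial_p": enr.binomial_p}, indent=1))
            record("scan", {"n_hits": len(hits), "n_central": enr.n_central,
                            "n_with_site": enr.n_total},
                   [outdir / "motif_hits.tsv", outdir / "central_enrichment.json"])

        if "integrate" in config.stages:
            if de_results is None or annotations is None:
                raise RuntimeError("stage dependency error: 'integrate' needs "
                                   "the 'de' and 'annotate' stage outputs")
            calls = integrate(de_results, assignments, annotations)
            cdf = pd.DataFrame([{**c.__dict__,
                                 "bound_categories": ",".join(sorted(c.bound_categories))}
                                for c in calls])
            write_table(cdf, outdir / "target_calls.tsv")
            write_table(dosage_direct_summary(calls),
                        outdir / "dosage_direct_summary.tsv")
            fracs = bound_fraction(calls)
            record("integrate", {"n_calls": len(calls),
                                 "bound_fraction_de": fracs["all"]},
                   [outdir / "target_calls.tsv",
                    outdir / "dosage_direct_summary.tsv"])
    except Exception as exc:
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
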