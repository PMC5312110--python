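"""Synthetic allelic-series expression data and a toy genome with planted truth.

The expression generator emulates a bead-array experiment over the
four-genotype functional-allele ladder (2,2) -> (0,2) -> (0,1) -> (0,0):
per-gene log2 baselines are normal, genotype effects are additive log2
offsets, replicate noise is additive log2 Gaussian, and intensities are the
exponentiated sums (a log-normal intensity model).  Detection p-values mark
expressed genes as confidently present and a configurable fraction of null
genes as absent in every sample.

The genome generator lays out widely spaced genes on a uniform-background
chromosome and plants one 300 bp peak per requested distance category at a
fixed offset from a gene's TSS, optionally inserting a motif consensus at the
peak summit, so that every downstream stage can be checked against recorded
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (ExpressionMatrix, GeneModel, Peak, SampleDesign,
                         SampleRecord, LADDER)
from .motif_scan import PWM

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_expression",
    "simulate_genome",
    "DEFAULT_EFFECT_PROFILES",
    "DEFAULT_CLASS_COUNTS",
]

# log2 offsets per ladder genotype; "up" classes are the sign-flipped "down"
# profiles.  Chosen so only the steps each group's definition requires cross
# the 1.5-fold threshold in expectation.
DEFAULT_EFFECT_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "null": (0.0, 0.0, 0.0, 0.0),
    "group1_down": (0.0, -0.20, -0.40, -0.80),
    "group2_down": (0.0, -0.10, -0.70, -0.75),
    "group3_down": (0.0, -0.05, -0.10, -0.80),
    "group1_up": (0.0, 0.20, 0.40, 0.80),
    "group2_up": (0.0, 0.10, 0.70, 0.75),
    "group3_up": (0.0, 0.05, 0.10, 0.80),
}

DEFAULT_CLASS_COUNTS = {
    "group1_down": 100, "group1_up": 100,
    "group2_down": 100, "group2_up": 100,
    "group3_down": 100, "group3_up": 100,
}

GENOTYPE_IDS = ("WT", "Pax1KO", "Pax1KO_Pax9Het", "Pax1KO_Pax9KO")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    replicates_per_genotype: int = 3
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.15
    effect_profiles: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILES))
    absent_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        planted = sum(self.class_counts.get(c, 0) for c in self.class_counts if c != "null")
        if planted > self.n_genes:
            raise ConfigError(f"class counts ({planted}) exceed n_genes ({self.n_genes})")
        if not 0 <= self.absent_fraction <= 1:
            raise ConfigError("absent_fraction must be in [0, 1]")
        if tuple(self.effect_profiles.get("null", (0, 0, 0, 0))) != (0, 0, 0, 0):
            raise ConfigError("null effect profile must be all-zero")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class labels, per-peak annotations."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SampleDesign, TruthTable]:
    """Simulate the ladder experiment; deterministic for a fixed config/seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    reps = config.replicates_per_genotype
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    classes = np.array(["null"] * n, dtype=object)
    pos = 0
    for cls in sorted(c for c in config.class_counts if c != "null"):
        cnt = config.class_counts[cls]
        classes[pos : pos + cnt] = cls
        pos += cnt
    rng.shuffle(classes)

    profiles = np.array([config.effect_profiles[c] for c in classes])  # n x 4
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    noise = rng.normal(0.0, config.noise_sd_log2, (n, 4, reps))
    log2_vals = baseline[:, None, None] + profiles[:, :, None] + noise
    values = 2.0 ** log2_vals  # n x 4 genotypes x reps

    # detection p: expressed genes confidently present everywhere; a fraction
    # of *null* genes absent in all samples (planted classes stay detectable)
    n_samples = 4 * reps
    det = rng.uniform(0.9, 1.0, (n, n_samples))
    null_idx = np.nonzero(classes == "null")[0]
    n_absent = int(round(config.absent_fraction * n))
    absent_idx = rng.choice(null_idx, size=min(n_absent, len(null_idx)), replace=False)
    det[absent_idx] = rng.uniform(0.0, 0.5, (len(absent_idx), n_samples))

    sample_ids = []
    records = []
    for gi, (geno, (p1, p9)) in enumerate(zip(GENOTYPE_IDS, LADDER)):
        for r in range(reps):
            sid = f"{geno}_rep{r + 1}"
            sample_ids.append(sid)
            records.append(SampleRecord(sid, geno, int(p1), int(p9), r + 1))
    inten = pd.DataFrame(values.reshape(n, n_samples), index=gene_ids, columns=sample_ids)
    detp = pd.DataFrame(det, index=gene_ids, columns=sample_ids)
    matrix = ExpressionMatrix(inten, detp, {g: g for g in gene_ids})
    design = SampleDesign(records)

    truth_genes = pd.DataFrame({
        "gene_id": gene_ids,
        "class": classes,
        "group": [c.split("_")[0] if c != "null" else "null" for c in classes],
        "direction": [c.split("_")[1] if c != "null" else "" for c in classes],
        "absent": np.isin(np.arange(n), absent_idx),
    })
    for j in range(4):
        truth_genes[f"effect_{j + 1}"] = profiles[:, j]
    return matrix, design, TruthTable(genes=truth_genes)


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

PEAK_WIDTH = 300
GENE_LENGTH = 20_000
GENE_PITCH = 260_000  # >= 250 kb TSS spacing keeps category windows unambiguous

# cyclic strand-oriented anchor offsets from the TSS per category; each
# variant of a category lands at a distinct, unambiguous distance
CATEGORY_OFFSETS: dict[str, tuple[int, ...]] = {
    "TSS": (0, 500, -500),
    "promoter": (-3000, -2000, -4500),
    "intragenic": (5000, 8000, 12000),
    "proximal": (-7500, -6000, -9000),
    "distal": (50_000, -50_000, 30_000),
    "others": (150_000, -150_000, 120_000),
}


def simulate_genome(n_genes: int, chrom_length: int | None, pwm: PWM | None,
                    category_plan: dict[str, int], seed: int = 0,
                    chrom: str = "chrS",
                    gene_ids: list[str] | None = None) -> tuple[dict[str, str], list[GeneModel], list[Peak], TruthTable]:
    """Toy chromosome with spaced genes, category-planted peaks and motifs.

    One peak occupies one (gene, category-variant) slot; peaks are dealt
    round-robin over genes so a gene carries at most one peak per category
    variant.  When ``pwm`` is given its consensus is inserted at every peak
    summit and recorded in the truth table.
    """
    unknown = set(category_plan) - set(CATEGORY_OFFSETS)
    if unknown:
        raise ConfigError(f"unknown categories in plan: {sorted(unknown)}")
    for cat, cnt in category_plan.items():
        if cnt > len(CATEGORY_OFFSETS[cat]) * n_genes:
            raise ConfigError(f"too many {cat} peaks for {n_genes} genes")
    needed = chrom_length if chrom_length is not None else 2 * GENE_PITCH + n_genes * GENE_PITCH
    min_len = 2 * GENE_PITCH + (n_genes - 1) * GENE_PITCH + GENE_LENGTH + 200_000
    if needed < min_len:
        raise ConfigError(f"chrom_length {needed} too small; need >= {min_len}")
    rng = np.random.default_rng(seed)
    seq_arr = rng.integers(0, 4, needed, dtype=np.int8)

    if gene_ids is not None and len(gene_ids) != n_genes:
        raise ConfigError("gene_ids length must equal n_genes")
    genes: list[GeneModel] = []
    for i in range(n_genes):
        tss = GENE_PITCH + i * GENE_PITCH
        strand = "+" if i % 2 == 0 else "-"
        gid = gene_ids[i] if gene_ids is not None else f"gene{i + 1:04d}"
        if strand == "+":
            g = GeneModel(chrom, tss, tss + GENE_LENGTH, "+", gid)
        else:
            g = GeneModel(chrom, tss - GENE_LENGTH + 1, tss + 1, "-", gid)
        genes.append(g)

    peaks: list[Peak] = []
    truth_rows = []
    consensus_idx = None
    if pwm is not None:
        from .motif_scan import encode
        consensus_idx = encode(pwm.consensus)
    gene_cursor = 0
    for category in sorted(category_plan):
        count = category_plan[category]
        offsets = CATEGORY_OFFSETS[category]
        for j in range(count):
            gene = genes[gene_cursor % n_genes]
            variant = (gene_cursor // n_genes) % len(offsets)
            gene_cursor += 1
            d = offsets[variant]
            anchor = gene.tss + d if gene.strand == "+" else gene.tss - d
            start = anchor - PEAK_WIDTH // 2
            pid = f"peak_{category}_{j + 1:03d}"
            peaks.append(Peak(chrom, start, start + PEAK_WIDTH,
                              summit_offset=PEAK_WIDTH // 2, name=pid))
            has_motif = pwm is not None
            if has_motif:
                mstart = anchor - pwm.width // 2
                seq_arr[mstart : mstart + pwm.width] = consensus_idx
            truth_rows.append({"peak_id": pid, "target_gene": gene.gene_id,
                               "category": category, "signed_distance": d,
                               "has_planted_motif": has_motif})
    seq = bytes(np.array([65, 67, 71, 84], dtype=np.uint8)[seq_arr]).decode("ascii")
    truth = TruthTable(peaks=pd.DataFrame(truth_rows))
    return {chrom: seq}, genes, peaks, truth
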