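"""Readers, writers and domain containers for the pipeline's external formats.

All interval arithmetic in this package uses 0-based half-open coordinates
(the BED convention).  GFF-style 1-based inputs are converted at the reader
boundary and nowhere else.  The transcription start site of a minus-strand
gene is ``end - 1``, the last base covered by the half-open interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "GeneModel",
    "Peak",
    "FormatError",
    "read_expression_table",
    "write_expression_table",
    "read_sample_design",
    "write_sample_design",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "write_fasta",
    "read_meme_motif",
    "write_meme_motif",
    "write_table",
]

LADDER = (("2", "2"), ("0", "2"), ("0", "1"), ("0", "0"))


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe-level fluorescence intensities with per-sample detection p-values.

    ``intensities`` and ``detection_p`` are probes x samples DataFrames sharing
    index (probe ids) and columns (sample ids).  ``gene_symbols`` maps probe id
    to gene symbol; many probes may map to one gene.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensities.shape != self.detection_p.shape:
            raise ValueError(
                "intensities and detection_p shapes differ: "
                f"{self.intensities.shape} vs {self.detection_p.shape}"
            )
        if not self.intensities.columns.equals(self.detection_p.columns):
            raise ValueError("intensity and detection-p sample ids differ")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        dp = self.detection_p.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection p-values outside [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        keep = [p for p in self.probe_ids if p in set(probes)]
        return ExpressionMatrix(
            intensities=self.intensities.loc[keep],
            detection_p=self.detection_p.loc[keep],
            gene_symbols={p: g for p, g in self.gene_symbols.items() if p in set(keep)},
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    genotype_id: str
    pax1_copies: int
    pax9_copies: int
    replicate_index: int


class SampleDesign:
    """Sample-to-genotype map defining the functional-allele ladder.

    The four ladder genotypes are identified by their (pax1, pax9) functional
    copy numbers in fixed order (2,2) -> (0,2) -> (0,1) -> (0,0).
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in design")
        for r in self.records:
            if r.pax1_copies not in (0, 1, 2) or r.pax9_copies not in (0, 1, 2):
                raise ValueError(f"copy numbers out of range for {r.sample_id}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def samples_for_genotype(self, genotype_id: str) -> list[str]:
        return [r.sample_id for r in self.records if r.genotype_id == genotype_id]

    def samples_for_copies(self, pax1: int, pax9: int) -> list[str]:
        return [
            r.sample_id
            for r in self.records
            if r.pax1_copies == pax1 and r.pax9_copies == pax9
        ]

    def ladder_genotypes(self) -> list[list[str]]:
        """Sample ids per ladder genotype, WT first."""
        out = []
        for p1, p9 in LADDER:
            out.append(self.samples_for_copies(int(p1), int(p9)))
        return out

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        design_ids = {r.sample_id for r in self.records}
        matrix_ids = set(matrix.sample_ids)
        if design_ids != matrix_ids:
            raise ValueError(
                f"design/matrix sample mismatch: only in design {sorted(design_ids - matrix_ids)}, "
                f"only in matrix {sorted(matrix_ids - design_ids)}"
            )


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError("summit outside peak")


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

DEFAULT_LAYOUT = {
    "probe_col": "ProbeID",
    "symbol_col": "Symbol",
    "signal_suffix": ".AVG_Signal",
    "detection_suffix": ".Detection",
}


def read_expression_table(path: str | Path, layout: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a tab-delimited probe profile with paired signal/detection columns.

    Sample columns are identified by ``signal_suffix``/``detection_suffix``;
    the sample id is the column name with the suffix stripped.
    """
    lay = dict(DEFAULT_LAYOUT)
    if layout:
        lay.update(layout)
    df = pd.read_csv(path, sep="\t", comment=None)
    for col in (lay["probe_col"],):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    sig_cols = [c for c in df.columns if c.endswith(lay["signal_suffix"])]
    det_cols = [c for c in df.columns if c.endswith(lay["detection_suffix"])]
    sig_samples = [c[: -len(lay["signal_suffix"])] for c in sig_cols]
    det_samples = [c[: -len(lay["detection_suffix"])] for c in det_cols]
    if not sig_cols:
        raise FormatError(f"no columns ending in {lay['signal_suffix']!r}")
    if sig_samples != det_samples:
        raise FormatError(
            f"signal/detection columns unpaired: {sig_samples} vs {det_samples}"
        )
    probes = df[lay["probe_col"]].astype(str)
    inten = df[sig_cols].copy()
    det = df[det_cols].copy()
    for frame, cols in ((inten, sig_cols), (det, det_cols)):
        for c in cols:
            vals = pd.to_numeric(frame[c], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise FormatError(f"non-numeric value at row {row}, column {c!r}")
            frame[c] = vals
    inten.columns = sig_samples
    det.columns = det_samples
    inten.index = probes
    det.index = probes
    symbols: dict[str, str] = {}
    if lay["symbol_col"] in df.columns:
        symbols = dict(zip(probes, df[lay["symbol_col"]].astype(str)))
    try:
        return ExpressionMatrix(inten, det, symbols)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           layout: Mapping[str, str] | None = None) -> None:
    lay = dict(DEFAULT_LAYOUT)
    if layout:
        lay.update(layout)
    out = pd.DataFrame({lay["probe_col"]: matrix.probe_ids})
    if matrix.gene_symbols:
        out[lay["symbol_col"]] = [matrix.gene_symbols.get(p, "") for p in matrix.probe_ids]
    for s in matrix.sample_ids:
        out[s + lay["signal_suffix"]] = matrix.intensities[s].to_numpy()
        out[s + lay["detection_suffix"]] = matrix.detection_p[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample_id", "genotype_id", "pax1_copies", "pax9_copies", "replicate_index"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    recs = [
        SampleRecord(
            sample_id=str(r.sample_id),
            genotype_id=str(r.genotype_id),
            pax1_copies=int(r.pax1_copies),
            pax9_copies=int(r.pax9_copies),
            replicate_index=int(r.replicate_index),
        )
        for r in df.itertuples()
    ]
    return SampleDesign(recs)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read peaks from BED3+ (0-based half-open).

    Column 4 (name) and 5 (score) are used when present; a ``summit=N``
    key in the name field records the summit offset.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            summit = None
            if name and "summit=" in name:
                for tok in name.split(";"):
                    if tok.startswith("summit="):
                        summit = int(tok.split("=", 1)[1])
            peaks.append(Peak(chrom, s, e, summit_offset=summit, score=score, name=name))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak{i + 1}"
            if p.summit_offset is not None and "summit=" not in name:
                name = f"{name};summit={p.summit_offset}"
            score = "." if p.score is None else f"{p.score:.6g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\n")


def read_gene_models(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Read a tab-delimited gene-model table (chrom, start, end, strand, gene_id).

    ``one_based=True`` converts GFF-style 1-based closed starts to 0-based
    half-open at this boundary.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "strand", "gene_id"], header=0)
    genes = []
    for r in df.itertuples():
        start = int(r.start) - 1 if one_based else int(r.start)
        genes.append(GeneModel(str(r.chrom), start, int(r.end), str(r.strand), str(r.gene_id)))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# sequences and motifs
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}; alphabet restricted to ACGTN."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise FormatError(f"sequence {rec.id}: unexpected letters {sorted(bad)}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_meme_motif(path: str | Path):
    """Read the first motif from a MEME (minimal v4) motif file as a PWM."""
    from .motif_scan import PWM  # deferred: avoid import cycle

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        mots = list(records)
    if not mots:
        raise FormatError(f"no motifs in {path}")
    m = mots[0]
    # the parser scales probability rows by nsites into counts; every row must
    # therefore carry the same total (probability rows summing to 1 +- 1e-3)
    counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)], float)
    rowsum = counts.sum(axis=1)
    if np.any(np.abs(rowsum / rowsum.mean() - 1.0) > 1e-3):
        raise FormatError("PWM probability rows do not sum to 1 within 1e-3")
    probs = counts / rowsum[:, None]
    bg = np.full(4, 0.25)
    if m.background:
        bg = np.array([m.background[b] for b in "ACGT"], float)
    return PWM(probs=probs, background=bg, name=m.name or "motif1")


def write_meme_motif(pwm, path: str | Path) -> None:
    bg = pwm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def write_table(records: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a result table: tab-delimited, header line prefixed with '#'."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("#" + "\t".join(map(str, records.columns)) + "\n")
        records.to_csv(fh, sep="\t", index=False, header=False, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    with open(path) as fh:
        header = None
        rows = []
        for line in fh:
            if line.startswith("#"):
                header = line[1:].rstrip("\n").split("\t")
                continue
            rows.append(line.rstrip("\n").split("\t"))
    if header is None:
        raise FormatError(f"no header line in {path}")
    df = pd.DataFrame(rows, columns=header)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df
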