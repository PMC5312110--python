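"""Array preprocessing: quantile normalization, detection-flag and percentile filters.

The stages mirror a standard bead-array workflow: raw intensities (background
subtracted upstream) are quantile normalized across samples, probes are kept if
flagged *present* (detection p > 0.8) in at least one sample, and then kept if
their intensity falls between the 20th and 100th per-sample percentile in at
least one sample.  The filters are order-dependent and are applied in that
order by :func:`preprocess_pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "compute_flags",
    "quantile_normalize",
    "flag_filter",
    "percentile_filter",
    "collapse_to_genes",
    "preprocess_pipeline",
    "PreprocessReport",
]

PRESENT_P = 0.8
ABSENT_P = 0.6


def compute_flags(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Detection flags: present (p > 0.8), absent (p < 0.6), marginal otherwise."""
    dp = matrix.detection_p
    flags = pd.DataFrame("marginal", index=dp.index, columns=dp.columns)
    flags = flags.mask(dp > PRESENT_P, "present")
    flags = flags.mask(dp < ABSENT_P, "absent")
    return flags


def _quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col_sorted_ref = np.empty(n)
        col_sorted_ref[order[:, j]] = ref
        # ties within a column get the mean of the reference values at
        # their tied ranks
        col = x[:, j]
        s = pd.Series(col_sorted_ref).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of cross-sample rank means."""
    if matrix.intensities.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = matrix.intensities.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing intensities")
    out = _quantile_normalize_values(vals)
    inten = pd.DataFrame(out, index=matrix.intensities.index, columns=matrix.intensities.columns)
    return ExpressionMatrix(inten, matrix.detection_p.copy(), dict(matrix.gene_symbols))


def flag_filter(matrix: ExpressionMatrix, flags: pd.DataFrame | None = None,
                min_present: int = 1) -> ExpressionMatrix:
    """Retain probes flagged present in at least ``min_present`` samples."""
    if flags is None:
        flags = compute_flags(matrix)
    if flags.shape != matrix.intensities.shape:
        raise ValueError("flag/matrix shape mismatch")
    keep = (flags == "present").sum(axis=1) >= min_present
    return matrix.subset_probes(list(flags.index[keep]))


def percentile_filter(matrix: ExpressionMatrix, low: float = 20.0,
                      high: float = 100.0) -> ExpressionMatrix:
    """Retain probes within the [low, high] per-sample percentile in >=1 sample.

    Percentiles are computed per sample over the currently retained probes with
    linear interpolation between order statistics.
    """
    if low >= high:
        raise ValueError(f"low percentile {low} must be < high {high}")
    vals = matrix.intensities.to_numpy(dtype=float)
    lo = np.percentile(vals, low, axis=0)
    hi = np.percentile(vals, high, axis=0)
    keep = ((vals >= lo) & (vals <= hi)).any(axis=1)
    return matrix.subset_probes(list(matrix.intensities.index[keep]))


def collapse_to_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse probes to gene level.

    When several probes map to one gene symbol, the probe with the highest mean
    intensity across all samples represents the gene; the result is indexed by
    gene symbol.
    """
    if not matrix.gene_symbols:
        raise ValueError("no probe->gene map on matrix")
    means = matrix.intensities.mean(axis=1)
    best: dict[str, str] = {}
    for probe in matrix.probe_ids:
        gene = matrix.gene_symbols.get(probe, probe)
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    probes = list(best.values())
    genes = list(best.keys())
    inten = matrix.intensities.loc[probes].copy()
    det = matrix.detection_p.loc[probes].copy()
    inten.index = genes
    det.index = genes
    return ExpressionMatrix(inten, det, {g: g for g in genes})


def detect_outlier_samples(matrix: ExpressionMatrix, min_median_rho: float = 0.8) -> list[str]:
    """Optional sample QC: flag samples whose median inter-sample Spearman
    correlation falls below ``min_median_rho``.  Off by default in the pipeline."""
    ranks = matrix.intensities.rank(axis=0)
    rho = np.corrcoef(ranks.to_numpy().T)
    np.fill_diagonal(rho, np.nan)
    med = np.nanmedian(rho, axis=1)
    return [s for s, r in zip(matrix.sample_ids, med) if r < min_median_rho]


@dataclass
class PreprocessReport:
    n_input: int
    n_after_flags: int
    n_after_percentile: int
    outlier_samples: list[str]


def preprocess_pipeline(matrix: ExpressionMatrix, min_present: int = 1,
                        percentile_low: float = 20.0, percentile_high: float = 100.0,
                        drop_outlier_samples: bool = False,
                        collapse: bool = True) -> tuple[ExpressionMatrix, PreprocessReport]:
    """quantile normalize -> flag filter -> percentile filter [-> gene collapse]."""
    n0 = matrix.n_probes
    outliers: list[str] = []
    if drop_outlier_samples:
        outliers = detect_outlier_samples(matrix)
        if outliers:
            keep = [s for s in matrix.sample_ids if s not in outliers]
            matrix = ExpressionMatrix(matrix.intensities[keep], matrix.detection_p[keep],
                                      dict(matrix.gene_symbols))
    norm = quantile_normalize(matrix)
    flagged = flag_filter(norm, min_present=min_present)
    n1 = flagged.n_probes
    filtered = percentile_filter(flagged, percentile_low, percentile_high)
    n2 = filtered.n_probes
    if collapse and filtered.gene_symbols:
        filtered = collapse_to_genes(filtered)
    return filtered, PreprocessReport(n0, n1, n2, outliers)
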