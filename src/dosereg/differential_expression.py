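"""Differential expression: fold changes, Welch tests, BH FDR and SNK post hoc.

Fold changes follow the bead-array convention of ratios of arithmetic group
means on the linear (normalized) intensity scale, reported as *signed* fold
changes: a ratio r >= 1 is reported as +r, a ratio r < 1 as -1/r, so that
|signed FC| >= 1 always and the sign carries the direction.  The significance
rule combines a multiplicity-corrected p-value (Benjamini-Hochberg by default)
with a |signed FC| >= 1.5 gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleDesign

__all__ = [
    "DEResult",
    "fold_change",
    "unpaired_ttest",
    "welch_anova",
    "welch_anova_matrix",
    "bh_fdr",
    "snk_posthoc",
    "call_de",
]


@dataclass
class DEResult:
    gene_id: str
    contrast: str
    fc_linear: float
    fc_signed: float
    p_raw: float
    q_bh: float
    significant: bool


def fold_change(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Linear and signed fold change of B relative to A.

    Returns ``(fc_linear, fc_signed)`` with ``fc_linear = mean_b / mean_a`` and
    ``fc_signed = fc_linear`` if >= 1 else ``-1 / fc_linear``.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("fold change requires positive group means")
    fc = mean_b / mean_a
    return fc, fc if fc >= 1 else -1.0 / fc


def signed_fc(fc_linear: np.ndarray) -> np.ndarray:
    fc = np.asarray(fc_linear, dtype=float)
    return np.where(fc >= 1, fc, -1.0 / fc)


def unpaired_ttest(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> float:
    """Two-sided unpaired t-test p-value.

    Degenerate inputs (zero variance in both groups) return p = 1 when the
    means are equal and p = 0 otherwise, by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def _welch_components(means: np.ndarray, variances: np.ndarray, ns: np.ndarray):
    """Welch's F statistic and degrees of freedom, vectorised over axis 0."""
    k = means.shape[-1]
    w = ns / variances
    sw = w.sum(axis=-1)
    mw = (w * means).sum(axis=-1) / sw
    num = (w * (means - mw[..., None]) ** 2).sum(axis=-1) / (k - 1)
    a = ((1 - w / sw[..., None]) ** 2 / (ns - 1)).sum(axis=-1) / (k * k - 1)
    den = 1 + 2 * (k - 2) * a
    f = num / den
    df2 = 1.0 / (3 * a)
    return f, k - 1, df2


def welch_anova(groups: Sequence[Sequence[float]]) -> float:
    """Welch's one-way ANOVA (unequal variances) p-value.

    Uses Welch's F with a Satterthwaite-type denominator df.  All-identical
    groups return p = 1 by convention; zero within-group variance with
    differing means returns p = 0.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs >= 2 values")
    means = np.array([g.mean() for g in arrs])
    variances = np.array([g.var(ddof=1) for g in arrs])
    ns = np.array([len(g) for g in arrs], float)
    if np.all(variances == 0):
        return 1.0 if np.all(means == means[0]) else 0.0
    if np.any(variances == 0):
        variances = np.maximum(variances, 1e-300)
    f, df1, df2 = _welch_components(means, variances, ns)
    return float(stats.f.sf(f, df1, df2))


def welch_anova_matrix(group_values: Sequence[np.ndarray]) -> np.ndarray:
    """Per-row Welch ANOVA p-values.

    ``group_values`` is a list of (n_rows x n_replicates) arrays, one per group.
    """
    means = np.stack([g.mean(axis=1) for g in group_values], axis=1)
    variances = np.stack([g.var(axis=1, ddof=1) for g in group_values], axis=1)
    ns = np.array([g.shape[1] for g in group_values], float)
    degenerate = (variances == 0).all(axis=1)
    variances = np.maximum(variances, 1e-300)
    f, df1, df2 = _welch_components(means, variances, ns)
    p = stats.f.sf(f, df1, df2)
    same = np.abs(means - means[:, :1]).max(axis=1) == 0
    p = np.where(degenerate & same, 1.0, np.where(degenerate & ~same, 0.0, p))
    return p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j >= rank(i)} p_(j)*m/j."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def snk_posthoc(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Student-Newman-Keuls stepwise post hoc over group means.

    Sorts the group means and tests ranges spanning r means against the
    studentized-range critical value q(alpha, r, df) * sqrt(MSE / n_h), where
    n_h is the harmonic mean group size and MSE/df come from the pooled
    within-group variance.  A non-significant span blocks every comparison it
    contains.  Returns a boolean k x k DataFrame (True = significantly
    different).
    """
    arrs = [np.asarray(g, float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    means = np.array([g.mean() for g in arrs])
    ns = np.array([len(g) for g in arrs], float)
    df_err = int((ns - 1).sum())
    mse = float(sum(((g - g.mean()) ** 2).sum() for g in arrs) / df_err)
    n_h = len(ns) / np.sum(1.0 / ns)  # harmonic mean for unequal sizes
    order = np.argsort(means)
    sig = np.zeros((k, k), dtype=bool)
    if mse == 0:
        for i in range(k):
            for j in range(k):
                sig[i, j] = means[i] != means[j]
        return pd.DataFrame(sig, index=range(k), columns=range(k))
    se = np.sqrt(mse / n_h)

    blocked = np.zeros((k, k), dtype=bool)  # over sorted positions
    for span in range(k, 1, -1):  # widest ranges first
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            if blocked[lo, hi]:
                continue
            q_obs = (means[order[hi]] - means[order[lo]]) / se
            q_crit = stats.studentized_range.ppf(1 - alpha, span, df_err)
            if q_obs >= q_crit:
                sig[order[lo], order[hi]] = sig[order[hi], order[lo]] = True
            else:
                for a in range(lo, hi + 1):  # block all inner comparisons
                    for b in range(a, hi + 1):
                        blocked[a, b] = True
    return pd.DataFrame(sig, index=range(k), columns=range(k))


def call_de(matrix: ExpressionMatrix, design: SampleDesign, contrast: tuple[str, str],
            fc_threshold: float = 1.5, alpha: float = 0.05,
            test: Literal["ttest", "welch_ttest", "welch_anova"] = "welch_anova",
            p_mode: Literal["bh", "raw"] = "bh",
            anova_genotypes: Sequence[str] | None = None) -> list[DEResult]:
    """Per-gene differential expression for ``contrast = (groupA, groupB)``.

    The fold change is always computed on the contrast's two genotypes; the
    p-value comes from the selected test (for ``welch_anova``, across
    ``anova_genotypes`` or all design genotypes).  Significance requires both
    the (BH-corrected by default) p-value below ``alpha`` and
    |signed FC| >= ``fc_threshold``.
    """
    design.validate_against(matrix)
    group_a, group_b = contrast
    samples_a = design.samples_for_genotype(group_a)
    samples_b = design.samples_for_genotype(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"contrast genotypes need >= 2 replicates: {contrast}")
    vals_a = matrix.intensities[samples_a].to_numpy(float)
    vals_b = matrix.intensities[samples_b].to_numpy(float)
    mean_a = vals_a.mean(axis=1)
    mean_b = vals_b.mean(axis=1)
    if np.any(mean_a <= 0) or np.any(mean_b <= 0):
        raise ValueError("non-positive group means")
    fc_lin = mean_b / mean_a
    fc_sgn = signed_fc(fc_lin)

    if test == "welch_anova":
        genos = list(anova_genotypes) if anova_genotypes else sorted(
            {r.genotype_id for r in design.records})
        groups = [matrix.intensities[design.samples_for_genotype(g)].to_numpy(float)
                  for g in genos]
        p_raw = welch_anova_matrix(groups)
    else:
        equal_var = test == "ttest"
        res = stats.ttest_ind(vals_a, vals_b, axis=1, equal_var=equal_var)
        p_raw = np.asarray(res.pvalue, float)
        degenerate = (vals_a.var(axis=1, ddof=1) == 0) & (vals_b.var(axis=1, ddof=1) == 0)
        p_raw = np.where(degenerate, np.where(mean_a == mean_b, 1.0, 0.0), p_raw)
    q = bh_fdr(p_raw)
    p_gate = q if p_mode == "bh" else p_raw
    signif = (p_gate < alpha) & (np.abs(fc_sgn) >= fc_threshold)
    label = f"{group_a}:{group_b}"
    return [
        DEResult(gene_id=g, contrast=label, fc_linear=float(fc_lin[i]),
                 fc_signed=float(fc_sgn[i]), p_raw=float(p_raw[i]),
                 q_bh=float(q[i]), significant=bool(signif[i]))
        for i, g in enumerate(matrix.probe_ids)
    ]


def de_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
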