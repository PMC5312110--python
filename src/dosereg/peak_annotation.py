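"""Peak-to-gene assignment and the six-way distance-category taxonomy.

Each peak is reduced to a single anchor base (summit if recorded, otherwise the
interval midpoint) and placed relative to a gene's transcription start site in
the gene's own orientation (negative distances are upstream).  Categories, in
precedence order:

* ``TSS``        |d| < 1 kb
* ``promoter``   1-5 kb upstream
* ``intragenic`` >= 1 kb downstream of the TSS, inside the gene body
* ``proximal``   5-10 kb upstream, or 1-10 kb downstream outside the gene
* ``distal``     10-100 kb either side, outside the gene
* ``others``     > 100 kb from the TSS

The downstream boundary at exactly +1 kb is assigned to intragenic/proximal so
that every distance receives exactly one category.  A peak is assigned to the
gene with the smallest |distance| on its chromosome (ties by lexicographic
gene id); if every gene is > 100 kb away the category is ``others`` against
the nearest gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak

__all__ = [
    "CATEGORIES",
    "PeakAnnotation",
    "peak_anchor",
    "categorize",
    "annotate_peaks",
    "category_distribution",
]

CATEGORIES = ("TSS", "promoter", "intragenic", "proximal", "distal", "others")


@dataclass
class PeakAnnotation:
    peak_id: str
    gene_id: str
    signed_distance: int
    category: str
    inside_gene: bool


def peak_anchor(peak: Peak) -> int:
    """Anchor base: summit if present, else floor midpoint."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def categorize(anchor: int, gene: GeneModel) -> tuple[int, str]:
    """Signed strand-oriented TSS distance and category for one (anchor, gene) pair."""
    if gene.strand == "+":
        d = anchor - gene.tss
    else:
        d = gene.tss - anchor
    inside = gene.start <= anchor < gene.end
    if abs(d) < 1000:
        cat = "TSS"
    elif -5000 <= d <= -1000:
        cat = "promoter"
    elif d >= 1000 and inside:
        cat = "intragenic"
    elif not inside and (-10000 <= d <= -5000 or 1000 <= d <= 10000):
        cat = "proximal"
    elif not inside and 10000 < abs(d) <= 100000:
        cat = "distal"
    else:
        cat = "others"
    return int(d), cat


def annotate_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel]) -> list[PeakAnnotation]:
    """Assign every peak to its nearest-TSS gene and categorize it.

    Uses a sorted-TSS index per chromosome; candidate genes within 200 kb of
    the anchor (plus the single nearest TSS) are compared by |signed distance|
    with lexicographic gene-id tie-break.
    """
    if not genes:
        raise ValueError("empty gene set")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gs in by_chrom.items():
        gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)

    out: list[PeakAnnotation] = []
    for i, peak in enumerate(peaks):
        pid = peak.name or f"peak{i + 1}"
        if peak.chrom not in index:
            continue
        tss_arr, gs_sorted = index[peak.chrom]
        anchor = peak_anchor(peak)
        lo = int(np.searchsorted(tss_arr, anchor - 200_000, side="left"))
        hi = int(np.searchsorted(tss_arr, anchor + 200_000, side="right"))
        j = int(np.searchsorted(tss_arr, anchor))
        cand_idx = set(range(lo, hi)) | {max(0, j - 1), min(len(gs_sorted) - 1, j)}
        best = None
        for ci in sorted(cand_idx):
            g = gs_sorted[ci]
            d, cat = categorize(anchor, g)
            key = (abs(d), g.gene_id)
            if best is None or key < best[0]:
                best = (key, g, d, cat)
        _, g, d, cat = best
        out.append(PeakAnnotation(pid, g.gene_id, d, cat,
                                  inside_gene=g.start <= anchor < g.end))
    return out


def category_distribution(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Counts and fractions per category (fractions sum to 1)."""
    if not annotations:
        raise ValueError("no annotations")
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    total = len(annotations)
    return pd.DataFrame({
        "category": list(CATEGORIES),
        "count": [counts[c] for c in CATEGORIES],
        "fraction": [counts[c] / total for c in CATEGORIES],
    })


def annotation_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations])
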