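"""Direct/indirect target calls: differential expression joined with binding.

A differentially expressed gene with at least one annotated binding peak (in
any category by default, or a restricted category set) is a *direct* target;
a DE gene with none is *indirect*.  Bound genes without expression change are
``bound_only`` and the rest ``unaffected``.  Overlap significance uses the
upper-tail hypergeometric test, and small collections of gene lists can be
broken into Venn regions for cross-study comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .differential_expression import DEResult
from .dosage_classifier import GroupAssignment
from .peak_annotation import PeakAnnotation

__all__ = [
    "TargetCall",
    "integrate",
    "bound_fraction",
    "dosage_direct_summary",
    "hypergeometric_overlap",
    "multiset_overlap",
]


@dataclass
class TargetCall:
    gene_id: str
    de_direction: str  # down / up / none
    dosage_group: str  # group1..3 / unclassified / none
    bound: bool
    bound_categories: set[str] = field(default_factory=set)
    call: str = "unaffected"  # direct / indirect / bound_only / unaffected


def integrate(de_results: Sequence[DEResult],
              assignments: Sequence[GroupAssignment] | None,
              peak_annotations: Sequence[PeakAnnotation],
              categories: Sequence[str] | None = None) -> list[TargetCall]:
    """Join DE calls, dosage groups and peak annotations into target calls.

    ``categories`` restricts what counts as "bound" (default: any category).
    Conflicting duplicate records for one gene id raise; duplicate peak
    annotations for the same gene are harmless.
    """
    de_by_gene: dict[str, DEResult] = {}
    for r in de_results:
        prev = de_by_gene.get(r.gene_id)
        if prev is not None and (prev.significant != r.significant
                                 or prev.fc_signed != r.fc_signed):
            raise ValueError(f"conflicting DE records for {r.gene_id}")
        de_by_gene[r.gene_id] = r
    group_by_gene: dict[str, GroupAssignment] = {}
    for a in assignments or []:
        prev = group_by_gene.get(a.gene_id)
        if prev is not None and prev.group != a.group:
            raise ValueError(f"conflicting dosage records for {a.gene_id}")
        group_by_gene[a.gene_id] = a
    cats_by_gene: dict[str, set[str]] = {}
    allowed = set(categories) if categories is not None else None
    for p in peak_annotations:
        if allowed is None or p.category in allowed:
            cats_by_gene.setdefault(p.gene_id, set()).add(p.category)

    calls = []
    for gene in sorted(set(de_by_gene) | set(cats_by_gene)):
        de = de_by_gene.get(gene)
        is_de = de is not None and de.significant
        de_dir = "none"
        if is_de:
            de_dir = "down" if de.fc_signed < 0 else "up"
        ga = group_by_gene.get(gene)
        group = ga.group if ga is not None and ga.in_universe else "none"
        bound = gene in cats_by_gene
        if is_de and bound:
            call = "direct"
        elif is_de:
            call = "indirect"
        elif bound:
            call = "bound_only"
        else:
            call = "unaffected"
        calls.append(TargetCall(gene, de_dir, group, bound,
                                cats_by_gene.get(gene, set()), call))
    return calls


def bound_fraction(calls: Sequence[TargetCall]) -> dict[str, float]:
    """Fraction of DE genes that are bound, overall and per direction."""
    de = [c for c in calls if c.de_direction != "none"]
    out = {}
    for label, subset in (("all", de),
                          ("down", [c for c in de if c.de_direction == "down"]),
                          ("up", [c for c in de if c.de_direction == "up"])):
        out[label] = sum(c.bound for c in subset) / len(subset) if subset else float("nan")
    return out


def dosage_direct_summary(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Direct-target counts per dosage group x DE direction.

    group3 & bound are the single-copy direct targets; group2 & bound the
    two-copy direct targets.
    """
    rows = []
    for group in ("group1", "group2", "group3", "unclassified"):
        for direction in ("down", "up"):
            n = sum(1 for c in calls
                    if c.call == "direct" and c.dosage_group == group
                    and c.de_direction == direction)
            rows.append({"group": group, "direction": direction, "direct_count": n})
    return pd.DataFrame(rows)


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> tuple[int, float, float]:
    """Overlap count, its null expectation, and the upper-tail hypergeometric p."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    m, na, nb = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = na * nb / m if m else 0.0
    p = float(stats.hypergeom.sf(k - 1, m, na, nb))
    return k, expected, min(p, 1.0)


def hypergeometric_overlap_exact(set_a: set, set_b: set, universe: set) -> float:
    """Brute-force combinatorial upper-tail probability (small universes)."""
    m, na, nb = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    total = comb(m, nb)
    favorable = sum(comb(na, j) * comb(m - na, nb - j)
                    for j in range(k, min(na, nb) + 1))
    return favorable / total


def multiset_overlap(named_sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Venn-region counts for 2-4 named sets.

    Keys are tuples of the member-set names for each region (every non-empty
    membership pattern); regions partition the union.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("multiset_overlap supports 2-4 sets")
    regions: dict[tuple[str, ...], int] = {}
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [named_sets[n] for n, p in zip(names, pattern) if p]
        outside = [named_sets[n] for n, p in zip(names, pattern) if not p]
        region = set.intersection(*inside)
        for s in outside:
            region -= s
        regions[tuple(n for n, p in zip(names, pattern) if p)] = len(region)
    return regions
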