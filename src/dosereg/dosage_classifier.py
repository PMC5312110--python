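"""Dosage-response classification across the four-genotype functional-allele ladder.

Genes differentially expressed between wild type and the double-null genotype
are sorted into three dosage-response groups from the pattern of consecutive
("step") fold changes along the ladder (2,2) -> (0,2) -> (0,1) -> (0,0):

* Group 1 - no single step crosses the fold-change threshold; expression
  drifts gradually and only the overall WT vs double-null contrast does.
* Group 2 - only the (0,2) -> (0,1) step crosses: two functional copies of the
  second paralog are needed to hold expression at its normal level.
* Group 3 - only the (0,1) -> (0,0) step crosses: a single remaining copy is
  sufficient, and expression collapses only when it too is lost.

Everything else in the differentially expressed universe is ``unclassified``.
The criteria are fold-change-only; a strict mode additionally requiring
per-step significance is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .differential_expression import signed_fc
from .io_formats import ExpressionMatrix, SampleDesign

__all__ = [
    "DosageProfile",
    "GroupAssignment",
    "dosage_profiles",
    "build_universe",
    "classify_dosage_group",
    "classify_all",
    "group_summary",
]

GROUPS = ("group1", "group2", "group3")


@dataclass
class DosageProfile:
    gene_id: str
    ladder_means: tuple[float, float, float, float]
    step_fc: tuple[float, float, float]  # signed FCs of consecutive contrasts
    overall_fc: float  # signed FC, WT vs double null

    @classmethod
    def from_means(cls, gene_id: str, ladder_means: Sequence[float]) -> "DosageProfile":
        m = np.asarray(ladder_means, float)
        if m.shape != (4,) or np.any(m <= 0):
            raise ValueError("need 4 positive ladder means")
        steps = tuple(float(s) for s in signed_fc(m[1:] / m[:-1]))
        overall = float(signed_fc(np.array([m[3] / m[0]]))[0])
        return cls(gene_id, tuple(float(v) for v in m), steps, overall)


@dataclass
class GroupAssignment:
    gene_id: str
    group: Literal["group1", "group2", "group3", "unclassified"]
    direction: Literal["down", "up"] | None
    in_universe: bool


def dosage_profiles(matrix: ExpressionMatrix, design: SampleDesign) -> list[DosageProfile]:
    """Per-gene ladder means and step/overall fold changes from the normalized matrix."""
    design.validate_against(matrix)
    ladder = design.ladder_genotypes()
    if any(len(s) < 2 for s in ladder):
        raise ValueError("every ladder genotype needs >= 2 replicates")
    means = np.stack(
        [matrix.intensities[s].to_numpy(float).mean(axis=1) for s in ladder], axis=1
    )
    if np.any(means <= 0):
        raise ValueError("non-positive ladder means")
    return [
        DosageProfile.from_means(g, means[i]) for i, g in enumerate(matrix.probe_ids)
    ]


def build_universe(profiles: Sequence[DosageProfile], fc_threshold: float = 1.5,
                   significant_ids: set[str] | None = None) -> set[str]:
    """Differentially expressed universe: |overall signed FC| >= threshold.

    ``significant_ids``, if given, additionally gates on a significance call
    for the overall contrast (mirroring ``call_de``).
    """
    universe = {p.gene_id for p in profiles if abs(p.overall_fc) >= fc_threshold}
    if significant_ids is not None:
        universe &= set(significant_ids)
    return universe


def classify_dosage_group(profile: DosageProfile, fc_threshold: float = 1.5) -> GroupAssignment:
    """Assign a universe gene to group 1/2/3 from its step fold-change pattern.

    With S_i = (|step_fc_i| >= threshold): group1 = (F,F,F), group2 = (F,T,F),
    group3 = (F,F,T); any other pattern is unclassified.  Direction is the sign
    of the overall fold change.
    """
    if abs(profile.overall_fc) < fc_threshold:
        raise ValueError(f"{profile.gene_id} is outside the universe")
    s1, s2, s3 = (abs(fc) >= fc_threshold for fc in profile.step_fc)
    if not s1 and not s2 and not s3:
        group = "group1"
    elif not s1 and s2 and not s3:
        group = "group2"
    elif not s1 and not s2 and s3:
        group = "group3"
    else:
        group = "unclassified"
    direction = "down" if profile.overall_fc < 0 else "up"
    return GroupAssignment(profile.gene_id, group, direction, True)


def classify_all(profiles: Sequence[DosageProfile], fc_threshold: float = 1.5,
                 significant_ids: set[str] | None = None) -> list[GroupAssignment]:
    """Classify every profile; genes outside the universe get group=unclassified,
    direction=None, in_universe=False."""
    universe = build_universe(profiles, fc_threshold, significant_ids)
    out = []
    for p in profiles:
        if p.gene_id in universe:
            out.append(classify_dosage_group(p, fc_threshold))
        else:
            out.append(GroupAssignment(p.gene_id, "unclassified", None, False))
    return out


def group_summary(assignments: Sequence[GroupAssignment],
                  profiles: Sequence[DosageProfile] | None = None) -> pd.DataFrame:
    """Per-group down/up counts and the mean ladder trend (standardized to WT=1).

    Returns one row per group (including ``unclassified`` within the universe)
    with columns down_count, up_count and trend_1..trend_4; trends are averages
    of per-gene ladder means divided by the gene's WT mean, or NaN for empty
    groups.
    """
    by_id = {p.gene_id: p for p in profiles} if profiles else {}
    rows = []
    for group in GROUPS + ("unclassified",):
        members = [a for a in assignments if a.in_universe and a.group == group]
        down = sum(1 for a in members if a.direction == "down")
        up = sum(1 for a in members if a.direction == "up")
        trend = [np.nan] * 4
        if members and by_id:
            mat = np.array([
                np.asarray(by_id[a.gene_id].ladder_means) / by_id[a.gene_id].ladder_means[0]
                for a in members if a.gene_id in by_id
            ])
            if len(mat):
                trend = list(mat.mean(axis=0))
        rows.append({"group": group, "down_count": down, "up_count": up,
                     "trend_1": trend[0], "trend_2": trend[1],
                     "trend_3": trend[2], "trend_4": trend[3]})
    return pd.DataFrame(rows)
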