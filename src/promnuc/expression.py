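"""Modification grouping of promoters and expression comparison.

Promoters are split into "modified" (>= 1 center from a family of modified-
histone mark sets within -500..+500 bp of the TSS) and "unmodified" groups,
and the downstream gene expression of the two groups is compared per
architecture class with a two-sided Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PositionSet, Promoter

# Activation-linked H3K4 methylation family; repressive marks (H3K27me3,
# H3K9me3) are accepted as inputs elsewhere but never folded in by default.
METHYLATION_FAMILY = ("H3K4me1", "H3K4me2", "H3K4me3")

MODIFIED = "modified"
UNMODIFIED = "unmodified"


@dataclass
class GroupComparison:
    """Mann-Whitney U comparison of modified vs. unmodified gene expression
    within one promoter class."""

    u_statistic: float
    p_value: float
    n_modified: int
    n_unmodified: int
    summaries: dict
    method: str

    def as_dict(self) -> dict:
        return {
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "n_modified": self.n_modified,
            "n_unmodified": self.n_unmodified,
            "summaries": self.summaries,
            "method": self.method,
        }


def label_modification(
    promoters: Sequence[Promoter],
    mark_sets: Sequence[PositionSet],
    window: tuple[int, int] = (-500, 500),
) -> dict[str, str]:
    """Label each promoter 'modified' iff any center from any mark set falls
    in the inclusive transcript-orientation offset window (default
    -500..+500). Returns promoter id -> label."""
    if not mark_sets:
        raise ValueError("empty mark family")
    a, b = window
    labels: dict[str, str] = {}
    for prom in promoters:
        modified = False
        for marks in mark_sets:
            arr = marks.positions(prom.chrom)
            if prom.strand == "+":
                lo, hi = prom.tss + a, prom.tss + b
            else:
                lo, hi = prom.tss - b, prom.tss - a
            i, j = np.searchsorted(arr, [lo, hi + 1])
            if j > i:
                modified = True
                break
        labels[prom.id] = MODIFIED if modified else UNMODIFIED
    return labels


def resolve_gene_promoters(promoters: Sequence[Promoter]) -> dict[str, Promoter]:
    """One promoter per gene: keep the promoter with the most CAGE tags,
    breaking ties toward the lowest TSS coordinate."""
    best: dict[str, Promoter] = {}
    for p in promoters:
        if p.gene_id is None:
            continue
        cur = best.get(p.gene_id)
        if cur is None or (p.n_tags, -p.tss) > (cur.n_tags, -cur.tss):
            best[p.gene_id] = p
    return best


def five_number(values: np.ndarray) -> dict:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]), "q3": float(q[3]), "max": float(q[4])}


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free groups,
    normal approximation with tie correction otherwise."""
    pooled = np.concatenate([x, y])
    exact = max(x.size, y.size) <= 20 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def expression_group_test(
    expr: pd.DataFrame,
    promoters: Sequence[Promoter],
    groups: Mapping[str, str],
    arch_class: str,
    window_label: str = "",
) -> GroupComparison:
    """Compare expression of modified vs. unmodified promoters of one class.

    Promoters of ``arch_class`` are joined to ``expr`` (gene_id, intensity,
    present) keeping only present genes; multi-promoter genes keep the
    promoter with the most CAGE tags.
    """
    members = [p for p in promoters if p.arch_class == arch_class]
    resolved = resolve_gene_promoters(members)
    present = expr[expr["present"]].set_index("gene_id")["intensity"]
    values: dict[str, list[float]] = {MODIFIED: [], UNMODIFIED: []}
    for gene_id, prom in resolved.items():
        if gene_id not in present.index:
            continue
        label = groups.get(prom.id)
        if label in values:
            values[label].append(float(present.loc[gene_id]))
    for label, vals in values.items():
        if not vals:
            raise ValueError(f"group {label!r} is empty for class {arch_class!r}")
    mod = np.asarray(values[MODIFIED])
    unmod = np.asarray(values[UNMODIFIED])
    u, p, method = _mannwhitney(mod, unmod)
    return GroupComparison(
        u_statistic=u,
        p_value=p,
        n_modified=int(mod.size),
        n_unmodified=int(unmod.size),
        summaries={MODIFIED: five_number(mod), UNMODIFIED: five_number(unmod)},
        method=method,
    )


def expression_matched_subset(
    expr: pd.DataFrame,
    promoters: Sequence[Promoter],
    lo: float = 250.0,
    hi: float = 750.0,
) -> list[Promoter]:
    """Promoters whose linked gene is present with intensity in the inclusive
    range [lo, hi] (default 250..750) — an expression-matched background for
    re-running class-contrast enrichment tests."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    present = expr[expr["present"]].set_index("gene_id")["intensity"]
    out = []
    for p in promoters:
        if p.gene_id is None or p.gene_id not in present.index:
            continue
        val = float(present.loc[p.gene_id])
        if lo <= val <= hi:
            out.append(p)
    return out
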