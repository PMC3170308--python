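"""Expression stratified by histone modification around the TSS.

Labels each promoter modified/unmodified by the presence of H3K4me1/2/3
centers within -500..+500 bp, then compares gene expression between the two
groups per promoter class (two-sided Wilcoxon rank-sum). The effect should
be confined to broad promoters. Also re-runs the +100..+130 enrichment test
on an expression-matched subset (intensities 250..750) to show the class
contrast is not an expression artifact.

Usage: python analysis/05_expression.py [--data DIR]
"""

import argparse
from pathlib import Path

from promnuc import io
from promnuc.core import split_by_class
from promnuc.expression import (
    METHYLATION_FAMILY,
    expression_group_test,
    expression_matched_subset,
    label_modification,
)
from promnuc.profiles import window_enrichment_test

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
args = parser.parse_args()
out = args.data.parent

promoters = io.read_promoters(out / "promoters_classified.tsv")
expr = io.read_expression(args.data / "expr.tsv")
marks = [
    io.read_points(args.data / f"{m}_resting.bed", fmt="bed", label=m)
    for m in METHYLATION_FAMILY
]
groups = label_modification(promoters, marks)

summary = {}
for cls in ("broad", "peak"):
    res = expression_group_test(expr, promoters, groups, cls)
    summary[cls] = res.as_dict()
    med_m = res.summaries["modified"]["median"]
    med_u = res.summaries["unmodified"]["median"]
    print(f"{cls:5s} modified n={res.n_modified:3d} median={med_m:7.0f} | "
          f"unmodified n={res.n_unmodified:3d} median={med_u:7.0f} | p={res.p_value:.3g}")

matched = expression_matched_subset(expr, promoters)
m_by = split_by_class(matched)
points = io.read_points(args.data / "H3K4me3_resting.bed", fmt="bed", label="H3K4me3")
enr = window_enrichment_test(m_by["broad"], m_by["peak"], points, window=(100, 130))
summary["matched_subset"] = {
    "n_broad": len(m_by["broad"]),
    "n_peak": len(m_by["peak"]),
    "enrichment": enr.as_dict(),
}
io.write_json(summary, out / "expression_summary.json")
print(f"expression-matched subset (250..750): {len(m_by['broad'])} broad / "
      f"{len(m_by['peak'])} peak; H3K4me3 enrichment p={enr.p_value:.3g}")
print("expected: modification raises expression at broad promoters only, and the")
print("class contrast survives expression matching")
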