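"""Classify promoters by tag-span width (peak <= 4 bp < broad) and annotate
TATA boxes (PWM scan, 50 bp upstream, relative score > 0.75) and CpG islands
(200 bp upstream). Reports the per-class feature frequencies: peak promoters
should be TATA-rich and broad promoters CpG-rich.

Usage: python analysis/02_classify_promoters.py [--data DIR]
"""

import argparse
from pathlib import Path

from promnuc import io
from promnuc.promoters import annotate_all, class_feature_frequencies, classify_all

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
args = parser.parse_args()

promoters = classify_all(io.read_promoters(args.data / "promoters.tsv"), threshold=4)
promoters = annotate_all(
    promoters,
    genome=io.read_fasta(args.data / "genome.fa"),
    cpg_islands=io.read_intervals(args.data / "cpg.bed"),
)
io.write_promoters(promoters, args.data.parent / "promoters_classified.tsv")
freqs = class_feature_frequencies(promoters)
io.write_json(freqs, args.data.parent / "feature_frequencies.json")

for cls in ("peak", "broad"):
    f = freqs[cls]
    print(f"{cls:5s} n={f['n']:4d}  TATA {100 * f['tata']:.1f}%  CpG {100 * f['cpg']:.1f}%")
print("expected: TATA overrepresented at peak promoters, CpG at broad promoters")
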