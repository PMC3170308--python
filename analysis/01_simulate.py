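"""Generate the synthetic study: promoters, genome, nucleosome/mark centers
under resting and activated conditions, TFBS sites, CpG islands, and gene
expression. Writes everything as plain-text files for the later stages.

Usage: python analysis/01_simulate.py [--seed N] [--out DIR]
"""

import argparse
from pathlib import Path

from promnuc import io
from promnuc.simulate import ACTIVATED, RESTING, SimConfig, simulate_all

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/analysis/data"))
args = parser.parse_args()

cfg = SimConfig(seed=args.seed)
sim = simulate_all(cfg)
args.out.mkdir(parents=True, exist_ok=True)
io.write_promoters(sim.promoters, args.out / "promoters.tsv")
io.write_fasta(sim.genome, args.out / "genome.fa")
io.write_intervals(sim.cpg_islands, args.out / "cpg.bed")
io.write_points(sim.tfbs, args.out / "tfbs.bed")
io.write_expression(sim.expression, args.out / "expr.tsv")
for cond, sets in ((RESTING, sim.nucleosomes_resting), (ACTIVATED, sim.nucleosomes_activated)):
    for mark, ps in sets.items():
        io.write_points(ps, args.out / f"{mark.replace('.', '')}_{cond}.bed")

n_broad = sum(p.arch_class == "broad" for p in sim.promoters)
print(f"simulated {len(sim.promoters)} promoters ({n_broad} broad, "
      f"{len(sim.promoters) - n_broad} peak) on {cfg.chrom_length/1e6:.0f} Mb, seed {args.seed}")
print(f"H3 centers: {len(sim.nucleosomes_resting['H3'])} per condition; wrote {args.out}")
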