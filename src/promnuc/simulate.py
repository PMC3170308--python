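"""Synthetic promoter / nucleosome / TFBS / expression generator.

Emulates the statistical structure the analysis assumes so every stage is
testable without external data: broad promoters carry a phased nucleosome
array downstream of the TSS (first center near +115, ~185 bp period) with a
nucleosome-free region (NFR) upstream, peak promoters carry unphased
nucleosomes at matched density; activated-condition centers are the resting
centers plus class-specific Gaussian jitter (broad more stable than peak);
activating marks are enriched on broad promoters; TFBS sites concentrate in
the broad NFR; and modified broad promoters express higher than unmodified
ones. Every generator is a pure function of (config, seed, condition tag).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, PositionSet, Promoter
from .expression import METHYLATION_FAMILY, MODIFIED, label_modification
from .promoters import default_tata_pwm, reverse_complement

RESTING = "resting"
ACTIVATED = "activated"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, stage tag)."""
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode()) & 0x7FFFFFFF])


def _class_dict(broad, peak) -> dict:
    return {"broad": broad, "peak": peak}


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults encode the qualitative structure the analysis is built to
    detect: first downstream nucleosome center at +115 bp (its +/-15 bp smear
    spans +100..+130), 185 bp phasing period (147 bp core + linker), an NFR
    around -50 bp, condition jitter sd 8 bp (broad) vs 15 bp (peak),
    H3K4me3-style mark enrichment 0.8 vs 0.1, and a broad-only e^1
    multiplicative expression effect for modified promoters.
    """

    n_broad: int = 500
    n_peak: int = 500
    chrom_name: str = "chrS"
    chrom_length: int = 12_000_000
    peak_width_range: tuple[int, int] = (1, 4)
    broad_width_range: tuple[int, int] = (5, 60)
    phase_first_center: int = 115
    phase_period: int = 185
    n_phased: int = 5
    n_phased_upstream: int = 3
    placement_jitter_sd: dict = field(default_factory=lambda: _class_dict(10.0, 0.0))
    nfr_center: int = -50
    nfr_halfwidth: int = 70
    condition_jitter_sd: dict = field(default_factory=lambda: _class_dict(8.0, 15.0))
    mark_enrichment: dict = field(
        default_factory=lambda: {
            "H3": _class_dict(1.0, 1.0),
            "H2A.Z": _class_dict(0.7, 0.2),
            "H3K4me1": _class_dict(0.35, 0.05),
            "H3K4me2": _class_dict(0.35, 0.05),
            "H3K4me3": _class_dict(0.8, 0.1),
            "H3K9ac": _class_dict(0.8, 0.1),
        }
    )
    tfbs_at_nfr_prob: dict = field(default_factory=lambda: _class_dict(0.7, 0.1))
    tfbs_nfr_sd: float = 10.0
    tfbs_scatter_flank: int = 500
    expr_lognormal_params: tuple[float, float] = (6.0, 1.0)
    modification_effect: dict = field(default_factory=lambda: _class_dict(math.e, 1.0))
    cpg_prob: dict = field(default_factory=lambda: _class_dict(0.9, 0.2))
    tata_prob: dict = field(default_factory=lambda: _class_dict(0.1, 0.7))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_broad < 0 or self.n_peak < 0:
            raise ValueError("promoter counts must be >= 0")
        for rng_ in (self.peak_width_range, self.broad_width_range):
            if rng_[0] < 1 or rng_[0] > rng_[1]:
                raise ValueError(f"invalid width range {rng_}")
        for name in ("placement_jitter_sd", "condition_jitter_sd"):
            for v in getattr(self, name).values():
                if v < 0:
                    raise ValueError(f"{name} must be >= 0")
        for mark, probs in self.mark_enrichment.items():
            for v in probs.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"mark_enrichment[{mark}] outside [0, 1]")
        for name in ("tfbs_at_nfr_prob", "cpg_prob", "tata_prob"):
            for v in getattr(self, name).values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} outside [0, 1]")
        if self.phase_period <= 0 or self.n_phased < 1:
            raise ValueError("need phase_period > 0 and n_phased >= 1")

    @property
    def array_span(self) -> int:
        """Genomic reach of the phased array on either side of the TSS."""
        down = self.phase_first_center + (self.n_phased - 1) * self.phase_period
        up = -self.upstream_first_center + (self.n_phased_upstream - 1) * self.phase_period
        return max(down, up)

    @property
    def upstream_first_center(self) -> int:
        """First upstream center: just outside the NFR's upstream edge."""
        return self.nfr_center - self.nfr_halfwidth - 20

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown sim config keys: {bad}")
        kwargs = dict(data)
        for key in ("peak_width_range", "broad_width_range", "expr_lognormal_params"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("peak_width_range", "broad_width_range", "expr_lognormal_params"):
            d[key] = list(d[key])
        return d


def _plant_sense(codes: np.ndarray, tss: int, strand: str, start_offset: int, motif: str) -> None:
    """Write a motif into the genome at a transcript-orientation offset
    (motif start at ``start_offset`` relative to the TSS, sense strand)."""
    if strand == "+":
        g0 = tss + start_offset
        seq = motif
    else:
        g0 = tss - (start_offset + len(motif) - 1)
        seq = reverse_complement(motif)
    codes[g0 : g0 + len(seq)] = [_CODE[b] for b in seq]


def generate_promoters(
    config: SimConfig,
) -> tuple[list[Promoter], dict[str, str], list[GenomicInterval]]:
    """Place non-overlapping promoters on both strands of a random genome.

    Tag positions realize the class width; a TATA consensus is planted
    upstream with probability tata_prob (higher for peak) and a CpG-like
    island interval recorded with probability cpg_prob (higher for broad).
    Returns (promoters, genome, cpg_islands).
    """
    n = config.n_broad + config.n_peak
    if n == 0:
        return [], {config.chrom_name: ""}, []
    gap = config.chrom_length // (n + 1)
    min_gap = 2 * config.array_span + 400
    if gap < min_gap:
        raise ValueError(
            f"promoters cannot be placed without overlap (gap {gap} < {min_gap} bp); "
            "increase chrom_length or reduce promoter counts"
        )
    rng = _rng(config.seed, "promoters")
    classes = np.array(["broad"] * config.n_broad + ["peak"] * config.n_peak)
    rng.shuffle(classes)
    strands = rng.choice(np.array(["+", "-"]), size=n)

    codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
    tata_motif = default_tata_pwm().consensus

    promoters: list[Promoter] = []
    cpg_islands: list[GenomicInterval] = []
    for i in range(n):
        cls = str(classes[i])
        strand = str(strands[i])
        tss = (i + 1) * gap
        wlo, whi = config.peak_width_range if cls == "peak" else config.broad_width_range
        width = int(rng.integers(wlo, whi + 1))
        if width == 1:
            tags = (tss,)
        else:
            n_extra = int(rng.integers(0, min(width - 2, 6) + 1))
            interior = rng.choice(np.arange(1, width - 1), size=n_extra, replace=False) if n_extra else []
            tags = tuple(sorted({0, width - 1, *map(int, interior)}))
            tags = tuple(tss + t for t in tags)
        has_tata = bool(rng.random() < config.tata_prob[cls])
        has_cpg = bool(rng.random() < config.cpg_prob[cls])
        if has_tata:
            _plant_sense(codes, tss, strand, -35, tata_motif)
        if has_cpg:
            # transcript-orientation interval covering [-180, -20] upstream
            if strand == "+":
                cpg_islands.append(GenomicInterval(config.chrom_name, tss - 180, tss - 19))
            else:
                cpg_islands.append(GenomicInterval(config.chrom_name, tss + 20, tss + 181))
        promoters.append(
            Promoter(
                id=f"P{i:05d}",
                chrom=config.chrom_name,
                strand=strand,
                tss=tss,
                tag_positions=tags,
                arch_class=cls,
                has_tata=has_tata,
                has_cpg=has_cpg,
                gene_id=f"G{i:05d}",
            )
        )
    genome = {config.chrom_name: _BASES[codes].tobytes().decode("ascii")}
    return promoters, genome, cpg_islands


def _resting_offsets(prom: Promoter, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Transcript-orientation center offsets for one promoter, resting."""
    n_centers = config.n_phased + config.n_phased_upstream
    if prom.arch_class == "broad":
        down = config.phase_first_center + config.phase_period * np.arange(config.n_phased)
        up = config.upstream_first_center - config.phase_period * np.arange(config.n_phased_upstream)
        offs = np.concatenate([down, up]).astype(float)
        offs += rng.normal(0.0, config.placement_jitter_sd["broad"], size=offs.size)
        offs = np.rint(offs).astype(np.int64)
        # enforce the nucleosome-free region: drop centers that jitter inside
        lo = config.nfr_center - config.nfr_halfwidth
        hi = config.nfr_center + config.nfr_halfwidth
        return offs[(offs < lo) | (offs > hi)]
    span = config.array_span
    return rng.integers(-span, span + 1, size=n_centers).astype(np.int64)


def generate_nucleosomes(
    promoters: Sequence[Promoter],
    config: SimConfig,
    condition: str = RESTING,
) -> dict[str, PositionSet]:
    """Per-mark nucleosome center sets for one condition.

    Resting centers are phased (broad) or uniform (peak); activated centers
    are the resting centers plus Normal(0, condition_jitter_sd[class]). Mark
    carriership is drawn once per (promoter, mark) — independent of the
    condition — so both conditions describe the same nucleosomes.
    """
    if condition not in (RESTING, ACTIVATED):
        raise ValueError(f"unknown condition {condition!r}")
    rng_place = _rng(config.seed, "nucleosome-placement")
    rng_marks = _rng(config.seed, "nucleosome-marks")
    rng_cond = _rng(config.seed, "nucleosome-activated")

    per_prom_centers: list[np.ndarray] = []
    for prom in promoters:
        offs = _resting_offsets(prom, config, rng_place)
        centers = prom.tss + offs if prom.strand == "+" else prom.tss - offs
        if condition == ACTIVATED:
            sd = config.condition_jitter_sd[prom.arch_class]
            centers = np.rint(centers + rng_cond.normal(0.0, sd, size=centers.size)).astype(np.int64)
        centers = centers[(centers >= 0) & (centers < config.chrom_length)]
        per_prom_centers.append(np.asarray(centers, dtype=np.int64))

    marks = sorted(config.mark_enrichment)
    carriers = {
        mark: np.array(
            [rng_marks.random() < config.mark_enrichment[mark][p.arch_class] for p in promoters]
        )
        for mark in marks
    }
    out: dict[str, PositionSet] = {}
    for mark in marks:
        chosen = [c for c, keep in zip(per_prom_centers, carriers[mark]) if keep]
        positions = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
        by_chrom = {config.chrom_name: positions} if positions.size else {}
        out[mark] = PositionSet(by_chrom, label=mark, condition=condition)
    return out


def generate_tfbs(promoters: Sequence[Promoter], config: SimConfig) -> PositionSet:
    """One TFBS site per promoter: at Normal(nfr_center, tfbs_nfr_sd) with
    class probability tfbs_at_nfr_prob, uniform in the scatter flank
    otherwise."""
    rng = _rng(config.seed, "tfbs")
    positions: list[int] = []
    for prom in promoters:
        if rng.random() < config.tfbs_at_nfr_prob[prom.arch_class]:
            off = int(np.rint(rng.normal(config.nfr_center, config.tfbs_nfr_sd)))
        else:
            off = int(rng.integers(-config.tfbs_scatter_flank, config.tfbs_scatter_flank + 1))
        pos = prom.tss + off if prom.strand == "+" else prom.tss - off
        if 0 <= pos < config.chrom_length:
            positions.append(pos)
    by_chrom = {config.chrom_name: positions} if positions else {}
    return PositionSet(by_chrom, label="Sp1", condition="n/a")


def generate_expression(
    promoters: Sequence[Promoter],
    groups: Mapping[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    """Log-normal microarray-like intensities with a multiplicative
    modification effect for modified promoters (default e^1 for broad, none
    for peak). All genes are flagged present."""
    rng = _rng(config.seed, "expression")
    mu, sigma = config.expr_lognormal_params
    rows = []
    base = rng.lognormal(mu, sigma, size=len(promoters))
    for prom, intensity in zip(promoters, base):
        if groups.get(prom.id) == MODIFIED:
            intensity *= config.modification_effect[prom.arch_class]
        rows.append({"gene_id": prom.gene_id, "intensity": float(intensity), "present": True})
    return pd.DataFrame(rows, columns=["gene_id", "intensity", "present"])


@dataclass
class SimData:
    """Everything one simulated study produces."""

    config: SimConfig
    promoters: list[Promoter]
    genome: dict[str, str]
    cpg_islands: list[GenomicInterval]
    nucleosomes_resting: dict[str, PositionSet]
    nucleosomes_activated: dict[str, PositionSet]
    tfbs: PositionSet
    groups: dict[str, str]
    expression: pd.DataFrame


def simulate_all(config: SimConfig) -> SimData:
    """Run every generator in dependency order for one seed."""
    promoters, genome, cpg_islands = generate_promoters(config)
    resting = generate_nucleosomes(promoters, config, RESTING)
    activated = generate_nucleosomes(promoters, config, ACTIVATED)
    tfbs = generate_tfbs(promoters, config)
    family = [resting[m] for m in METHYLATION_FAMILY if m in resting]
    groups = label_modification(promoters, family) if family and promoters else {}
    expression = generate_expression(promoters, groups, config)
    return SimData(
        config=config,
        promoters=promoters,
        genome=genome,
        cpg_islands=cpg_islands,
        nucleosomes_resting=resting,
        nucleosomes_activated=activated,
        tfbs=tfbs,
        groups=groups,
        expression=expression,
    )
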