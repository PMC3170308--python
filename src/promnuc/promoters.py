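"""Promoter architecture classification and sequence-feature annotation.

A promoter is "peak" when its CAGE tag 5' ends fall within a narrow span
(width <= 4 bp by default) and "broad" otherwise. Peak promoters are
annotated for a TATA box within 50 bp upstream of the TSS (PWM scan,
relative score > 0.75); broad promoters for a CpG island overlapping the
200 bp upstream of the TSS. Upstream is always taken in transcript
orientation: minus-strand promoters scan the reverse complement of the
genomically downstream sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GenomicInterval, Promoter

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """A position weight matrix: per-position log-odds scores for A, C, G, T.

    ``matrix`` has shape (length, 4), columns ordered A, C, G, T.
    """

    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (length >= 1, 4)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM matrix must be finite")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        name: str = "",
        pseudocount: float = 0.8,
        background: float = 0.25,
    ) -> "Pwm":
        """Build log-odds scores from a count matrix (length x 4). The
        pseudocount is split across bases by the background frequency."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("count matrix must have shape (length, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        freqs = (counts + pseudocount * background) / (
            counts.sum(axis=1, keepdims=True) + pseudocount
        )
        return cls(np.log2(freqs / background), name=name)


# Built-in synthetic TATA-box count matrix encoding the TATAWAWR consensus.
# A stand-in for a curated TBP matrix, adequate for scanning planted or
# consensus-like sites; any JASPAR-format count matrix can be supplied instead.
TATA_BOX_COUNTS = np.array(
    [
        # A   C   G   T
        [5, 5, 5, 85],   # T
        [85, 5, 5, 5],   # A
        [5, 5, 5, 85],   # T
        [85, 5, 5, 5],   # A
        [45, 5, 5, 45],  # W
        [80, 6, 6, 8],   # A
        [45, 5, 5, 45],  # W
        [45, 5, 45, 5],  # R
    ]
)


def default_tata_pwm() -> Pwm:
    return Pwm.from_counts(TATA_BOX_COUNTS, name="TATA-box (synthetic consensus matrix)")


def read_jaspar_counts(path) -> Pwm:
    """Read a JASPAR-style 4-row count matrix text file.

    Accepts an optional '>' header line and rows like ``A [ 61 16 ... ]`` or
    bare whitespace-separated numbers in A, C, G, T order.
    """
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    name = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise ValueError(f"{path}: unexpected row {line!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
            order.append(base)
    if set(rows) != {"A", "C", "G", "T"}:
        raise ValueError(f"{path}: need exactly one row per base A, C, G, T")
    counts = np.array([rows["A"], rows["C"], rows["G"], rows["T"]]).T
    return Pwm.from_counts(counts, name=name)


@dataclass(frozen=True)
class PwmHit:
    """Best motif match: offset of the motif start relative to the TSS in
    transcript orientation, the strand scanned, and the min-max relative
    score in [0, 1]."""

    offset: int
    strand: str
    relative_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_score <= 1.0:
            raise ValueError("relative_score must lie in [0, 1]")


def classify_architecture(promoter: Promoter, threshold: int = 4) -> str:
    """'peak' iff the tag-span width is <= threshold (default 4 bp), else
    'broad'."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if promoter.width is None:
        raise ValueError(f"promoter {promoter.id}: width undefined")
    return "peak" if promoter.width <= threshold else "broad"


def classify_all(promoters: Sequence[Promoter], threshold: int = 4) -> list[Promoter]:
    """Return copies with arch_class set from the width threshold."""
    return [replace(p, arch_class=classify_architecture(p, threshold)) for p in promoters]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN base {exc.args[0]!r}") from None


def _extended_matrix(pwm: Pwm) -> np.ndarray:
    """PWM with a fifth column for N, scoring the per-position column mean."""
    return np.hstack([pwm.matrix, pwm.matrix.mean(axis=1, keepdims=True)])


def pwm_relative_score(window_seq: str, pwm: Pwm) -> float:
    """Min-max relative score (S - Smin) / (Smax - Smin) of one window.

    S sums the per-position scores; Smin/Smax are the least/greatest
    achievable sums. N contributes the column mean. Invariant under a common
    positive rescaling and shift of all columns.
    """
    if len(window_seq) != pwm.length:
        raise ValueError(f"window length {len(window_seq)} != PWM length {pwm.length}")
    ext = _extended_matrix(pwm)
    score = float(ext[np.arange(pwm.length), _encode(window_seq)].sum())
    smin = float(pwm.matrix.min(axis=1).sum())
    smax = float(pwm.matrix.max(axis=1).sum())
    if smax == smin:
        raise ValueError("degenerate PWM: all windows score identically")
    return (score - smin) / (smax - smin)


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Genomic slice [start, end); raises if out of range."""
    try:
        seq = genome[chrom]
    except KeyError:
        raise ValueError(f"chromosome {chrom!r} not in genome") from None
    if start < 0 or end > len(seq):
        raise ValueError(f"sequence window [{start}, {end}) unavailable on {chrom}")
    return str(seq[start:end]).upper()


def upstream_sequence(promoter: Promoter, genome: Mapping[str, str], length: int) -> str:
    """The ``length`` bases immediately upstream of the TSS, sense strand,
    5'->3' (last character abuts the TSS)."""
    if promoter.strand == "+":
        return _fetch(genome, promoter.chrom, promoter.tss - length, promoter.tss)
    return reverse_complement(
        _fetch(genome, promoter.chrom, promoter.tss + 1, promoter.tss + 1 + length)
    )


def annotate_tata(
    promoter: Promoter,
    genome: Mapping[str, str],
    pwm: Pwm | None = None,
    search_window: int = 50,
    min_rel_score: float = 0.75,
) -> tuple[bool, PwmHit | None]:
    """Scan the sense strand for a TATA box fully within ``search_window`` bp
    upstream of the TSS; positive iff any window's relative score exceeds
    ``min_rel_score`` (strictly). Returns the call and the best hit."""
    pwm = pwm or default_tata_pwm()
    if search_window < pwm.length:
        raise ValueError("search window shorter than the motif")
    seq = upstream_sequence(promoter, genome, search_window)
    codes = _encode(seq)
    ext = _extended_matrix(pwm)
    windows = np.lib.stride_tricks.sliding_window_view(codes, pwm.length)
    scores = ext[np.arange(pwm.length), windows].sum(axis=1)
    smin = float(pwm.matrix.min(axis=1).sum())
    smax = float(pwm.matrix.max(axis=1).sum())
    rel = (scores - smin) / (smax - smin)
    best = int(np.argmax(rel))
    hit = PwmHit(
        offset=best - search_window,
        strand=promoter.strand,
        relative_score=float(np.clip(rel[best], 0.0, 1.0)),
    )
    return bool(rel[best] > min_rel_score), hit


def annotate_cpg(
    promoter: Promoter,
    cpg_islands: Sequence[GenomicInterval] | IntervalTree | Mapping[str, IntervalTree],
    search_window: int = 200,
) -> bool:
    """True iff any CpG island overlaps (>= 1 bp) the inclusive window
    [tss - search_window, tss] in transcript orientation."""
    if isinstance(cpg_islands, Mapping):
        trees = cpg_islands
    else:
        trees = build_interval_trees(cpg_islands)
    tree = trees.get(promoter.chrom)
    if tree is None:
        return False
    if promoter.strand == "+":
        lo, hi = promoter.tss - search_window, promoter.tss + 1
    else:
        lo, hi = promoter.tss, promoter.tss + search_window + 1
    return bool(tree.overlap(max(lo, 0), hi))


def build_interval_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def annotate_all(
    promoters: Sequence[Promoter],
    genome: Mapping[str, str] | None = None,
    cpg_islands: Sequence[GenomicInterval] | None = None,
    pwm: Pwm | None = None,
    tata_window: int = 50,
    min_rel_score: float = 0.75,
    cpg_window: int = 200,
) -> list[Promoter]:
    """Annotate TATA and/or CpG status on copies of the promoters."""
    trees = build_interval_trees(cpg_islands) if cpg_islands is not None else None
    out = []
    for p in promoters:
        has_tata = p.has_tata
        has_cpg = p.has_cpg
        if genome is not None:
            has_tata, _ = annotate_tata(p, genome, pwm, tata_window, min_rel_score)
        if trees is not None:
            has_cpg = annotate_cpg(p, trees, cpg_window)
        out.append(replace(p, has_tata=has_tata, has_cpg=has_cpg))
    return out


def class_feature_frequencies(promoters: Sequence[Promoter]) -> dict[str, dict]:
    """Per-class proportions of promoters with a TATA box and with a CpG
    island. An empty class yields None proportions (undefined)."""
    out: dict[str, dict] = {}
    for cls in ("peak", "broad"):
        members = [p for p in promoters if p.arch_class == cls]
        if not members:
            out[cls] = {"n": 0, "tata": None, "cpg": None}
            continue
        n = len(members)
        out[cls] = {
            "n": n,
            "tata": sum(1 for p in members if p.has_tata) / n,
            "cpg": sum(1 for p in members if p.has_cpg) / n,
        }
    return out
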