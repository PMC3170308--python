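"""Core genomic data model.

All coordinates are 0-based. Intervals are half-open ``[start, end)``; point
features carry a single base position. Strand-aware quantities (profile
offsets, upstream windows) are computed in transcript orientation, i.e. the
promoter's strand decides which genomic direction counts as downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicPoint:
    """A single genomic base position, e.g. a nucleosome center or TFBS site."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end), e.g. a CpG island or a smeared
    nucleosome footprint."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Floor midpoint; ties on even lengths break toward the lower coordinate."""
        return (self.start + self.end - 1) // 2

    def overlaps(self, start: int, end: int) -> bool:
        """Overlap (>= 1 bp) with the half-open interval [start, end)."""
        return self.start < end and start < self.end


@dataclass
class Promoter:
    """A CAGE-defined promoter: a representative TSS plus the dispersion of
    tag 5' ends that determines its architecture class.

    ``width`` is the inclusive span ``max(tags) - min(tags) + 1``; a peak
    promoter initiates within a narrow span (<= 4 bp by default), a broad one
    over a wider range.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tag_positions: tuple[int, ...] = ()
    width: int | None = None
    arch_class: str = "unclassified"
    has_tata: bool | None = None
    has_cpg: bool | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"promoter strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.arch_class not in ("peak", "broad", "unclassified"):
            raise ValueError(f"unknown arch_class {self.arch_class!r}")
        self.tag_positions = tuple(int(t) for t in self.tag_positions)
        if self.tag_positions:
            span = max(self.tag_positions) - min(self.tag_positions) + 1
            if self.width is None:
                self.width = span
            elif self.width != span:
                raise ValueError(
                    f"promoter {self.id}: width {self.width} inconsistent with tag span {span}"
                )
            if self.tss not in self.tag_positions:
                raise ValueError(f"promoter {self.id}: tss {self.tss} not among tag positions")
        if self.width is not None and self.width < 1:
            raise ValueError("width must be >= 1")

    @property
    def n_tags(self) -> int:
        return len(self.tag_positions)

    def offset_of(self, pos: int) -> int:
        """Transcript-orientation offset of a genomic position (0 = TSS,
        positive downstream)."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


class PositionSet:
    """A named multiset of genomic point positions, per-chromosome and sorted.

    Duplicate positions are kept: tag-depth data can legitimately repeat a
    coordinate. ``label`` names the feature (H3, H2A.Z, H3K4me3, Sp1, ...)
    and ``condition`` the cellular condition (resting/activated/n/a).
    """

    def __init__(
        self,
        positions: Mapping[str, Iterable[int]] | None = None,
        label: str = "",
        condition: str = "n/a",
    ) -> None:
        self.label = label
        self.condition = condition
        self._by_chrom: dict[str, np.ndarray] = {}
        if positions:
            for chrom, vals in positions.items():
                arr = np.sort(np.asarray(list(vals), dtype=np.int64))
                if arr.size and arr[0] < 0:
                    raise ValueError(f"negative position on {chrom}")
                self._by_chrom[chrom] = arr

    @classmethod
    def from_points(
        cls,
        points: Iterable[GenomicPoint | tuple[str, int]],
        label: str = "",
        condition: str = "n/a",
    ) -> "PositionSet":
        by_chrom: dict[str, list[int]] = {}
        for p in points:
            chrom, pos = (p.chrom, p.pos) if isinstance(p, GenomicPoint) else p
            by_chrom.setdefault(chrom, []).append(int(pos))
        return cls(by_chrom, label=label, condition=condition)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted positions on a chromosome (empty array if none)."""
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def n_points(self) -> int:
        return sum(a.size for a in self._by_chrom.values())

    def __len__(self) -> int:
        return self.n_points

    def __iter__(self) -> Iterator[GenomicPoint]:
        for chrom in self.chroms():
            for pos in self._by_chrom[chrom]:
                yield GenomicPoint(chrom, int(pos))

    def __eq__(self, other: object) -> bool:
        """Positional equality; label/condition metadata is not compared."""
        if not isinstance(other, PositionSet):
            return NotImplemented
        mine = {c: a for c, a in self._by_chrom.items() if a.size}
        theirs = {c: a for c, a in other._by_chrom.items() if a.size}
        if mine.keys() != theirs.keys():
            return False
        return all(np.array_equal(mine[c], theirs[c]) for c in mine)

    def __repr__(self) -> str:
        return (
            f"PositionSet(label={self.label!r}, condition={self.condition!r}, "
            f"n={self.n_points}, chroms={self.chroms()})"
        )

    def shift(self, delta: int) -> "PositionSet":
        """Translate every position by ``delta`` bp."""
        return PositionSet(
            {c: a + delta for c, a in self._by_chrom.items()},
            label=self.label,
            condition=self.condition,
        )

    def mirror(self, chrom_lengths: Mapping[str, int]) -> "PositionSet":
        """Reflect positions through chromosome ends (pos -> L - 1 - pos)."""
        return PositionSet(
            {c: chrom_lengths[c] - 1 - a for c, a in self._by_chrom.items()},
            label=self.label,
            condition=self.condition,
        )


def mirror_promoter(promoter: Promoter, chrom_length: int) -> Promoter:
    """Reflect a promoter through the chromosome end, flipping its strand.

    Used to assert that every strand-aware statistic is invariant under a
    global coordinate mirror.
    """
    flip = {"+": "-", "-": "+"}
    return replace(
        promoter,
        tss=chrom_length - 1 - promoter.tss,
        strand=flip[promoter.strand],
        tag_positions=tuple(chrom_length - 1 - t for t in promoter.tag_positions),
    )


def split_by_class(promoters: Sequence[Promoter]) -> dict[str, list[Promoter]]:
    out: dict[str, list[Promoter]] = {}
    for p in promoters:
        out.setdefault(p.arch_class, []).append(p)
    return out
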