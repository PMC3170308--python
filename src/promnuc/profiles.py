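"""TSS-anchored occupancy profiles and class-contrast statistics.

A profile aggregates point features (nucleosome centers, TFBS sites) over a
symmetric window around every TSS of one promoter class, in transcript
orientation. Nucleosome centers are smeared +/- 15 bp by default, treating the
31 bp around each mapped center as occupied; TFBS sites are kept as points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, GenomicPoint, PositionSet, Promoter

DEFAULT_SMEAR_HALFWIDTH = 15


@dataclass
class ProfileTrack:
    """Per-offset values over a contiguous offset range around the TSS.

    ``values[i]`` belongs to ``offsets[i]``; offset 0 is the TSS base and
    positive offsets are downstream in transcript orientation. For occupancy
    profiles the values are proportions (counts divided by the number of
    TSSs); relative-abundance tracks may hold negative values.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_tss: int = 0
    feature_label: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must have equal length")
        if self.offsets.size > 1 and not np.all(np.diff(self.offsets) == 1):
            raise ValueError("offsets must be contiguous")

    def __len__(self) -> int:
        return self.offsets.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileTrack):
            return NotImplemented
        return np.array_equal(self.offsets, other.offsets) and np.allclose(
            self.values, other.values, rtol=0, atol=1e-12
        )

    def _index(self, offset: int) -> int:
        if self.offsets.size == 0 or not self.offsets[0] <= offset <= self.offsets[-1]:
            raise KeyError(f"offset {offset} outside track range")
        return int(offset - self.offsets[0])

    def value_at(self, offset: int) -> float:
        return float(self.values[self._index(offset)])

    def window(self, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """Offsets and values over the inclusive offset window [a, b]."""
        i, j = self._index(a), self._index(b)
        return self.offsets[i : j + 1], self.values[i : j + 1]

    def argmax(self, a: int, b: int) -> int:
        """Offset of the maximum value over [a, b] (first on ties)."""
        offs, vals = self.window(a, b)
        return int(offs[int(np.argmax(vals))])

    def argmin(self, a: int, b: int) -> int:
        offs, vals = self.window(a, b)
        return int(offs[int(np.argmin(vals))])


@dataclass
class EnrichmentTest:
    """A 2x2 class-by-feature contingency test over a TSS-relative window.

    Rows are {broad, peak}; columns are {has >= 1 smeared feature overlapping
    the window, has none}. Pearson chi-squared, 1 df, no continuity
    correction.
    """

    window: tuple[int, int]
    table: np.ndarray
    statistic: float
    p_value: float
    warning: str | None = None

    def as_dict(self) -> dict:
        return {
            "window": list(self.window),
            "table": np.asarray(self.table).tolist(),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "warning": self.warning,
        }


def smear_center(point: GenomicPoint, halfwidth: int = DEFAULT_SMEAR_HALFWIDTH) -> GenomicInterval:
    """The occupied footprint around a nucleosome center: genomic positions
    from -halfwidth to +halfwidth inclusive (31 bp at the default 15)."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    return GenomicInterval(point.chrom, point.pos - halfwidth, point.pos + halfwidth + 1, point.strand)


def occupancy_profile(
    promoters: Sequence[Promoter],
    points: PositionSet,
    flank: int = 5000,
    halfwidth: int = DEFAULT_SMEAR_HALFWIDTH,
    mode: str = "per_nucleosome",
) -> ProfileTrack:
    """TSS-anchored occupancy profile over offsets [-flank, +flank].

    per_nucleosome mode: at each offset, the number of smeared features
    covering it (summed over promoters) divided by the number of TSSs.
    per_tss mode: the proportion of TSSs with at least one smeared feature
    covering the offset. Offsets are transcript-oriented: (pos - tss) on the
    plus strand and (tss - pos) on the minus strand. Flanks running past a
    chromosome end simply accumulate nothing.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if mode not in ("per_nucleosome", "per_tss"):
        raise ValueError(f"unknown mode {mode!r}")

    size = 2 * flank + 1
    acc = np.zeros(size)
    for prom in promoters:
        arr = points.positions(prom.chrom)
        lo = prom.tss - flank - halfwidth
        hi = prom.tss + flank + halfwidth
        i, j = np.searchsorted(arr, [lo, hi + 1])
        sub = arr[i:j]
        if sub.size == 0:
            continue
        off = (sub - prom.tss) if prom.strand == "+" else (prom.tss - sub)
        # range-add [off-hw, off+hw] via a difference array, clipped to the track
        starts = np.clip(off - halfwidth + flank, 0, size)
        ends = np.clip(off + halfwidth + 1 + flank, 0, size)
        keep = ends > starts
        diff = np.zeros(size + 1)
        np.add.at(diff, starts[keep], 1.0)
        np.add.at(diff, ends[keep], -1.0)
        cov = np.cumsum(diff[:-1])
        acc += (cov > 0) if mode == "per_tss" else cov

    return ProfileTrack(
        offsets=np.arange(-flank, flank + 1),
        values=acc / len(promoters),
        n_tss=len(promoters),
        feature_label=points.label,
        class_label=promoters[0].arch_class,
    )


def tfbs_profile(
    promoters: Sequence[Promoter], sites: PositionSet, flank: int = 500
) -> ProfileTrack:
    """TFBS site density around TSSs: sites per position divided by the number
    of TSSs. Sites are points (no smear)."""
    return occupancy_profile(promoters, sites, flank=flank, halfwidth=0, mode="per_nucleosome")


def relative_abundance(
    broad: ProfileTrack, peak: ProfileTrack, window: tuple[int, int] = (-2000, 2000)
) -> ProfileTrack:
    """Class contrast (Bj - Pj) / sum_i(Bi) at each offset j, where B and P
    are the broad and peak proportions and the denominator sums the broad
    proportions over the window (default -2000..+2000)."""
    a, b = window
    b_off, b_vals = broad.window(a, b)
    _, p_vals = peak.window(a, b)
    denom = float(b_vals.sum())
    if denom == 0.0:
        raise ValueError("sum of broad proportions over the window is zero; contrast undefined")
    return ProfileTrack(
        offsets=b_off,
        values=(b_vals - p_vals) / denom,
        n_tss=broad.n_tss,
        feature_label=broad.feature_label,
        class_label="broad-peak",
    )


def promoters_with_feature_in_window(
    promoters: Sequence[Promoter],
    points: PositionSet,
    window: tuple[int, int],
    halfwidth: int = DEFAULT_SMEAR_HALFWIDTH,
) -> np.ndarray:
    """Boolean per promoter: does >= 1 smeared feature overlap the inclusive
    transcript-orientation offset window [a, b]?

    A smear of +/- halfwidth overlaps [a, b] iff the center offset lies in
    [a - halfwidth, b + halfwidth].
    """
    a, b = window
    out = np.zeros(len(promoters), dtype=bool)
    for k, prom in enumerate(promoters):
        arr = points.positions(prom.chrom)
        if prom.strand == "+":
            lo, hi = prom.tss + a - halfwidth, prom.tss + b + halfwidth
        else:
            lo, hi = prom.tss - b - halfwidth, prom.tss - a + halfwidth
        i, j = np.searchsorted(arr, [lo, hi + 1])
        out[k] = j > i
    return out


def window_enrichment_test(
    broad_promoters: Sequence[Promoter],
    peak_promoters: Sequence[Promoter],
    points: PositionSet,
    window: tuple[int, int] = (100, 130),
    halfwidth: int = DEFAULT_SMEAR_HALFWIDTH,
) -> EnrichmentTest:
    """Chi-squared test of class vs. presence of a smeared feature in a
    TSS-relative window (default +100..+130, both ends inclusive)."""
    if not broad_promoters or not peak_promoters:
        raise ValueError("both promoter classes must be non-empty")
    b_has = promoters_with_feature_in_window(broad_promoters, points, window, halfwidth)
    p_has = promoters_with_feature_in_window(peak_promoters, points, window, halfwidth)
    table = np.array(
        [
            [int(b_has.sum()), int((~b_has).sum())],
            [int(p_has.sum()), int((~p_has).sum())],
        ]
    )
    warning = None
    col_sums = table.sum(axis=0)
    if (col_sums == 0).any():
        # all promoters on one side: no association measurable
        return EnrichmentTest(tuple(window), table, 0.0, 1.0, "degenerate table (empty column)")
    res = stats.chi2_contingency(table, correction=False)
    expected = np.asarray(res.expected_freq)
    if (expected < 1).any():
        warning = f"expected cell below 1 (min {expected.min():.3g})"
    return EnrichmentTest(tuple(window), table, float(res.statistic), float(res.pvalue), warning)


def profile_correlation(
    track_a: ProfileTrack, track_b: ProfileTrack, window: tuple[int, int]
) -> float:
    """Pearson correlation of two tracks over aligned offsets [a, b]; NaN if
    either track has zero variance over the window (undefined)."""
    a, b = window
    _, va = track_a.window(a, b)
    _, vb = track_b.window(a, b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return math.nan
    return float(np.corrcoef(va, vb)[0, 1])
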