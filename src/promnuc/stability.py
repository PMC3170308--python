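"""Nucleosome positional stability between two cellular conditions.

For every nucleosome center observed in the resting condition, the signed
distance to the nearest center in the activated condition (same chromosome,
genomic orientation) measures how far that nucleosome moved. Distances whose
magnitude exceeds 100 bp are excluded from the mean, since such pairs are
more plausibly different nucleosomes than one that slid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import PositionSet, Promoter


@dataclass
class StabilityResult:
    """Signed nearest-neighbor distances for one promoter class, their 15 bp
    binned distribution, and the exclusion-filtered mean absolute distance."""

    distances: np.ndarray
    binned: pd.DataFrame
    mean_abs: float
    n_used: int
    n_excluded: int
    n_undefined: int
    class_label: str = ""

    def summary(self) -> dict:
        return {
            "class": self.class_label,
            "n_distances": int(self.distances.size),
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "n_undefined": self.n_undefined,
            "mean_abs": None if math.isnan(self.mean_abs) else self.mean_abs,
        }


@dataclass
class StabilityComparison:
    statistic: float
    p_value: float
    mean_broad: float
    mean_peak: float


def promoter_proximal_nucleosomes(
    promoters: Sequence[Promoter],
    points: PositionSet,
    window: tuple[int, int] = (1, 200),
) -> PositionSet:
    """Subset of centers whose transcript-orientation offset to at least one
    promoter lies in the inclusive window (default +1..+200). A center
    associated with several promoters appears once."""
    a, b = window
    keep: dict[str, set[int]] = {}
    for prom in promoters:
        arr = points.positions(prom.chrom)
        if prom.strand == "+":
            lo, hi = prom.tss + a, prom.tss + b
        else:
            lo, hi = prom.tss - b, prom.tss - a
        i, j = np.searchsorted(arr, [lo, hi + 1])
        if j > i:
            keep.setdefault(prom.chrom, set()).update(range(i, j))
    by_chrom = {
        chrom: points.positions(chrom)[sorted(idx)] for chrom, idx in keep.items()
    }
    return PositionSet(by_chrom, label=points.label, condition=points.condition)


def min_distances(rest: PositionSet, act: PositionSet) -> tuple[np.ndarray, int]:
    """Signed distance (activated - resting, genomic orientation) from each
    resting center to the nearest activated center on the same chromosome.

    Ties between equally near neighbors break toward the negative (lower
    genomic coordinate) side. Resting centers on chromosomes with no
    activated centers are undefined; they are dropped and counted.
    Returns (distances, n_undefined).
    """
    out: list[np.ndarray] = []
    n_undefined = 0
    for chrom in rest.chroms():
        r = rest.positions(chrom)
        a = act.positions(chrom)
        if r.size == 0:
            continue
        if a.size == 0:
            n_undefined += int(r.size)
            continue
        idx = np.searchsorted(a, r)
        left = a[np.clip(idx - 1, 0, a.size - 1)]
        right = a[np.clip(idx, 0, a.size - 1)]
        d_left = np.where(idx > 0, r - left, np.iinfo(np.int64).max)
        d_right = np.where(idx < a.size, right - r, np.iinfo(np.int64).max)
        signed = np.where(d_left <= d_right, -d_left, d_right)
        out.append(signed)
    if not out:
        return np.empty(0, dtype=np.int64), n_undefined
    return np.concatenate(out).astype(np.int64), n_undefined


def distance_distribution(distances: np.ndarray, bin_size: int = 15) -> pd.DataFrame:
    """Histogram of signed distances in [x, x + bin_size) bins anchored at 0,
    as proportions of the total count."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    d = np.asarray(distances)
    if d.size == 0:
        return pd.DataFrame({"bin_start": pd.Series(dtype=np.int64), "proportion": pd.Series(dtype=float)})
    lo = int(np.floor(d.min() / bin_size)) * bin_size
    hi = (int(np.floor(d.max() / bin_size)) + 1) * bin_size
    edges = np.arange(lo, hi + bin_size, bin_size)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "proportion": counts / d.size})


def mean_abs_min_distance(
    distances: np.ndarray, exclusion: int = 100
) -> tuple[float, int, int]:
    """Mean |d| over distances with |d| <= exclusion ("longer than" the
    cutoff is excluded, so |d| == exclusion is kept). Returns
    (mean_abs or NaN, n_used, n_excluded)."""
    if exclusion <= 0:
        raise ValueError("exclusion must be > 0")
    mags = np.abs(np.asarray(distances, dtype=float))
    used = mags[mags <= exclusion]
    n_used = int(used.size)
    n_excluded = int(mags.size - n_used)
    mean_abs = float(used.mean()) if n_used else math.nan
    return mean_abs, n_used, n_excluded


def compare_stability(
    broad_abs: np.ndarray, peak_abs: np.ndarray, equal_var: bool = False
) -> StabilityComparison:
    """Two-sample t-test (Welch by default) on absolute minimum distances
    after exclusion, two-sided."""
    b = np.asarray(broad_abs, dtype=float)
    p = np.asarray(peak_abs, dtype=float)
    if b.size < 2 or p.size < 2:
        raise ValueError("need >= 2 values per group")
    if b.std() == 0 and p.std() == 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(b, p, equal_var=equal_var)
    return StabilityComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_broad=float(b.mean()),
        mean_peak=float(p.mean()),
    )


def stability_analysis(
    promoters: Sequence[Promoter],
    rest: PositionSet,
    act: PositionSet,
    window: tuple[int, int] = (1, 200),
    exclusion: int = 100,
    bin_size: int = 15,
    class_label: str = "",
) -> StabilityResult:
    """End-to-end stability for one promoter class: select promoter-proximal
    resting centers, compute signed nearest-activated distances, bin them,
    and compute the exclusion-filtered mean absolute distance."""
    proximal = promoter_proximal_nucleosomes(promoters, rest, window)
    distances, n_undefined = min_distances(proximal, act)
    binned = distance_distribution(distances, bin_size)
    mean_abs, n_used, n_excluded = mean_abs_min_distance(distances, exclusion)
    return StabilityResult(
        distances=distances,
        binned=binned,
        mean_abs=mean_abs,
        n_used=n_used,
        n_excluded=n_excluded,
        n_undefined=n_undefined,
        class_label=class_label,
    )
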