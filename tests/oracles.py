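"""Independent brute-force oracles used to cross-check the library.

Everything here is written as a naive per-base / per-pair scan or a direct
closed-form/enumeration formula, deliberately sharing no code path with the
implementations under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from promnuc.core import PositionSet, Promoter


def occupancy_profile_bruteforce(promoters, points: PositionSet, flank, halfwidth, mode):
    """Naive O(promoters x points x window) profile, as proportions."""
    size = 2 * flank + 1
    acc = np.zeros(size)
    for prom in promoters:
        cov = np.zeros(size)
        for pos in points.positions(prom.chrom):
            off = int(pos) - prom.tss if prom.strand == "+" else prom.tss - int(pos)
            for j in range(off - halfwidth, off + halfwidth + 1):
                if -flank <= j <= flank:
                    cov[j + flank] += 1
        acc += (cov > 0) if mode == "per_tss" else cov
    return acc / len(promoters)


def min_distances_bruteforce(rest: PositionSet, act: PositionSet):
    """All-pairs nearest neighbor; ties break toward the lower coordinate."""
    dists = []
    undef = 0
    for chrom in rest.chroms():
        r = rest.positions(chrom)
        a = [int(v) for v in act.positions(chrom)]
        if len(r) and not a:
            undef += len(r)
            continue
        for x in r:
            x = int(x)
            best = min(a, key=lambda y: (abs(y - x), y - x))
            dists.append(best - x)
    return np.array(dists, dtype=np.int64), undef


def enrichment_table_bruteforce(broad, peak, points: PositionSet, window, halfwidth):
    a, b = window

    def has(prom: Promoter) -> bool:
        for pos in points.positions(prom.chrom):
            off = int(pos) - prom.tss if prom.strand == "+" else prom.tss - int(pos)
            if a - halfwidth <= off <= b + halfwidth:
                return True
        return False

    bh = sum(has(p) for p in broad)
    ph = sum(has(p) for p in peak)
    return np.array([[bh, len(broad) - bh], [ph, len(peak) - ph]])


def chi2_2x2(table):
    """Closed-form Pearson chi-squared for a 2x2 table (1 df, no correction)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def welch_t(x, y):
    """Closed-form Welch t statistic (sample variances, ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = ((x - x.mean()) ** 2).sum() / (x.size - 1)
    vy = ((y - y.mean()) ** 2).sum() / (y.size - 1)
    return (x.mean() - y.mean()) / np.sqrt(vx / x.size + vy / y.size)


def mannwhitney_exact_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    of the pooled (tie-free) values."""
    x = list(x)
    y = list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    nx = len(x)

    def u_stat(group_x, group_y):
        return sum(1 for xi in group_x for yi in group_y if xi > yi)

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(gx, gy))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def pearson_manual(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def pwm_score_window(seq, matrix):
    """Direct per-position sum of log-odds scores; N scores the column mean."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for i, base in enumerate(seq.upper()):
        total += matrix[i].mean() if base == "N" else matrix[i][idx[base]]
    return total


def random_promoters(rng, n, chroms=("c1", "c2"), span=100_000, margin=500):
    """Random single-class promoters for oracle-equivalence instances."""
    out = []
    for i in range(n):
        out.append(
            Promoter(
                id=f"r{i}",
                chrom=str(rng.choice(chroms)),
                strand=str(rng.choice(["+", "-"])),
                tss=int(rng.integers(margin, span - margin)),
                width=int(rng.integers(1, 60)),
            )
        )
    return out


def random_position_set(rng, n_points, chroms=("c1", "c2"), span=100_000):
    by_chrom = {}
    for chrom in chroms:
        k = int(rng.integers(0, n_points + 1))
        by_chrom[chrom] = rng.integers(0, span, size=k)
    return PositionSet(by_chrom, label="rand")
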