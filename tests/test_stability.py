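"""Nearest-neighbor positional stability between conditions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from promnuc.core import PositionSet, Promoter
from promnuc.simulate import ACTIVATED, RESTING, SimConfig, generate_nucleosomes, generate_promoters
from promnuc.stability import (
    compare_stability,
    distance_distribution,
    mean_abs_min_distance,
    min_distances,
    promoter_proximal_nucleosomes,
    stability_analysis,
)


def prom(tss, strand="+", arch="broad"):
    return Promoter("p", "c1", strand, tss, width=10, arch_class=arch)


class TestProximalSelection:
    def test_downstream_center_included_upstream_excluded(self):
        points = PositionSet({"c1": [5100, 4900]})
        sub = promoter_proximal_nucleosomes([prom(5000)], points)
        assert sub.positions("c1").tolist() == [5100]

    def test_minus_strand_downstream_is_genomically_upstream(self):
        points = PositionSet({"c1": [4900]})
        sub = promoter_proximal_nucleosomes([prom(5000, strand="-")], points)
        assert sub.positions("c1").tolist() == [4900]

    def test_shared_center_appears_once(self):
        points = PositionSet({"c1": [5100]})
        sub = promoter_proximal_nucleosomes([prom(5000), prom(5050)], points)
        assert sub.n_points == 1

    def test_window_bounds_inclusive(self):
        points = PositionSet({"c1": [5001, 5200, 5201]})
        sub = promoter_proximal_nucleosomes([prom(5000)], points, window=(1, 200))
        assert sub.positions("c1").tolist() == [5001, 5200]


class TestMinDistances:
    def test_identical_sets_all_zero(self):
        ps = PositionSet({"c1": [10, 50, 90]})
        d, undef = min_distances(ps, ps)
        assert d.tolist() == [0, 0, 0] and undef == 0

    def test_nearest_neighbor_signed(self):
        d, _ = min_distances(PositionSet({"c1": [100]}), PositionSet({"c1": [90, 130]}))
        assert d.tolist() == [-10]

    def test_tie_breaks_toward_negative(self):
        d, _ = min_distances(PositionSet({"c1": [100]}), PositionSet({"c1": [90, 110]}))
        assert d.tolist() == [-10]

    def test_missing_chromosome_counts_undefined(self):
        d, undef = min_distances(
            PositionSet({"c1": [100], "c2": [5, 6]}), PositionSet({"c1": [100]})
        )
        assert d.tolist() == [0] and undef == 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        rest=st.lists(st.integers(0, 10_000), min_size=1, max_size=30),
        act=st.lists(st.integers(0, 10_000), min_size=1, max_size=30),
        shift=st.integers(0, 5_000),
    )
    def test_translation_invariance_and_bruteforce(self, rest, act, shift):
        r = PositionSet({"c1": rest})
        a = PositionSet({"c1": act})
        d, undef = min_distances(r, a)
        expect, expect_undef = oracles.min_distances_bruteforce(r, a)
        assert np.array_equal(np.sort(d), np.sort(expect)) and undef == expect_undef
        d_shifted, _ = min_distances(r.shift(shift), a.shift(shift))
        assert np.array_equal(d_shifted, d)


class TestDistribution:
    def test_all_zero_single_bin(self):
        df = distance_distribution(np.zeros(5, dtype=int))
        assert df["bin_start"].tolist() == [0] and df["proportion"].tolist() == [1.0]

    def test_bins_anchored_at_zero(self):
        df = distance_distribution(np.array([-1, 1]))
        assert df["bin_start"].tolist() == [-15, 0]
        assert df["proportion"].tolist() == [0.5, 0.5]

    def test_empty_input(self):
        assert len(distance_distribution(np.array([], dtype=int))) == 0

    def test_random_matches_counting_oracle(self, rng):
        d = rng.integers(-30, 30, size=100)
        df = distance_distribution(d)
        assert df["proportion"].sum() == pytest.approx(1.0)
        for start, proportion in zip(df["bin_start"], df["proportion"]):
            assert proportion == np.mean((d >= start) & (d < start + 15))


class TestMeanAbs:
    def test_small_examples(self):
        mean, used, excl = mean_abs_min_distance(np.array([0, 10, -10]))
        assert mean == pytest.approx(20 / 3) and (used, excl) == (3, 0)
        mean, used, excl = mean_abs_min_distance(np.array([5, 150]))
        assert mean == 5.0 and (used, excl) == (1, 1)

    def test_boundary_kept_strictly_longer_excluded(self):
        mean, used, excl = mean_abs_min_distance(np.array([100, 101]))
        assert mean == 100.0 and (used, excl) == (1, 1)

    def test_all_excluded_reports_missing(self):
        mean, used, excl = mean_abs_min_distance(np.array([500, -500]))
        assert np.isnan(mean) and used == 0 and excl == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dists=st.lists(st.integers(-300, 300), min_size=1, max_size=50),
        cut=st.integers(1, 200),
    )
    def test_tightening_cutoff_never_increases_n_used(self, dists, cut):
        d = np.array(dists)
        _, used_tight, _ = mean_abs_min_distance(d, cut)
        _, used_loose, _ = mean_abs_min_distance(d, cut + 10)
        assert used_tight <= used_loose


class TestCompare:
    def test_identical_groups(self):
        res = compare_stability(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        b = np.array([1.0, 2.0, 3.0])
        p = b + 10.0
        res = compare_stability(b, p)
        assert res.statistic == pytest.approx(oracles.welch_t(b, p), rel=1e-12)
        assert res.p_value < 1e-3

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_stability(np.array([2.0, 2.0]), np.array([5.0, 5.0]))

    def test_jitter_ordering_recovered_across_seeds(self):
        """With per-class condition jitter sd 8 (broad) vs 15 (peak), the
        pipeline reports smaller broad mean |d| in every replicate tried."""
        for seed in range(5):
            cfg = SimConfig(seed=100 + seed, n_broad=200, n_peak=200, chrom_length=5_000_000)
            promoters, _, _ = generate_promoters(cfg)
            rest = generate_nucleosomes(promoters, cfg, RESTING)["H3"]
            act = generate_nucleosomes(promoters, cfg, ACTIVATED)["H3"]
            broad = [p for p in promoters if p.arch_class == "broad"]
            peak = [p for p in promoters if p.arch_class == "peak"]
            res_b = stability_analysis(broad, rest, act, class_label="broad")
            res_p = stability_analysis(peak, rest, act, class_label="peak")
            assert res_b.mean_abs < res_p.mean_abs

    def test_binned_proportions_sum_to_one_before_exclusion(self, default_sim):
        broad = [p for p in default_sim.promoters if p.arch_class == "broad"]
        res = stability_analysis(
            broad,
            default_sim.nucleosomes_resting["H3"],
            default_sim.nucleosomes_activated["H3"],
        )
        assert res.binned["proportion"].sum() == pytest.approx(1.0)
        assert res.n_used + res.n_excluded == res.distances.size
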