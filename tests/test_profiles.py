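"""TSS-anchored profiles, class contrasts, and window enrichment."""

import numpy as np
import pytest

import oracles
from promnuc.core import GenomicPoint, PositionSet, Promoter, mirror_promoter
from promnuc.profiles import (
    ProfileTrack,
    occupancy_profile,
    profile_correlation,
    relative_abundance,
    smear_center,
    tfbs_profile,
    window_enrichment_test,
)


def prom(tss, strand="+", chrom="c1", arch="broad", pid="p"):
    return Promoter(pid, chrom, strand, tss, width=10, arch_class=arch)


class TestSmear:
    def test_default_covers_31_bases(self):
        iv = smear_center(GenomicPoint("c1", 1000))
        assert (iv.start, iv.end) == (985, 1016)  # [985, 1015] inclusive

    def test_zero_halfwidth_single_base(self):
        iv = smear_center(GenomicPoint("c1", 1000), halfwidth=0)
        assert (iv.start, iv.end) == (1000, 1001)

    def test_adjacent_centers_overlap(self):
        a = smear_center(GenomicPoint("c1", 1000))
        b = smear_center(GenomicPoint("c1", 1010))
        assert a.overlaps(b.start, b.end)


class TestOccupancyProfile:
    def test_center_at_tss_plus_strand(self):
        track = occupancy_profile([prom(5000)], PositionSet({"c1": [5000]}), flank=100)
        assert np.all(track.values[(track.offsets >= -15) & (track.offsets <= 15)] == 1.0)
        assert track.values.sum() == 31.0

    def test_minus_strand_center_downstream_maps_upstream(self):
        track = occupancy_profile([prom(5000, strand="-")], PositionSet({"c1": [5100]}), flank=200)
        covered = track.offsets[track.values > 0]
        assert covered.min() == -115 and covered.max() == -85

    def test_per_tss_mode_counts_promoters_not_centers(self):
        proms = [prom(5000, pid="a"), prom(9000, pid="b")]
        points = PositionSet({"c1": [5000, 5005]})
        per_tss = occupancy_profile(proms, points, flank=100, mode="per_tss")
        per_nuc = occupancy_profile(proms, points, flank=100, mode="per_nucleosome")
        assert per_tss.value_at(0) == 0.5  # one of two promoters covered
        assert per_nuc.value_at(0) == 1.0  # two centers / two promoters
        assert np.all(per_tss.values <= per_nuc.values)

    def test_empty_promoters_error_empty_points_zero(self):
        with pytest.raises(ValueError, match="empty promoter"):
            occupancy_profile([], PositionSet())
        track = occupancy_profile([prom(5000)], PositionSet(), flank=50)
        assert not track.values.any()

    def test_tfbs_profile_is_unsmeared(self):
        proms = [prom(5000, pid="a"), prom(9000, pid="b"), prom(12000, pid="c")]
        sites = PositionSet({"c1": [4950, 8950]})
        track = tfbs_profile(proms, sites)
        assert track.value_at(-50) == pytest.approx(2 / 3)
        assert track.values.sum() == pytest.approx(2 / 3)
        far = tfbs_profile([prom(5000)], PositionSet({"c1": [5501]}))
        assert not far.values.any()


class TestRelativeAbundance:
    def test_identical_tracks_give_zero(self):
        offs = np.arange(-50, 51)
        vals = np.linspace(0.1, 1.0, offs.size)
        b = ProfileTrack(offs, vals)
        p = ProfileTrack(offs, vals.copy())
        ra = relative_abundance(b, p, (-50, 50))
        assert not ra.values.any()

    def test_spike_normalizes_to_one(self):
        offs = np.arange(-50, 51)
        b_vals = np.zeros(offs.size)
        b_vals[60] = 1.0
        ra = relative_abundance(ProfileTrack(offs, b_vals), ProfileTrack(offs, np.zeros(offs.size)), (-50, 50))
        assert ra.value_at(int(offs[60])) == 1.0

    def test_matches_direct_formula_on_random_tracks(self, rng):
        offs = np.arange(-20, 21)
        b = ProfileTrack(offs, rng.random(offs.size))
        p = ProfileTrack(offs, rng.random(offs.size))
        ra = relative_abundance(b, p, (-20, 20))
        expect = (b.values - p.values) / b.values.sum()
        assert np.allclose(ra.values, expect, rtol=1e-12, atol=0)

    def test_zero_denominator_errors(self):
        offs = np.arange(-5, 6)
        z = ProfileTrack(offs, np.zeros(offs.size))
        with pytest.raises(ValueError, match="zero"):
            relative_abundance(z, z, (-5, 5))


class TestEnrichmentTest:
    def test_identical_classes_no_association(self):
        broad = [prom(5000, arch="broad", pid="b0")]
        peak = [prom(5000, arch="peak", pid="p0")]
        res = window_enrichment_test(broad, peak, PositionSet({"c1": [5115]}))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            window_enrichment_test([], [prom(1000)], PositionSet())

    def test_expected_cell_warning(self):
        broad = [prom(5000 + 20000 * i, pid=f"b{i}") for i in range(2)]
        peak = [prom(100000 + 20000 * i, arch="peak", pid=f"p{i}") for i in range(2)]
        points = PositionSet({"c1": [5115]})
        res = window_enrichment_test(broad, peak, points)
        assert res.warning is not None and "expected" in res.warning


class TestProfileCorrelation:
    def test_self_and_negation(self):
        offs = np.arange(-10, 11)
        vals = np.sin(offs / 3.0) + 1.5
        t = ProfileTrack(offs, vals)
        assert profile_correlation(t, t, (-10, 10)) == pytest.approx(1.0)
        neg = ProfileTrack(offs, -vals)
        assert profile_correlation(t, neg, (-10, 10)) == pytest.approx(-1.0)

    def test_random_tracks_match_direct_formula(self, rng):
        offs = np.arange(-30, 31)
        a = ProfileTrack(offs, rng.random(offs.size))
        b = ProfileTrack(offs, rng.random(offs.size))
        r = profile_correlation(a, b, (-30, 30))
        assert r == pytest.approx(oracles.pearson_manual(a.values, b.values), rel=1e-12)

    def test_zero_variance_is_missing(self):
        offs = np.arange(-5, 6)
        flat = ProfileTrack(offs, np.ones(offs.size))
        wavy = ProfileTrack(offs, np.arange(offs.size, dtype=float))
        assert np.isnan(profile_correlation(flat, wavy, (-5, 5)))


class TestStrandMirror:
    def test_mirrored_instance_reproduces_profile_and_table(self, rng):
        """Reflecting all coordinates and flipping strands must leave every
        transcript-orientation statistic unchanged."""
        length = 200_000
        proms = oracles.random_promoters(rng, 20, chroms=("c1",), span=length, margin=6000)
        broad = [p if p.arch_class == "broad" else p for p in proms[:10]]
        peak = proms[10:]
        for p in broad:
            p.arch_class = "broad"
        for p in peak:
            p.arch_class = "peak"
        points = oracles.random_position_set(rng, 400, chroms=("c1",), span=length)
        track = occupancy_profile(broad, points, flank=2000)
        enr = window_enrichment_test(broad, peak, points)

        m_points = points.mirror({"c1": length})
        m_broad = [mirror_promoter(p, length) for p in broad]
        m_peak = [mirror_promoter(p, length) for p in peak]
        m_track = occupancy_profile(m_broad, m_points, flank=2000)
        m_enr = window_enrichment_test(m_broad, m_peak, m_points)
        assert np.array_equal(track.values, m_track.values)
        assert np.array_equal(enr.table, m_enr.table)


class TestBruteForceEquivalence:
    def test_occupancy_matches_naive_scan(self, rng):
        for _ in range(25):
            n_prom = int(rng.integers(1, 10))
            proms = oracles.random_promoters(rng, n_prom, span=20_000, margin=600)
            points = oracles.random_position_set(rng, int(rng.integers(5, 60)), span=20_000)
            flank = int(rng.integers(50, 400))
            hw = int(rng.integers(0, 20))
            mode = str(rng.choice(["per_nucleosome", "per_tss"]))
            got = occupancy_profile(proms, points, flank=flank, halfwidth=hw, mode=mode)
            expect = oracles.occupancy_profile_bruteforce(proms, points, flank, hw, mode)
            assert np.array_equal(got.values, expect)
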