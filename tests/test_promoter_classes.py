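"""Architecture classification, PWM scanning, and feature annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from promnuc.core import GenomicInterval, Promoter
from promnuc.promoters import (
    Pwm,
    annotate_cpg,
    annotate_tata,
    class_feature_frequencies,
    classify_architecture,
    default_tata_pwm,
    pwm_relative_score,
    read_jaspar_counts,
    reverse_complement,
)


def make_promoter(width, strand="+", tss=5000, **kw):
    return Promoter("p", "c1", strand, tss, width=width, **kw)


class TestClassification:
    @pytest.mark.parametrize(
        "width, threshold, expected",
        [
            (4, 4, "peak"),     # the widest span still called peak
            (5, 4, "broad"),    # just past the default threshold
            (5, 10, "peak"),    # the alternative 10 bp threshold
            (1, 4, "peak"),
            (11, 10, "broad"),
        ],
    )
    def test_threshold_rule(self, width, threshold, expected):
        assert classify_architecture(make_promoter(width), threshold) == expected

    def test_undefined_width_errors(self):
        p = Promoter("p", "c1", "+", 100, tag_positions=(100,))
        p.width = None
        with pytest.raises(ValueError, match="width"):
            classify_architecture(p)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(width=st.integers(1, 80), threshold=st.integers(1, 40))
    def test_monotone_in_threshold(self, width, threshold):
        """Raising the threshold can only move promoters broad -> peak."""
        p = make_promoter(width)
        if classify_architecture(p, threshold) == "peak":
            assert classify_architecture(p, threshold + 1) == "peak"


TOY = Pwm(np.array([[2.0, 0.0, -1.0, 1.0], [0.5, 3.0, 0.0, -2.0]]))


class TestPwmScore:
    def test_consensus_scores_one_and_anticonsensus_zero(self):
        assert pwm_relative_score("AC", TOY) == pytest.approx(1.0)
        assert pwm_relative_score("GT", TOY) == pytest.approx(0.0)

    def test_all_dinucleotides_match_enumeration_oracle(self):
        smin, smax = -3.0, 5.0
        for b1 in "ACGT":
            for b2 in "ACGT":
                seq = b1 + b2
                expect = (oracles.pwm_score_window(seq, TOY.matrix) - smin) / (smax - smin)
                assert pwm_relative_score(seq, TOY) == pytest.approx(expect, rel=1e-12)

    def test_n_scores_column_mean(self):
        expect = (TOY.matrix[0].mean() + 3.0 - (-3.0)) / 8.0
        assert pwm_relative_score("NC", TOY) == pytest.approx(expect)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            pwm_relative_score("ACG", TOY)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-5, 5, allow_nan=False),
        seq=st.text(alphabet="ACGT", min_size=2, max_size=2),
    )
    def test_affine_invariance(self, scale, shift, seq):
        """A common positive rescale-and-shift of all columns leaves the
        relative score unchanged."""
        rescaled = Pwm(TOY.matrix * scale + shift)
        assert pwm_relative_score(seq, rescaled) == pytest.approx(
            pwm_relative_score(seq, TOY), rel=1e-9, abs=1e-9
        )

    def test_jaspar_counts_reader(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">M0001 TEST\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
        pwm = read_jaspar_counts(path)
        assert pwm.length == 2 and pwm.consensus == "AC"


def plant_genome(upstream_seq, tss=200, strand="+", chrom_len=500):
    """A genome whose sense-strand upstream window ends just before the TSS."""
    base = ["A"] * chrom_len
    if strand == "+":
        for i, b in enumerate(upstream_seq):
            base[tss - len(upstream_seq) + i] = b
    else:
        rc = reverse_complement(upstream_seq)
        for i, b in enumerate(rc):
            base[tss + 1 + i] = b
    return {"c1": "".join(base)}


class TestAnnotateTata:
    def test_perfect_consensus_upstream_is_positive(self):
        pwm = default_tata_pwm()
        up = "C" * (50 - 30) + pwm.consensus + "C" * (30 - pwm.length)
        genome = plant_genome(up)
        found, hit = annotate_tata(make_promoter(4, tss=200), genome, pwm)
        assert found and hit.relative_score == pytest.approx(1.0)
        assert hit.offset == -30

    def test_all_n_upstream_is_negative(self):
        genome = {"c1": "N" * 500}
        found, hit = annotate_tata(make_promoter(4, tss=200), genome)
        assert not found and hit.relative_score < 0.75

    def test_minus_strand_mirrors_plus_strand_call(self):
        pwm = default_tata_pwm()
        up = "C" * (50 - 42) + pwm.consensus + "C" * (42 - pwm.length)
        for planted_strand in ("+", "-"):
            genome = plant_genome(up, strand=planted_strand)
            prom = make_promoter(4, strand=planted_strand, tss=200)
            found, hit = annotate_tata(prom, genome, pwm)
            assert found and hit.offset == -42

    def test_window_unavailable_errors(self):
        genome = {"c1": "A" * 40}
        with pytest.raises(ValueError, match="unavailable"):
            annotate_tata(make_promoter(4, tss=30), genome)


class TestAnnotateCpg:
    def test_island_near_tss_found(self):
        islands = [GenomicInterval("c1", 4950, 4990)]  # ends 10 bp upstream
        assert annotate_cpg(make_promoter(10), islands)

    def test_island_far_upstream_not_found(self):
        islands = [GenomicInterval("c1", 4500, 4700)]  # entirely > 200 bp upstream
        assert not annotate_cpg(make_promoter(10), islands)

    def test_island_overlapping_only_tss_base(self):
        islands = [GenomicInterval("c1", 5000, 5001)]
        assert annotate_cpg(make_promoter(10), islands)

    def test_minus_strand_looks_genomically_downstream(self):
        islands = [GenomicInterval("c1", 5100, 5150)]
        assert annotate_cpg(make_promoter(10, strand="-"), islands)
        assert not annotate_cpg(make_promoter(10, strand="+"), islands)


class TestFeatureFrequencies:
    def test_small_example(self):
        proms = [
            make_promoter(10, arch_class="broad", has_cpg=True, has_tata=False),
            make_promoter(10, arch_class="broad", has_cpg=False, has_tata=False),
            make_promoter(2, arch_class="peak", has_cpg=False, has_tata=True),
            make_promoter(2, arch_class="peak", has_cpg=False, has_tata=True),
        ]
        freqs = class_feature_frequencies(proms)
        assert freqs["broad"]["cpg"] == 0.5 and freqs["peak"]["cpg"] == 0.0
        assert freqs["peak"]["tata"] == 1.0

    def test_empty_class_reports_missing(self):
        freqs = class_feature_frequencies([make_promoter(10, arch_class="broad", has_cpg=True)])
        assert freqs["peak"]["tata"] is None and freqs["peak"]["n"] == 0

    def test_matches_counting_oracle_on_random_annotation(self, rng):
        proms = []
        for i in range(100):
            cls = "broad" if rng.random() < 0.5 else "peak"
            proms.append(
                make_promoter(
                    10 if cls == "broad" else 2,
                    arch_class=cls,
                    has_tata=bool(rng.random() < 0.3),
                    has_cpg=bool(rng.random() < 0.6),
                )
            )
        freqs = class_feature_frequencies(proms)
        for cls in ("broad", "peak"):
            members = [p for p in proms if p.arch_class == cls]
            assert freqs[cls]["tata"] == sum(p.has_tata for p in members) / len(members)
            assert freqs[cls]["cpg"] == sum(p.has_cpg for p in members) / len(members)
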