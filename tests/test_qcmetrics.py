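"""Run metrics, aggregation conventions and analytic utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocap.basecount import build_basecounts
from mitocap.mtref import Region
from mitocap.qcmetrics import (
    MetricsError,
    aggregate,
    compute_run_metrics,
    copies_from_mass,
    linguistic_complexity,
    pearson,
    read_length_histogram,
    round_half_up,
)
from mitocap.readfilter import filter_reads, mark_duplicates
from tests.conftest import build_read


def _mixed_run(mt_ref):
    """10 reads: 4 mt (1 duplicate), 3 human, 3 unaligned."""
    mt = [
        build_read(name="m1", start=16100, cigar=(("M", 50),), label="mt"),
        build_read(name="m2", start=16100, cigar=(("M", 50),), label="mt"),  # dup of m1
        build_read(name="m3", start=200, cigar=(("M", 60),), label="mt"),
        build_read(name="m4", start=9000, cigar=(("M", 40),), label="mt"),
    ]
    other = [
        build_read(name=f"h{i}", aligned=False, bases="A" * 30, label="human")
        for i in range(3)
    ] + [
        build_read(name=f"u{i}", aligned=False, bases="A" * 20, label="unaligned")
        for i in range(3)
    ]
    return mt + other


class TestComputeRunMetrics:
    def test_label_percentages(self, mt_ref):
        reads = _mixed_run(mt_ref)
        report = filter_reads(reads, mt_ref)
        mark_duplicates(report.kept)
        m_all = build_basecounts(report.kept, mt_ref)
        m_unique = build_basecounts(report.kept, mt_ref, unique_only=True)
        cr = Region(16024, 576)
        m = compute_run_metrics(reads, report.kept, m_all, m_unique, mt_ref, cr)
        assert m.total_reads == 10
        assert m.pct_mt_of_total == pytest.approx(40.0)
        assert m.pct_unique_mt_of_total == pytest.approx(30.0)
        assert m.n_unique_mt == 3
        assert m.pct_human_of_total == pytest.approx(30.0)
        assert m.pct_unaligned_of_total == pytest.approx(30.0)
        # m1, m2 overlap the CR (16100..16149); m3 at 200 is inside the
        # wrapped arm; m4 at 9000 is not: 3 of 4 mt reads
        assert m.pct_cr_of_mt == pytest.approx(75.0)
        assert m.pct_mt_of_total + m.pct_human_of_total + m.pct_unaligned_of_total \
            == pytest.approx(100.0)

    def test_zero_read_run_is_all_zero(self, mt_ref):
        m_all = build_basecounts([], mt_ref)
        m = compute_run_metrics([], [], m_all, m_all, mt_ref, Region(16024, 576))
        assert m.total_reads == 0
        for field in ("pct_mt_of_total", "pct_cr_of_mt", "mean_strand_bias",
                      "cr_cov_mean", "cr_cov_max", "rl_mean", "pct_cr_cov2"):
            assert getattr(m, field) == 0

    def test_read_length_includes_soft_clips(self, mt_ref):
        reads = [build_read(start=100, cigar=(("M", 30), ("S", 20)), label="mt")]
        report = filter_reads(reads, mt_ref, ratio_min=0.5)
        m_all = build_basecounts(report.kept, mt_ref)
        m = compute_run_metrics(reads, report.kept, m_all, m_all, mt_ref,
                                Region(16024, 576))
        assert m.rl_mean == pytest.approx(50.0)

    def test_histogram_mean_matches_rl_mean(self, mt_ref):
        reads = _mixed_run(mt_ref)
        report = filter_reads(reads, mt_ref)
        m_all = build_basecounts(report.kept, mt_ref)
        m = compute_run_metrics(reads, report.kept, m_all, m_all, mt_ref,
                                Region(16024, 576))
        hist = read_length_histogram(reads)
        assert hist.mean() == pytest.approx(m.rl_mean)
        assert hist.total == len(reads)


class TestAggregate:
    def test_single_value(self):
        agg = aggregate([5.0])
        assert (agg.mean, agg.sd_sample, agg.sd_population, agg.n) == (5.0, 0, 0, 1)

    def test_both_sd_conventions_bruteforce(self):
        values = [3.0, 7.0, 8.0]
        agg = aggregate(values)
        mean = sum(values) / 3
        ss = sum((v - mean) ** 2 for v in values)
        assert agg.sd_sample == pytest.approx((ss / 2) ** 0.5)
        assert agg.sd_population == pytest.approx((ss / 3) ** 0.5)
        assert agg.sd_sample >= agg.sd_population

    def test_empty_rejected(self):
        with pytest.raises(MetricsError):
            aggregate([])

    def test_round_half_up(self):
        assert round_half_up(1.565, 2) == 1.57
        assert round_half_up(2.5, 0) == 3.0
        assert round_half_up(-2.5, 0) == -3.0


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_errors(self):
        with pytest.raises(MetricsError):
            pearson([1, 2], [1, 2])
        with pytest.raises(MetricsError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(MetricsError):
            pearson([1, 2, 3], [1, 2])

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            expected = cov / (x.std() * y.std())
            assert pearson(x, y) == pytest.approx(expected)


class TestCopiesFromMass:
    def test_zero_mass(self):
        assert copies_from_mass(0, 405) == 0

    def test_five_pg_405bp(self):
        # N = m N_A / (L M): 5e-12 g * 6.022e23 / (405 * 660) ~ 1.13e7
        assert copies_from_mass(5, 405) == pytest.approx(1.126e7, rel=1e-3)

    def test_inverse_in_length(self):
        assert copies_from_mass(5, 810) == pytest.approx(copies_from_mass(5, 405) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(MetricsError):
            copies_from_mass(-1, 405)
        with pytest.raises(MetricsError):
            copies_from_mass(5, 0)


class TestLinguisticComplexity:
    def test_homopolymer(self):
        # k=1: 1/4; k=2: 1 distinct of min(16, 3) windows
        assert linguistic_complexity("AAAA", 2) == pytest.approx(1 / 12)

    def test_all_monomers_factor_one(self):
        assert linguistic_complexity("ACGT", 1) == pytest.approx(1.0)

    def test_repeat_below_random(self):
        rng = np.random.default_rng(7)
        random_seq = "".join(rng.choice(list("ACGT"), size=60))
        repeat = "AC" * 30
        assert linguistic_complexity(repeat, 3) < linguistic_complexity(random_seq, 3)

    def test_too_short_rejected(self):
        with pytest.raises(MetricsError):
            linguistic_complexity("AC", 3)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_alphabet_bijection(self, seq):
        mapped = seq.translate(str.maketrans("ACGT", "TGCA"))
        assert linguistic_complexity(seq, 3) == pytest.approx(
            linguistic_complexity(mapped, 3)
        )


class TestReadLengthHistogram:
    def test_binning(self):
        reads = [build_read(name=f"r{i}", cigar=(("M", n),)) for i, n in
                 enumerate([70, 70, 150])]
        hist = read_length_histogram(reads)
        assert hist.bins == {70: 2, 150: 1}

    def test_empty(self):
        hist = read_length_histogram([])
        assert hist.bins == {} and hist.total == 0 and hist.mean() == 0.0
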