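"""Terminal misincorporation profiling and geometric-decay fitting."""

import numpy as np
import pytest

from mitocap.damage import (
    DamageError,
    DamageProfile,
    EndProfile,
    compare_profiles,
    fit_decay,
    misincorporation_profile,
)
from mitocap.mtref import CircularReference, Region, revcomp
from mitocap.readfilter import FORWARD, REVERSE
from mitocap.simreads import SimConfig, simulate, to_aligned_reads
from tests.conftest import build_read


def make_profile(f5_freqs, opportunities=10_000, window=None):
    window = window or len(f5_freqs)
    opp = np.full(window, opportunities, dtype=float)
    mism = np.asarray(f5_freqs, dtype=float) * opp
    zero = EndProfile(np.zeros(window), opp.copy())
    return DamageProfile(f5=EndProfile(mism, opp), f3=zero, window=window)


def _sim_reads(mt_ref, **kwargs):
    defaults = dict(
        seed=29,
        n_fragments=4000,
        background_fraction=0.0,
        off_target_fraction=1.0,
        duplication_rate=0.0,
        seq_error_rate=0.0,
    )
    defaults.update(kwargs)
    result = simulate(SimConfig(**defaults), mt_ref)
    return to_aligned_reads(result, mt_ref)


class TestMisincorporationProfile:
    def test_undamaged_reads_have_zero_frequencies(self, mt_ref):
        reads = _sim_reads(mt_ref, n_fragments=500, damage_amplitude=0.0)
        profile = misincorporation_profile(reads, mt_ref)
        assert profile.f5.mismatches.sum() == 0
        assert profile.f3.mismatches.sum() == 0
        assert profile.f5.opportunities.sum() > 0

    def test_constructed_terminal_damage_frequency_one(self):
        # every read starts on a reference C and reads T there
        ref = CircularReference(name="r", sequence="CA" * 20)
        reads = [
            build_read(name=f"r{i}", start=1, cigar=(("M", 10),),
                       bases="T" + "ACACACACA"[:9])
            for i in range(5)
        ]
        profile = misincorporation_profile(reads, ref, window=5)
        freqs = profile.f5.frequencies()
        assert freqs[0] == 1.0

    def test_reverse_strand_measures_molecule_frame(self):
        # molecule 5' end of a reverse read is the right-hand end in
        # reference orientation; its terminal reference G (complement C)
        # read as A (complement T) is 5' C->T damage
        ref = CircularReference(name="r", sequence="AAAAAAAAGG")
        read = build_read(
            name="rev", start=1, cigar=(("M", 10),), bases="AAAAAAAAGA",
            strand=REVERSE,
        )
        profile = misincorporation_profile([read], ref, window=3)
        assert profile.f5.frequencies()[0] == 1.0  # position 10: G->A => C->T in molecule frame

    def test_missing_opportunities_are_nan_not_zero(self):
        ref = CircularReference(name="r", sequence="AAAAAAAAAA")
        read = build_read(start=1, cigar=(("M", 10),), bases="A" * 10)
        profile = misincorporation_profile([read], ref, window=4)
        assert np.isnan(profile.f5.frequencies()).all()  # no reference C at all

    def test_short_reads_do_not_double_count_middle(self, mt_ref):
        reads = [r for r in _sim_reads(mt_ref, n_fragments=300, frag_len_mean=36.0,
                                       frag_len_sd=3.0, frag_len_min=30)
                 if len(r.cigar) == 1]
        profile = misincorporation_profile(reads, mt_ref, window=25)
        total_counted = profile.f5.opportunities.sum() + profile.f3.opportunities.sum()
        # each molecule position belongs to exactly one end: C opportunities
        # in the 5' half, G opportunities in the 3' half (error-free reads
        # equal the reference, so the molecule is just the oriented bases)
        expected = 0
        for r in reads:
            mol = r.bases if r.strand == FORWARD else revcomp(r.bases)
            L = len(mol)
            lim5, lim3 = min(25, (L + 1) // 2), min(25, L // 2)
            expected += mol[:lim5].count("C") + mol[L - lim3:].count("G")
        assert total_counted == expected

    def test_terminal_frequency_within_binomial_interval(self, mt_ref):
        amp, dec = 0.3, 0.5
        reads = _sim_reads(mt_ref, n_fragments=10_000, damage_amplitude=amp,
                           damage_decay=dec)
        profile = misincorporation_profile(reads, mt_ref)
        n = profile.f5.opportunities[0]
        half_width = 2.576 * np.sqrt(amp * (1 - amp) / n)
        assert abs(profile.f5.frequencies()[0] - amp) < half_width

    def test_mirror_symmetry_of_reference_leaves_profile_unchanged(self, mt_ref):
        """Molecule-frame invariance: mirroring the coordinate system
        (reverse-complemented reference, flipped strands, mirrored
        starts) describes the same physical molecules, so the damage
        profile must be identical."""
        reads = [r for r in _sim_reads(mt_ref, n_fragments=400,
                                       damage_amplitude=0.3, damage_decay=0.6)
                 if len(r.cigar) == 1]  # skip origin-spanning (clipped) reads
        mirror_ref = CircularReference(name="m", sequence=revcomp(mt_ref.sequence))
        mirrored = []
        for r in reads:
            mirrored.append(
                build_read(
                    name=r.name,
                    start=mt_ref.length - r.reference_end + 1,
                    cigar=r.cigar,
                    bases=revcomp(r.bases),
                    strand=REVERSE if r.strand == FORWARD else FORWARD,
                )
            )
        p1 = misincorporation_profile(reads, mt_ref)
        p2 = misincorporation_profile(mirrored, mirror_ref)
        assert (p1.f5.mismatches == p2.f5.mismatches).all()
        assert (p1.f5.opportunities == p2.f5.opportunities).all()
        assert (p1.f3.mismatches == p2.f3.mismatches).all()


class TestFitDecay:
    def test_exact_model_recovery(self):
        profile = make_profile([0.2 * 0.6**i for i in range(10)])
        fit = fit_decay(profile)
        assert fit.amplitude == pytest.approx(0.2, abs=1e-6)
        assert fit.decay == pytest.approx(0.6, abs=1e-6)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_profile_unidentifiable(self):
        profile = make_profile([0.0] * 10)
        fit = fit_decay(profile)
        assert fit.amplitude == 0.0
        assert not fit.identifiable

    def test_too_few_points_rejected(self):
        profile = make_profile([0.2, 0.1])
        with pytest.raises(DamageError):
            fit_decay(profile)

    def test_weighting_favours_well_observed_distances(self):
        # distance 0 has 100x the opportunities; corrupting a sparse
        # distance barely moves the fit
        freqs = [0.2 * 0.6**i for i in range(10)]
        profile = make_profile(freqs)
        profile.f5.opportunities[5] = 100.0
        profile.f5.mismatches[5] = 60.0  # corrupted: freq 0.6 instead of 0.016
        fit = fit_decay(profile)
        assert fit.amplitude == pytest.approx(0.2, abs=0.02)


class TestCompareProfiles:
    def test_identical_profiles_zero_difference(self):
        p = make_profile([0.3 * 0.5**i for i in range(8)])
        cmp = compare_profiles(p, p)
        assert np.allclose(cmp.diff5, 0.0)
        assert cmp.terminal_ratio_5p == pytest.approx(1.0)

    def test_ancient_vs_modern_terminal_difference(self, mt_ref):
        ancient = misincorporation_profile(
            _sim_reads(mt_ref, n_fragments=6000, damage_amplitude=0.3), mt_ref
        )
        modern = misincorporation_profile(
            _sim_reads(mt_ref, seed=31, n_fragments=6000, damage_amplitude=0.0),
            mt_ref,
        )
        cmp = compare_profiles(ancient, modern)
        assert cmp.diff5[0] == pytest.approx(0.3, abs=0.03)

    def test_window_mismatch_rejected(self):
        with pytest.raises(DamageError):
            compare_profiles(make_profile([0.1] * 5), make_profile([0.1] * 6))
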