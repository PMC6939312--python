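"""NCPR profiles, charged tracts, and the kappa charge-segregation
parameter."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abtscore import (
    NCPRProfile,
    charge_fractions,
    delta,
    delta_max,
    find_tracts,
    kappa,
    ncpr_profile,
    residue_charge,
    sum_filtered_areas,
)

from oracles import naive_delta, naive_delta_max, naive_kappa, naive_ncpr, naive_tracts

charged_seq = st.text(alphabet="DEKRG", min_size=6, max_size=40)


class TestResidueCharge:
    @pytest.mark.parametrize(
        "aa,q",
        [("D", -1), ("E", -1), ("K", 1), ("R", 1), ("H", 0), ("X", 0), ("U", 0), ("G", 0)],
    )
    def test_charge_assignment(self, aa, q):
        assert residue_charge(aa) == q


class TestNCPR:
    def test_homogeneous_acidic(self):
        assert ncpr_profile("DDDDD", 5).values.tolist() == [-1, -1, -1, -1, -1]

    def test_uncharged_is_zero(self):
        assert not ncpr_profile("GGGGG", 5).values.any()

    def test_diblock_decapeptide_profile(self):
        expected = [-1, -1, -1, -0.6, -0.2, 0.2, 0.6, 1, 1, 1]
        assert np.allclose(ncpr_profile("DDDDDKKKKK", 5).values, expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ncpr_profile("", 5)

    def test_matches_naive_on_random_sequences(self, rng):
        from conftest import random_sequence

        for _ in range(300):
            seq = random_sequence(rng, int(rng.integers(1, 100)))
            profile = ncpr_profile(seq, 5)
            assert np.allclose(profile.values, naive_ncpr(seq, 5))
            got = [(t.start, t.end, t.sign) for t in find_tracts(profile)]
            want = [(s, e, g) for s, e, g, _ in naive_tracts(naive_ncpr(seq, 5))]
            assert got == want


class TestTracts:
    def test_single_negative_tract(self):
        tracts = find_tracts(NCPRProfile(np.array([-1.0] * 5), 5))
        assert len(tracts) == 1 and tracts[0].sign == -1 and tracts[0].area == 5.0

    def test_zero_interrupts(self):
        tracts = find_tracts(NCPRProfile(np.array([-1.0, -1, 0, -1, -1]), 5))
        assert [(t.start, t.end) for t in tracts] == [(0, 2), (3, 5)]

    def test_sign_change_interrupts(self):
        vals = np.array([1.0, -1, 1, -1, 1, -1])
        assert len(find_tracts(NCPRProfile(vals, 5))) == 6

    def test_total_area_bounded_by_length(self, rng):
        from conftest import random_sequence

        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(1, 80)))
            profile = ncpr_profile(seq, 5)
            total = sum(t.area for t in find_tracts(profile))
            assert total <= np.abs(profile.values).sum() + 1e-9 <= len(seq) + 1e-9


class TestFilteredAreas:
    def test_diblock_decapeptide(self):
        assert sum_filtered_areas(ncpr_profile("DDDDDKKKKK", 5)) == pytest.approx(7.6)

    def test_alternating_charges_filtered_out(self):
        assert sum_filtered_areas(ncpr_profile("DKDKDKDKDK", 5)) == 0.0

    def test_uncharged(self):
        assert sum_filtered_areas(ncpr_profile("G" * 20, 5)) == 0.0

    @given(charged_seq, st.floats(0, 5), st.floats(0, 5))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_min_area(self, seq, a, b):
        lo, hi = sorted((a, b))
        profile = ncpr_profile(seq, 5)
        assert sum_filtered_areas(profile, hi) <= sum_filtered_areas(profile, lo) + 1e-12


class TestChargeFractions:
    @pytest.mark.parametrize(
        "seq,expected",
        [("DDKK", (0.5, 0.5)), ("GGGG", (0.0, 0.0)), ("DDDG", (0.0, 0.75))],
    )
    def test_fractions(self, seq, expected):
        assert charge_fractions(seq) == pytest.approx(expected)


class TestDelta:
    def test_homogeneous_sequence_is_zero(self):
        assert delta("EEEEEE", 5) == 0.0

    def test_uncharged_is_zero(self):
        assert delta("GGGGGG", 5) == 0.0

    def test_segregated_is_positive(self):
        assert delta("EEEKKK", 5) > 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            delta("EEE", 5)

    @given(charged_seq, st.sampled_from([5, 6]))
    @settings(deadline=None, max_examples=150)
    def test_matches_naive_and_bounded_by_max(self, seq, blob):
        assert delta(seq, blob) == pytest.approx(naive_delta(seq, blob), abs=1e-12)
        assert delta(seq, blob) <= delta_max(seq, blob) + 1e-12


class TestDeltaMax:
    def test_segregated_diblock_attains_max(self):
        assert delta_max("EEEKKK", 5) == pytest.approx(delta("EEEKKK", 5))

    def test_uncharged_composition_is_zero(self):
        assert delta_max("GGGGGG", 5) == 0.0

    @given(charged_seq, st.sampled_from([5, 6]))
    @settings(deadline=None, max_examples=60)
    def test_matches_naive_convention(self, seq, blob):
        assert delta_max(seq, blob) == pytest.approx(naive_delta_max(seq, blob), abs=1e-9)


class TestKappa:
    def test_fully_segregated_diblock_is_one(self):
        assert kappa("EEEEEKKKKK").value == 1.0

    def test_well_mixed_is_low(self):
        assert kappa("EKEKEKEKEK").value < 0.1

    def test_uncharged_is_undefined(self):
        result = kappa("GGGGGGGGGG")
        assert result.value is None and not result.defined

    def test_single_sign_is_undefined(self):
        # every arrangement of an all-D sequence is equivalent: delta_max = 0
        assert kappa("DDDDDDDDDD").value is None

    def test_shorter_than_both_blobs_is_undefined(self):
        assert kappa("DKDK").value is None

    @given(charged_seq)
    @settings(deadline=None, max_examples=100)
    def test_range_and_symmetries(self, seq):
        k = kappa(seq)
        if k.defined:
            assert 0.0 <= k.value <= 1.0 + 1e-12
        # reversal invariance
        kr = kappa(seq[::-1])
        assert (k.value is None) == (kr.value is None)
        if k.defined:
            assert k.value == pytest.approx(kr.value, abs=1e-9)
        # global charge swap invariance
        swapped = seq.translate(str.maketrans("DKER", "KDRE"))
        ks = kappa(swapped)
        if k.defined:
            assert k.value == pytest.approx(ks.value, abs=1e-9)

    def test_matches_naive_on_random_40mers(self, rng):
        from conftest import random_sequence

        for _ in range(20):
            seq = random_sequence(rng, 40)
            got = kappa(seq).value
            want = naive_kappa(seq)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9)
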