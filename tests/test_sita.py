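"""Natural-abundance correction, pool abundances and surrogate ratios."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaboflux import is_undefined
from metaboflux.isotopes import apply_natural_abundance
from metaboflux.sita import (
    AbundanceSummary,
    IsotopologSpectrum,
    MIDProfile,
    correct_natural_abundance,
    correction_matrix,
    labeled_abundance,
    pc_surrogate,
    pdh_surrogate,
)


class TestCorrectionMatrix:
    def test_no_natural_abundance_is_identity(self):
        C = correction_matrix(4, p13_natural=0.0, tracer_purity=1.0)
        np.testing.assert_allclose(C, np.eye(5))

    def test_single_carbon_binomial(self):
        C = correction_matrix(1, p13_natural=0.011, tracer_purity=1.0)
        np.testing.assert_allclose(C[:, 0], [0.989, 0.011])

    def test_three_carbon_m1_term(self):
        C = correction_matrix(3, p13_natural=0.011, tracer_purity=1.0)
        assert C[1, 0] == pytest.approx(3 * 0.011 * 0.989**2, rel=1e-9)

    def test_columns_sum_to_one(self):
        C = correction_matrix(6, p13_natural=0.0107, tracer_purity=0.99)
        np.testing.assert_allclose(C.sum(axis=0), 1.0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            correction_matrix(3, p13_natural=0.6)
        with pytest.raises(ValueError):
            correction_matrix(3, tracer_purity=0.0)


class TestCorrectNaturalAbundance:
    def test_pure_unlabeled_recovery(self):
        C = correction_matrix(3, 0.011, 1.0)
        spec = IsotopologSpectrum("pyruvate", 3, 500.0 * C[:, 0])
        mid = correct_natural_abundance(spec, 0.011, 1.0)
        np.testing.assert_allclose(mid.fractions, [1, 0, 0, 0], atol=1e-10)

    def test_zero_p13_is_intensity_normalization(self):
        spec = IsotopologSpectrum("citrate", 3, [10.0, 0.0, 20.0, 10.0])
        mid = correct_natural_abundance(spec, 0.0, 1.0)
        np.testing.assert_allclose(mid.fractions, [0.25, 0, 0.5, 0.25])

    def test_forward_then_correct_round_trip(self):
        mid = MIDProfile("citrate", [0.2, 0.0, 0.5, 0.3])
        spec = apply_natural_abundance(mid, 0.011, 1.0, total_intensity=800.0)
        back = correct_natural_abundance(spec, 0.011, 1.0)
        np.testing.assert_allclose(back.fractions, mid.fractions, atol=1e-6)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            IsotopologSpectrum("x", 2, [0.0, 0.0, 0.0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=6),
        raw=st.lists(st.floats(0.0, 1.0), min_size=7, max_size=7),
        p13=st.floats(0.0, 0.05),
        purity=st.floats(0.9, 1.0, exclude_min=True),
        data=st.data(),
    )
    def test_round_trip_property(self, n, raw, p13, purity, data):
        weights = np.asarray(raw[: n + 1]) + 1e-3
        mid = MIDProfile("m", weights / weights.sum())
        spec = apply_natural_abundance(mid, p13, purity, total_intensity=1000.0)
        back = correct_natural_abundance(spec, p13, purity)
        assert np.abs(back.fractions - mid.fractions).max() < 1e-6
        assert (back.fractions >= 0).all()
        assert back.fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestMIDProfile:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MIDProfile("x", [0.5, 0.4])

    def test_negative_fractions_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            MIDProfile("x", [1.2, -0.2])


class TestLabeledAbundance:
    def test_unlabeled_pool(self):
        spec = IsotopologSpectrum("fumarate", 3, [1, 0, 0, 0], protein_ug=10.0)
        ab = labeled_abundance(spec, MIDProfile("fumarate", [1, 0, 0, 0]), total_pool=100.0)
        assert ab == AbundanceSummary("fumarate", 0.0, 10.0)

    def test_split_arithmetic(self):
        spec = IsotopologSpectrum("fumarate", 3, [1, 0, 0, 0], protein_ug=10.0)
        ab = labeled_abundance(spec, MIDProfile("fumarate", [0.4, 0, 0.6, 0]), total_pool=100.0)
        assert ab.labeled_c13 == pytest.approx(6.0)
        assert ab.unlabeled_c12 == pytest.approx(4.0)

    def test_protein_normalization(self):
        mid = MIDProfile("m", [0.4, 0, 0.6, 0])
        s1 = IsotopologSpectrum("m", 3, [1, 0, 0, 0], protein_ug=10.0)
        s2 = IsotopologSpectrum("m", 3, [1, 0, 0, 0], protein_ug=20.0)
        a1, a2 = labeled_abundance(s1, mid, 100.0), labeled_abundance(s2, mid, 100.0)
        assert a2.labeled_c13 == pytest.approx(a1.labeled_c13 / 2)
        assert a2.unlabeled_c12 == pytest.approx(a1.unlabeled_c12 / 2)

    def test_nonpositive_protein_rejected(self):
        spec = IsotopologSpectrum("m", 1, [1.0, 0.0], protein_ug=-1.0)
        with pytest.raises(ValueError, match="protein_ug"):
            labeled_abundance(spec, MIDProfile("m", [1.0, 0.0]))


class TestSurrogates:
    def _mids(self, cit_m2, cit_m3, pyr_m3):
        cit = np.zeros(7)
        cit[2], cit[3] = cit_m2, cit_m3
        cit[0] = 1 - cit.sum()
        pyr = np.array([1 - pyr_m3, 0, 0, pyr_m3])
        return MIDProfile("citrate", cit), MIDProfile("pyruvate", pyr)

    def test_pdh_ratio_arithmetic(self):
        cit, pyr = self._mids(0.30, 0.0, 0.60)
        assert pdh_surrogate(cit, pyr) == pytest.approx(0.5)

    def test_pc_ratio_arithmetic(self):
        cit, pyr = self._mids(0.0, 0.15, 0.60)
        assert pc_surrogate(cit, pyr) == pytest.approx(0.25)

    def test_zero_numerator_gives_zero(self):
        cit, pyr = self._mids(0.0, 0.0, 0.5)
        assert pdh_surrogate(cit, pyr) == 0.0
        assert pc_surrogate(cit, pyr) == 0.0

    def test_zero_pyruvate_m3_is_flagged(self):
        cit, pyr = self._mids(0.3, 0.1, 0.0)
        assert is_undefined(pdh_surrogate(cit, pyr))
        assert is_undefined(pc_surrogate(cit, pyr))

    def test_ratios_invariant_under_intensity_scaling(self):
        # correcting a scaled spectrum gives the same MID, hence same ratios
        mid = MIDProfile("citrate", [0.2, 0, 0.3, 0.2, 0.1, 0.1, 0.1])
        s1 = apply_natural_abundance(mid, 0.0107, 0.99, total_intensity=100.0)
        s2 = apply_natural_abundance(mid, 0.0107, 0.99, total_intensity=7000.0)
        m1 = correct_natural_abundance(s1, 0.0107, 0.99)
        m2 = correct_natural_abundance(s2, 0.0107, 0.99)
        np.testing.assert_allclose(m1.fractions, m2.fractions, atol=1e-9)
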