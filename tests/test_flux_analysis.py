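"""Trace segmentation, protein normalization and stress-test parameters."""
import numpy as np
import pytest

from metaboflux import is_undefined
from metaboflux.flux import (
    FluxTrace,
    InjectionSchedule,
    PerConversion,
    PlateRecord,
    acute_injection_response,
    glyco_rate_params,
    glyco_stress_params,
    inhibitor_dependent_respiration,
    mito_stress_params,
    normalize_to_protein,
    segment_phases,
)

from conftest import GLYCO_EVENTS, MITO_EVENTS, RATE_EVENTS, make_trace, phase_trace


class TestNormalizeToProtein:
    @pytest.mark.parametrize(
        "values,protein,expected",
        [
            ([100, 50], 10, [10, 5]),
            ([80, 84, 76], 4, [20, 21, 19]),
            ([7, 3], 1, [7, 3]),
        ],
    )
    def test_scalar_division(self, values, protein, expected):
        out = normalize_to_protein(make_trace(values), protein)
        np.testing.assert_allclose(out.values, expected)
        assert out.unit.endswith("/ug")

    def test_nonpositive_protein_names_the_well(self):
        with pytest.raises(ValueError, match="wellX"):
            normalize_to_protein(make_trace([1.0], well="wellX"), 0.0)


class TestSegmentPhases:
    def test_even_split(self):
        sched = InjectionSchedule.from_events(
            [("a", "a", 3), ("b", "b", 6), ("c", "c", 9)]
        )
        tr = segment_phases(make_trace(np.ones(12)), sched)
        assert tr.phases == ["baseline"] * 3 + ["a"] * 3 + ["b"] * 3 + ["c"] * 3

    def test_empty_schedule_is_all_baseline(self):
        tr = segment_phases(make_trace(np.ones(5)), InjectionSchedule(()))
        assert set(tr.phases) == {"baseline"}

    def test_uneven_partition(self):
        sched = InjectionSchedule.from_events([("p1", "p1", 2), ("p2", "p2", 5)])
        tr = segment_phases(make_trace(np.ones(8)), sched)
        assert tr.phases == ["baseline"] * 2 + ["p1"] * 3 + ["p2"] * 3

    def test_injection_beyond_trace_rejected(self):
        sched = InjectionSchedule.from_events([("late", "late", 5)])
        with pytest.raises(ValueError, match="late"):
            segment_phases(make_trace(np.ones(5)), sched)

    def test_labels_partition_the_trace(self):
        sched = InjectionSchedule.from_events([("a", "a", 1), ("b", "b", 4)])
        tr = segment_phases(make_trace(np.arange(6.0)), sched)
        assert len(tr.phases) == 6 and all(p for p in tr.phases)


class TestMitoStress:
    def test_hand_evaluated_example(self):
        tr = phase_trace([100, 40, 150, 20])
        p = mito_stress_params(tr, ecar_first=10.0)
        assert p.nonmito_respiration == 20
        assert p.basal_respiration == 80
        assert p.proton_leak == 20
        assert p.atp_production == 60
        assert p.maximal_respiration == 130
        assert p.spare_respiratory_capacity_pct == pytest.approx(162.5)
        assert p.ocr_ecar_ratio == pytest.approx(10.0)
        assert p.flags == ()

    def test_flat_trace_flags_spare_capacity(self):
        p = mito_stress_params(phase_trace([20, 20, 20, 20]), ecar_first=5.0)
        assert p.basal_respiration == 0 and p.maximal_respiration == 0
        assert is_undefined(p.spare_respiratory_capacity_pct)
        assert "spare_capacity_nonpositive_basal" in p.flags

    def test_equal_basal_and_maximal_gives_100pct(self):
        p = mito_stress_params(phase_trace([100, 40, 100, 20]), ecar_first=5.0)
        assert p.spare_respiratory_capacity_pct == pytest.approx(100.0)

    def test_missing_phase_errors(self):
        tr = phase_trace([100, 40, 150], events=MITO_EVENTS[:2])
        with pytest.raises(ValueError, match="rotenone_antimycin"):
            mito_stress_params(tr, ecar_first=5.0)

    def test_atp_plus_leak_equals_basal_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            levels = rng.uniform(5, 200, size=4)
            p = mito_stress_params(phase_trace(levels), ecar_first=1.0)
            assert p.atp_production + p.proton_leak == pytest.approx(
                p.basal_respiration, rel=1e-15, abs=1e-12)


class TestGlycoStress:
    def test_hand_evaluated_example(self):
        tr = phase_trace([10, 50, 70, 12], channel="ECAR", events=GLYCO_EVENTS)
        p = glyco_stress_params(tr)
        assert p.nonglycolytic_acidification == 10
        assert p.glycolysis == 40
        assert p.glycolytic_capacity == 60
        assert p.glycolytic_reserve == 20

    def test_glucose_phase_equal_to_baseline_gives_zero_glycolysis(self):
        p = glyco_stress_params(phase_trace([10, 10, 40, 5], channel="ECAR", events=GLYCO_EVENTS))
        assert p.glycolysis == 0

    def test_negative_reserve_reported_as_is(self):
        p = glyco_stress_params(phase_trace([10, 70, 50, 5], channel="ECAR", events=GLYCO_EVENTS))
        assert p.glycolytic_reserve == pytest.approx(-20)

    def test_reserve_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            levels = rng.uniform(1, 100, size=4)
            p = glyco_stress_params(phase_trace(levels, channel="ECAR", events=GLYCO_EVENTS))
            assert p.glycolytic_reserve == pytest.approx(p.glycolytic_capacity - p.glycolysis)


class TestGlycoRate:
    def test_neutral_conversion_example(self):
        ecar = phase_trace([40, 90, 5], channel="ECAR", events=RATE_EVENTS)
        ocr = phase_trace([100, 20, 20], channel="OCR", events=RATE_EVENTS)
        p = glyco_rate_params(ocr, ecar, PerConversion.neutral())
        assert p.basal_glycolysis == 40
        assert p.compensatory_glycolysis == 90
        assert p.mito_ocr_over_glycoper == pytest.approx(2.0)
        assert p.pct_per_from_glycolysis == pytest.approx(100.0)

    def test_all_zero_ecar_flags_ratios(self):
        ecar = phase_trace([0, 0, 0], channel="ECAR", events=RATE_EVENTS)
        ocr = phase_trace([100, 20, 20], channel="OCR", events=RATE_EVENTS)
        p = glyco_rate_params(ocr, ecar, PerConversion.neutral())
        assert p.basal_glycolysis == 0 and p.compensatory_glycolysis == 0
        assert is_undefined(p.mito_ocr_over_glycoper)
        assert is_undefined(p.pct_per_from_glycolysis)

    def test_buffer_scale_doubles_rates_but_not_percentage(self):
        ecar = phase_trace([40, 90, 5], channel="ECAR", events=RATE_EVENTS)
        ocr = phase_trace([100, 20, 20], channel="OCR", events=RATE_EVENTS)
        one = glyco_rate_params(ocr, ecar, PerConversion(1.0, 1.0, 1.0, 0.0))
        two = glyco_rate_params(ocr, ecar, PerConversion(2.0, 1.0, 1.0, 0.0))
        assert two.basal_glycolysis == pytest.approx(2 * one.basal_glycolysis)
        assert two.compensatory_glycolysis == pytest.approx(2 * one.compensatory_glycolysis)
        assert two.pct_per_from_glycolysis == pytest.approx(one.pct_per_from_glycolysis)


class TestInhibitorResponse:
    def test_drop_across_injection(self):
        events = [("uk5099", "UK5099", 3)]
        tr = phase_trace([130, 70], events=events)
        tr.values[3:] = [70, 72, 70]
        assert inhibitor_dependent_respiration(tr, "uk5099") == pytest.approx(60)

    def test_no_change_gives_zero(self):
        tr = phase_trace([50, 50], events=[("etomoxir", "etomoxir", 3)])
        assert inhibitor_dependent_respiration(tr, "etomoxir") == 0

    def test_post_injection_rise_is_negative(self):
        tr = phase_trace([50, 80], events=[("uk5099", "UK5099", 3)])
        assert inhibitor_dependent_respiration(tr, "uk5099") == pytest.approx(-30)

    def test_unknown_event_lists_available(self):
        tr = phase_trace([50, 40], events=[("uk5099", "UK5099", 3)])
        with pytest.raises(ValueError, match="uk5099"):
            inhibitor_dependent_respiration(tr, "nonsense")


def _acute_plate(responses, group, event="lps"):
    """One plate with given per-well post/pre response ratios for a group."""
    traces = []
    for i, r in enumerate(responses, 1):
        tr = phase_trace([20.0, 20.0 * r], channel="ECAR", events=[(event, event, 3)],
                         well=f"{group}_w{i}", group=group)
        traces.append(tr)
    return traces


class TestAcuteResponse:
    def _plates(self, treated_resp, control_resp):
        traces = _acute_plate(treated_resp, "t") + _acute_plate(control_resp, "c")
        sched = InjectionSchedule.from_events([("lps", "LPS", 3)])
        protein = {t.well_id: 10.0 for t in traces}
        return [PlateRecord(traces, protein, sched)]

    def test_constructed_fold_change(self):
        res = acute_injection_response(self._plates([1.5, 1.5], [1.0, 1.0]), "lps", "t", "c")
        assert res.fold_change == pytest.approx(1.5)

    def test_identical_groups_give_unity(self):
        res = acute_injection_response(self._plates([1.2, 1.2], [1.2, 1.2]), "lps", "t", "c")
        assert res.fold_change == pytest.approx(1.0)

    def test_technical_wells_average_before_ratio(self):
        res = acute_injection_response(self._plates([1.4, 1.6], [1.0, 1.0]), "lps", "t", "c")
        assert res.fold_change == pytest.approx(1.5)

    def test_zero_pre_event_well_excluded_with_warning(self):
        plates = self._plates([1.5, 1.5], [1.0, 1.0])
        dead = phase_trace([0.0, 0.0], channel="ECAR", events=[("lps", "lps", 3)],
                           well="t_w3", group="t")
        plates[0].traces.append(dead)
        plates[0].protein_ug["t_w3"] = 10.0
        with pytest.warns(UserWarning, match="t_w3"):
            res = acute_injection_response(plates, "lps", "t", "c")
        assert res.fold_change == pytest.approx(1.5)
        assert res.excluded_wells == ("t_w3",)


class TestInvariances:
    """Shift/scale behavior of the derived parameters."""

    def _params(self, levels, scale=1.0, shift_min=0.0):
        tr = phase_trace(np.asarray(levels) * scale)
        tr.times = tr.times + shift_min
        return mito_stress_params(tr, ecar_first=10.0 * scale)

    def test_time_shift_invariance(self):
        base = self._params([100, 40, 150, 20])
        shifted = self._params([100, 40, 150, 20], shift_min=42.0)
        assert base == shifted

    def test_value_scaling_equivariance(self):
        base = self._params([100, 40, 150, 20])
        scaled = self._params([100, 40, 150, 20], scale=3.0)
        for name in ("nonmito_respiration", "basal_respiration", "proton_leak",
                     "atp_production", "maximal_respiration"):
            assert getattr(scaled, name) == pytest.approx(3.0 * getattr(base, name))
        # the two ratio quantities are scale-invariant
        assert scaled.spare_respiratory_capacity_pct == pytest.approx(
            base.spare_respiratory_capacity_pct)
        assert scaled.ocr_ecar_ratio == pytest.approx(base.ocr_ecar_ratio)

    def test_normalization_commutes_with_difference_parameters(self):
        tr = phase_trace([100, 40, 150, 20])
        p_then_n = mito_stress_params(tr, ecar_first=10.0)
        n_then_p = mito_stress_params(normalize_to_protein(tr, 4.0), ecar_first=10.0)
        for name in ("nonmito_respiration", "basal_respiration", "proton_leak",
                     "atp_production", "maximal_respiration"):
            assert getattr(n_then_p, name) == pytest.approx(getattr(p_then_n, name) / 4.0)
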