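import numpy as np
import pytest

from circuitseq import (DesignPrediction, Part, PartType, RpuConversion,
                        compare_predicted_observed, fit_rpu_conversion,
                        predict_profile, trace_profile)
from circuitseq.io import SENSE, CircuitAnnotation, TranscriptionProfile
from tests.conftest import REF, REF_LENGTH, build_two_gate_annotation


class TestRpuConversion:
    def test_exact_proportional_points(self):
        rpu = [0.1, 0.5, 1.0, 2.0]
        au = [2895 * x for x in rpu]
        conversion = fit_rpu_conversion(rpu, au)
        assert conversion.slope == pytest.approx(2895.0)
        assert conversion.r_squared == pytest.approx(1.0)

    def test_any_slope_recovered_with_unit_r_squared(self):
        rpu = np.array([0.2, 0.7, 1.4])
        conversion = fit_rpu_conversion(rpu, 123.4 * rpu)
        assert conversion.slope == pytest.approx(123.4)
        assert conversion.r_squared == pytest.approx(1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_rpu_conversion([1.0], [2895.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_rpu_conversion([0.0, 0.0], [0.0, 0.0])


class TestTraceProfile:
    def test_ribozyme_splits_promoter_strength(self, annotation):
        values = trace_profile(annotation, {"P1": 100.0, "P2": 0.0},
                               {"T1": 1.0, "T2": 1.0},
                               {"R1": 0.9, "R2": 0.0})
        # uncleaved fraction between the TSS and the cut site
        assert values[150] == pytest.approx(10.0)
        # full strength from the cut site onward
        assert values[500] == pytest.approx(100.0)

    def test_terminator_divides_by_strength(self, annotation):
        values = trace_profile(annotation, {"P1": 100.0, "P2": 0.0},
                               {"T1": 50.0, "T2": 1.0}, {})
        assert values[1100] == pytest.approx(100.0)
        assert values[1250] == pytest.approx(2.0)

    def test_tandem_promoters_sum_at_the_ribozyme(self):
        parts = [
            Part("Pa", PartType.PROMOTER, REF, 100, 130, "+", {"tss": 130}),
            Part("Pb", PartType.PROMOTER, REF, 140, 170, "+", {"tss": 170}),
            Part("R", PartType.RIBOZYME, REF, 170, 245, "+",
                 {"cut_site": 215}),
            Part("T", PartType.TERMINATOR, REF, 800, 860, "+"),
        ]
        annotation = CircuitAnnotation(parts, REF, 1000)
        values = trace_profile(annotation, {"Pa": 30.0, "Pb": 70.0},
                               {"T": 10.0}, {"R": 0.9})
        assert values[500] == pytest.approx(100.0)
        # before the cut only the uncleaved fractions contribute
        assert values[200] == pytest.approx(10.0)

    def test_read_through_feeds_the_next_ribozyme(self, annotation):
        values = trace_profile(annotation, {"P1": 100.0, "P2": 40.0},
                               {"T1": 50.0, "T2": 1.0},
                               {"R1": 1.0, "R2": 1.0})
        assert values[2000] == pytest.approx(40.0 + 100.0 / 50.0)

    def test_piecewise_constant_with_known_change_points(self, annotation):
        values = trace_profile(annotation, {"P1": 100.0, "P2": 40.0},
                               {"T1": 50.0, "T2": 20.0},
                               {"R1": 0.9, "R2": 0.8})
        change_points = set((np.flatnonzero(np.diff(values)) + 1).tolist())
        assert change_points <= {135, 180, 1220, 1335, 1380, 2420}

    def test_linear_in_promoter_strengths(self, annotation):
        kwargs = dict(terminator_ts={"T1": 50.0, "T2": 20.0},
                      ribozyme_pc={"R1": 0.9, "R2": 0.8})
        base = trace_profile(annotation, {"P1": 10.0, "P2": 4.0}, **kwargs)
        scaled = trace_profile(annotation, {"P1": 25.0, "P2": 10.0},
                               **kwargs)
        assert np.allclose(scaled, 2.5 * base)

    def test_promoter_without_downstream_elements_warns(self):
        parts = [Part("P", PartType.PROMOTER, REF, 100, 130, "+",
                      {"tss": 130})]
        annotation = CircuitAnnotation(parts, REF, 500)
        with pytest.warns(UserWarning, match="p_c = 0"):
            values = trace_profile(annotation, {"P": 10.0}, {}, {})
        assert values[300] == pytest.approx(10.0)


class TestPredictProfile:
    def test_rpu_states_traced_in_au(self):
        annotation = build_two_gate_annotation()
        prediction = DesignPrediction(
            promoter_rpu={"on": {"P1": 2.0, "P2": 0.0}},
            terminator_ts={"T1": 50.0, "T2": 20.0},
            ribozyme_pc={"R1": 0.9, "R2": 0.9})
        conversion = RpuConversion(slope=2895.0)
        profile = predict_profile(annotation, prediction, conversion, "on")
        assert profile.values[500] == pytest.approx(2.0 * 2895.0)

    def test_unknown_state_rejected(self):
        annotation = build_two_gate_annotation()
        prediction = DesignPrediction(promoter_rpu={"on": {}},
                                      terminator_ts={})
        with pytest.raises(ValueError, match="state"):
            predict_profile(annotation, prediction, RpuConversion(2895.0),
                            "off")


class TestComparePredictedObserved:
    GENES = [Part("G1", PartType.CDS, REF, 240, 1140, "+"),
             Part("G2", PartType.CDS, REF, 1440, 2340, "+")]

    def _profiles(self, scale):
        rng = np.random.default_rng(0)
        base = np.repeat(rng.random(60) * 1000 + 10, 100)
        predicted = TranscriptionProfile(REF, SENSE, base)
        observed = TranscriptionProfile(REF, SENSE, base * scale)
        return {"s": predicted}, {"s": observed}

    def test_identical_profiles_give_unit_slope(self):
        predicted, observed = self._profiles(1.0)
        table, summary = compare_predicted_observed(predicted, observed,
                                                    self.GENES)
        assert summary["slope"] == pytest.approx(1.0)
        assert summary["log_r_squared"] == pytest.approx(1.0)
        assert len(table) == 2

    def test_doubled_observation_doubles_slope(self):
        predicted, observed = self._profiles(2.0)
        _, summary = compare_predicted_observed(predicted, observed,
                                                self.GENES)
        assert summary["slope"] == pytest.approx(2.0)

    def test_disjoint_references_rejected(self):
        predicted, observed = self._profiles(1.0)
        observed["s"].reference_id = "other"
        with pytest.raises(ValueError, match="observed on"):
            compare_predicted_observed(predicted, observed, self.GENES)

    def test_empty_gene_list_rejected(self):
        predicted, observed = self._profiles(1.0)
        with pytest.raises(ValueError):
            compare_predicted_observed(predicted, observed, [])
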