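import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circuitseq import (GateObservation, ResponseFunction, SeriesGate,
                        SeriesSensor, eval_response_function,
                        fit_gate_response, fit_series, gate_input_flux,
                        sensor_response, split_series_activity)
from circuitseq.devices import DEFAULT_LOG_FLOOR

RF = ResponseFunction(dJ_min=1.0, dJ_max=101.0, K=10.0, n_coop=2.0)


class TestResponseFunction:
    def test_half_maximal_at_threshold(self):
        assert eval_response_function(RF, 10.0) == pytest.approx(51.0)

    def test_maximal_without_input(self):
        assert eval_response_function(RF, 0.0) == pytest.approx(101.0)

    def test_approaches_minimum_at_saturation(self):
        assert eval_response_function(RF, 1e7) == pytest.approx(1.0,
                                                                abs=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            eval_response_function(RF, -1.0)

    def test_strictly_decreasing_in_input(self):
        J = np.geomspace(1e-3, 1e4, 200)
        outputs = [eval_response_function(RF, j) for j in J]
        assert all(a > b for a, b in zip(outputs, outputs[1:]))


class TestSensorResponse:
    def test_mean_over_on_and_off_states(self):
        activities = {"a": 8.0, "b": 9.0, "c": 9.0, "d": 10.0, "e": 0.0}
        on = {"a": True, "b": True, "c": True, "d": True, "e": False}
        response = sensor_response(activities, on)
        assert response.dJ_on == pytest.approx(9.0)
        assert response.dJ_off == 0.0

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValueError):
            sensor_response({"a": 1.0}, {"a": True})


class TestGateInputFlux:
    def test_sum_with_read_through(self):
        assert gate_input_flux([5.0, 7.0], J0=0.5) == 12.5

    def test_single_input_no_read_through(self):
        assert gate_input_flux([3.2]) == 3.2

    def test_all_zero(self):
        assert gate_input_flux([0.0, 0.0]) == 0.0


class TestFitGateResponse:
    TRUTH = ResponseFunction(dJ_min=1.0, dJ_max=201.0, K=8.0, n_coop=2.4)
    J_IN = [0.1, 0.5, 4.0, 6.5, 10.0, 16.0, 60.0, 400.0]

    def _observations(self, rng=None, sigma=0.0):
        obs = []
        for i, j in enumerate(self.J_IN):
            j_real = j if rng is None else j * rng.lognormal(0, sigma)
            y = eval_response_function(self.TRUTH, j_real)
            if rng is not None:
                y *= rng.lognormal(0, sigma)
            obs.append(GateObservation(f"s{i}", j_real, y))
        return obs

    def test_noiseless_recovery_to_high_precision(self):
        fit = fit_gate_response(self._observations())
        r = fit.response
        for got, want in [(r.dJ_min, 1.0), (r.dJ_max, 201.0), (r.K, 8.0),
                          (r.n_coop, 2.4)]:
            assert abs(got - want) / want < 1e-3
        assert fit.converged and not fit.degenerate

    def test_flat_outputs_flagged_degenerate(self):
        obs = [GateObservation(f"s{i}", j, 5.0)
               for i, j in enumerate(self.J_IN)]
        fit = fit_gate_response(obs)
        assert fit.degenerate

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_gate_response(self._observations()[:3])

    def test_noisy_recovery_rate(self):
        # lognormal sigma=0.1 on realized inputs and outputs
        ok = 0
        for seq in np.random.SeedSequence(42).spawn(25):
            rng = np.random.default_rng(seq)
            fit = fit_gate_response(self._observations(rng, sigma=0.1))
            k_err = abs(fit.response.K - self.TRUTH.K) / self.TRUTH.K
            n_err = abs(fit.response.n_coop - self.TRUTH.n_coop) / \
                self.TRUTH.n_coop
            if k_err <= 0.15 and n_err <= 0.15:
                ok += 1
        assert ok >= 21   # >= ~85% on this subsample


class TestFitSeries:
    ON1 = {"00": False, "01": False, "10": True, "11": True}
    ON2 = {"00": False, "01": True, "10": False, "11": True}

    def test_two_sensor_exact_recovery(self):
        truth1 = (DEFAULT_LOG_FLOOR, 10.0)   # first sensor tight when off
        truth2 = (1.0, 100.0)
        measured = {}
        for state in self.ON1:
            a = truth1[1] if self.ON1[state] else truth1[0]
            b = truth2[1] if self.ON2[state] else truth2[0]
            measured[state] = a + b
        (s1, s2), diag = fit_series(measured,
                                    [SeriesSensor("A", self.ON1),
                                     SeriesSensor("B", self.ON2)])
        assert diag["error"] < 1e-12
        for got, want in [(s1.dJ_off, truth1[0]), (s1.dJ_on, truth1[1]),
                          (s2.dJ_off, truth2[0]), (s2.dJ_on, truth2[1])]:
            assert abs(got - want) / want < 1e-6

    def test_gate_pair_recovery_within_one_percent(self):
        g1_truth = ResponseFunction(DEFAULT_LOG_FLOOR, 201.0, 8.0, 2.4)
        g2_truth = ResponseFunction(0.5, 80.0, 15.0, 1.8)
        states = [f"s{i}" for i in range(8)]
        J1 = dict(zip(states, [0.1, 0.5, 4, 6.5, 10, 16, 60, 400]))
        J2 = dict(zip(states, [300, 50, 20, 12, 9, 5, 1, 0.2]))
        measured = {s: eval_response_function(g1_truth, J1[s])
                    + eval_response_function(g2_truth, J2[s])
                    for s in states}
        (r1, r2), diag = fit_series(measured, [SeriesGate("G1", J1),
                                               SeriesGate("G2", J2)])
        for fitted, truth in [(r1, g1_truth), (r2, g2_truth)]:
            for got, want in [(fitted.dJ_min, truth.dJ_min),
                              (fitted.dJ_max, truth.dJ_max),
                              (fitted.K, truth.K),
                              (fitted.n_coop, truth.n_coop)]:
                assert abs(got - want) / want < 0.015

    def test_confounded_sensors_rejected_by_name(self):
        with pytest.raises(ValueError, match="confounded"):
            fit_series({s: 1.0 for s in self.ON1},
                       [SeriesSensor("X", self.ON1),
                        SeriesSensor("Y", self.ON1)])

    def test_underdetermined_state_set_rejected(self):
        measured = {"00": 1.0, "11": 111.0}
        on1 = {"00": False, "11": True}
        on2 = {"00": False, "11": True}
        with pytest.raises(ValueError):
            fit_series(measured, [SeriesSensor("A", on1),
                                  SeriesSensor("B", on2)])


class TestSplitSeriesActivity:
    def test_proportional_split(self):
        assert split_series_activity(121.0, 11.0, 110.0) == \
            pytest.approx((11.0, 110.0))

    def test_zero_measurement(self):
        assert split_series_activity(0.0, 5.0, 5.0) == (0.0, 0.0)

    def test_zero_expectations_rejected(self):
        with pytest.raises(ValueError):
            split_series_activity(10.0, 0.0, 0.0)

    @given(st.floats(0, 1e6), st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conserves_the_measurement(self, total, e1, e2):
        part1, part2 = split_series_activity(total, e1, e2)
        # conserved analytically; allow one ulp of rounding in the re-sum
        assert math.isclose(part1 + part2, total, rel_tol=1e-15, abs_tol=0.0)
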