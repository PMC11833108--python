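import numpy as np
import pytest

from pdlrom import (HistoryPulse, MeasurementRecord, TestProtocol,
                    campaign_pulses, goodness_r2, history_term, peak_force,
                    rate_term, relaxation_modulus, simulate_response)
from pdlrom.protocols import _displacement_profile
from pdlrom.rom import default_dt  # noqa: F401


def naive_superposition(params, protocol, times, dt):
    """Brute-force hereditary sum: dF_i * G(t - t_i), O(n^2) oracle."""
    x = _displacement_profile(protocol, times)
    f = params.elastic_force(x)
    df = np.diff(f, prepend=0.0)
    y = np.zeros_like(times)
    for i, (ti, dfi) in enumerate(zip(times, df)):
        if dfi != 0.0:
            mask = times >= ti
            y[mask] += dfi * relaxation_modulus(params.prony, times[mask] - ti)
    return y


class TestRateTerm:
    def test_decays_with_ramp_time(self, truth):
        assert rate_term(truth, 0.2, 1e9) == pytest.approx(0.0, abs=1e-30)

    def test_worked_value(self, truth):
        # 22.9 * 0.2 * exp(-60/12.6)
        assert float(rate_term(truth, 0.2, 60.0)) == pytest.approx(0.039, abs=5e-4)

    def test_e_folding_ramp_time(self, truth):
        val = float(rate_term(truth, 0.2, truth.tau_rate))
        assert val == pytest.approx(22.9 * 0.2 / np.e, rel=1e-12)


class TestHistoryTerm:
    def test_empty_history_is_zero(self, truth):
        assert history_term(truth, (), 100.0, 5.0) == 0.0

    def test_decays_to_zero(self, truth):
        pulses = [HistoryPulse(t_ps=5.0, t_pe=600.0, d_ramp=0.1)]
        late = history_term(truth, pulses, 1260.0, 1e6)
        assert abs(late) < 1e-12

    def test_second_test_residual_is_small(self, truth, protocols):
        # one prior 0.1 mm pulse; the baseline-corrected contribution a
        # few seconds into the next test is well below the force scale
        pulses = campaign_pulses(protocols, before_test_id=2)
        assert len(pulses) == 1
        t_start = protocols[1].start_offset
        k5 = history_term(truth, pulses, t_start, 5.0)
        k0 = history_term(truth, pulses, t_start, 0.0)
        assert abs(k5 - k0) < 0.01

    def test_overlapping_pulse_rejected(self, truth):
        pulses = [HistoryPulse(t_ps=5.0, t_pe=700.0, d_ramp=0.1)]
        with pytest.raises(ValueError):
            history_term(truth, pulses, 600.0, 0.0)

    def test_pulse_order_irrelevant(self, truth):
        pulses = [HistoryPulse(5.0, 600.0, 0.1), HistoryPulse(900.0, 1500.0, 0.2)]
        fwd = history_term(truth, pulses, 2000.0, 10.0)
        rev = history_term(truth, pulses[::-1], 2000.0, 10.0)
        assert fwd == pytest.approx(rev, rel=1e-15)


class TestSimulateResponse:
    def test_hereditary_matches_bruteforce_oracle(self, truth):
        proto = TestProtocol(test_id=0, t_ramp=5.0, d_ramp=0.2,
                             t_sample=0.5, t_max=30.0)
        dt = 0.5
        times = np.arange(61) * dt
        rec = simulate_response(truth, proto, mode="hereditary", dt=dt)
        oracle = naive_superposition(truth, proto, times, dt)
        oracle += rate_term(truth, _displacement_profile(proto, times),
                            proto.t_ramp)
        np.testing.assert_allclose(
            rec.forces, np.interp(rec.times, times, oracle), rtol=1e-10)

    def test_single_step_superposition_identity(self, truth):
        # all displacement arriving in the first increment: both modes
        # reduce to F(d) * G(t) up to one grid step (rate term disabled)
        from dataclasses import replace
        params = replace(truth, p10=0.0)
        proto = TestProtocol(test_id=0, t_ramp=0.01, d_ramp=0.1,
                             t_sample=0.01, t_max=100.0)
        dt = 0.01
        her = simulate_response(params, proto, mode="hereditary", dt=dt)
        sep = simulate_response(params, proto, mode="separable", dt=dt)
        f_d = float(params.elastic_force(0.1))
        expected = f_d * relaxation_modulus(truth.prony, her.times[2:])
        np.testing.assert_allclose(her.forces[2:], expected, rtol=2e-3)
        np.testing.assert_allclose(sep.forces[2:], expected, rtol=2e-3)

    def test_starts_at_zero_even_with_history(self, truth, protocols,
                                              pulses_by_test):
        rec = simulate_response(truth, protocols[9], pulses_by_test[10])
        assert rec.forces[0] == pytest.approx(0.0, abs=1e-12)

    def test_dt_convergence(self, truth, protocols):
        proto = protocols[9]
        dt0 = proto.t_ramp / 400
        coarse = simulate_response(truth, proto, mode="hereditary", dt=dt0)
        fine = simulate_response(truth, proto, mode="hereditary", dt=dt0 / 2)
        i = int(proto.t_ramp / proto.t_sample)
        rel = abs(fine.forces[i] - coarse.forces[i]) / fine.forces[i]
        assert rel < 0.005

    def test_separable_below_hereditary_at_ramp_end(self, truth, protocols):
        # early increments relax more in the hereditary sum, so its value
        # at the end of a monotone ramp exceeds the product form
        for proto in protocols[:4]:
            her = simulate_response(truth, proto, mode="hereditary")
            sep = simulate_response(truth, proto, mode="separable")
            i = int(proto.t_ramp / proto.t_sample)
            assert sep.forces[i] <= her.forces[i] + 1e-9

    def test_peak_envelope_all_valid_tests(self, truth, protocols,
                                           pulses_by_test):
        # coarse sanity: predicted peaks within [0.5x, 2x] of recorded
        from pdlrom import recorded_peaks
        peaks = recorded_peaks()
        for proto in protocols:
            if proto.discarded:
                continue
            for mode in ("hereditary", "separable"):
                rec = simulate_response(truth, proto,
                                        pulses_by_test[proto.test_id],
                                        mode=mode)
                predicted = peak_force(rec).f_max
                measured = peaks[proto.test_id][0]
                assert 0.5 * measured <= predicted <= 2.0 * measured

    def test_bad_dt_rejected(self, truth, protocols):
        with pytest.raises(ValueError):
            simulate_response(truth, protocols[0], dt=-0.1)
        with pytest.raises(ValueError):
            simulate_response(truth, protocols[0],
                              dt=2 * protocols[0].t_sample)

    def test_unknown_mode_rejected(self, truth, protocols):
        with pytest.raises(ValueError):
            simulate_response(truth, protocols[0], mode="spectral")


class TestPeakForce:
    def test_model_peaks_at_ramp_end(self, truth, protocols):
        rec = simulate_response(truth, protocols[9], mode="hereditary")
        assert peak_force(rec).t_peak == pytest.approx(60.0, abs=0.2)

    def test_monotone_record_peaks_last(self, protocols):
        proto = protocols[0]
        times = np.arange(0, 10.0, 0.5)
        rec = MeasurementRecord(proto, times, times / 50.0, times * 0.1)
        pk = peak_force(rec)
        assert pk.t_peak == times[-1]

    def test_tie_broken_earliest(self, protocols):
        times = np.arange(0.0, 5.0)
        forces = np.array([0.0, 1.0, 1.0, 0.5, 0.2])
        rec = MeasurementRecord(protocols[0], times, times / 50.0, forces)
        assert peak_force(rec).t_peak == 1.0


class TestGoodnessR2:
    def _record(self, proto, forces):
        times = np.arange(len(forces), dtype=float)
        times[0] = 0.0
        return MeasurementRecord(proto, times, times / 100.0,
                                 np.asarray(forces, dtype=float))

    def test_perfect_prediction(self, truth, protocols):
        rec = simulate_response(truth, protocols[1])
        assert goodness_r2([rec], [rec]) == pytest.approx(1.0)

    def test_mean_prediction_zero(self, protocols):
        meas = self._record(protocols[0], [1.0, 2.0, 3.0])
        mean_pred = self._record(protocols[0], [2.0, 2.0, 2.0])
        assert goodness_r2([mean_pred], [meas]) == pytest.approx(0.0)

    def test_hand_worked_example(self, protocols):
        meas = self._record(protocols[0], [1.0, 2.0, 3.0])
        pred = self._record(protocols[0], [1.0, 2.0, 4.0])
        assert goodness_r2([pred], [meas]) == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self, protocols):
        a = self._record(protocols[0], [1.0, 2.0, 3.0])
        b = self._record(protocols[0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            goodness_r2([a], [b])
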