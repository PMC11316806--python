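"""Izhikevich afferent encoding: porting gain, derivative pathway,
integration semantics and the FSS calibration objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tactosense import (
    FAI_PARAMS,
    INITIAL_PARAMS,
    SAI_PARAMS,
    IzhikevichParams,
    SensorTraceArray,
    drive_derivative,
    fit_afferent_params,
    fss,
    port_sensor_current,
    simulate_afferent,
)
from tactosense.encoder import _predict_rates


def constant_drive(amplitude, duration_ms=1000.0, dt=0.1):
    n = int(round(duration_ms / dt)) + 1
    return np.full(n, amplitude)


class TestPortingGain:
    def test_constant_unit_current_times_sai_gain(self):
        trace = SensorTraceArray(np.ones((36, 100)), dt=0.1)
        assert np.all(port_sensor_current(trace, 55.0) == 55.0)

    def test_zero_gain_annihilates(self):
        trace = SensorTraceArray(np.random.default_rng(0).random((36, 50)), dt=0.1)
        assert np.all(port_sensor_current(trace, 0.0) == 0.0)

    def test_ramp_elementwise_against_loop_oracle(self):
        ramp = np.linspace(0.0, 2.0, 10001)
        ported = port_sensor_current(ramp, 56.0)
        oracle = np.array([56.0 * x for x in ramp])
        assert np.allclose(ported, oracle)
        assert ported[-1] == pytest.approx(112.0)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            port_sensor_current(np.ones(10), -1.0)


class TestDriveDerivative:
    def test_constant_is_zero(self):
        assert np.all(drive_derivative(np.full(100, 3.3), 0.1) == 0.0)

    def test_ramp_slope(self):
        m = 0.7  # units per ms
        drive = m * np.arange(0, 50, 0.1)
        assert np.allclose(drive_derivative(drive, 0.1), m)

    def test_sinusoid_matches_analytic_cosine(self):
        dt = 0.1
        t = np.arange(0, 200, dt)
        w = 2 * np.pi / 50.0  # 50 ms period
        deriv = drive_derivative(np.sin(w * t), dt)
        analytic = w * np.cos(w * t)
        interior = slice(1, -1)
        err = np.abs(deriv[interior] - analytic[interior]).max()
        assert err < 0.01 * np.abs(analytic).max()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            drive_derivative(np.array([1.0]), 0.1)


class TestSimulateAfferent:
    def test_zero_drive_rests_silent(self):
        train = simulate_afferent(constant_drive(0.0), SAI_PARAMS, 0.1)
        assert len(train) == 0
        assert train.duration == pytest.approx(1000.0)

    def test_reset_semantics_visible_in_trajectory(self):
        train, (v, u) = simulate_afferent(
            constant_drive(20.0, 300.0), SAI_PARAMS, 0.1, return_state=True)
        assert len(train) > 2
        idx = np.round(train.times / 0.1).astype(int)
        assert np.allclose(v[idx], 30.0)          # recorded peak
        assert np.allclose(v[idx + 1], SAI_PARAMS.c)   # next recorded v is c
        # u jumps by d at the spike sample
        jumps = u[idx] - u[idx - 1]
        assert np.all(jumps > SAI_PARAMS.d * 0.9)

    def test_spike_times_strictly_increasing_within_duration(self, rng):
        drive = np.clip(rng.normal(10.0, 5.0, 5001), 0, None)
        train = simulate_afferent(drive, SAI_PARAMS, 0.1)
        assert np.all(np.diff(train.times) > 0)
        assert train.times.size == 0 or (
            train.times[0] >= 0 and train.times[-1] <= train.duration)

    def test_fine_step_oracle_agreement(self):
        # same constant drive integrated at dt and dt/10
        drive_c = constant_drive(15.0, 1000.0, 0.1)
        coarse = simulate_afferent(drive_c, SAI_PARAMS, 0.1)
        fine = simulate_afferent(constant_drive(15.0, 1000.0, 0.01), SAI_PARAMS, 0.01)
        assert abs(len(coarse) - len(fine)) <= 1

    def test_rate_nondecreasing_in_gain(self):
        counts = []
        for K in (10.0, 25.0, 55.0, 100.0):
            drive = K * constant_drive(0.4)
            counts.append(len(simulate_afferent(drive, SAI_PARAMS, 0.1)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]

    def test_sai_sustains_fai_adapts_on_step(self):
        dt = 0.1
        n = 10001
        sensor = np.zeros(n)
        sensor[2000:] = 0.4  # step at 200 ms, held
        sai = simulate_afferent(55.0 * sensor, SAI_PARAMS, dt)
        fai = simulate_afferent(56.0 * sensor, FAI_PARAMS, dt)
        # SAI keeps firing through the hold phase
        assert np.sum(sai.times > 600.0) > 5
        # FAI answers the transient only: silent once dI/dt returns to 0
        assert len(fai) >= 1
        assert np.sum(fai.times > 600.0) == 0

    def test_nonfinite_drive_rejected(self):
        bad = constant_drive(1.0, 10.0)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            simulate_afferent(bad, SAI_PARAMS, 0.1)

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning):
            simulate_afferent(constant_drive(1.0, 50.0, 1.0), SAI_PARAMS, 1.0)


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"a": 0.0}, {"d": -1.0}, {"c": 40.0}, {"K": -5.0}, {"Cm": 0.0},
        {"unit_type": "PC"},
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            IzhikevichParams(**kw)


class TestFSS:
    def test_exact_prediction_scores_one(self):
        assert fss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_prediction_scores_zero(self):
        assert fss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        assert fss([10.0, 20.0], [12.0, 18.0]) == pytest.approx(1.0 - 8.0 / 500.0)

    def test_all_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            fss([0.0, 0.0], [1.0, 2.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    def test_never_exceeds_one(self, meas, pred):
        n = min(len(meas), len(pred))
        meas, pred = meas[:n], pred[:n]
        if not any(m != 0 for m in meas):
            return
        assert fss(meas, pred) <= 1.0 + 1e-12


class TestCalibration:
    def test_gain_recovered_within_ten_percent(self):
        stimuli = np.array([0.25, 0.35, 0.45, 0.55])
        true = SAI_PARAMS
        rates = _predict_rates(stimuli, true, dt=0.1, duration=1000.0)
        result = fit_afferent_params(list(zip(stimuli, rates)),
                                     INITIAL_PARAMS, {"K": (10.0, 150.0)})
        assert abs(result.params.K - true.K) / true.K < 0.10
        assert result.fss > 0.95

    def test_initialization_is_the_literature_set(self):
        assert (INITIAL_PARAMS.a, INITIAL_PARAMS.b, INITIAL_PARAMS.c,
                INITIAL_PARAMS.d, INITIAL_PARAMS.K) == (0.02, 0.2, -65.0, 6.0, 25.0)

    def test_returned_fit_never_below_initialization(self):
        stimuli = np.array([0.2, 0.4, 0.6])
        rates = _predict_rates(stimuli, SAI_PARAMS, dt=0.1, duration=500.0)
        result = fit_afferent_params(list(zip(stimuli, rates)),
                                     INITIAL_PARAMS, {"K": (10.0, 150.0)},
                                     duration=500.0)
        init_fss = fss(rates, _predict_rates(stimuli, INITIAL_PARAMS, 0.1, 500.0))
        assert result.fss >= init_fss

    def test_single_point_flags_underdetermined(self):
        result = fit_afferent_params([(0.4, 40.0)], INITIAL_PARAMS,
                                     {"K": (10.0, 100.0)}, duration=300.0)
        assert result.underdetermined

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            fit_afferent_params([], INITIAL_PARAMS)
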