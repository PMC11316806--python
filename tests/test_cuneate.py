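"""Cuneate layer: PSP kernel shape, convolution linearity, recruitment
arithmetic, wiring determinism, signed integration and winner-take-all."""

import numpy as np
import pytest

from tactosense import (
    SAI_PARAMS,
    CuneateLayerMap,
    PSPKernelSpec,
    afferent_to_cuneate,
    build_mapping,
    convolve_spike_train,
    generate_grasp_scenario,
    GraspScenario,
    integrate_psp,
    psp_kernel,
    psp_peak_time,
    recruited_count,
    simulate_cuneate,
    winner_take_all,
)


class TestKernel:
    def test_zero_at_origin_nonnegative_normalized(self):
        spec = PSPKernelSpec()
        k = psp_kernel(spec)
        assert k[0] == pytest.approx(0.0)
        assert np.all(k >= 0)
        assert k.max() == pytest.approx(1.0)
        assert k[-1] < 0.01  # decays toward zero at the horizon

    def test_single_interior_maximum(self):
        k = psp_kernel(PSPKernelSpec(dt=0.05))
        peaks = np.flatnonzero((k[1:-1] > k[:-2]) & (k[1:-1] >= k[2:]))
        assert peaks.size == 1

    def test_peak_time_matches_closed_form(self):
        spec = PSPKernelSpec(dt=0.05)
        k = psp_kernel(spec)
        assert abs(np.argmax(k) * spec.dt - psp_peak_time(spec)) <= spec.dt

    def test_reference_time_constants_build(self):
        spec = PSPKernelSpec.from_time_constants(4.0, 12.5)
        assert (spec.tau_fast, spec.tau_slow) == (4.0, 12.5)
        psp_kernel(spec)

    def test_inverted_time_constants_rejected(self):
        with pytest.raises(ValueError):
            PSPKernelSpec(tau_fast=12.5, tau_slow=4.0)


class TestConvolution:
    dt = 0.1

    def test_empty_train_gives_zero_series(self, make_train):
        k = psp_kernel(PSPKernelSpec(dt=self.dt))
        out = convolve_spike_train(make_train([], duration=100.0), k, self.dt)
        assert np.all(out == 0)

    def test_single_spike_translates_kernel(self, make_train):
        k = psp_kernel(PSPKernelSpec(dt=self.dt))
        t0 = 20.0
        out = convolve_spike_train(make_train([t0], duration=200.0), k, self.dt)
        i0 = int(round(t0 / self.dt))
        n = min(k.size, out.size - i0)
        assert np.allclose(out[i0:i0 + n], k[:n], atol=1e-12)
        assert np.allclose(out[:i0], 0.0, atol=1e-12)

    def test_two_spikes_shift_and_add_oracle(self, make_train):
        k = psp_kernel(PSPKernelSpec(dt=self.dt))
        times = [15.0, 22.5]
        out = convolve_spike_train(make_train(times, duration=150.0), k, self.dt)
        oracle = np.zeros_like(out)
        for t in times:
            i0 = int(round(t / self.dt))
            n = min(k.size, oracle.size - i0)
            oracle[i0:i0 + n] += k[:n]
        assert np.allclose(out, oracle, atol=1e-9)

    def test_linearity_merged_equals_sum(self, make_train):
        k = psp_kernel(PSPKernelSpec(dt=self.dt))
        a = make_train([10.0, 40.0], duration=120.0)
        b = make_train([25.0, 70.0], duration=120.0)
        merged = make_train(sorted([*a.times, *b.times]), duration=120.0)
        lhs = convolve_spike_train(merged, k, self.dt)
        rhs = (convolve_spike_train(a, k, self.dt)
               + convolve_spike_train(b, k, self.dt))
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestRecruitment:
    def test_reference_ratio(self):
        assert recruited_count(100, 1700, 300) == 567

    def test_zero_active(self):
        assert recruited_count(0) == 0

    def test_exact_ratio(self):
        assert recruited_count(300, 1700, 300) == 1700

    def test_zero_convergence_rejected(self):
        with pytest.raises(ValueError):
            recruited_count(10, 1700, 0)


class TestMapping:
    def test_small_array_connects_fully(self):
        m = build_mapping(36)
        assert m.n_cuneate == recruited_count(36)
        assert all(a.size == 36 for a in m.adjacency)

    def test_seed_determinism(self):
        a = build_mapping(500, convergence=50, seed=7)
        b = build_mapping(500, convergence=50, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.adjacency, b.adjacency))

    def test_binding_convergence_cap(self):
        m = build_mapping(36, convergence=10, n_cuneate=25, seed=3)
        for adj in m.adjacency:
            assert adj.size == 10
            assert np.unique(adj).size == 10

    def test_roundtrip_serialization(self):
        m = build_mapping(36, inhibitory_fraction=0.2, seed=11)
        m2 = CuneateLayerMap.from_dict(m.to_dict())
        assert all(np.array_equal(x, y) for x, y in zip(m.adjacency, m2.adjacency))
        assert all(np.array_equal(x, y) for x, y in zip(m.weights, m2.weights))


class TestIntegration:
    def test_single_edge_identity(self):
        psp = np.random.default_rng(0).random((1, 50))
        m = CuneateLayerMap(1700, 300, 1, 1, [np.array([0])], [np.array([1.0])])
        assert np.allclose(integrate_psp(psp, m), psp)

    def test_full_excitatory_equals_plain_sum(self):
        psp = np.random.default_rng(1).random((36, 80))
        m = build_mapping(36, seed=0)
        out = integrate_psp(psp, m)
        assert np.allclose(out, psp.sum(axis=0))

    def test_inhibitory_edge_cancels_duplicate(self):
        psp = np.vstack([np.ones((1, 30)), np.ones((1, 30))])
        m = CuneateLayerMap(1700, 300, 2, 1, [np.array([0, 1])],
                            [np.array([1.0, -1.0])])
        assert np.allclose(integrate_psp(psp, m), 0.0)


class TestWinnerTakeAll:
    def test_single_unit_wins(self):
        idx, series = winner_take_all(np.ones((1, 10)))
        assert idx == 0

    def test_tie_breaks_to_lowest_index(self):
        s = np.vstack([np.ones(20), np.ones(20)])
        assert winner_take_all(s)[0] == 0

    def test_matches_trapezoid_integral_oracle(self, rng):
        series = rng.random((50, 200))
        idx, _ = winner_take_all(series, dt=0.1)
        oracle = int(np.argmax([np.trapezoid(s, dx=0.1) for s in series]))
        assert idx == oracle

    def test_permutation_equivariance(self, rng):
        series = rng.random((10, 100)) * np.linspace(1, 2, 10)[:, None]
        perm = rng.permutation(10)
        idx, _ = winner_take_all(series)
        idx_p, _ = winner_take_all(series[perm])
        assert perm[idx_p] == idx


class TestCuneateSimulation:
    def test_zero_psp_is_silent(self):
        train = simulate_cuneate(np.zeros(5000), dt=0.1)
        assert len(train) == 0
        assert train.unit_type == "cuneate"

    def test_gain_monotonicity(self):
        psp = 8.0 * np.ones(10001)
        counts = [len(simulate_cuneate(psp, gain_cuneate=g, dt=0.1))
                  for g in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]

    def test_default_parameters_are_the_calibrated_sai_set(self):
        # the cuneate unit reuses the calibrated SAI dynamics
        train = simulate_cuneate(np.zeros(100), dt=0.1)
        assert train.unit_type == "cuneate"
        ref = SAI_PARAMS
        assert (ref.a, ref.b, ref.c, ref.d) == (0.02, 0.205, -65.0, 6.20)

    def test_firing_rate_tracks_curvature(self):
        rates = []
        for d in (50.0, 100.0):
            sc = GraspScenario(diameter_mm=d, noise_sd=0.0,
                               amplitude_jitter_sd=0.0, seed=1)
            resp = afferent_to_cuneate(generate_grasp_scenario(sc))
            rates.append(len(resp.cuneate_train))
        assert rates[0] > rates[1]
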