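"""Fast-spiking interneuron model: steady-state curves, window current
(closed-form logistic oracle), integration properties, and the
parameter-scan / best-fit machinery."""

from dataclasses import replace

import numpy as np
import pytest

from ca1lamina import pvcell as P

VGRID = np.linspace(-100.0, 20.0, 2401)


@pytest.fixture(scope="module")
def baseline():
    return P.PVModelParams()


@pytest.fixture(scope="module")
def baseline_trace(baseline):
    return P.simulate(baseline)


class TestSteadyStates:
    def test_h_inf_half_at_midpoint(self, baseline):
        _, h = P.steady_states(baseline, VGRID)
        vh = baseline.th_inf + P.TH_INF_TO_MIDPOINT_MV
        assert np.interp(vh, VGRID, h) == pytest.approx(0.5, abs=1e-3)

    def test_best_fit_shift_moves_midpoint_minus35_to_minus445(self, baseline):
        # baseline midpoint -35 mV; th_inf = -59 moves it to -44.5 mV
        _, h0 = P.steady_states(baseline, VGRID)
        assert np.interp(-35.0, VGRID, h0) == pytest.approx(0.5, abs=1e-3)
        _, h1 = P.steady_states(replace(baseline, th_inf=-59.0), VGRID)
        assert np.interp(-44.5, VGRID, h1) == pytest.approx(0.5, abs=1e-3)

    def test_activation_unchanged_by_inactivation_shift(self, baseline):
        m0, _ = P.steady_states(baseline, VGRID)
        m1, _ = P.steady_states(replace(baseline, th_inf=-59.0), VGRID)
        np.testing.assert_array_equal(m0, m1)

    def test_monotone_and_bounded(self, baseline):
        m, h = P.steady_states(baseline, VGRID)
        assert np.all(np.diff(m) > 0) and np.all(np.diff(h) < 0)
        assert m.min() >= 0 and m.max() <= 1 and h.min() >= 0 and h.max() <= 1

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            P.PVModelParams(km=0.0)


class TestWindowCurrent:
    def test_closed_form_logistic_oracle(self):
        # mirrored logistic curves sharing midpoint V0, slope k:
        # integral of min over [V0-L, V0+L] = 2*(L - k*ln(1+e^(L/k)) + k*ln 2)
        v0, k, L = -40.0, 6.0, 60.0
        v = np.linspace(v0 - L, v0 + L, 200001)
        rise = 1.0 / (1.0 + np.exp(-(v - v0) / k))
        fall = 1.0 - rise
        exact = 2.0 * (L - k * np.log(1 + np.exp(L / k)) + k * np.log(2.0))
        assert P.window_current_area(rise, fall, v) == pytest.approx(exact, abs=1e-6)

    def test_hyperpolarizing_h_shift_strictly_decreases_area(self, baseline):
        m0, h0 = P.steady_states(baseline, VGRID)
        a_prev = P.window_current_area(m0, h0, VGRID)
        for th in (-52.0, -55.0, -59.0):
            _, h = P.steady_states(replace(baseline, th_inf=th), VGRID)
            a = P.window_current_area(m0, h, VGRID)
            assert a < a_prev
            a_prev = a

    def test_common_shift_leaves_area_invariant(self, baseline):
        # shifting both curves by the same voltage only translates the
        # overlap; with a wide enough grid the area is unchanged
        wide = np.linspace(-150.0, 70.0, 8801)
        m0, h0 = P.steady_states(baseline, wide)
        m1, h1 = P.steady_states(replace(baseline, sh=10.0), wide)
        a0 = P.window_current_area(m0, h0, wide)
        a1 = P.window_current_area(m1, h1, wide)
        assert a1 == pytest.approx(a0, rel=1e-6)

    def test_best_fit_window_reduction_regression(self, baseline):
        # numeric-oracle regression value for the -35 -> -44.5 mV shift with
        # the adopted slope constants (the printed figure is slope-dependent)
        m0, h0 = P.steady_states(baseline, VGRID)
        _, h1 = P.steady_states(replace(baseline, th_inf=-59.0), VGRID)
        rel = P.relative_change(
            P.window_current_area(m0, h0, VGRID),
            P.window_current_area(m0, h1, VGRID),
        )
        assert rel == pytest.approx(0.4472, abs=0.001)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            P.window_current_area(np.zeros(10), np.zeros(11), np.zeros(10))


class TestSimulation:
    def test_zero_stimulus_rests(self, baseline):
        tr = P.simulate(replace(baseline, i_stim=0.0, stim_duration_ms=300.0))
        assert tr.spike_times_ms.size == 0
        dv = abs(tr.v_mv[-1] - tr.v_mv[-2]) / baseline.dt_ms
        assert dv < 1e-6

    def test_baseline_fires_repetitively(self, baseline_trace):
        assert baseline_trace.firing_rate_hz >= 5.0
        assert baseline_trace.spike_width_ms > 0
        assert baseline_trace.spike_amplitude_mv > 0

    def test_step_halving_convergence(self, baseline, baseline_trace):
        fine = P.simulate(replace(baseline, dt_ms=baseline.dt_ms / 2))
        assert fine.firing_rate_hz == pytest.approx(
            baseline_trace.firing_rate_hz, rel=0.01
        )
        assert fine.spike_width_ms == pytest.approx(
            baseline_trace.spike_width_ms, rel=0.01
        )
        assert fine.spike_amplitude_mv == pytest.approx(
            baseline_trace.spike_amplitude_mv, rel=0.01
        )

    def test_baseline_vs_itself_unit_triple(self, baseline_trace):
        ft = P.factor_triple(baseline_trace, baseline_trace)
        assert (ft.rate, ft.width, ft.amplitude) == (1.0, 1.0, 1.0)

    def test_determinism(self, baseline, baseline_trace):
        again = P.simulate(baseline)
        np.testing.assert_array_equal(again.v_mv, baseline_trace.v_mv)


class TestFactors:
    def test_experimental_triple_from_printed_means(self):
        ft = P.experimental_factor_triple((3.09, 0.263, 170.0), (7.46, 0.373, 367.0))
        assert round(ft.rate, 2) == 0.41
        assert round(ft.width, 2) == 0.71
        assert round(ft.amplitude, 2) == 0.46

    def test_hyperpolarizing_th_inf_reduces_all_factors(self, baseline, baseline_trace):
        tr = P.simulate(replace(baseline, th_inf=-57.0))
        ft = P.factor_triple(tr, baseline_trace)
        assert ft.rate < 1.0 and ft.width < 1.0 and ft.amplitude < 1.0

    def test_monotone_reduction_with_shift(self, baseline, baseline_trace):
        factors = []
        for th in (-53.0, -56.0, -59.0):
            tr = P.simulate(replace(baseline, th_inf=th))
            factors.append(P.factor_triple(tr, baseline_trace).as_array())
        factors = np.array(factors)
        assert np.all(np.diff(factors, axis=0) <= 0)
        assert np.all(factors[-1] < factors[0])


class TestScan:
    def test_baseline_only_grid(self, baseline):
        scan = P.parameter_scan([{"name": "baseline", "deltas": {}}],
                                baseline=baseline)
        fit = P.best_fit(scan)
        expected_loss = float(
            np.sum((np.ones(3) - P.EXPERIMENTAL_TRIPLE.as_array()) ** 2)
        )
        assert fit["loss"] == pytest.approx(expected_loss, abs=1e-9)

    def test_single_parameter_shift_beats_unperturbed(self, baseline):
        scan = P.parameter_scan(
            [{"name": "baseline", "deltas": {}},
             {"name": "th-shift", "deltas": {"th_inf": -59.0}}],
            baseline=baseline,
        )
        fit = P.best_fit(scan)
        assert fit["name"] == "th-shift"

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            P.parameter_scan([])

    def test_non_spiking_rows_reported_failed(self, baseline):
        scan = P.parameter_scan(
            [{"name": "dead", "deltas": {"g_na": 0.0}},
             {"name": "baseline", "deltas": {}}],
            baseline=baseline,
        )
        assert bool(scan.loc[scan["name"] == "dead", "failed"].iloc[0])
        fit = P.best_fit(scan)
        assert fit["name"] == "baseline"
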