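import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from bgnet.neurons import (NeuronState, b_inf, integrate_single, membrane_rhs,
                           rest_state, single_neuron_rate,
                           spike_times_from_trace, steady_state, tau_x,
                           thalamic_rhs)
from bgnet.params import gp_params, stn_params


class TestSteadyState:
    def test_midpoint_is_half(self):
        assert steady_state(-30.0, -30.0, 15.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert steady_state(1e3, -30.0, 15.0) == pytest.approx(1.0)
        assert steady_state(-1e3, -30.0, 15.0) == pytest.approx(0.0, abs=1e-12)

    def test_one_sigma_above_midpoint(self):
        assert steady_state(-29.0, -30.0, 1.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_monotone_with_slope_sign(self):
        v = np.linspace(-80, 0, 50)
        up = steady_state(v, -40.0, 8.0)
        down = steady_state(v, -40.0, -8.0)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)

    def test_rejects_zero_slope_and_nonfinite(self):
        with pytest.raises(ValueError):
            steady_state(-50.0, -40.0, 0.0)
        with pytest.raises(ValueError):
            steady_state(np.nan, -40.0, 8.0)


class TestBInf:
    def test_vanishes_at_zero(self):
        assert b_inf(0.0, 0.4, -0.1) == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_closed_form(self):
        expected = 0.5 - 1 / (1 + np.exp(-0.4 / -0.1))
        assert b_inf(0.4, 0.4, -0.1) == pytest.approx(expected)

    def test_full_activation(self):
        # r=1 with the subthalamic constants: 1/(1+e^-6) - 1/(1+e^4)
        expected = 1 / (1 + np.exp(-6.0)) - 1 / (1 + np.exp(4.0))
        assert b_inf(1.0, 0.4, -0.1) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.9796, abs=5e-4)


class TestTau:
    def test_stn_n_limits(self, stn):
        # with a negative sigmoid slope the logistic term vanishes for
        # V -> +inf (tau_n0/phi_n) and saturates for V -> -inf
        assert tau_x(1e3, stn, "n") == pytest.approx(1.0 / 0.75)
        assert tau_x(-1e3, stn, "n") == pytest.approx((1.0 + 100.0) / 0.75)

    def test_limits_bracket_midpoint(self, stn):
        lo = tau_x(-1e3, stn, "n")
        hi = tau_x(1e3, stn, "n")
        mid = tau_x(stn.theta_tau_n, stn, "n")
        assert min(lo, hi) < mid < max(lo, hi)

    def test_tha_h_closed_form(self, tha):
        v = -46.0
        a_h = 0.128 * np.exp(-(v + 46.0) / 18.0)
        b_h = 4.0 / (1.0 + np.exp(-(v + 23.0) / 5.0))
        assert tau_x(v, tha, "h") == pytest.approx(1.0 / (a_h + b_h))

    def test_gp_r_gate_is_constant(self, gp):
        # no sigmoid parameters are defined for the pallidal r gate
        assert tau_x(-80.0, gp, "r") == tau_x(0.0, gp, "r")

    def test_constant_tau_flag(self, stn):
        stn.constant_tau = True
        assert tau_x(-30.0, stn, "n") == pytest.approx(1.0 / 0.75)

    def test_unknown_gate_rejected(self, stn):
        with pytest.raises(ValueError):
            tau_x(-60.0, stn, "m")


class TestMembraneRhs:
    def test_pure_capacitor(self, stn):
        for name in ("g_leak", "g_k", "g_na", "g_t", "g_ca", "g_ahp"):
            setattr(stn, name, 0.0)
        st = rest_state(stn, -60.0)
        d = membrane_rhs(st, 0.0, 7.0, 0.0, stn)
        assert d.v == pytest.approx(7.0 / stn.capacitance)

    @pytest.mark.parametrize("maker", [stn_params, gp_params])
    def test_derivatives_vanish_at_fixed_point(self, maker):
        p = maker()

        def f(y):
            st = NeuronState(v=y[0], n=y[1], h=y[2], r=y[3], ca=y[4], s=y[5])
            d = membrane_rhs(st, 0.0, -10.0, 0.0, p)  # clamp below threshold
            return [d.v, d.n, d.h, d.r, d.ca, d.s]

        st0 = rest_state(p, -70.0)
        y0 = [float(st0.v), float(st0.n), float(st0.h), float(st0.r), 0.1, 0.0]
        root, info, ier, _ = fsolve(f, y0, full_output=True)
        assert ier == 1
        assert np.allclose(f(root), 0.0, atol=1e-7)

    def test_population_mismatch_rejected(self, tha):
        with pytest.raises(ValueError):
            membrane_rhs(rest_state(tha), 0.0, 0.0, 0.0, tha)

    def test_thalamic_requires_tha(self, stn):
        with pytest.raises(ValueError):
            thalamic_rhs(rest_state(stn), 0.0, 0.0, stn)


class TestSpikeDetection:
    def test_constant_trace_has_no_spikes(self):
        t = np.arange(0, 1000, 0.1)
        assert spike_times_from_trace(t, np.full(t.size, -60.0)).size == 0

    def test_sine_crossing_rate(self):
        t = np.arange(0, 1000, 0.1)
        v = -20.0 + 30.0 * np.sin(2 * np.pi * 10e-3 * t)  # 10 Hz, crosses -15
        assert spike_times_from_trace(t, v).size == 10


class TestFiringRates:
    """Frozen rates of the calibrated cell models (2.5 s, 500 ms transient).

    The frozen values are this implementation's measured output under the
    published integration settings; they guard against regressions in the
    kinetics, not against the original figure captions.
    """

    def test_stn_rest_and_driven(self, stn):
        assert single_neuron_rate(stn, 0.0) == pytest.approx(2.5, abs=0.5)
        assert single_neuron_rate(stn, 10.0) == pytest.approx(12.5, abs=1.0)

    def test_gp_rest_and_driven(self, gp):
        assert single_neuron_rate(gp, 0.0) == pytest.approx(33.0, abs=2.0)
        assert single_neuron_rate(gp, 5.0) == pytest.approx(59.0, abs=2.0)

    def test_stn_tuning_monotone(self, stn):
        currents = np.linspace(0, 20, 10)
        rates = [single_neuron_rate(stn, i, duration=1500) for i in currents]
        assert np.all(np.diff(rates) >= 0)

    def test_gp_tonic_branch_monotone(self, gp):
        rates = [single_neuron_rate(gp, i, duration=1500) for i in (1.0, 3.0, 5.0)]
        assert np.all(np.diff(rates) >= 0)

    def test_short_duration_rejected(self, stn):
        with pytest.raises(ValueError):
            single_neuron_rate(stn, 0.0, duration=500.0)


class TestRebound:
    def test_stn_post_inhibitory_burst(self, stn):
        # hyperpolarising pulse between 1000 and 1200 ms; compare the 200 ms
        # after release with the 200 ms before injection
        def drive(t):
            return -20.0 if 1000.0 <= t < 1200.0 else 0.0

        t, v = integrate_single(stn, i_app_fn=drive, duration=1600.0)
        spikes = spike_times_from_trace(t, v)
        before = np.count_nonzero((spikes >= 800.0) & (spikes < 1000.0))
        after = np.count_nonzero((spikes >= 1200.0) & (spikes < 1400.0))
        assert after > before


class TestTrajectoryBounds:
    @settings(max_examples=5, deadline=None)
    @given(v0=st.floats(-75.0, -45.0), i_app=st.floats(-5.0, 15.0))
    def test_gates_bounded_calcium_positive(self, v0, i_app):
        from scipy.integrate import solve_ivp
        p = stn_params()

        def rhs(t, y):
            s = NeuronState(v=y[0], n=y[1], h=y[2], r=y[3], ca=y[4], s=y[5])
            d = membrane_rhs(s, 0.0, i_app, 0.0, p)
            return [d.v, d.n, d.h, d.r, d.ca, d.s]

        st0 = rest_state(p, v0)
        y0 = [v0, float(st0.n), float(st0.h), float(st0.r), 0.1, 0.0]
        sol = solve_ivp(rhs, (0, 300), y0, method="RK23", rtol=1e-6, atol=1e-6)
        gates = sol.y[1:4]
        assert gates.min() >= -1e-6 and gates.max() <= 1 + 1e-6
        assert sol.y[4].min() >= -1e-9
        assert sol.y[5].min() >= -1e-6 and sol.y[5].max() <= 1 + 1e-6


class TestConvergence:
    def test_tolerance_halving_shifts_spikes_under_1ms(self, stn):
        t1, v1 = integrate_single(stn, i_app=10.0, duration=2000.0,
                                  rtol=1e-6, atol=1e-6)
        t2, v2 = integrate_single(stn, i_app=10.0, duration=2000.0,
                                  rtol=5e-7, atol=5e-7)
        s1 = spike_times_from_trace(t1, v1)
        s2 = spike_times_from_trace(t2, v2)
        assert s1.size == s2.size
        assert np.max(np.abs(s1 - s2)) < 1.0
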