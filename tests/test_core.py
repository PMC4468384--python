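import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obpc.core import (
    CellParams,
    NeuronState,
    SimulationDivergence,
    SynapseKernelParams,
    ahp_drive,
    ahp_step,
    check_divergence,
    conductance_kernel,
    couple_mitral_compartments,
    euler_membrane_step,
    kernel_decay_factors,
    spike_and_reset,
    synaptic_drive,
    transfer,
)

GR = CellParams(tau=5.0, beta=2.0, theta_min=-1.0, theta_max=6.0)
PYR = CellParams(tau=10.0, beta=2.0, theta_min=0.0, theta_max=15.0,
                 a_ahc=40.0, tau_ahc=100.0, e_ahc=-15.0)


class TestEulerStep:
    def test_single_step_hand_value(self):
        v = euler_membrane_step(np.array([0.0]), np.array([1.0]), tau=5.0, dt=0.5)
        assert v[0] == pytest.approx(0.1, abs=1e-15)

    def test_fixed_point(self):
        v0 = np.array([-3.0, 0.0, 7.5])
        v = euler_membrane_step(v0, v0, tau=4.0, dt=0.5)
        np.testing.assert_array_equal(v, v0)

    def test_exponential_decay_limit(self):
        tau, dt = 5.0, 0.01
        v = np.array([1.0])
        for _ in range(int(tau / dt)):
            v = euler_membrane_step(v, np.zeros(1), tau, dt)
        assert v[0] == pytest.approx(np.exp(-1), rel=2e-3)

    @pytest.mark.parametrize("dt,tau", [(0.0, 5.0), (-0.5, 5.0), (5.0, 5.0), (6.0, 5.0)])
    def test_invalid_steps(self, dt, tau):
        with pytest.raises(ValueError):
            euler_membrane_step(np.zeros(1), np.zeros(1), tau, dt)

    def test_nonfinite_input_fails(self):
        with pytest.raises(SimulationDivergence):
            euler_membrane_step(np.array([np.nan]), np.zeros(1), 5.0, 0.5)


class TestTransfer:
    def test_branch_boundaries(self):
        assert transfer(np.array([GR.theta_min]), GR)[0] == 0.0
        assert transfer(np.array([GR.theta_max]), GR)[0] == 1.0

    def test_midpoint_beta2(self):
        p = CellParams(tau=5.0, beta=2.0, theta_min=0.0, theta_max=10.0)
        assert transfer(np.array([5.0]), p)[0] == pytest.approx(0.25)

    def test_granule_resting_value(self):
        # the mechanism for nonzero spontaneous activity: output at v = 0
        assert transfer(np.array([0.0]), GR)[0] == pytest.approx((1 / 7) ** 2)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        ya, yb = transfer(np.array([lo]), GR)[0], transfer(np.array([hi]), GR)[0]
        assert 0.0 <= ya <= yb <= 1.0

    def test_continuity_at_branch_points(self):
        eps = 1e-9
        for v in (GR.theta_min, GR.theta_max):
            lo = transfer(np.array([v - eps]), GR)[0]
            hi = transfer(np.array([v + eps]), GR)[0]
            assert abs(hi - lo) < 1e-6


class TestConductanceKernel:
    K = SynapseKernelParams(g_max=1.0, e_nernst=70.0, tau1=1.0, tau2=2.0)

    def test_zero_at_spike_time(self):
        assert conductance_kernel(0.0, self.K) == pytest.approx(0.0)

    def test_peak_location(self):
        # d/dt = 0 at t = 2 ln 2 for rise 1 ms, fall 2 ms
        t = np.linspace(0, 10, 100001)
        g = conductance_kernel(t, self.K)
        assert t[np.argmax(g)] == pytest.approx(2 * np.log(2), abs=1e-3)
        assert self.K.t_peak == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_vanishes_at_infinity(self):
        assert conductance_kernel(1e4, self.K) == pytest.approx(0.0, abs=1e-300)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            conductance_kernel(-0.1, self.K)

    def test_nonnegative_with_table_labels(self):
        t = np.linspace(0, 50, 2000)
        assert np.all(conductance_kernel(t, self.K) >= 0)
        swapped = SynapseKernelParams(1.0, 70.0, tau1=2.0, tau2=1.0)
        assert np.all(conductance_kernel(t, swapped) >= 0)

    def test_finite_positive_integral(self):
        t = np.linspace(0, 100, 200001)
        integral = np.trapezoid(conductance_kernel(t, self.K), t)
        # closed form: g_max (tau_fall - tau_rise)
        assert integral == pytest.approx(1.0, rel=1e-6)

    def test_incremental_state_matches_closed_form(self):
        # the simulator tracks two decaying exponentials; they must agree
        # with the closed-form kernel at machine precision on the grid
        dt = 0.5
        d_fall, d_rise = kernel_decay_factors(self.K, dt)
        a = b = 1.0
        for step in range(1, 200):
            a *= d_fall
            b *= d_rise
            expected = conductance_kernel(step * dt, self.K)
            assert self.K.g_max * (a - b) == pytest.approx(expected, abs=1e-15)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseKernelParams(1.0, 70.0, tau1=2.0, tau2=2.0)


class TestSynapticDrive:
    def test_zero_driving_force(self):
        assert synaptic_drive(1.0, 0.3, -10.0, -10.0) == 0.0

    def test_inhibitory_sign(self):
        assert synaptic_drive(0.5, 0.2, -10.0, 0.0) < 0

    def test_hand_value(self):
        assert synaptic_drive(1.0, 0.5, 70.0, 10.0) == pytest.approx(30.0)


class TestSpikeAndReset:
    def _state(self, v):
        n = len(v)
        s = NeuronState.zeros(n)
        s.v = np.asarray(v, dtype=float)
        return s

    def test_zero_probability_never_spikes(self, rng):
        s = self._state(np.full(50, GR.theta_min - 1.0))
        for step in range(100):
            spiked = spike_and_reset(s, GR, step * 0.5, 0.5, rng)
            assert not spiked.any()

    def test_certain_spike_and_reset(self, rng):
        s = self._state([GR.theta_max + 1.0])
        spiked = spike_and_reset(s, GR, 0.0, 0.5, rng)
        assert spiked[0]
        assert s.v[0] == GR.v_hyper == -10.0

    def test_refractory_period_suppresses(self, rng):
        s = self._state([GR.theta_max + 1.0])
        spike_and_reset(s, GR, 0.0, 0.5, rng)
        s.v[0] = GR.theta_max + 1.0  # force suprathreshold again
        assert not spike_and_reset(s, GR, 1.0, 0.5, rng)[0]  # 1 ms later
        s.v[0] = GR.theta_max + 1.0
        assert spike_and_reset(s, GR, 2.0, 0.5, rng)[0]  # refractory over

    def test_missing_rng_fails(self):
        with pytest.raises(ValueError):
            spike_and_reset(self._state([0.0]), GR, 0.0, 0.5, None)

    def test_continuous_population_rejected(self):
        p = CellParams(tau=5.0, beta=1.0, theta_min=0.0, theta_max=15.0,
                       is_spiking=False)
        with pytest.raises(ValueError):
            spike_and_reset(self._state([0.0]), p, 0.0, 0.5,
                            np.random.default_rng(0))

    def test_spike_count_within_binomial_bounds(self, rng):
        # constant probability, no refractoriness: pure Bernoulli counting
        from scipy.stats import binom
        p_spike = 0.3
        p = CellParams(tau=5.0, beta=1.0, theta_min=0.0, theta_max=1.0,
                       t_refrac=0.0)
        n, steps = 200, 500
        total = 0
        s = self._state(np.full(n, p_spike))
        for step in range(steps):
            spiked = spike_and_reset(s, p, step * 0.5, 0.5, rng)
            total += int(spiked.sum())
            s.v[:] = p_spike  # undo resets
        lo, hi = binom.ppf([0.005, 0.995], n * steps, p_spike)
        assert lo <= total <= hi

    def test_refractory_caps_rate(self, rng):
        # certain firing with 2 ms refractoriness: one spike every 2 ms
        s = self._state([GR.theta_max + 1.0])
        count = 0
        for step in range(200):  # 100 ms
            spiked = spike_and_reset(s, GR, step * 0.5, 0.5, rng)
            count += int(spiked[0])
            s.v[0] = GR.theta_max + 1.0
        assert count == 50


class TestAhp:
    def test_no_spike_stays_zero(self):
        v_ahc = np.zeros(10)
        for _ in range(100):
            v_ahc = ahp_step(v_ahc, np.zeros(10), PYR, 0.5)
        np.testing.assert_array_equal(v_ahc, 0.0)

    def test_single_spike_decay(self):
        dt = 0.5
        v_ahc = ahp_step(np.zeros(1), np.ones(1), PYR, dt)
        jump = v_ahc[0]
        assert jump > 0
        for _ in range(int(PYR.tau_ahc / dt)):
            v_ahc = ahp_step(v_ahc, np.zeros(1), PYR, dt)
        assert v_ahc[0] == pytest.approx(jump * np.exp(-1), rel=5e-3)

    def test_zero_amplitude_means_zero_drive(self):
        p = PYR.with_updates(a_ahc=0.0)
        v_ahc = ahp_step(np.zeros(5), np.ones(5), p, 0.5)
        np.testing.assert_array_equal(v_ahc, 0.0)
        np.testing.assert_array_equal(ahp_drive(v_ahc, np.zeros(5), p), 0.0)

    def test_adaptation_lowers_sustained_rate(self):
        # paired seeds: identical constant drive, adaptation on vs off
        def steady_rate(p, seed):
            rng = np.random.default_rng(seed)
            n, dt = 100, 0.5
            s = NeuronState.zeros(n)
            v_ahc = np.zeros(n)
            x = np.zeros(n)
            count = 0
            for step in range(4000):  # 2 s
                drive = np.full(n, 8.0) + ahp_drive(v_ahc, s.v, p)
                s.v = s.v + (dt / p.tau) * (drive - s.v)
                spiked = spike_and_reset(s, p, step * dt, dt, rng)
                v_ahc = ahp_step(v_ahc, x, p, dt)
                x = spiked.astype(float)
                if step >= 1000:
                    count += int(spiked.sum())
            return count

        adapted = steady_rate(PYR, 7)
        free = steady_rate(PYR.with_updates(a_ahc=0.0), 7)
        assert adapted < free


class TestMitralCoupling:
    def test_equal_compartments_no_drive(self):
        np.testing.assert_array_equal(
            couple_mitral_compartments(np.ones(4), np.ones(4)), 0.0)

    def test_literal_difference(self):
        assert couple_mitral_compartments(np.array([5.0]), np.array([2.0]))[0] == 3.0

    def test_monotone_in_apical(self):
        soma = np.zeros(3)
        lo = couple_mitral_compartments(np.array([-1.0, 0.0, 1.0]), soma)
        assert np.all(np.diff(lo) > 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            couple_mitral_compartments(np.zeros(3), np.zeros(4))


class TestParamsValidation:
    def test_theta_ordering(self):
        with pytest.raises(ValueError):
            CellParams(tau=5.0, beta=1.0, theta_min=5.0, theta_max=5.0)

    def test_positive_tau(self):
        with pytest.raises(ValueError):
            CellParams(tau=0.0, beta=1.0, theta_min=0.0, theta_max=1.0)

    def test_euler_stability_with_default_taus(self, cfg):
        # dt = 0.5 ms against the smallest tau (2 ms): |1 - dt/tau| < 1
        for p in cfg.cells.values():
            assert abs(1 - cfg.dt / p.tau) < 1

    def test_divergence_guard(self):
        with pytest.raises(SimulationDivergence):
            check_divergence("X", np.array([2e3]))
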