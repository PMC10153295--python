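"""Marcus event-driven simulation, regularized dynamics, IF and diffusion."""

import numpy as np
import pytest

from aoncb import (
    DriveRealization,
    IFParams,
    MembraneParams,
    SynapticKinetics,
    build_joint,
    diffusion_reference,
    expand_and_jitter,
    integrate_and_fire,
    marcus_jump,
    psp_response,
    sample_drive,
    simulate_marcus,
    simulate_moments,
    simulate_regularized,
    small_weight_moments,
    stationary_moments,
    trace_moments,
    trains_to_drive,
)


class TestMarcusJump:
    def test_excitatory_axis_reduction(self, membrane):
        v = 3.0
        expected = v + (membrane.Ve - v) * (1 - np.exp(-0.2))
        assert marcus_jump(v, 0.2, 0.0, membrane) == pytest.approx(expected, rel=1e-14)

    def test_mixed_jump_plugin(self, membrane):
        # target (0.5*60 + 0.5*(-10))/1 = 25 mV, fraction 1 - e^{-1}
        assert marcus_jump(0.0, 0.5, 0.5, membrane) == pytest.approx(
            25 * (1 - np.exp(-1)), rel=1e-14
        )

    def test_huge_jump_saturates_at_reversal(self, membrane):
        assert marcus_jump(-5.0, 50.0, 0.0, membrane) == pytest.approx(
            membrane.Ve, abs=1e-12
        )

    def test_zero_jump_rejected(self, membrane):
        with pytest.raises(ValueError):
            marcus_jump(0.0, 0.0, 0.0, membrane)

    def test_confinement(self, membrane, rng):
        """No jump exits [Vi, Ve]."""
        for _ in range(500):
            v = rng.uniform(membrane.Vi, membrane.Ve)
            we, wi = rng.exponential(1.0, 2)
            v2 = marcus_jump(v, we, wi, membrane)
            assert membrane.Vi - 1e-12 <= v2 <= membrane.Ve + 1e-12


class TestSimulateMarcus:
    def test_empty_drive_is_pure_leak(self, membrane):
        drive = DriveRealization(
            times=np.array([]), We=np.array([]), Wi=np.array([]), T=0.1
        )
        trace = simulate_marcus(drive, membrane, v0=12.0)
        t = np.linspace(0, 0.1, 7)
        np.testing.assert_allclose(
            trace.sample(t), 12.0 * np.exp(-t / membrane.tau), rtol=1e-12
        )

    def test_single_event_two_segment_closed_form(self, membrane):
        t1, we = 0.02, 0.3
        drive = DriveRealization(
            times=np.array([t1]), We=np.array([we]), Wi=np.array([0.0]), T=0.05
        )
        trace = simulate_marcus(drive, membrane, v0=5.0)
        v_pre = 5.0 * np.exp(-t1 / membrane.tau)
        v_post = marcus_jump(v_pre, we, 0.0, membrane)
        assert trace.v_pre[0] == pytest.approx(v_pre, rel=1e-12)
        assert trace.v_post[0] == pytest.approx(v_post, rel=1e-12)
        assert trace.sample(np.array([0.04]))[0] == pytest.approx(
            v_post * np.exp(-(0.04 - t1) / membrane.tau), rel=1e-12
        )

    def test_voltage_confined_for_any_drive(self, membrane):
        joint = build_joint(20, 5, 50.0, 50.0, 0.05, 0.2, 0.2, 0.2, 0.2)
        drive = sample_drive(joint, 5.0, 77)
        trace = simulate_marcus(drive, membrane, v0=0.0)
        assert np.all(trace.v_pre >= membrane.Vi - 1e-12)
        assert np.all(trace.v_post <= membrane.Ve + 1e-12)

    def test_event_anchored_moments_match_dense_sampling(self, membrane):
        joint = build_joint(50, 10, 20.0, 20.0, 0.01, 0.04, 0.1, 0.1, 0.0)
        drive = sample_drive(joint, 20.0, 13)
        trace = simulate_marcus(drive, membrane, v0=0.0)
        mean, var = trace_moments(trace, burn_in=1.0)
        t = np.arange(1.0, 20.0, 1e-4)
        v = trace.sample(t)
        assert mean == pytest.approx(v.mean(), abs=0.02)
        assert var == pytest.approx(v.var(), rel=0.01)


class TestTraceMoments:
    def test_constant_trace(self):
        m = MembraneParams(tau=10e-3, I_over_G=4.0)
        drive = DriveRealization(
            times=np.array([]), We=np.array([]), Wi=np.array([]), T=2.0
        )
        trace = simulate_marcus(drive, m, v0=4.0)
        mean, var = trace_moments(trace, burn_in=0.0)
        assert mean == pytest.approx(4.0, abs=1e-12)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_pure_decay_exact_integral(self, membrane):
        v0, T = 10.0, 1.0
        drive = DriveRealization(
            times=np.array([]), We=np.array([]), Wi=np.array([]), T=T
        )
        trace = simulate_marcus(drive, membrane, v0=v0)
        mean, _ = trace_moments(trace, burn_in=0.0)
        tau = membrane.tau
        assert mean == pytest.approx(v0 * tau * (1 - np.exp(-T / tau)) / T, rel=1e-12)

    def test_short_horizon_rejected(self, membrane):
        drive = DriveRealization(
            times=np.array([]), We=np.array([]), Wi=np.array([]), T=0.05
        )
        trace = simulate_marcus(drive, membrane, v0=1.0)
        with pytest.raises(ValueError):
            trace_moments(trace, burn_in=0.04)


class TestRegularizedScheme:
    def test_unitary_psp_matches_closed_form(self, membrane):
        w, eps = 0.01, 0.25
        kin = SynapticKinetics.from_epsilon(eps, membrane)
        drive = DriveRealization(
            times=np.array([1e-9]), We=np.array([w]), Wi=np.array([0.0]), T=0.02
        )
        trace = simulate_regularized(drive, membrane, kin, dt=kin.tau_s / 1000)
        peak, t_peak = psp_response(w, eps, membrane)
        assert trace.v.max() == pytest.approx(peak, rel=1e-3)
        assert trace.times[np.argmax(trace.v)] == pytest.approx(t_peak, rel=0.01)
        assert peak == pytest.approx(0.528, abs=0.001)  # the ~0.5 mV calibration

    def test_variance_insensitive_to_epsilon(self, membrane):
        """Finite-tau_s variance changes by <5% between eps=1/7.5 and 1/750
        on a common drive realization."""
        joint = build_joint(100, 25, 10.0, 10.0, 0.01, 0.04, 0.03, 0.03, 0.0)
        drive = sample_drive(joint, 20.0, 55)
        out = {}
        for eps in (1 / 7.5, 1 / 750):
            kin = SynapticKinetics.from_epsilon(eps, membrane)
            trace = simulate_regularized(
                drive, membrane, kin, dt=min(kin.tau_s / 10, 2e-4)
            )
            out[eps] = trace_moments(trace, burn_in=0.5)[1]
        assert abs(out[1 / 7.5] - out[1 / 750]) / out[1 / 750] < 0.05

    def test_converges_to_marcus_on_fixture(self, membrane):
        drive = DriveRealization(
            times=np.array([0.01, 0.025, 0.04]),
            We=np.array([0.3, 0.0, 0.2]),
            Wi=np.array([0.0, 0.5, 0.1]),
            T=0.06,
        )
        exact = simulate_marcus(drive, membrane, v0=2.0)
        t = np.array([0.005, 0.02, 0.035, 0.055])
        errors = []
        for tau_s in (2e-3, 2e-4, 2e-5):
            kin = SynapticKinetics(tau_s=tau_s, epsilon=tau_s / membrane.tau)
            approx = simulate_regularized(drive, membrane, kin, dt=tau_s / 200, v0=2.0)
            errors.append(np.abs(approx.sample(t) - exact.sample(t)).max())
        # sup-norm at event-free times decays ~O(tau_s) toward the Marcus path
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 0.05

    def test_coarse_dt_rejected(self, membrane):
        kin = SynapticKinetics.from_epsilon(0.25, membrane)
        drive = DriveRealization(
            times=np.array([0.01]), We=np.array([0.01]), Wi=np.array([0.0]), T=0.1
        )
        with pytest.raises(ValueError):
            simulate_regularized(drive, membrane, kin, dt=kin.tau_s)


class TestTrainsToDrive:
    def test_single_synapse_spikes_become_events(self):
        from aoncb import SpikeTrains

        trains = SpikeTrains(
            ids=np.zeros(3, dtype=int), times=np.array([0.1, 0.4, 0.9]),
            K=1, t_start=0.0, t_stop=1.0,
        )
        drive = trains_to_drive(trains, w=0.02)
        assert drive.n_events == 3
        np.testing.assert_allclose(drive.We, 0.02)

    def test_simultaneous_spikes_merge_additively(self):
        from aoncb import SpikeTrains

        trains = SpikeTrains(
            ids=np.array([0, 1]), times=np.array([0.5, 0.5]),
            K=2, t_start=0.0, t_stop=1.0,
        )
        drive = trains_to_drive(trains, w=0.02)
        assert drive.n_events == 1
        assert drive.We[0] == pytest.approx(0.04)

    def test_roundtrip_with_zero_jitter(self):
        joint = build_joint(30, 0, 10.0, 10.0, 1e-3, 1e-3, rho_e=0.2)
        drive = sample_drive(joint, 20.0, 41)
        trains = expand_and_jitter(drive, 30, 0.0, seed=42)
        back = trains_to_drive(trains, w=1e-3)
        assert back.n_events == drive.n_events
        np.testing.assert_array_equal(back.counts_e, drive.counts_e)


class TestMonteCarloVsAnalytic:
    def test_stationary_moments_match_closed_form(self, membrane):
        """Long-run Marcus moments agree with the exact formulas (3 SE)."""
        joint = build_joint(100, 25, 10.0, 10.0, 0.01, 0.04, 0.03, 0.03, 0.0)
        exact = stationary_moments(joint, membrane)
        mc_mean, mc_var, info = simulate_moments(
            joint, membrane, 150.0, 2024, n_batches=20
        )
        batches = info["batches"]
        means = [bv / bT for bT, bv, _ in batches]
        varis = [bv2 / bT - (bv / bT) ** 2 for bT, bv, bv2 in batches]
        se_mean = np.std(means, ddof=1) / np.sqrt(len(means))
        se_var = np.std(varis, ddof=1) / np.sqrt(len(varis))
        assert abs(mc_mean - exact.mean) < 3 * se_mean
        assert abs(mc_var - exact.variance) < 3 * se_var


class TestIntegrateAndFire:
    def test_threshold_above_reversal_never_spikes(self, membrane):
        joint = build_joint(50, 0, 20.0, 20.0, 0.05, 0.05, rho_e=0.1)
        drive = sample_drive(joint, 5.0, 3)
        _, spikes = integrate_and_fire(
            drive, membrane, IFParams(VT=membrane.Ve + 1.0, VR=0.0)
        )
        assert spikes.size == 0

    def test_single_huge_jump_spikes_once_and_resets(self, membrane):
        drive = DriveRealization(
            times=np.array([0.01]), We=np.array([10.0]), Wi=np.array([0.0]), T=0.05
        )
        trace, spikes = integrate_and_fire(drive, membrane, IFParams(VT=15.0, VR=12.0))
        assert spikes.size == 1
        assert spikes[0] == pytest.approx(0.01)
        assert trace.v_post[0] == 12.0

    def test_synchronous_drive_firing_stable_across_seeds(self, membrane):
        """Threshold-crossing rate exists and has CV < 0.2 over 10 seeds for
        a dense synchronous E/I drive."""
        joint = build_joint(1000, 350, 25.0, 25.0, 0.001, 0.004, 0.03, 0.03, 0.0)
        f = IFParams(VT=15.0, VR=12.0)
        rates = []
        for s in range(10):
            drive = sample_drive(joint, 8.0, 1000 + s)
            _, spikes = integrate_and_fire(drive, membrane, f)
            rates.append(spikes[spikes > 0.5].size / 7.5)
        rates = np.array(rates)
        assert np.all(rates > 0)
        assert rates.std(ddof=1) / rates.mean() < 0.2


class TestDiffusionReference:
    def test_ou_calibrated_to_small_weight_moments(self, membrane):
        Ke, Ki, re, ri, we, wi = 1000, 250, 20.0, 20.0, 0.001, 0.004
        mom = small_weight_moments(Ke, Ki, re, ri, we, wi, 0.0, 0.0, 0.0, membrane)
        trace, _ = diffusion_reference(
            Ke, Ki, re, ri, we, wi, membrane, dt=2e-4, T=60.0, seed=8
        )
        mean, var = trace_moments(trace, burn_in=0.5)
        tau_eff = 1.0 / (1 / membrane.tau + Ke * re * we + Ki * ri * wi)
        n_eff = 59.5 / (2 * tau_eff)
        assert abs(mean - mom.mean) < 3 * np.sqrt(mom.variance / n_eff)
        assert abs(var - mom.variance) < 3 * mom.variance * np.sqrt(2 / n_eff)

    def test_if_rate_agrees_with_marcus_within_20_percent(self, membrane):
        """Diffusion comparator reproduces the AONCB threshold-crossing rate
        for the dense synchronous parameter set."""
        Ke, Ki, re, ri, we, wi = 1000, 350, 25.0, 25.0, 0.001, 0.004
        f = IFParams(VT=15.0, VR=12.0)
        joint = build_joint(Ke, Ki, re, ri, we, wi, 0.03, 0.03, 0.0)
        n_m = n_d = 0.0
        T = 12.0
        for s in range(6):
            drive = sample_drive(joint, T, 300 + s)
            _, spk = integrate_and_fire(drive, membrane, f)
            n_m += spk[spk > 0.5].size
            _, spk_d = diffusion_reference(
                Ke, Ki, re, ri, we, wi, membrane, dt=1e-4, T=T, seed=600 + s,
                rho_e=0.03, rho_i=0.03, f=f,
            )
            n_d += spk_d[spk_d > 0.5].size
        rate_m = n_m / (6 * (T - 0.5))
        rate_d = n_d / (6 * (T - 0.5))
        assert abs(rate_d - rate_m) / rate_m < 0.2
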