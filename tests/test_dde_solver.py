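import numpy as np
import pytest

from delaywta.dde_solver import (
    NegativeRateWarning,
    SolverDivergence,
    Trajectory,
    integrate_dde,
    integrate_sdde,
)
from delaywta.model_core import (
    ADDITIVE_INPUT,
    CLAMPED_HISTORY,
    ModelParams,
    StimulusProtocol,
    hill,
    resting_fixed_point,
)


def dense_euler_oracle(params, stim, dt):
    """Naive dense-history Euler integration, independent of the solver.

    Delays must be integer multiples of dt; clamped-history stimulation only.
    """
    base = params.I_1
    n = int(round(params.T / dt))
    d1 = int(round(params.tau_1 / dt))
    d2 = int(round(params.tau_2 / dt))
    assert abs(params.tau_1 - d1 * dt) < 1e-12 and abs(params.tau_2 - d2 * dt) < 1e-12
    r1 = np.empty(n + 1)
    r2 = np.empty(n + 1)
    k0 = int(round(stim.t_off / dt))
    r1[: k0 + 1] = base + stim.sigma
    r2[: k0 + 1] = base
    for k in range(k0, n):
        rd1 = r1[k - d1] if k >= d1 else base
        rd2 = r2[k - d2] if k >= d2 else base
        w = hill(r1[k] * r2[k])
        r1[k + 1] = r1[k] + dt * (-rd1 + w * r2[k] + params.I_1) / params.tau_r
        r2[k + 1] = r2[k] + dt * (-rd2 + w * r1[k] + params.I_2) / params.tau_r
    return np.arange(n + 1) * dt, r1, r2


class TestDeterministic:
    def test_fixed_point_history_stays_put(self):
        r_star, _ = resting_fixed_point(0.4)
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        traj = integrate_dde(p, StimulusProtocol(sigma=0.0), base_value=r_star)
        assert np.max(np.abs(traj.r1 - r_star)) < 1e-6
        assert np.max(np.abs(traj.r2 - r_star)) < 1e-6

    def test_resting_symmetry_exact(self, traj_rest):
        assert np.array_equal(traj_rest.r1, traj_rest.r2)

    def test_fig3b_evidence_dominance(self, traj_fig3b):
        # the *accumulated* evidence never switches subcritically (the raw
        # rates may still cross during the damped post-stimulus transient)
        x = np.cumsum((traj_fig3b.r1 - traj_fig3b.r2)[:-1] + (traj_fig3b.r1 - traj_fig3b.r2)[1:])
        post = traj_fig3b.t[1:] > 0.5
        assert np.all(x[post] > 0)

    def test_fig3c_oscillatory_difference(self, traj_fig3c):
        post = traj_fig3c.t > 0.5
        diff = (traj_fig3c.r1 - traj_fig3c.r2)[post]
        assert np.any(diff > 0) and np.any(diff < 0)

    def test_weights_are_quasi_steady(self, traj_fig3b):
        w = hill(traj_fig3b.r1 * traj_fig3b.r2)
        assert np.array_equal(traj_fig3b.w1, w)
        assert np.array_equal(traj_fig3b.w2, w)

    def test_clamp_window_values_fixed(self, traj_fig3b):
        inwin = traj_fig3b.t <= 0.5
        assert np.all(traj_fig3b.r1[inwin] == 0.4 + 0.3)
        assert np.all(traj_fig3b.r2[inwin] == 0.4)

    def test_sigma_zero_modes_identical(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        a = integrate_dde(p, StimulusProtocol(sigma=0.0, mode=CLAMPED_HISTORY))
        b = integrate_dde(p, StimulusProtocol(sigma=0.0, mode=ADDITIVE_INPUT))
        assert np.array_equal(a.r1, b.r1) and np.array_equal(a.r2, b.r2)

    def test_continuity_no_large_jumps(self, traj_fig3c):
        dt = traj_fig3c.dt
        assert np.max(np.abs(np.diff(traj_fig3c.r1))) < 10.0 * dt
        assert np.max(np.abs(np.diff(traj_fig3c.r2))) < 10.0 * dt

    def test_convergence_order(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3)
        sols = {
            dt: integrate_dde(p, stim, dt=dt) for dt in (4e-3, 2e-3, 1e-3)
        }
        # compare on the shared coarse grid
        coarse = sols[4e-3]
        e1 = np.max(np.abs(coarse.r1 - sols[2e-3].r1[::2]))
        e2 = np.max(np.abs(sols[2e-3].r1[::2] - sols[1e-3].r1[::4]))
        assert e1 / e2 >= 1.9  # at least first order across delay discontinuities

    def test_against_dense_euler_oracle(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3)
        traj = integrate_dde(p, stim, dt=1e-3)
        t_o, r1_o, r2_o = dense_euler_oracle(p, stim, dt=1e-4)
        assert np.max(np.abs(traj.r1 - r1_o[::10])) < 1e-3
        assert np.max(np.abs(traj.r2 - r2_o[::10])) < 1e-3

    def test_negative_rate_warning(self):
        # a low background input lets the delayed inhibition overshoot zero
        p = ModelParams(tau_1=1.7, tau_2=1.7, I_1=0.05, I_2=0.05)
        with pytest.warns(NegativeRateWarning):
            traj = integrate_dde(p, StimulusProtocol(sigma=0.3), base_value=0.05)
        assert traj.meta["negative_rates"] is True

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            integrate_dde(ModelParams(), StimulusProtocol(), dt=0.0)

    def test_horizon_must_cover_stimulus(self):
        with pytest.raises(ValueError):
            integrate_dde(
                ModelParams(T=0.3), StimulusProtocol(sigma=0.3, t_max=0.5)
            )

    def test_zero_delay_reduces_to_ode(self):
        # with tau = 0 the resting dynamics relax monotonically to r*
        p = ModelParams(tau_1=0.0, tau_2=0.0, T=20.0)
        traj = integrate_dde(p, StimulusProtocol(sigma=0.0))
        r_star, _ = resting_fixed_point(0.4)
        assert abs(traj.r1[-1] - r_star) < 1e-6


class TestStochastic:
    def test_zero_noise_equals_euler_bitwise(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3, mode=ADDITIVE_INPUT)
        sd = integrate_sdde(p, stim, b=0.0, dt=1e-2, seed=7)
        det = integrate_dde(p, stim, dt=1e-2, method="euler")
        assert np.array_equal(sd.r1, det.r1)
        assert np.array_equal(sd.r2, det.r2)

    def test_same_seed_identical(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3, mode=ADDITIVE_INPUT)
        a = integrate_sdde(p, stim, b=0.1, dt=1e-2, seed=42)
        b = integrate_sdde(p, stim, b=0.1, dt=1e-2, seed=42)
        assert np.array_equal(a.r1, b.r1) and np.array_equal(a.r2, b.r2)

    def test_monte_carlo_mean_matches_deterministic(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3, mode=ADDITIVE_INPUT)
        det = integrate_dde(p, stim, dt=1e-2, method="euler")
        n_runs = 200
        acc = np.zeros((n_runs, len(det.t)))
        for i in range(n_runs):
            acc[i] = integrate_sdde(p, stim, b=0.1, dt=1e-2, seed=100 + i).r1
        mean = acc.mean(axis=0)
        se = acc.std(axis=0, ddof=1) / np.sqrt(n_runs)
        # checked away from t=0 where se vanishes
        late = det.t > 1.0
        assert np.all(np.abs(mean - det.r1)[late] < 3.5 * se[late])

    def test_clamped_with_noise_rejected(self):
        with pytest.raises(ValueError):
            integrate_sdde(
                ModelParams(), StimulusProtocol(sigma=0.3, mode=CLAMPED_HISTORY), b=0.5
            )

    def test_divergence_signalled(self):
        p = ModelParams(tau_1=1.4, tau_2=1.4)
        stim = StimulusProtocol(sigma=0.3, mode=ADDITIVE_INPUT)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(SolverDivergence):
                integrate_sdde(p, stim, b=1e200, dt=1e-2, seed=0)


class TestTrajectoryIO:
    def test_csv_roundtrip_lossless(self, tmp_path, traj_fig3b):
        path = tmp_path / "traj.csv"
        traj_fig3b.to_csv(path)
        back = Trajectory.from_csv(path)
        for attr in ("t", "r1", "r2", "w1", "w2"):
            a = getattr(traj_fig3b, attr)
            b = getattr(back, attr)
            assert np.allclose(a, b, rtol=1e-15, atol=0.0)
        assert back.meta["mode"] == traj_fig3b.meta["mode"]
        assert back.meta["dt"] == traj_fig3b.meta["dt"]

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(
                t=np.arange(3.0),
                r1=np.arange(2.0),
                r2=np.arange(3.0),
                w1=np.arange(3.0),
                w2=np.arange(3.0),
            )
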