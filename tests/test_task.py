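import numpy as np
import pytest
from scipy.integrate import quad

from latentnav.behavior import response_regression
from latentnav.task import (
    ControllerParams,
    TaskConfig,
    Trial,
    apply_perturbation,
    exclude_disengaged,
    integrate_unicycle,
    sample_target,
    simulate_trial,
    simulate_trials,
)


class TestSampleTarget:
    def test_within_ranges(self, task_config, rng):
        t = sample_target(task_config, rng, n=10_000)
        assert np.all((t[:, 0] >= 0.7) & (t[:, 0] <= 4.0))
        assert np.all(np.abs(t[:, 1]) <= 40.0)

    def test_deterministic(self, task_config):
        a = sample_target(task_config, np.random.default_rng(7), n=100)
        b = sample_target(task_config, np.random.default_rng(7), n=100)
        np.testing.assert_array_equal(a, b)

    def test_area_uniform_radial_cdf(self, task_config, rng):
        # area-uniform sampling: P(r <= c) = (c^2 - r0^2)/(r1^2 - r0^2)
        t = sample_target(task_config, rng, n=40_000)
        frac = np.mean(t[:, 0] <= 2.875)
        expected = (2.875**2 - 0.7**2) / (4.0**2 - 0.7**2)
        assert expected == pytest.approx(0.5, abs=0.01)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_polar_uniform_alternative(self, rng):
        cfg = TaskConfig(area_uniform_targets=False)
        t = sample_target(cfg, rng, n=40_000)
        assert np.mean(t[:, 0] <= 2.35) == pytest.approx(0.5, abs=0.01)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(target_r_range=(4.0, 0.7))


class TestPerturbation:
    def test_peak_additivity_and_identity(self, task_config):
        v = np.zeros(3000)
        w = np.ones(3000)
        v2, w2 = apply_perturbation(v, w, 1.5, -60.0, 0.5, task_config)
        t = np.arange(3000) * task_config.dt
        center = np.argmin(np.abs(t - 1.0))  # pulse peaks at onset + 0.5 s
        assert v2[center] == pytest.approx(1.5, rel=1e-3)
        assert np.min(w2 - w) == pytest.approx(-60.0, rel=1e-3)
        v3, w3 = apply_perturbation(v, w, 0.0, 0.0, 0.5, task_config)
        np.testing.assert_array_equal(v3, v)
        np.testing.assert_array_equal(w3, w)

    def test_pulse_integral_matches_quadrature(self, task_config):
        amp, sigma = 1.2, 0.2
        v = np.zeros(5000)
        v2, _ = apply_perturbation(v, v, amp, 0.0, 1.0, task_config)
        num = np.sum(v2) * task_config.dt
        # oracle: quadrature of the truncated Gaussian profile over its 1 s support
        oracle, _ = quad(lambda t: amp * np.exp(-0.5 * ((t - 1.5) / sigma) ** 2),
                         1.0, 2.0)
        assert num == pytest.approx(oracle, rel=1e-3)

    def test_amplitude_bounds(self, task_config):
        v = np.zeros(100)
        with pytest.raises(ValueError):
            apply_perturbation(v, v, 2.5, 0.0, 0.5, task_config)
        with pytest.raises(ValueError):
            apply_perturbation(v, v, 0.0, 150.0, 0.5, task_config)


class TestTrialDynamics:
    def test_position_is_velocity_integral(self, task_config, noiseless_ctrl, rng):
        tr = simulate_trial(task_config, noiseless_ctrl, np.array([3.0, 25.0]), rng)
        # midpoint-rule oracle on the recorded velocities
        dt = 1.0 / tr.sample_rate
        h = np.deg2rad(tr.heading)
        hm = 0.5 * (h[:-1] + h[1:])
        vm = tr.linear_velocity[:-1]
        x = np.concatenate([[0], np.cumsum(vm * np.sin(hm)) * dt])
        y = np.concatenate([[0], np.cumsum(vm * np.cos(hm)) * dt])
        err = np.hypot(tr.position[:, 0] - x, tr.position[:, 1] - y)
        assert err.max() < 5e-3  # forward Euler vs midpoint at 1.2 ms steps

    def test_noiseless_straight_target_rewarded(self, task_config, noiseless_ctrl):
        tr = simulate_trial(task_config, noiseless_ctrl, np.array([2.0, 0.0]),
                            np.random.default_rng(0))
        assert tr.rewarded
        assert tr.stop_error < 0.6

    def test_zero_gain_controller_times_out(self, task_config):
        ctrl = ControllerParams(gain_linear=0.0, gain_angular=0.0,
                                motor_noise_sd=0.0, sensory_noise_sd=0.0,
                                sensory_noise_sd_ang=0.0)
        tr = simulate_trial(task_config, ctrl, np.array([2.0, 0.0]),
                            np.random.default_rng(0))
        assert tr.timed_out
        assert tr.events["stop_time"] == pytest.approx(
            task_config.max_trial_duration, abs=0.01)
        exclude_disengaged([tr], ctrl)
        assert tr.excluded

    def test_gain_scales_both_velocities_equally(self, noiseless_ctrl, rng):
        cfg = TaskConfig(gain=2.0)
        tr = simulate_trial(cfg, noiseless_ctrl, np.array([3.0, 20.0]), rng,
                            condition="gain")
        # the plant maps identical joystick commands to exactly gain-scaled
        # velocities on both axes
        np.testing.assert_allclose(
            tr.linear_velocity, 2.0 * cfg.v_max * tr.cmd_linear, atol=1e-12)
        np.testing.assert_allclose(
            tr.angular_velocity, 2.0 * cfg.omega_max * tr.cmd_angular, atol=1e-12)
        assert np.max(np.abs(tr.linear_velocity)) <= 2.0 * cfg.v_max + 1e-9

    def test_density_changes_only_noise_not_limits(self, task_config, rng):
        ctrl = ControllerParams()
        tr = simulate_trial(task_config, ctrl, np.array([3.0, 0.0]), rng,
                            condition="density")
        assert np.max(np.abs(tr.linear_velocity)) <= task_config.v_max + 1e-9
        assert np.max(np.abs(tr.angular_velocity)) <= task_config.omega_max + 1e-9

    def test_kinematic_limits_always_respected(self, task_config, rng):
        trials = simulate_trials(task_config, ControllerParams(), 10, rng)
        for tr in trials:
            assert np.max(np.abs(tr.linear_velocity)) <= task_config.v_max + 1e-9


class TestExclusion:
    def test_constructed_exclusion_counts(self, task_config, rng):
        ctrl = ControllerParams()
        good = simulate_trials(task_config, ctrl, 15, rng)
        zero_ctrl = ControllerParams(gain_linear=0.0, gain_angular=0.0,
                                     motor_noise_sd=0.0, sensory_noise_sd=0.0,
                                     sensory_noise_sd_ang=0.0)
        stationary = [simulate_trial(task_config, zero_ctrl,
                                     np.array([2.0, 0.0]), rng) for _ in range(3)]
        # timed-out movers: a sluggish agent still under way at the deadline
        runner = ControllerParams(gain_linear=0.05, stop_distance=0.0,
                                  motor_noise_sd=0.0, sensory_noise_sd=0.0,
                                  sensory_noise_sd_ang=0.0)
        movers = [simulate_trial(task_config, runner, np.array([3.9, 30.0]), rng)
                  for _ in range(2)]
        allt = exclude_disengaged(good + stationary + movers, ctrl)
        assert sum(t.excluded for t in allt) == sum(t.excluded for t in good) + 5

    def test_empty_list(self):
        assert exclude_disengaged([]) == []


def test_noiseless_agent_is_unbiased(task_config, noiseless_ctrl):
    trials = simulate_trials(task_config, noiseless_ctrl, 30, seed=5)
    reg = response_regression(trials)
    assert reg.slope_radial == pytest.approx(1.0, abs=0.05)
    assert reg.slope_angular == pytest.approx(1.0, abs=0.08)
    assert reg.r_radial > 0.99


def test_unicycle_integration_conventions():
    # positive omega turns rightward (+x); heading 0 moves along +y
    v = np.full(100, 1.0)
    w = np.full(100, 90.0)
    pos, h = integrate_unicycle(v, w, 0.01)
    assert pos[-1, 0] > 0.1          # drifted rightward
    assert h[-1] == pytest.approx(89.1, abs=1e-6)
    pos2, _ = integrate_unicycle(v, np.zeros(100), 0.01)
    np.testing.assert_allclose(pos2[:, 0], 0, atol=1e-12)
    assert pos2[-1, 1] == pytest.approx(0.99, abs=1e-9)
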