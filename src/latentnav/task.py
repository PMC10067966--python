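"""Closed-loop virtual navigation task simulator.

Trials emulate a firefly-style steering task: a target is flashed briefly at a
random location on the ground plane, then the agent steers to the remembered
location using a joystick that controls linear and angular velocity, with
self-motion conveyed only through (noisy) optic-flow-like velocity
observations.  The agent here is a saturating proportional controller acting
on an internally path-integrated position estimate; it is artifact plumbing
that stands in for the animal and produces realistic trial statistics
(near-unity response regression slopes, distance-dependent errors).

Conventions: heading 0 points straight ahead (+y), positive angles/angular
velocities are rightward, and the unicycle kinematics are
``dh/dt = omega, dx/dt = v*sin(h), dy/dt = v*cos(h)`` integrated with forward
Euler at the behavioral sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class TruncExp:
    """Truncated exponential delay specification (seconds)."""

    lo: float
    hi: float
    mean: float

    def scale(self) -> float:
        """Rate parameter of the parent exponential whose truncation to
        [lo, hi] has the requested mean (solved numerically)."""

        def trunc_mean(s: float) -> float:
            a, b = self.lo / s, self.hi / s
            # E[X | a < X < b] for X ~ Exp(1), scaled by s
            num = (a + 1) * np.exp(-a) - (b + 1) * np.exp(-b)
            den = np.exp(-a) - np.exp(-b)
            return s * num / den

        return brentq(lambda s: trunc_mean(s) - self.mean, 1e-3, 1e3)

    def sample(self, rng: np.random.Generator) -> float:
        s = self.scale()
        while True:
            x = rng.exponential(s)
            if self.lo <= x <= self.hi:
                return x


@dataclass(frozen=True)
class TaskConfig:
    """Task constants. Distances in meters, angles in degrees, times in s."""

    target_r_range: tuple[float, float] = (0.7, 4.0)
    target_theta_range: tuple[float, float] = (-40.0, 40.0)
    target_radius: float = 0.2
    reward_radius: float = 0.6
    v_max: float = 2.0
    omega_max: float = 90.0
    target_display: float = 0.3
    max_trial_duration: float = 7.0
    sample_rate: float = 2500.0 / 3.0
    density: float = 2.5
    density_low: float = 0.1
    gain: float = 1.0
    feedback_delay: TruncExp = TruncExp(0.1, 0.6, 0.25)
    intertrial_delay: TruncExp = TruncExp(0.2, 2.0, 0.5)
    area_uniform_targets: bool = True

    def __post_init__(self) -> None:
        r_lo, r_hi = self.target_r_range
        if not (0 < r_lo < r_hi):
            raise ValueError("target_r_range must satisfy 0 < r_min < r_max")
        if self.reward_radius >= r_lo:
            raise ValueError("reward radius must be smaller than the nearest target")
        if self.sample_rate <= 0 or self.v_max <= 0 or self.omega_max <= 0:
            raise ValueError("rates and kinematic limits must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class ControllerParams:
    """Synthetic steering agent parameters.

    The agent path-integrates its observed velocity (true velocity plus
    Ornstein-Uhlenbeck sensory noise, emulating unreliable optic flow),
    computes the egocentric location of the remembered target from the
    integrated estimate, and issues saturating proportional joystick commands.
    It releases the joystick (zero command, no motor noise) once the estimated
    distance falls below ``stop_distance``.
    """

    gain_linear: float = 0.9      # 1/s, command per meter of estimated distance
    gain_angular: float = 3.0     # 1/s, command per radian of estimated bearing
    motor_noise_sd: float = 0.04  # sd of OU noise on joystick deflection
    sensory_noise_sd: float = 0.30  # m/s sd of OU noise on observed linear velocity
    sensory_noise_sd_ang: float = 12.0  # deg/s sd on observed angular velocity
    noise_tau: float = 0.6        # s, OU correlation time (sensory)
    motor_noise_tau: float = 0.3  # s, OU correlation time (motor)
    stop_distance: float = 0.1    # m, estimated distance below which agent releases
    stop_threshold: float = 0.01  # m/s, speed counted as stationary
    stop_threshold_ang: float = 1.0  # deg/s
    stop_hold: float = 0.05       # s the agent must stay below threshold
    reaction_time_range: tuple[float, float] = (0.2, 0.5)
    density_noise_factor: float = 5.0  # sensory noise scale-up at low density

    def __post_init__(self) -> None:
        if min(self.motor_noise_sd, self.sensory_noise_sd, self.sensory_noise_sd_ang) < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class Trial:
    """One navigation trial (time series sampled at ``config.sample_rate``)."""

    trial_id: int
    target_polar: tuple[float, float]      # (r*, theta*) m, deg
    linear_velocity: np.ndarray            # m/s
    angular_velocity: np.ndarray           # deg/s
    position: np.ndarray                   # (T, 2) x, y in m
    heading: np.ndarray                    # deg
    cmd_linear: np.ndarray                 # joystick deflection in [0, 1]
    cmd_angular: np.ndarray                # joystick deflection in [-1, 1]
    events: dict[str, float]               # target_on/off, movement_onset, stop_time, feedback_time
    response_polar: tuple[float, float]    # (r, theta) of the stop location
    rewarded: bool
    est_position: np.ndarray | None = None  # (T, 2) agent's path-integrated estimate
    condition: str = "baseline"
    condition_params: dict = field(default_factory=dict)
    perturbation: Optional[tuple[float, float, float]] = None  # (amp_v, amp_w, t_onset)
    timed_out: bool = False
    stationary: bool = False
    excluded: bool = False
    sample_rate: float = 2500.0 / 3.0

    @property
    def duration(self) -> float:
        return (len(self.linear_velocity) - 1) / self.sample_rate

    @property
    def target_xy(self) -> np.ndarray:
        r, th = self.target_polar
        return np.array([r * np.sin(np.deg2rad(th)), r * np.cos(np.deg2rad(th))])

    @property
    def stop_xy(self) -> np.ndarray:
        r, th = self.response_polar
        return np.array([r * np.sin(np.deg2rad(th)), r * np.cos(np.deg2rad(th))])

    @property
    def stop_error(self) -> float:
        """Euclidean distance from stop location to target center (m)."""
        return float(np.linalg.norm(self.stop_xy - self.target_xy))


def sample_target(
    config: TaskConfig, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Draw target locations ``(r*, theta*)`` uniformly over ground-plane area.

    Area-uniform sampling within the annular sector makes the radial density
    proportional to r, i.e. ``r = sqrt(u*(r_max^2 - r_min^2) + r_min^2)``;
    ``config.area_uniform_targets=False`` selects uniform-in-(r, theta)
    sampling instead.  Returns shape ``(2,)`` or ``(n, 2)``.
    """
    r_lo, r_hi = config.target_r_range
    th_lo, th_hi = config.target_theta_range
    size = 1 if n is None else n
    u = rng.uniform(size=size)
    if config.area_uniform_targets:
        r = np.sqrt(u * (r_hi**2 - r_lo**2) + r_lo**2)
    else:
        r = r_lo + u * (r_hi - r_lo)
    th = rng.uniform(th_lo, th_hi, size=size)
    out = np.column_stack([r, th])
    return out[0] if n is None else out


def gaussian_pulse(t: np.ndarray, amp: float, t_onset: float, sigma: float = 0.2,
                   duration: float = 1.0) -> np.ndarray:
    """Gaussian-profile velocity pulse, peak ``amp`` at the window center,
    support truncated to ``duration`` starting at ``t_onset``."""
    center = t_onset + duration / 2.0
    pulse = amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    pulse[(t < t_onset) | (t > t_onset + duration)] = 0.0
    return pulse


def apply_perturbation(
    v: np.ndarray,
    omega: np.ndarray,
    amp_v: float,
    amp_omega: float,
    t_onset: float,
    config: TaskConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Add the passive-displacement pulse to velocity series.

    The pulse has a Gaussian velocity profile (sd 0.2 s), a fixed 1 s support,
    and peak amplitudes ``amp_v`` (m/s, within +/-2) and ``amp_omega`` (deg/s,
    within +/-120).
    """
    if not -2.0 <= amp_v <= 2.0:
        raise ValueError("linear perturbation amplitude outside [-2, 2] m/s")
    if not -120.0 <= amp_omega <= 120.0:
        raise ValueError("angular perturbation amplitude outside [-120, 120] deg/s")
    t = np.arange(len(v)) * config.dt
    return (
        v + gaussian_pulse(t, amp_v, t_onset),
        omega + gaussian_pulse(t, amp_omega, t_onset),
    )


def integrate_unicycle(
    v: np.ndarray, omega: np.ndarray, dt: float,
    x0: float = 0.0, y0: float = 0.0, h0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler integration of the unicycle model.

    Returns ``(position (T,2), heading (T,) in degrees)``; sample t uses the
    velocity at sample t-1 (position[0] is the initial pose).
    """
    h = h0 + np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])
    hr = np.deg2rad(h)
    x = x0 + np.concatenate([[0.0], np.cumsum(v[:-1] * np.sin(hr[:-1])) * dt])
    y = y0 + np.concatenate([[0.0], np.cumsum(v[:-1] * np.cos(hr[:-1])) * dt])
    return np.column_stack([x, y]), h


def _ou_steps(rng: np.random.Generator, n: int, sd: float, tau: float, dt: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise series."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - a**2)
    innov[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], innov)


def simulate_trial(
    config: TaskConfig,
    ctrl: ControllerParams,
    target: np.ndarray,
    rng: np.random.Generator,
    trial_id: int = 0,
    condition: str = "baseline",
    perturbation: Optional[tuple[float, float, float]] = None,
) -> Trial:
    """Simulate one closed-loop trial.

    ``condition`` is one of ``baseline | density | gain | perturbation``;
    the density condition scales the agent's sensory noise by
    ``ctrl.density_noise_factor`` (kinematic limits untouched), the gain
    condition multiplies both executed velocities by ``config.gain``, and the
    perturbation condition adds a Gaussian velocity pulse the agent observes
    and may compensate for.
    """
    dt = config.dt
    n_max = int(np.round(config.max_trial_duration / dt)) + 1
    t_grid = np.arange(n_max) * dt

    sens_scale = ctrl.density_noise_factor if condition == "density" else 1.0
    gain = config.gain if condition == "gain" else 1.0

    noise_v = _ou_steps(rng, n_max, ctrl.sensory_noise_sd * sens_scale, ctrl.noise_tau, dt)
    noise_w = _ou_steps(rng, n_max, ctrl.sensory_noise_sd_ang * sens_scale, ctrl.noise_tau, dt)
    mnoise_v = _ou_steps(rng, n_max, ctrl.motor_noise_sd, ctrl.motor_noise_tau, dt)
    mnoise_w = _ou_steps(rng, n_max, ctrl.motor_noise_sd, ctrl.motor_noise_tau, dt)

    t_move = rng.uniform(*ctrl.reaction_time_range)
    pulse_v = pulse_w = None
    if perturbation is not None:
        amp_v, amp_w, t_on = perturbation
        if not -2.0 <= amp_v <= 2.0 or not -120.0 <= amp_w <= 120.0:
            raise ValueError("perturbation amplitude out of bounds")
        pulse_v = gaussian_pulse(t_grid, amp_v, t_move + t_on)
        pulse_w = gaussian_pulse(t_grid, amp_w, t_move + t_on)

    tx, ty = (
        target[0] * np.sin(np.deg2rad(target[1])),
        target[0] * np.cos(np.deg2rad(target[1])),
    )

    v = np.zeros(n_max)
    w = np.zeros(n_max)
    cmd_v = np.zeros(n_max)
    cmd_w = np.zeros(n_max)
    x = np.zeros(n_max)
    y = np.zeros(n_max)
    h = np.zeros(n_max)
    xe_tr = np.zeros(n_max)
    ye_tr = np.zeros(n_max)
    xe = ye = he = 0.0  # agent's internal pose estimate

    hold_n = int(np.round(ctrl.stop_hold / dt))
    below = 0
    stop_idx = None
    moved = False

    for i in range(n_max - 1):
        if t_grid[i] >= t_move:
            # egocentric target in the agent's estimated frame
            dx, dy = tx - xe, ty - ye
            her = np.deg2rad(he)
            fwd = dx * np.sin(her) + dy * np.cos(her)
            lat = dx * np.cos(her) - dy * np.sin(her)
            d_est = np.hypot(dx, dy)
            bearing = np.arctan2(lat, fwd)  # rad, + rightward
            if d_est < ctrl.stop_distance:
                uv, uw = 0.0, 0.0  # joystick released: no motor noise either
            else:
                uv = float(np.clip(ctrl.gain_linear * d_est * max(np.cos(bearing), 0.0), 0, 1))
                uw = float(np.clip(ctrl.gain_angular * bearing, -1, 1))
                uv = float(np.clip(uv + mnoise_v[i], 0, 1))
                uw = float(np.clip(uw + mnoise_w[i], -1, 1))
        else:
            uv, uw = 0.0, 0.0
        cmd_v[i] = uv
        cmd_w[i] = uw
        v[i] = gain * config.v_max * uv
        w[i] = gain * config.omega_max * uw
        if pulse_v is not None:
            v[i] += pulse_v[i]
            w[i] += pulse_w[i]

        # world update (unicycle, forward Euler)
        hr = np.deg2rad(h[i])
        x[i + 1] = x[i] + v[i] * np.sin(hr) * dt
        y[i + 1] = y[i] + v[i] * np.cos(hr) * dt
        h[i + 1] = h[i] + w[i] * dt

        # agent's path integration of observed velocity
        v_obs = v[i] + noise_v[i]
        w_obs = w[i] + noise_w[i]
        her = np.deg2rad(he)
        xe += v_obs * np.sin(her) * dt
        ye += v_obs * np.cos(her) * dt
        he += w_obs * dt
        xe_tr[i + 1] = xe
        ye_tr[i + 1] = ye

        # stop detection (only once moving has begun)
        speed_low = abs(v[i]) < ctrl.stop_threshold and abs(w[i]) < ctrl.stop_threshold_ang
        if not moved and not speed_low:
            moved = True
        if moved:
            below = below + 1 if speed_low else 0
            if below >= hold_n:
                stop_idx = i
                break

    timed_out = stop_idx is None
    if timed_out:
        stop_idx = n_max - 1
    stop_time = t_grid[stop_idx]
    # hold the pose through the post-stop feedback window
    x[stop_idx + 1:] = x[stop_idx]
    y[stop_idx + 1:] = y[stop_idx]
    h[stop_idx + 1:] = h[stop_idx]
    xe_tr[stop_idx + 1:] = xe_tr[stop_idx]
    ye_tr[stop_idx + 1:] = ye_tr[stop_idx]

    fb_delay = config.feedback_delay.sample(rng)
    end_idx = min(int(np.round((stop_time + fb_delay) / dt)), n_max - 1)
    sl = slice(0, end_idx + 1)

    sx, sy = x[stop_idx], y[stop_idx]
    resp_r = float(np.hypot(sx, sy))
    resp_th = float(np.rad2deg(np.arctan2(sx, sy)))
    err = float(np.hypot(sx - tx, sy - ty))
    rewarded = (not timed_out) and err <= config.reward_radius

    return Trial(
        trial_id=trial_id,
        target_polar=(float(target[0]), float(target[1])),
        linear_velocity=v[sl],
        angular_velocity=w[sl],
        position=np.column_stack([x[sl], y[sl]]),
        heading=h[sl],
        cmd_linear=cmd_v[sl],
        cmd_angular=cmd_w[sl],
        events={
            "target_on": 0.0,
            "target_off": config.target_display,
            "movement_onset": t_move,
            "stop_time": stop_time,
            "feedback_time": t_grid[end_idx],
        },
        response_polar=(resp_r, resp_th),
        rewarded=rewarded,
        est_position=np.column_stack([xe_tr[sl], ye_tr[sl]]),
        condition=condition,
        condition_params=(
            {"gain": gain} if condition == "gain"
            else {"density": config.density_low} if condition == "density"
            else {}
        ),
        perturbation=perturbation,
        timed_out=timed_out,
        stationary=not moved,
        sample_rate=config.sample_rate,
    )


def simulate_trials(
    config: TaskConfig,
    ctrl: ControllerParams,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    condition: str = "baseline",
) -> list[Trial]:
    """Simulate a block of trials of one condition.

    For the perturbation condition, amplitudes are drawn uniformly within the
    allowed ranges and the onset uniformly in [0, 1] s after movement onset.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    trials = []
    for k in range(n_trials):
        target = sample_target(config, rng)
        pert = None
        if condition == "perturbation":
            pert = (
                float(rng.uniform(-2, 2)),
                float(rng.uniform(-120, 120)),
                float(rng.uniform(0, 1)),
            )
        trials.append(
            simulate_trial(config, ctrl, target, rng, trial_id=k,
                           condition=condition, perturbation=pert)
        )
    return exclude_disengaged(trials, ctrl)


def exclude_disengaged(trials: list[Trial], ctrl: ControllerParams | None = None) -> list[Trial]:
    """Flag disengaged trials: stationary throughout, or no stop before timeout.

    Downstream analyses operate on trials with ``excluded == False``.
    """
    thr = ctrl.stop_threshold if ctrl is not None else 0.01
    thr_a = ctrl.stop_threshold_ang if ctrl is not None else 1.0
    for tr in trials:
        stationary = bool(
            np.all(np.abs(tr.linear_velocity) < thr)
            and np.all(np.abs(tr.angular_velocity) < thr_a)
        )
        tr.stationary = stationary
        tr.excluded = stationary or tr.timed_out
    return trials


def active_trials(trials: list[Trial]) -> list[Trial]:
    return [t for t in trials if not t.excluded]
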