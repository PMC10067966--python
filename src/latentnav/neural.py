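"""Ground-truth spiking sessions for parameter-recovery testing.

Spike trains are generated from the same coupled Poisson model that the
encoding stage fits: each neuron's log rate is a sum of piecewise-constant
tuning functions of continuous task variables, temporal filters of discrete
events and motor channels, a causal spike-history filter, and causal coupling
filters from the other neurons, plus a baseline.  Because generation and
fitting share one design-matrix code path, recovery tests compare fitted
coefficients directly against the generating ones.

A session consists of simulated navigation trials (see :mod:`latentnav.task`)
whose per-trial epochs (target onset to feedback) are binned at ``dt`` and
concatenated on a session clock; filters never cross trial boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from . import basis as _basis
from .task import ControllerParams, TaskConfig, Trial, active_trials, simulate_trials

#: continuous variables with piecewise-constant tuning, and their generation
#: ranges (fit-time ranges are re-estimated from session percentiles)
TUNING_RANGES: dict[str, tuple[float, float]] = {
    "linear_velocity": (0.0, 2.0),
    "angular_velocity": (-90.0, 90.0),
    "dist_to_target": (0.0, 4.0),
    "angle_to_target": (-60.0, 60.0),
    "lfp_phase": (-180.0, 180.0),
    "gaze_x": (-20.0, 20.0),
    "gaze_y": (-20.0, 20.0),
}
MOTOR_CHANNELS = ("motor_1", "motor_2")
EVENT_NAMES = ("target_on", "reward")
CIRCULAR_VARS = ("lfp_phase",)

ELECTRODE_PITCH_UM = 400.0


@dataclass
class GroundTruthEncoding:
    """Per-neuron generating parameters of the coupled Poisson model."""

    n_neurons: int
    dt: float
    tuning: list[dict[str, np.ndarray]]          # var -> 10 boxcar weights
    event_coefs: list[dict[str, np.ndarray]]     # event -> 10 cosine coefs
    motor_coefs: list[dict[str, np.ndarray]]     # channel -> 10 cosine coefs
    history_coefs: list[np.ndarray]              # 10 cosine coefs
    coupling_coefs: list[dict[int, np.ndarray]]  # source j -> 10 cosine coefs
    baseline: np.ndarray                         # log-rate offsets, per neuron
    lfp_freq: float = 15.0
    electrode_pos: np.ndarray | None = None      # (N, 2) grid rows/cols

    def __post_init__(self) -> None:
        for i, cp in enumerate(self.coupling_coefs):
            if i in cp:
                raise ValueError("self-coupling is the role of the history filter")


@dataclass
class SessionData:
    """Binned trials, spikes, and aligned predictor channels."""

    dt: float
    trials: list[Trial]
    trial_slices: list[tuple[int, int]]          # [start, stop) bins per trial
    counts: np.ndarray                           # (N, T) spike counts per bin
    spike_times: list[np.ndarray]                # session-clock seconds
    signals: dict[str, np.ndarray]               # name -> (T,)
    events: dict[str, np.ndarray]                # name -> (T,) binary
    electrode_pos: np.ndarray | None = None
    truth: Optional[GroundTruthEncoding] = None
    config: TaskConfig | None = None

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_counts(self, k: int) -> np.ndarray:
        a, b = self.trial_slices[k]
        return self.counts[:, a:b]

    def bins_of_trials(self, trial_idx: np.ndarray) -> np.ndarray:
        """Boolean mask over session bins selecting the given trials."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for k in np.asarray(trial_idx):
            a, b = self.trial_slices[int(k)]
            mask[a:b] = True
        return mask


def simulate_lfp(
    duration: float,
    dt: float,
    rng: np.random.Generator,
    freq: float = 15.0,
    freq_jitter: float = 0.5,
) -> np.ndarray:
    """Instantaneous phase (degrees) of a ~``freq`` Hz oscillator.

    Phase lies in [-180, 180): 0 is the oscillation peak, +/-180 the trough.
    Frequency jitter (Hz, OU-like white modulation) desynchronizes cycles.
    """
    n = int(np.round(duration / dt))
    f_inst = freq + freq_jitter * rng.standard_normal(n)
    phase = np.cumsum(360.0 * f_inst * dt) + rng.uniform(-180, 180)
    return (phase + 180.0) % 360.0 - 180.0


def derive_motor_channels(
    trial: Trial,
    rng: np.random.Generator,
    mix: np.ndarray | None = None,
    noise_sd: float = 0.4,
    noise_tau: float = 0.15,
) -> np.ndarray:
    """Two smooth velocity channels standing in for hand-speed components.

    An invertible linear mix of the commanded joystick velocities plus
    low-pass noise; emulates hand speed along the two leading principal
    components of hand position.  Returns shape ``(T, 2)``.
    """
    if mix is None:
        mix = np.array([[1.0, 0.4], [-0.3, 0.9]])
    cmds = np.column_stack([trial.cmd_linear, trial.cmd_angular])
    out = cmds @ mix.T
    if noise_sd > 0:
        dt = 1.0 / trial.sample_rate
        a = np.exp(-dt / noise_tau)
        innov = rng.standard_normal(cmds.shape) * noise_sd * np.sqrt(1 - a**2)
        out = out + lfilter([1.0], [1.0, -a], innov, axis=0)
    return out


def _bin_series(x: np.ndarray, n_bins: int, per_bin: int) -> np.ndarray:
    return x[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


def bin_trials(
    trials: list[Trial],
    dt: float,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
) -> SessionData:
    """Assemble binned predictor channels from simulated trials.

    Only non-excluded trials enter the session.  Distance and angle to target
    are recomputed per bin from the binned trajectory and the target; spike
    containers are left empty for :func:`simulate_spikes` to fill.
    """
    use = active_trials(trials)
    if not use:
        raise ValueError("no non-excluded trials")
    sr = use[0].sample_rate
    per_bin = int(np.round(dt * sr))
    if abs(per_bin - dt * sr) > 1e-6:
        raise ValueError("dt must be an integer multiple of the behavioral sample step")

    slices = []
    sig = {k: [] for k in
           ("linear_velocity", "angular_velocity", "dist_to_target",
            "angle_to_target", "motor_1", "motor_2", "lfp_phase",
            "gaze_x", "gaze_y")}
    ev = {k: [] for k in EVENT_NAMES}
    start = 0
    for tr in use:
        n_bins = len(tr.linear_velocity) // per_bin
        if n_bins < 2:
            continue
        slices.append((start, start + n_bins))
        start += n_bins

        v = _bin_series(tr.linear_velocity, n_bins, per_bin)
        w = _bin_series(tr.angular_velocity, n_bins, per_bin)
        px = _bin_series(tr.position[:, 0], n_bins, per_bin)
        py = _bin_series(tr.position[:, 1], n_bins, per_bin)
        hd = _bin_series(tr.heading, n_bins, per_bin)
        tx, ty = tr.target_xy
        dx, dy = tx - px, ty - py
        dist = np.hypot(dx, dy)
        hr = np.deg2rad(hd)
        fwd = dx * np.sin(hr) + dy * np.cos(hr)
        lat = dx * np.cos(hr) - dy * np.sin(hr)
        ang = np.rad2deg(np.arctan2(lat, fwd))

        motor = derive_motor_channels(tr, rng)
        m1 = _bin_series(motor[:, 0], n_bins, per_bin)
        m2 = _bin_series(motor[:, 1], n_bins, per_bin)
        lfp = simulate_lfp(n_bins * dt, dt, rng)

        gaze = np.column_stack([
            lfilter([1.0], [1.0, -0.98], rng.standard_normal(n_bins) * 1.0),
            lfilter([1.0], [1.0, -0.98], rng.standard_normal(n_bins) * 1.0),
        ])

        sig["linear_velocity"].append(v)
        sig["angular_velocity"].append(w)
        sig["dist_to_target"].append(dist)
        sig["angle_to_target"].append(ang)
        sig["motor_1"].append(m1)
        sig["motor_2"].append(m2)
        sig["lfp_phase"].append(lfp[:n_bins])
        sig["gaze_x"].append(np.clip(gaze[:, 0], -20, 20))
        sig["gaze_y"].append(np.clip(gaze[:, 1], -20, 20))

        e_on = np.zeros(n_bins)
        e_on[0] = 1.0
        e_rw = np.zeros(n_bins)
        if tr.rewarded:
            e_rw[min(int(tr.events["feedback_time"] / dt), n_bins - 1)] = 1.0
        ev["target_on"].append(e_on)
        ev["reward"].append(e_rw)

    T = start
    signals = {k: np.concatenate(v) for k, v in sig.items()}
    events = {k: np.concatenate(v) for k, v in ev.items()}
    kept = [tr for tr, _ in zip(use, slices)]
    return SessionData(
        dt=dt, trials=kept[: len(slices)], trial_slices=slices,
        counts=np.zeros((0, T), dtype=np.int64), spike_times=[],
        signals=signals, events=events, config=config,
    )


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def _project(basis: _basis.CosineBasis, target: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(basis.B, target, rcond=None)
    return coef


def _bump_weights(centers: np.ndarray, pref: float, width: float, amp: float,
                  circular: bool = False, period: float = 360.0) -> np.ndarray:
    d = centers - pref
    if circular:
        d = (d + period / 2) % period - period / 2
    w = amp * np.exp(-0.5 * (d / width) ** 2)
    return w - w.mean()


def make_ground_truth(
    n_neurons: int,
    rng: np.random.Generator,
    dt: float = 0.006,
    coupling_pairs: list[tuple[int, int, float]] | None = None,
    n_coupling_pairs: int | None = None,
    dense_coupling: float | None = None,
    base_rate_hz: float = 10.0,
    tuning_amp: float = 0.8,
    grid_shape: tuple[int, int] = (10, 10),
) -> GroundTruthEncoding:
    """Default generating parameters emulating the recorded population.

    Tuning preferences tile each variable's range (with the documented skews
    toward small target distances and eccentric angles) and lock to the LFP
    phase shortly before its trough; target onset evokes an ON response at
    ~120 ms latency; history filters are refractory.  Coupling is either
    sparse (``coupling_pairs`` as ``(source, target, amplitude)`` triples, or
    ``n_coupling_pairs`` drawn randomly) or, with ``dense_coupling`` set to
    an amplitude scale, present between every directed pair with random sign
    and strength decaying with inter-electrode distance.
    """
    ev_on = _basis.event_basis(dt, causal=True)
    ev_off = _basis.event_basis(dt, causal=False)
    hb = _basis.history_basis(dt)
    cb = _basis.coupling_basis(dt)

    tuning, event_coefs, motor_coefs, history_coefs = [], [], [], []
    for _ in range(n_neurons):
        tn: dict[str, np.ndarray] = {}
        rngs = TUNING_RANGES
        cen = lambda v: _basis.BoxcarBasis(*rngs[v]).centers  # noqa: E731
        tn["linear_velocity"] = _bump_weights(
            cen("linear_velocity"), rng.uniform(0, 2), 0.7, tuning_amp * rng.uniform(0.5, 1.2))
        tn["angular_velocity"] = _bump_weights(
            cen("angular_velocity"), rng.uniform(-90, 90), 35, tuning_amp * rng.uniform(0.5, 1.2))
        # preferences tile the range, skewed toward small distances and
        # eccentric angles
        pref_d = 4.0 * rng.beta(1.2, 2.2)
        tn["dist_to_target"] = _bump_weights(
            cen("dist_to_target"), pref_d, rng.uniform(0.8, 1.8),
            tuning_amp * rng.uniform(0.5, 1.2))
        pref_a = rng.choice([-1, 1]) * rng.uniform(10, 60)
        tn["angle_to_target"] = _bump_weights(
            cen("angle_to_target"), pref_a, rng.uniform(20, 40),
            tuning_amp * rng.uniform(0.5, 1.2))
        tn["lfp_phase"] = _bump_weights(
            cen("lfp_phase"), 162.0 + 8.0 * rng.standard_normal(), 60,
            tuning_amp * rng.uniform(0.3, 0.8), circular=True)
        tn["gaze_x"] = _bump_weights(cen("gaze_x"), rng.uniform(-20, 20), 15,
                                     0.1 * tuning_amp)
        tn["gaze_y"] = _bump_weights(cen("gaze_y"), rng.uniform(-20, 20), 15,
                                     0.1 * tuning_amp)
        tuning.append(tn)

        lat = 0.122 + 0.015 * rng.standard_normal()
        on_shape = rng.uniform(0.4, 1.0) * np.exp(
            -0.5 * ((ev_on.lags - lat) / 0.06) ** 2)
        rw_shape = (rng.uniform(0, 0.3) if rng.uniform() < 0.1 else 0.0) * np.exp(
            -0.5 * ((ev_off.lags - 0.1) / 0.08) ** 2)
        event_coefs.append({
            "target_on": _project(ev_on, on_shape),
            "reward": _project(ev_off, rw_shape),
        })
        # motor kernels act on a continuous channel, so their time-integral
        # (not their amplitude) sets the contribution scale
        motor_scale = 0.4 / ev_off.B.sum(axis=0).mean()
        motor_coefs.append({
            ch: motor_scale * tuning_amp * rng.standard_normal(ev_off.n) * np.exp(
                -np.arange(ev_off.n) / 4.0)
            for ch in MOTOR_CHANNELS
        })
        hist_shape = -4.0 * np.exp(-hb.lags / 0.008) + 0.3 * np.exp(-hb.lags / 0.06)
        history_coefs.append(_project(hb, hist_shape))

    cells = [(r, c) for r in range(grid_shape[0]) for c in range(grid_shape[1])]
    pos = np.array([cells[k] for k in
                    rng.choice(len(cells), n_neurons, replace=False)])

    coupling_coefs: list[dict[int, np.ndarray]] = [dict() for _ in range(n_neurons)]
    if dense_coupling is not None:
        # every directed pair coupled; strength decays with array distance
        for i in range(n_neurons):
            for j in range(n_neurons):
                if i == j:
                    continue
                d = np.linalg.norm(pos[i] - pos[j])
                amp = dense_coupling * rng.standard_normal() * np.exp(-d / 3.0)
                tau = rng.uniform(0.02, 0.05)
                coupling_coefs[i][j] = _project(cb, amp * np.exp(-cb.lags / tau))
    else:
        if coupling_pairs is None and n_coupling_pairs:
            coupling_pairs = []
            seen = set()
            while len(coupling_pairs) < n_coupling_pairs:
                j, i = rng.integers(0, n_neurons, 2)
                if i == j or (j, i) in seen:
                    continue
                seen.add((j, i))
                coupling_pairs.append(
                    (int(j), int(i),
                     float(rng.choice([-1, 1]) * rng.uniform(0.6, 1.2))))
        for (j, i, amp) in coupling_pairs or []:
            tau = rng.uniform(0.02, 0.05)
            coupling_coefs[i][j] = _project(cb, amp * np.exp(-cb.lags / tau))

    baseline = np.log(base_rate_hz * dt) + 0.3 * rng.standard_normal(n_neurons)

    return GroundTruthEncoding(
        n_neurons=n_neurons, dt=dt, tuning=tuning, event_coefs=event_coefs,
        motor_coefs=motor_coefs, history_coefs=history_coefs,
        coupling_coefs=coupling_coefs, baseline=baseline, electrode_pos=pos,
    )


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

MAX_RATE_HZ = 400.0  # per-bin rate cap during generation


def exogenous_lograte(session: SessionData, truth: GroundTruthEncoding) -> np.ndarray:
    """(N, T) log-rate from tuning, event, and motor terms plus baseline."""
    from .design import exogenous_design

    X, groups = exogenous_design(session, ranges=TUNING_RANGES)
    out = np.tile(truth.baseline[:, None], (1, session.n_bins)).astype(np.float64)
    for g in groups:
        for i in range(truth.n_neurons):
            if g.kind == "tuning":
                coef = truth.tuning[i].get(g.name)
            elif g.kind == "event":
                coef = truth.event_coefs[i].get(g.name)
            else:
                coef = truth.motor_coefs[i].get(g.name)
            if coef is not None:
                out[i] += X[:, g.sl] @ coef
    return out


def simulate_spikes(
    session: SessionData,
    truth: GroundTruthEncoding,
    rng: np.random.Generator,
) -> SessionData:
    """Sequential bin-by-bin generative pass of the coupled Poisson model.

    Each bin's log rate combines the precomputed exogenous terms with history
    and coupling contributions from earlier spikes (scatter-added into a
    log-rate accumulator as spikes occur); emission is Poisson per bin and
    spike times are placed uniformly within their bin.  Log rates exceeding
    the ``MAX_RATE_HZ`` cap are clipped with a warning.
    """
    N, T = truth.n_neurons, session.n_bins
    dt = session.dt
    hb = _basis.history_basis(dt)
    cb = _basis.coupling_basis(dt)
    hf = np.array([hb.reconstruct(c) for c in truth.history_coefs])  # (N, Lh)
    cf = {(j, i): cb.reconstruct(c)
          for i, d in enumerate(truth.coupling_coefs) for j, c in d.items()}
    targets_of = [[] for _ in range(N)]
    for (j, i) in cf:
        targets_of[j].append(i)
    Lh, Lc = hf.shape[1], cb.B.shape[0]

    acc = exogenous_lograte(session, truth)  # (N, T), mutated in place
    counts = np.zeros((N, T), dtype=np.int64)
    cap = np.log(MAX_RATE_HZ * dt)
    n_clipped = 0

    for (a, b) in session.trial_slices:
        for t in range(a, b):
            lr = acc[:, t]
            over = lr > cap
            if np.any(over):
                n_clipped += int(over.sum())
                lr = np.minimum(lr, cap)
            c = rng.poisson(np.exp(lr))
            if not c.any():
                continue
            counts[:, t] = c
            for j in np.flatnonzero(c):
                cj = c[j]
                hi = min(b, t + 1 + Lh)
                acc[j, t + 1:hi] += cj * hf[j, : hi - t - 1]
                for i in targets_of[j]:
                    ci = min(b, t + 1 + Lc)
                    acc[i, t + 1:ci] += cj * cf[(j, i)][: ci - t - 1]

    if n_clipped:
        warnings.warn(f"log-rate cap hit in {n_clipped} neuron-bins", RuntimeWarning)

    spike_times = []
    for i in range(N):
        bins = np.repeat(np.arange(T), counts[i])
        times = (bins + rng.uniform(size=bins.size)) * dt
        spike_times.append(np.sort(times))

    session.counts = counts
    session.spike_times = spike_times
    session.truth = truth
    session.electrode_pos = truth.electrode_pos
    return session


def make_session(
    n_neurons: int = 40,
    n_trials: int = 200,
    seed: int = 0,
    dt: float = 0.006,
    config: TaskConfig | None = None,
    ctrl: ControllerParams | None = None,
    truth: GroundTruthEncoding | None = None,
    condition: str = "baseline",
    n_coupling_pairs: int | None = None,
    **truth_kwargs,
) -> SessionData:
    """End-to-end synthetic session: behavior, channels, then spikes."""
    rng = np.random.default_rng(seed)
    config = config or TaskConfig()
    ctrl = ctrl or ControllerParams()
    trials = simulate_trials(config, ctrl, n_trials, rng, condition=condition)
    session = bin_trials(trials, dt, rng, config=config)
    if truth is None:
        truth = make_ground_truth(
            n_neurons, rng, dt=dt, n_coupling_pairs=n_coupling_pairs, **truth_kwargs)
        calibrate_baseline(session, truth)
    return simulate_spikes(session, truth, rng)


def calibrate_baseline(session: SessionData, truth: GroundTruthEncoding) -> None:
    """Recenter per-neuron baselines so the session-mean exogenous rate
    equals the rate implied by the drawn baseline (summed tuning bumps
    otherwise inflate the mean, since E[exp(f)] > exp(E[f]))."""
    exo = exogenous_lograte(session, truth)
    mean_count = np.exp(exo).mean(axis=1)
    truth.baseline -= np.log(mean_count) - truth.baseline
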