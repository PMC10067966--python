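"""Closed-loop recurrent network model of latent-state navigation.

A fully connected rate network (``tau r' = -r + tanh(W_rec r + W_in xtil)``,
``y = W_out r``) receives the target location as a transient two-channel
pulse and controls a plant: the two outputs encode acceleration, integrated
once into 2D self-motion velocity z (with process noise, so the network
cannot learn a purely autonomous policy) and again into position s.  The
velocity is fed back to the remaining two input channels with sensory noise,
closing the sensorimotor loop the way the virtual-reality rig closes it for
the animal.  Recurrent (and initially input/output) weights are trained by
backpropagation through time on the loss ``sum_k sum_{t>t*} |s_k(t) - x_k|^2``
where the deadline t* is the time an idealized circular trajectory at
maximum speed needs to reach the target; a metabolic variant adds penalties
on output/activity amplitude and their derivatives.  Task manipulations
(extra sensory noise, motor gain, feedback perturbation pulses) retrain only
``W_rec`` with input/output weights frozen.

Everything here is plain numpy: forward passes and the exact reverse-mode
gradients are written out explicitly and vectorized over a batch of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import behavioral_auc_from_trials
from .task import TaskConfig, sample_target


@dataclass(frozen=True)
class RnnConfig:
    n_units: int = 100
    n_inputs: int = 4
    n_outputs: int = 2
    tau: float = 0.020          # s, unit time constant
    dt: float = 0.010           # s, Euler step (tau/2)
    pulse_duration: float = 0.3
    hold_duration: float = 0.6  # stay-at-target window after the deadline
    min_duration: float = 2.0
    max_duration: float = 3.0
    v_max: float = 2.0          # m/s, used for the deadline computation
    target_scale: float = 4.0   # divides target coords onto the pulse channels
    feedback_scale: float = 0.5 # velocity -> input channel units
    process_noise_sd: float = 0.05
    sensory_noise_sd: float = 0.05
    w_y: float = 0.0            # metabolic penalty weights
    w_dy: float = 0.0
    w_r: float = 0.0
    w_dr: float = 0.0
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if self.dt >= self.tau:
            raise ValueError("integration step must be smaller than tau")
        if min(self.n_units, self.n_inputs, self.n_outputs) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class RnnParams:
    W_rec: np.ndarray  # (N, N)
    W_in: np.ndarray   # (N, M)
    W_out: np.ndarray  # (P, N)

    def copy(self) -> "RnnParams":
        return RnnParams(self.W_rec.copy(), self.W_in.copy(), self.W_out.copy())


def init_params(config: RnnConfig, rng: np.random.Generator,
                g_rec: float = 1.2) -> RnnParams:
    N, M, P = config.n_units, config.n_inputs, config.n_outputs
    return RnnParams(
        W_rec=g_rec * rng.standard_normal((N, N)) / np.sqrt(N),
        W_in=rng.standard_normal((N, M)) / np.sqrt(M),
        W_out=np.zeros((P, N)),
    )


def compute_deadline(target_xy: np.ndarray, config: RnnConfig) -> float:
    """Travel time along the idealized circular path to the target.

    The circle is tangent to the initial straight-ahead heading (+y) at the
    origin and passes through the target; its arc length is ``c*psi/sin(psi)``
    with c the chord (distance to target) and psi the bearing angle, reducing
    to the straight-line distance for a dead-ahead target.  Deadline is arc
    length over maximum speed.
    """
    tx, ty = float(target_xy[0]), float(target_xy[1])
    c = np.hypot(tx, ty)
    if c == 0:
        return 0.0
    psi = abs(np.arctan2(tx, ty))
    arc = c if psi < 1e-9 else c * psi / np.sin(psi) if psi < np.pi - 1e-9 else np.inf
    return float(arc / config.v_max)


def sample_targets_xy(n: int, config: RnnConfig, rng: np.random.Generator) -> np.ndarray:
    pol = sample_target(config.task, rng, n=n)
    th = np.deg2rad(pol[:, 1])
    return np.column_stack([pol[:, 0] * np.sin(th), pol[:, 0] * np.cos(th)])


def _trial_spec(targets: np.ndarray, config: RnnConfig):
    """Per-trial deadline, end time, and the common step count for a batch."""
    tstars = np.array([compute_deadline(t, config) for t in targets])
    ends = np.clip(tstars + config.hold_duration + 2 * config.dt,
                   config.min_duration, config.max_duration)
    T = int(np.ceil(ends.max() / config.dt))
    return tstars, ends, T


def forward(
    params: RnnParams,
    config: RnnConfig,
    targets: np.ndarray,
    rng: np.random.Generator | None,
    manipulation: dict | None = None,
) -> dict:
    """Closed-loop rollout for a batch of targets.

    ``manipulation`` may contain ``sensory_noise_mult`` (scales feedback
    noise), ``motor_gain`` (scales the output before the plant), or
    ``perturb`` with ``(amp_scale, rng)`` adding a Gaussian temporal pulse
    (sd 0.2 s) to the feedback channels at a random time after target onset.
    ``rng=None`` disables both noise sources (deterministic rollout).

    Returns all state needed for the backward pass.
    """
    manipulation = manipulation or {}
    B = len(targets)
    N, M, P = config.n_units, config.n_inputs, config.n_outputs
    k = config.dt / config.tau
    tstars, ends, T = _trial_spec(targets, config)

    sn = config.sensory_noise_sd * manipulation.get("sensory_noise_mult", 1.0)
    pn = config.process_noise_sd
    gain = manipulation.get("motor_gain", 1.0)

    if rng is None:
        noise_p = np.zeros((T, B, P))
        noise_s = np.zeros((T, B, 2))
    else:
        noise_p = pn * rng.standard_normal((T, B, P))
        noise_s = sn * rng.standard_normal((T, B, 2))

    pulse = np.zeros((T, B, 2))
    if "perturb" in manipulation:
        amp_scale = manipulation["perturb"]
        prng = rng or np.random.default_rng(0)
        t_grid = np.arange(T) * config.dt
        for b in range(B):
            t0 = prng.uniform(config.pulse_duration, 1.0 + config.pulse_duration)
            amp = amp_scale * prng.uniform(-1, 1, size=2)
            prof = np.exp(-0.5 * ((t_grid - (t0 + 0.5)) / 0.2) ** 2)
            prof[(t_grid < t0) | (t_grid > t0 + 1.0)] = 0.0
            pulse[:, b, :] = prof[:, None] * amp[None, :]

    n_pulse = int(np.round(config.pulse_duration / config.dt))
    x_in = np.zeros((T, B, M))
    x_in[:n_pulse, :, 0:2] = (targets / config.target_scale)[None, :, :]

    r = np.zeros((T + 1, B, N))
    a = np.zeros((T, B, N))
    y = np.zeros((T, B, P))
    z = np.zeros((T + 1, B, 2))
    s = np.zeros((T + 1, B, 2))
    xt = np.zeros((T, B, M))

    for t in range(T):
        xt[t] = x_in[t]
        xt[t, :, 2:4] += config.feedback_scale * z[t] + noise_s[t] + pulse[t]
        u = r[t] @ params.W_rec.T + xt[t] @ params.W_in.T
        a[t] = np.tanh(u)
        r[t + 1] = (1 - k) * r[t] + k * a[t]
        y[t] = r[t + 1] @ params.W_out.T
        z[t + 1] = z[t] + config.dt * gain * (y[t] + noise_p[t])
        s[t + 1] = s[t] + config.dt * z[t + 1]

    t_idx = (np.arange(T) + 1) * config.dt
    mask = (t_idx[:, None] > tstars[None, :]) & (t_idx[:, None] <= ends[None, :])

    loss = float(np.sum(mask[:, :, None] * (s[1:] - targets[None, :, :]) ** 2))
    if config.w_y:
        loss += config.w_y * float(np.sum(y**2))
    if config.w_dy:
        loss += config.w_dy * float(np.sum(np.diff(y, axis=0) ** 2))
    if config.w_r:
        loss += config.w_r * float(np.sum(r[1:] ** 2))
    if config.w_dr:
        loss += config.w_dr * float(np.sum(np.diff(r, axis=0) ** 2))
    loss /= B

    return dict(r=r, a=a, y=y, z=z, s=s, xt=xt, mask=mask, loss=loss,
                tstars=tstars, ends=ends, targets=targets, gain=gain, T=T)


def backward(params: RnnParams, config: RnnConfig, fwd: dict) -> dict:
    """Exact reverse-mode gradients of the (batch-mean) loss."""
    r, a, y, z, s = fwd["r"], fwd["a"], fwd["y"], fwd["z"], fwd["s"]
    xt, mask, targets, gain, T = fwd["xt"], fwd["mask"], fwd["targets"], fwd["gain"], fwd["T"]
    B = len(targets)
    k = config.dt / config.tau
    dt = config.dt

    gy_met = np.zeros_like(y)
    if config.w_y:
        gy_met += 2 * config.w_y * y
    if config.w_dy:
        d = np.diff(y, axis=0)
        gy_met[:-1] -= 2 * config.w_dy * d
        gy_met[1:] += 2 * config.w_dy * d
    gr_met = np.zeros_like(r)
    if config.w_r:
        gr_met[1:] += 2 * config.w_r * r[1:]
    if config.w_dr:
        d = np.diff(r, axis=0)
        gr_met[:-1] -= 2 * config.w_dr * d
        gr_met[1:] += 2 * config.w_dr * d

    gW_rec = np.zeros_like(params.W_rec)
    gW_in = np.zeros_like(params.W_in)
    gW_out = np.zeros_like(params.W_out)
    gr_next = np.zeros((B, config.n_units))
    gz_next = np.zeros((B, 2))
    gs_next = np.zeros((B, 2))
    gxt_next = None

    for t in range(T - 1, -1, -1):
        gs1 = gs_next + 2 * (s[t + 1] - targets) * mask[t][:, None]
        gz1 = gz_next + dt * gs1
        if gxt_next is not None:
            gz1 = gz1 + config.feedback_scale * gxt_next[:, 2:4]
        gy = dt * gain * gz1 + gy_met[t]
        gW_out += gy.T @ r[t + 1]
        gr1 = gr_next + gy @ params.W_out + gr_met[t + 1]
        gu = k * gr1 * (1 - a[t] ** 2)
        gW_rec += gu.T @ r[t]
        gW_in += gu.T @ xt[t]
        gxt_next = gu @ params.W_in
        gr_next = (1 - k) * gr1 + gu @ params.W_rec
        gz_next = gz1
        gs_next = gs1

    return {"W_rec": gW_rec / B, "W_in": gW_in / B, "W_out": gW_out / B}


def responses_polar(fwd: dict, config: RnnConfig) -> np.ndarray:
    """Network 'stop location' per trial: position at the end of the
    stay-at-target window, in polar (r, theta-degrees) form."""
    end_idx = np.minimum(np.round(fwd["ends"] / config.dt).astype(int), fwd["T"])
    stops = fwd["s"][end_idx, np.arange(len(end_idx))]
    return np.column_stack([
        np.hypot(stops[:, 0], stops[:, 1]),
        np.rad2deg(np.arctan2(stops[:, 0], stops[:, 1])),
    ])


def _xy_to_polar(xy: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.hypot(xy[:, 0], xy[:, 1]),
        np.rad2deg(np.arctan2(xy[:, 0], xy[:, 1])),
    ])


def network_auc(
    params: RnnParams,
    config: RnnConfig,
    n_trials: int = 200,
    seed: int = 1234,
    manipulation: dict | None = None,
) -> float:
    """Behavioral ROC AUC of the network on fresh noisy trials."""
    rng = np.random.default_rng(seed)
    targets = sample_targets_xy(n_trials, config, rng)
    fwd = forward(params, config, targets, rng, manipulation)
    resp = responses_polar(fwd, config)
    return behavioral_auc_from_trials((_xy_to_polar(targets), resp), rng=rng)


class _Adam:
    def __init__(self, shapes, lr=2e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = {}
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mh = self.m[key] / (1 - self.b1**self.t)
            vh = self.v[key] / (1 - self.b2**self.t)
            out[key] = self.lr * mh / (np.sqrt(vh) + self.eps)
        return out


def _clip(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        grads = {key: g * (max_norm / total) for key, g in grads.items()}
    return grads


@dataclass
class TrainHistory:
    losses: list = field(default_factory=list)
    aucs: list = field(default_factory=list)
    n_trials: int = 0
    reached_criterion: bool = False


def train_bptt(
    config: RnnConfig,
    seed: int = 0,
    params: RnnParams | None = None,
    max_trials: int = 20_000,
    batch_size: int = 32,
    lr: float = 2e-3,
    clip_norm: float = 2.0,
    auc_target: float = 0.88,
    eval_every: int = 25,
    eval_trials: int = 150,
    manipulation: dict | None = None,
    train_io: bool = True,
) -> tuple[RnnParams, TrainHistory]:
    """Train the network on random targets until the behavioral AUC reaches
    the criterion (matching average subject performance) or the trial budget
    is exhausted.

    ``train_io=False`` freezes input and output weights (manipulation
    retraining updates only the recurrent weights).  Raises on divergence.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = init_params(config, rng)
    keys = ("W_rec", "W_in", "W_out") if train_io else ("W_rec",)
    opt = _Adam({k: getattr(params, k).shape for k in keys}, lr=lr)
    hist = TrainHistory()
    eval_seed = int(rng.integers(2**31 - 1))

    n_batches = max_trials // batch_size
    for it in range(n_batches):
        targets = sample_targets_xy(batch_size, config, rng)
        fwd = forward(params, config, targets, rng, manipulation)
        if not np.isfinite(fwd["loss"]):
            raise FloatingPointError(
                f"training diverged at batch {it} (loss={fwd['loss']})")
        grads = backward(params, config, fwd)
        grads = _clip({k: grads[k] for k in keys}, clip_norm)
        steps = opt.step(grads)
        for k in keys:
            getattr(params, k)[...] -= steps[k]
        hist.losses.append(fwd["loss"])
        hist.n_trials += batch_size

        if (it + 1) % eval_every == 0 or it == n_batches - 1:
            auc = network_auc(params, config, eval_trials, eval_seed, manipulation)
            hist.aucs.append((hist.n_trials, auc))
            if auc >= auc_target:
                hist.reached_criterion = True
                break
    return params, hist


def retrain_recurrent(
    params: RnnParams,
    manipulation: dict,
    config: RnnConfig,
    seed: int = 0,
    auc_target: float = 0.88,
    max_trials: int = 20_000,
    **kwargs,
) -> tuple[RnnParams, TrainHistory]:
    """Adapt a trained network to a manipulation, updating only W_rec.

    Input and output weights are bit-identical before and after.  (The
    added-sensory-noise condition is normally evaluated without retraining;
    this function applies to the motor-gain and perturbation conditions.)
    """
    new = params.copy()
    return train_bptt(config, seed=seed, params=new, max_trials=max_trials,
                      auc_target=auc_target, manipulation=manipulation,
                      train_io=False, **kwargs)


# ---------------------------------------------------------------------------
# evaluation battery: treat units as neurons and reuse the session analyses
# ---------------------------------------------------------------------------

def run_trials(
    params: RnnParams, config: RnnConfig, n_trials: int, seed: int,
    manipulation: dict | None = None,
) -> dict:
    """Fresh rollouts plus derived per-bin task variables.

    Returns activities ``r`` (T+1, B, N), task variable arrays (T, B): the
    two velocity components (sensory), distance and angle to target (latent),
    and the two output channels (motor), along with masks and geometry.
    """
    rng = np.random.default_rng(seed)
    targets = sample_targets_xy(n_trials, config, rng)
    fwd = forward(params, config, targets, rng, manipulation)
    s, z, y = fwd["s"][1:], fwd["z"][1:], fwd["y"]
    d = np.linalg.norm(targets[None] - s, axis=2)
    ang = np.rad2deg(np.arctan2(targets[None, :, 0] - s[:, :, 0],
                                targets[None, :, 1] - s[:, :, 1]))
    fwd["task_vars"] = {
        "linear_velocity": z[:, :, 1],
        "angular_velocity": z[:, :, 0],
        "dist_to_target": d,
        "angle_to_target": ang,
        "motor_1": y[:, :, 0],
        "motor_2": y[:, :, 1],
    }
    return fwd


def unit_tuning_model(
    fwd: dict,
    config: RnnConfig,
    n_bins: int = 10,
    ridge: float = 1e-3,
    include_coupling: bool = True,
) -> dict:
    """Gaussian-likelihood encoding model of the unit activities.

    Each unit's activity (mapped to [0, 1] via (r+1)/2) is ridge-regressed on
    boxcar expansions of the six task variables plus, optionally, the
    one-step-lagged activities of all units (the unit's own lag acting as its
    history term, the others as linear coupling terms).  Returns per-unit
    tuning curves per variable, coupling weight vectors, and the variance
    contribution of each variable group (R^2 drop when the group is removed),
    from which mixed-selectivity participation ratios follow.
    """
    from .basis import BoxcarBasis

    tv = fwd["task_vars"]
    mask = (np.arange(fwd["T"])[:, None] * config.dt) <= fwd["ends"][None, :]
    rows = mask.ravel()
    act = ((fwd["r"][1:] + 1) / 2).reshape(-1, config.n_units)[rows]
    lag = ((fwd["r"][:-1] + 1) / 2).reshape(-1, config.n_units)[rows]

    cols, groups, bases = [], {}, {}
    p = 0
    for name, series in tv.items():
        x = series.ravel()[rows]
        lo, hi = np.percentile(x, [1, 99])
        bx = BoxcarBasis(lo, hi if hi > lo else lo + 1e-6, n=n_bins)
        X = bx.design(x)
        cols.append(X)
        groups[name] = slice(p, p + n_bins)
        bases[name] = bx
        p += n_bins
    X_tun = np.column_stack(cols + [np.ones(len(act))])
    G = X_tun.T @ X_tun + ridge * np.eye(X_tun.shape[1])
    W = np.linalg.solve(G, X_tun.T @ act)  # tuning-only model

    pred = X_tun @ W
    var_tot = act.var(axis=0)
    r2_full = 1 - ((act - pred) ** 2).mean(axis=0) / np.maximum(var_tot, 1e-12)

    # per-variable variance contribution: R^2 drop when the group is removed
    # from the tuning-only model (the lagged-activity block would otherwise
    # absorb nearly all variance, masking the tuning terms)
    contrib = {}
    for name in tv:
        keep = np.ones(X_tun.shape[1], dtype=bool)
        keep[groups[name]] = False
        Gk = G[np.ix_(keep, keep)]
        Wk = np.linalg.solve(Gk, X_tun[:, keep].T @ act)
        predk = X_tun[:, keep] @ Wk
        r2k = 1 - ((act - predk) ** 2).mean(axis=0) / np.maximum(var_tot, 1e-12)
        contrib[name] = np.maximum(r2_full - r2k, 0.0)

    tuning = {name: W[groups[name]].T for name in tv}  # (N, n_bins)
    coupling = None
    if include_coupling:
        Xf = np.column_stack([X_tun[:, :-1], lag, np.ones(len(act))])
        Gf = Xf.T @ Xf + ridge * np.eye(Xf.shape[1])
        Wf = np.linalg.solve(Gf, Xf.T @ act)
        n_tun = X_tun.shape[1] - 1
        coupling = Wf[n_tun:n_tun + config.n_units].T  # (N units, N sources)
        tuning = {name: Wf[groups[name]].T for name in tv}
    return dict(tuning=tuning, bases=bases, coupling=coupling,
                contrib=contrib, r2_full=r2_full)


def mixed_selectivity(model: dict) -> np.ndarray:
    """Per-unit participation ratio over the six task-variable variance
    contributions."""
    from .stability import participation_ratio

    names = list(model["contrib"])
    V = np.stack([model["contrib"][n] for n in names], axis=1)
    out = np.full(V.shape[0], np.nan)
    for i in range(V.shape[0]):
        if V[i].sum() > 0:
            out[i] = participation_ratio(V[i])
    return out


def latent_tuned_fraction(
    fwd: dict,
    config: RnnConfig,
    n_bins: int = 10,
    ridge: float = 1e-3,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Fraction of units for which selection retains the latent terms.

    Mirrors the encoding pipeline's grouped selection logic: the tuning-only
    model is cross-validated (trial-level folds) with and without the
    distance/angle-to-target groups; a unit counts as latent-tuned when
    removing them lowers the held-out R^2 by more than one standard error of
    the paired per-fold differences.
    """
    from .basis import BoxcarBasis

    tv = fwd["task_vars"]
    T, B = next(iter(tv.values())).shape
    mask = (np.arange(T)[:, None] * config.dt) <= fwd["ends"][None, :]

    cols, latent_cols = [], []
    p = 0
    for name, series in tv.items():
        x = series.ravel()
        lo, hi = np.percentile(x, [1, 99])
        bx = BoxcarBasis(lo, hi if hi > lo else lo + 1e-6, n=n_bins)
        cols.append(bx.design(x))
        if name in ("dist_to_target", "angle_to_target"):
            latent_cols.extend(range(p, p + n_bins))
        p += n_bins
    X = np.column_stack(cols + [np.ones(T * B)])
    act = ((fwd["r"][1:] + 1) / 2).reshape(T * B, -1)
    keep = np.ones(X.shape[1], dtype=bool)
    keep[latent_cols] = False

    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(B), n_folds)
    trial_of_row = np.tile(np.arange(B), (T, 1)).ravel()
    row_ok = mask.ravel()

    diffs = np.zeros((n_folds, act.shape[1]))
    for f, val_trials in enumerate(folds):
        vmask = np.isin(trial_of_row, val_trials) & row_ok
        tmask = ~np.isin(trial_of_row, val_trials) & row_ok
        for cols_mask, sign in ((np.ones_like(keep), 1.0), (keep, -1.0)):
            Xt = X[tmask][:, cols_mask]
            G = Xt.T @ Xt + ridge * np.eye(Xt.shape[1])
            W = np.linalg.solve(G, Xt.T @ act[tmask])
            resid = act[vmask] - X[vmask][:, cols_mask] @ W
            var = act[vmask].var(axis=0) + 1e-12
            diffs[f] += sign * (1 - (resid**2).mean(axis=0) / var)
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    return float(np.mean(mean > se))


def rescaled_activity_map(fwd: dict, config: RnnConfig, M: int = 50) -> np.ndarray:
    """Trial-averaged unit activation magnitude |r| on a rescaled-time grid
    from target onset to the deadline, for sequence statistics.  (Magnitude,
    not (r+1)/2: a silent tanh unit should read as inactive, not as tonically
    half-active.)"""
    B = len(fwd["targets"])
    N = fwd["r"].shape[2]
    acc = np.zeros((N, M))
    grid = (np.arange(M) + 0.5) / M
    for b in range(B):
        n_end = max(int(fwd["tstars"][b] / config.dt), 2)
        seg = np.abs(fwd["r"][1:n_end + 1, b])  # (n_end, N)
        pos = np.linspace(0, 1, n_end)
        for i in range(N):
            acc[i] += np.interp(grid, pos, seg[:, i])
    return acc / B


def decode_variable(fwd: dict, name: str, train_frac: float = 0.8,
                    seed: int = 0) -> tuple[float, np.ndarray]:
    """OLS decode of a task variable from unit activities; returns the test
    Pearson r, the weights, and the intercept."""
    from .decoding import LinearPopulationDecoder

    rng = np.random.default_rng(seed)
    B = len(fwd["targets"])
    perm = rng.permutation(B)
    n_tr = int(train_frac * B)
    tr_b, te_b = perm[:n_tr], perm[n_tr:]
    R = fwd["r"][1:]
    x = fwd["task_vars"][name]
    Rtr = R[:, tr_b].reshape(-1, R.shape[2])
    xtr = x[:, tr_b].ravel()
    Rte = R[:, te_b].reshape(-1, R.shape[2])
    xte = x[:, te_b].ravel()
    dec = LinearPopulationDecoder(fit_intercept=True).fit(Rtr, xtr)
    return dec.score(Rte, xte), dec.coef_, dec.intercept_


def per_trial_decode_error(fwd: dict, config: RnnConfig, name: str,
                           weights: np.ndarray,
                           intercept: float = 0.0) -> np.ndarray:
    """Per-trial time-averaged decoding error within the pre-deadline
    window."""
    R = fwd["r"][1:]
    x = fwd["task_vars"][name]
    decoded = R @ weights + intercept
    T, B = x.shape
    out = np.empty(B)
    for b in range(B):
        n_end = min(max(int(fwd["tstars"][b] / config.dt), 2), T)
        out[b] = np.mean(decoded[:n_end, b] - x[:n_end, b])
    return out


def evaluate_network(
    params: RnnParams,
    config: RnnConfig,
    n_trials: int = 300,
    seed: int = 7,
    include_coupling: bool = True,
) -> dict:
    """Analysis battery over fresh trials: behavioral AUC, sequentiality of
    the rescaled activity map, unit tuning (latent fraction, mixed
    selectivity), decoding of target distance, and the decode-error vs
    stopping-error correlation."""
    from scipy import stats as _stats

    from .sequences import rate_map_from_matrix, sequentiality_index

    fwd = run_trials(params, config, n_trials, seed)
    resp = responses_polar(fwd, config)
    targ = _xy_to_polar(fwd["targets"])
    auc = behavioral_auc_from_trials((targ, resp), rng=np.random.default_rng(seed))

    amap = rescaled_activity_map(fwd, config)
    sql = sequentiality_index(rate_map_from_matrix(amap))

    model = unit_tuning_model(fwd, config, include_coupling=include_coupling)
    frac_latent = latent_tuned_fraction(fwd, config)
    pr = mixed_selectivity(model)

    r_dist, w_dist, b_dist = decode_variable(fwd, "dist_to_target")
    derr = per_trial_decode_error(fwd, config, "dist_to_target", w_dist, b_dist)
    beh_err = resp[:, 0] - targ[:, 0]
    r_err = float(_stats.pearsonr(derr, beh_err)[0])

    return dict(auc=auc, sql=sql, latent_tuned_fraction=frac_latent,
                mixed_selectivity=pr, decode_r_dist=float(r_dist),
                r_decode_vs_behavior=r_err, tuning_model=model, fwd=fwd)
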