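"""Linear population decoding of task variables.

Instantaneous firing rates are estimated by convolving each spike train with
a causal exponential filter whose time constant eta is selected (per decoded
variable) on a validation split; ordinary least squares on the training split
gives a weight per neuron, w = (R'R)^-1 R'x, and performance is the Pearson
correlation between decoded and true values on a final test split.  The
error-propagation analyses correlate per-trial time-averaged decoding errors
with behavioral error (stop distance relative to the target) and with each
other (sensory vs latent channels), with a surrogate-mode null that matches
the angle between decoder weight vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, RegressorMixin

from .neural import SessionData

DEFAULT_ETA_GRID = np.geomspace(0.025, 0.250, 8)
DECODABLE = ("dist_to_target", "linear_velocity", "angle_to_target",
             "angular_velocity", "motor_1", "motor_2")


def smooth_rates(counts: np.ndarray, dt: float, eta: float,
                 trial_slices: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Causal exponential smoothing of binned counts into rates (Hz).

    The kernel is unit-normalized so a steady train of rate lambda converges
    to lambda; smoothing restarts at each trial boundary.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    a = np.exp(-dt / eta)
    out = np.empty_like(counts)
    if trial_slices is None:
        trial_slices = [(0, counts.shape[1])]
    for (lo, hi) in trial_slices:
        out[:, lo:hi] = lfilter([1 - a], [1.0, -a], counts[:, lo:hi], axis=1)
    return np.squeeze(out / dt)


class LinearPopulationDecoder(BaseEstimator, RegressorMixin):
    """OLS readout of one task variable from smoothed population rates.

    ``fit(R, x)`` with ``R`` of shape (bins, neurons); ``coef_`` holds the
    per-neuron weights.  If R'R is singular the pseudo-inverse is used and
    ``singular_`` is set.
    """

    def __init__(self, fit_intercept: bool = False):
        self.fit_intercept = fit_intercept

    def fit(self, R: np.ndarray, x: np.ndarray) -> "LinearPopulationDecoder":
        R = np.asarray(R, dtype=float)
        x = np.asarray(x, dtype=float)
        if R.ndim != 2 or R.shape[0] != x.shape[0]:
            raise ValueError("R must be (bins, neurons) aligned with x")
        if not np.any(R):
            raise ValueError("all-zero rate matrix")
        M = np.column_stack([R, np.ones(len(R))]) if self.fit_intercept else R
        gram = M.T @ M
        self.singular_ = bool(np.linalg.matrix_rank(gram) < gram.shape[0])
        if self.singular_:
            warnings.warn("singular R'R: using pseudo-inverse")
            w = np.linalg.pinv(M) @ x
        else:
            w = np.linalg.solve(gram, M.T @ x)
        if self.fit_intercept:
            self.coef_, self.intercept_ = w[:-1], float(w[-1])
        else:
            self.coef_, self.intercept_ = w, 0.0
        return self

    def predict(self, R: np.ndarray) -> np.ndarray:
        return np.asarray(R, dtype=float) @ self.coef_ + self.intercept_

    def score(self, R: np.ndarray, x: np.ndarray) -> float:
        """Pearson correlation between decoded and true values."""
        xh = self.predict(R)
        if np.std(xh) == 0 or np.std(x) == 0:
            return np.nan
        return float(np.corrcoef(xh, x)[0, 1])


@dataclass
class DecoderFit:
    variable: str
    weights: np.ndarray
    eta: float
    split: dict[str, np.ndarray]
    performance: float                  # Pearson r on the test split
    validation_errors: dict[float, float] = field(default_factory=dict)
    intercept: float = 0.0


def split_trials(n_trials: int, seed: int, fractions=(0.8, 0.1, 0.1)) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    n_tr = int(round(fractions[0] * n_trials))
    n_va = int(round(fractions[1] * n_trials))
    return {"train": perm[:n_tr], "val": perm[n_tr:n_tr + n_va],
            "test": perm[n_tr + n_va:]}


def decoding_window_mask(session: SessionData) -> np.ndarray:
    """Bins between target onset and stop, where latent variables are
    defined."""
    mask = np.zeros(session.n_bins, dtype=bool)
    for k, (a, b) in enumerate(session.trial_slices):
        tr = session.trials[k]
        hi = a + min(int(np.ceil(tr.events["stop_time"] / session.dt)), b - a)
        mask[a:hi] = True
    return mask


def select_timescale(
    session: SessionData,
    variable: str,
    eta_grid: np.ndarray = DEFAULT_ETA_GRID,
    seed: int = 0,
    fit_intercept: bool = True,
) -> DecoderFit:
    """Fit the decoder at each smoothing timescale and keep the one that
    minimizes validation decoding error.

    Trials are split 80/10/10 (train/validation/test, seeded); the decoding
    error on a split is ``sqrt(sum_t (w'R_t - x_t)^2)``; test performance is
    the Pearson r of decoded vs true values.
    """
    if session.n_trials < 30:
        raise ValueError("need at least 30 trials to split 80/10/10")
    x_full = session.signals[variable]
    split = split_trials(session.n_trials, seed)
    win = decoding_window_mask(session)
    masks = {k: session.bins_of_trials(v) & win for k, v in split.items()}

    best = None
    val_errors = {}
    for eta in eta_grid:
        R = smooth_rates(session.counts, session.dt, eta, session.trial_slices).T
        dec = LinearPopulationDecoder(fit_intercept=fit_intercept)
        dec.fit(R[masks["train"]], x_full[masks["train"]])
        err = float(np.sqrt(np.sum(
            (dec.predict(R[masks["val"]]) - x_full[masks["val"]]) ** 2)))
        val_errors[float(eta)] = err
        if best is None or err < best[0]:
            best = (err, float(eta), dec, R)
    _, eta_star, dec, R = best
    perf = dec.score(R[masks["test"]], x_full[masks["test"]])
    return DecoderFit(variable=variable, weights=dec.coef_, eta=eta_star,
                      split=split, performance=float(perf),
                      validation_errors=val_errors, intercept=dec.intercept_)


# ---------------------------------------------------------------------------
# error propagation
# ---------------------------------------------------------------------------

def per_trial_decoding_error(
    session: SessionData, fit: DecoderFit, trial_idx: np.ndarray | None = None
) -> np.ndarray:
    """Time-averaged signed decoding error (decoded minus true) per trial,
    over the target-onset-to-stop window."""
    R = smooth_rates(session.counts, session.dt, fit.eta, session.trial_slices).T
    decoded = R @ fit.weights + fit.intercept
    x = session.signals[fit.variable]
    win = decoding_window_mask(session)
    if trial_idx is None:
        trial_idx = np.arange(session.n_trials)
    out = np.empty(len(trial_idx))
    for n, k in enumerate(trial_idx):
        a, b = session.trial_slices[int(k)]
        m = win[a:b]
        out[n] = float(np.mean(decoded[a:b][m] - x[a:b][m]))
    return out


@dataclass
class ErrorAnalysis:
    r_decode_vs_behavior: float
    p_decode_vs_behavior: float
    undershoot_overshoot_auc: float
    r_linear_vs_distance: float
    r_angular_vs_angle: float
    behavioral_error: np.ndarray
    decoding_errors: dict[str, np.ndarray]


def error_analysis(
    session: SessionData,
    fits: dict[str, DecoderFit],
    trial_idx: np.ndarray | None = None,
) -> ErrorAnalysis:
    """Link decoding errors to behavior and to each other.

    Behavioral error is signed as stop distance minus target distance
    (negative = undershoot).  The undershoot/overshoot classification AUC is
    computed from the distribution of target-distance decoding errors via the
    rank (Mann-Whitney) statistic.
    """
    from sklearn.metrics import roc_auc_score

    needed = ("dist_to_target", "linear_velocity", "angle_to_target",
              "angular_velocity")
    for v in needed:
        if v not in fits:
            raise KeyError(f"decoder for '{v}' is required")
    if trial_idx is None:
        trial_idx = np.arange(session.n_trials)
    derr = {v: per_trial_decoding_error(session, fits[v], trial_idx)
            for v in needed}
    beh = np.array([session.trials[int(k)].response_polar[0]
                    - session.trials[int(k)].target_polar[0] for k in trial_idx])

    # an underestimated distance-to-target (negative decoding error) means
    # the population believes it has arrived early -> stop short (undershoot)
    d_dist = derr["dist_to_target"]
    r_beh, p_beh = stats.pearsonr(d_dist, beh)

    over = beh > 0
    if over.all() or not over.any():
        warnings.warn("no undershoot/overshoot contrast: AUC undefined")
        auc = np.nan
    else:
        auc = float(roc_auc_score(over.astype(int), d_dist))

    r_lin = float(stats.pearsonr(derr["linear_velocity"],
                                 derr["dist_to_target"])[0])
    r_ang = float(stats.pearsonr(derr["angular_velocity"],
                                 derr["angle_to_target"])[0])
    return ErrorAnalysis(float(r_beh), float(p_beh), auc, r_lin, r_ang,
                         beh, derr)


def surrogate_angle_null(
    w_a: np.ndarray,
    w_b: np.ndarray,
    activity: np.ndarray,
    trial_slices: list[tuple[int, int]],
    n_surrogate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of error-proxy correlations from random mode pairs
    separated by the same angle as the two decoders.

    Draw a random unit direction u and a random unit u_perp orthogonal to it,
    set v = cos(phi) u + sin(phi) u_perp with phi the decoder angle, project
    the activity onto (u, v), and correlate per-trial mean projections.
    """
    w_a = np.asarray(w_a, float)
    w_b = np.asarray(w_b, float)
    na, nb = np.linalg.norm(w_a), np.linalg.norm(w_b)
    if na == 0 or nb == 0:
        raise ValueError("decoder angle undefined for zero weight vectors")
    phi = np.arccos(np.clip(w_a @ w_b / (na * nb), -1, 1))
    N = w_a.size
    out = np.empty(n_surrogate)
    for s in range(n_surrogate):
        u = rng.standard_normal(N)
        u /= np.linalg.norm(u)
        q = rng.standard_normal(N)
        q -= (q @ u) * u
        q /= np.linalg.norm(q)
        v = np.cos(phi) * u + np.sin(phi) * q
        pu = activity @ u
        pv = activity @ v
        mu = np.array([pu[a:b].mean() for a, b in trial_slices])
        mv = np.array([pv[a:b].mean() for a, b in trial_slices])
        out[s] = np.corrcoef(mu, mv)[0, 1]
    return out


def decoder_angle(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """Angle (radians) between unit-normalized weight vectors."""
    w_a, w_b = np.asarray(w_a, float), np.asarray(w_b, float)
    return float(np.arccos(np.clip(
        w_a @ w_b / (np.linalg.norm(w_a) * np.linalg.norm(w_b)), -1, 1)))
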