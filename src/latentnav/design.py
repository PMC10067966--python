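"""Design matrices for the coupled Poisson encoding model.

Continuous variables enter through boxcar indicator columns; events, motor
channels, spike histories, and other neurons' spike trains enter through
convolution with their raised-cosine bases.  The resulting model is linear in
all coefficients (the generalized-additive formulation is a GLM on this
expanded design).  All convolutions are computed within trial epochs so
filters never leak across trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import fftconvolve

from . import basis as _basis

if TYPE_CHECKING:
    from .neural import SessionData

TUNING_VARS = (
    "linear_velocity", "angular_velocity", "dist_to_target", "angle_to_target",
    "lfp_phase", "gaze_x", "gaze_y",
)
MOTOR_VARS = ("motor_1", "motor_2")
EVENTS = ("target_on", "reward")


@dataclass(frozen=True)
class Group:
    """A predictor group: one backward-elimination unit (coupling filters of
    all source neurons form a single group)."""

    name: str
    kind: str  # tuning | event | motor | history | coupling
    sl: slice
    basis: object | None = None
    source: int | None = None  # source neuron for coupling columns


def _conv_columns(
    series: np.ndarray,
    trial_slices: list[tuple[int, int]],
    cbasis: _basis.CosineBasis,
) -> np.ndarray:
    """Convolve a session-long series with each basis filter, per trial.

    Column t of the output is ``sum_k B[k] * series[t - k]`` over the basis
    lag grid (negative lags reach into the future for acausal filters);
    contributions are zero-padded at trial edges.
    """
    T = series.shape[0]
    K = cbasis.B
    k_min = int(np.round(cbasis.lags[0] / cbasis.dt))
    out = np.zeros((T, K.shape[1]), dtype=np.float32)
    for (a, b) in trial_slices:
        y = series[a:b]
        full = fftconvolve(y[:, None], K, axes=0)
        idx = np.arange(b - a) - k_min
        valid = (idx >= 0) & (idx < full.shape[0])
        seg = np.zeros((b - a, K.shape[1]), dtype=np.float32)
        seg[valid] = full[idx[valid]]
        out[a:b] = seg
    return out


def tuning_ranges_from_session(
    session: "SessionData", variables: tuple[str, ...] = TUNING_VARS
) -> dict[str, tuple[float, float]]:
    """Per-variable boxcar ranges: 1st-99th percentile over the session
    (avoids empty outer bins); LFP phase keeps its full circular domain."""
    out = {}
    for v in variables:
        if v == "lfp_phase":
            out[v] = (-180.0, 180.0)
        else:
            x = session.signals[v]
            lo, hi = np.percentile(x, [1, 99])
            if hi <= lo:
                hi = lo + 1e-6
            out[v] = (float(lo), float(hi))
    return out


def exogenous_design(
    session: "SessionData",
    ranges: dict[str, tuple[float, float]] | None = None,
    variables: tuple[str, ...] = TUNING_VARS,
    motor: tuple[str, ...] = MOTOR_VARS,
    events: tuple[str, ...] = EVENTS,
    n_boxcars: int = 10,
) -> tuple[np.ndarray, list[Group]]:
    """Spike-independent design columns shared by all neurons.

    Layout: boxcar indicators per continuous variable, then event-filter
    columns (causal basis for target onset, acausal otherwise), then acausal
    motor-channel kernel columns.
    """
    if ranges is None:
        ranges = tuning_ranges_from_session(session, variables)
    dt = session.dt
    cols: list[np.ndarray] = []
    groups: list[Group] = []
    p = 0

    for v in variables:
        if v not in session.signals:
            raise KeyError(f"session is missing continuous channel '{v}'")
        bx = _basis.BoxcarBasis(*ranges[v], n=n_boxcars, circular=v in ("lfp_phase",))
        X = bx.design(session.signals[v])
        cols.append(X)
        groups.append(Group(v, "tuning", slice(p, p + X.shape[1]), bx))
        p += X.shape[1]

    for e in events:
        if e not in session.events:
            raise KeyError(f"session is missing event channel '{e}'")
        eb = _basis.event_basis(dt, causal=(e == "target_on"))
        X = _conv_columns(session.events[e], session.trial_slices, eb)
        cols.append(X)
        groups.append(Group(e, "event", slice(p, p + X.shape[1]), eb))
        p += X.shape[1]

    mb = _basis.event_basis(dt, causal=False)
    for m in motor:
        if m not in session.signals:
            raise KeyError(f"session is missing motor channel '{m}'")
        X = _conv_columns(session.signals[m], session.trial_slices, mb)
        cols.append(X)
        groups.append(Group(m, "motor", slice(p, p + X.shape[1]), mb))
        p += X.shape[1]

    return np.concatenate(cols, axis=1, dtype=np.float32), groups


class SpikeConvCache:
    """Per-neuron history- and coupling-basis spike convolutions, computed
    once per session and shared across all target-neuron fits."""

    def __init__(self, session: "SessionData"):
        hb = _basis.history_basis(session.dt)
        cb = _basis.coupling_basis(session.dt)
        self.hist = [
            _conv_columns(session.counts[j].astype(np.float32),
                          session.trial_slices, hb)
            for j in range(session.n_neurons)
        ]
        self.coup = [
            _conv_columns(session.counts[j].astype(np.float32),
                          session.trial_slices, cb)
            for j in range(session.n_neurons)
        ]
        self.hist_basis = hb
        self.coup_basis = cb


def neuron_design(
    session: "SessionData",
    neuron: int,
    cache: SpikeConvCache | None = None,
    coupled: bool = True,
    spike_history: bool = True,
    ranges: dict[str, tuple[float, float]] | None = None,
    variables: tuple[str, ...] = TUNING_VARS,
    motor: tuple[str, ...] = MOTOR_VARS,
    events: tuple[str, ...] = EVENTS,
    exo: tuple[np.ndarray, list[Group]] | None = None,
) -> tuple[np.ndarray, list[Group]]:
    """Full design for one target neuron (exogenous + history + coupling).

    ``exo`` and ``cache`` allow sharing the expensive shared blocks across
    neurons.  Coupling columns for all source neurons belong to one group
    (selection removes them together), but per-source sub-slices are recorded
    as separate ``coupling`` entries with ``source`` set.
    """
    if exo is None:
        exo = exogenous_design(session, ranges, variables, motor, events)
    X_exo, groups_exo = exo
    if cache is None:
        cache = SpikeConvCache(session)

    cols = [X_exo]
    groups = list(groups_exo)
    p = X_exo.shape[1]
    if spike_history:
        H = cache.hist[neuron]
        cols.append(H)
        groups.append(Group("spike_history", "history", slice(p, p + H.shape[1]),
                            cache.hist_basis))
        p += H.shape[1]
    if coupled:
        for j in range(session.n_neurons):
            if j == neuron:
                continue
            C = cache.coup[j]
            cols.append(C)
            groups.append(Group(f"coupling_{j}", "coupling",
                                slice(p, p + C.shape[1]), cache.coup_basis, source=j))
            p += C.shape[1]
    return np.concatenate(cols, axis=1, dtype=np.float32), groups
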