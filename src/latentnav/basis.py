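"""Basis functions for tuning curves and temporal filters.

Continuous-variable tuning functions are piecewise constant on ten boxcar
(indicator) functions spanning the observed range of the predictor.  Temporal
filters (event responses, spike history, inter-neuronal coupling) are weighted
sums of raised-cosine bumps, linearly spaced for event filters and
logarithmically spaced for history/coupling filters so that fine structure is
resolved at short lags and coarse structure at long lags.  A separate
seven-exponential basis (decay constants 6..384 ms, octave spaced) is used
only to re-express fitted coupling filters when summarizing their timescale
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: decay constants (seconds) of the exponential re-expression basis
EXP7_TAUS = np.array([0.006, 0.012, 0.024, 0.048, 0.096, 0.192, 0.384])


@dataclass(frozen=True)
class BoxcarBasis:
    """Equal-width indicator functions partitioning ``[lo, hi]``.

    Values outside the range are clipped into the outer bins so the boxcars
    always partition the data exactly (each sample activates one column).
    ``circular`` marks variables (LFP phase) whose smoothness penalty wraps
    around the domain edges.
    """

    lo: float
    hi: float
    n: int = 10
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError(f"degenerate boxcar range [{self.lo}, {self.hi}]")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def bin_index(self, x: np.ndarray) -> np.ndarray:
        """Index of the active boxcar for each sample (clipped at the edges)."""
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.lo) / (self.hi - self.lo) * self.n).astype(np.int64)
        return np.clip(idx, 0, self.n - 1)

    def design(self, x: np.ndarray) -> np.ndarray:
        """(T, n) one-hot indicator matrix."""
        idx = self.bin_index(x)
        out = np.zeros((idx.size, self.n), dtype=np.float32)
        out[np.arange(idx.size), idx] = 1.0
        return out

    def evaluate(self, weights: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.asarray(weights, dtype=float)[self.bin_index(x)]


def raised_cosine_basis(
    n: int,
    t_min: float,
    t_max: float,
    dt: float,
    log_spaced: bool = False,
    log_offset: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine bump basis sampled on a lag grid.

    Returns ``(lags, B)`` where ``lags`` is the grid ``t_min .. t_max`` at step
    ``dt`` and ``B`` has shape ``(len(lags), n)``.  Bumps are
    ``0.5*(1+cos(pi*(phi - c_j)/w))`` restricted to ``|phi - c_j| <= w`` in
    warped time ``phi`` (identity warp, or ``log(t - t_min + log_offset)`` for
    log spacing), with half-width ``w`` equal to twice the center spacing so
    adjacent bumps overlap and the basis tiles its support.
    """
    if n < 2:
        raise ValueError("need at least two basis functions")
    lags = np.arange(np.round(t_min / dt), np.round(t_max / dt) + 1) * dt

    if log_spaced:
        if t_min < 0:
            raise ValueError("log spacing requires a causal (t_min >= 0) support")
        warp = lambda t: np.log(t - t_min + log_offset)  # noqa: E731
    else:
        warp = lambda t: t  # noqa: E731

    phi = warp(lags)
    centers = np.linspace(phi[0], phi[-1], n)
    width = 2.0 * (centers[1] - centers[0])
    arg = (phi[:, None] - centers[None, :]) / width
    B = 0.5 * (1.0 + np.cos(np.pi * np.clip(arg, -1.0, 1.0)))
    B[np.abs(arg) >= 1.0] = 0.0
    return lags, B


@dataclass(frozen=True)
class CosineBasis:
    """A raised-cosine filter basis on a lag grid at resolution ``dt``.

    ``t_min < 0`` yields a non-causal (acausal) filter; causal bases for spike
    history and coupling start at one bin of lag (a filter may not act on the
    bin it is predicting).
    """

    n: int
    t_min: float
    t_max: float
    dt: float
    log_spaced: bool = False
    lags: np.ndarray = field(init=False, repr=False, compare=False)
    B: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lags, B = raised_cosine_basis(
            self.n, self.t_min, self.t_max, self.dt, self.log_spaced
        )
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "B", B)

    def reconstruct(self, coef: np.ndarray) -> np.ndarray:
        """Filter values on the lag grid for coefficient vector ``coef``."""
        return self.B @ np.asarray(coef, dtype=float)


def event_basis(dt: float, causal: bool) -> CosineBasis:
    """Ten raised cosines spanning 600 ms: [0, 600] ms for target onset
    (causal), [-300, 300] ms for other events and motor-channel kernels."""
    if causal:
        return CosineBasis(10, 0.0, 0.600, dt)
    return CosineBasis(10, -0.300, 0.300, dt)


def history_basis(dt: float) -> CosineBasis:
    """Ten causal log-spaced raised cosines spanning 350 ms."""
    return CosineBasis(10, dt, 0.350, dt, log_spaced=True)


def coupling_basis(dt: float) -> CosineBasis:
    """Ten causal log-spaced raised cosines spanning 1.375 s."""
    return CosineBasis(10, dt, 1.375, dt, log_spaced=True)


def exp7_basis(dt: float, t_max: float = 1.375) -> tuple[np.ndarray, np.ndarray]:
    """Seven exponentials with octave-spaced decay constants 6..384 ms."""
    lags = np.arange(1, int(np.round(t_max / dt)) + 1) * dt
    B = np.exp(-lags[:, None] / EXP7_TAUS[None, :])
    return lags, B
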