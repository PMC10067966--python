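"""Time-rescaled population rate maps and sequence statistics.

Because trial durations vary, spike times between target onset and movement
end are rescaled to [0, 1] before trial-averaging, yielding a neurons x bins
rate map per trial group.  Sequentiality is the geometric mean of peak
sparseness (normalized entropy of the distribution of peak-activity bins
across neurons) and temporal sparseness (one minus the mean normalized
entropy of the across-neuron activity distribution per bin); it is 1 for an
ideal one-neuron-per-bin sequence and 0 when all peaks coincide or activity
is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neural import SessionData
from .task import Trial


@dataclass
class RateMap:
    """Trial-averaged, peak-normalized rescaled-time rate map."""

    values: np.ndarray                 # (N, M), each row's max is 1 (if active)
    sort_order: np.ndarray             # permutation by peak time
    group_label: str = ""
    silent: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def sorted_values(self) -> np.ndarray:
        return self.values[self.sort_order]


def trial_group_indices(session: SessionData, group: str) -> np.ndarray:
    """Built-in trial groupings: nearby/distant (target distance median
    split), leftward/rightward (target angle sign), odd/even."""
    tr = session.trials
    r = np.array([t.target_polar[0] for t in tr])
    th = np.array([t.target_polar[1] for t in tr])
    idx = np.arange(len(tr))
    if group == "nearby":
        return idx[r <= np.median(r)]
    if group == "distant":
        return idx[r > np.median(r)]
    if group == "leftward":
        return idx[th < 0]
    if group == "rightward":
        return idx[th >= 0]
    if group == "odd":
        return idx[1::2]
    if group == "even":
        return idx[::2]
    raise KeyError(f"unknown trial group '{group}'")


def build_rate_map(
    session: SessionData,
    trial_idx: np.ndarray | str,
    M: int = 50,
    normalize: bool = True,
    sort: bool = True,
) -> RateMap:
    """Rescaled-time rate map over the given trials.

    Per trial, spikes between target onset and movement end are mapped to
    [0, 1] and histogrammed into ``M`` bins (divided by the rescaled bin
    duration so longer trials do not weigh more); bins are averaged across
    trials, each row is normalized by its peak, and rows are sorted by peak
    bin (earliest bin of the maximum breaks ties).  Silent neurons keep a
    zero row and are flagged.
    """
    label = trial_idx if isinstance(trial_idx, str) else ""
    if isinstance(trial_idx, str):
        trial_idx = trial_group_indices(session, trial_idx)
    trial_idx = np.asarray(trial_idx)
    if trial_idx.size < 5:
        raise ValueError("need at least 5 trials in the group")

    N = session.n_neurons
    acc = np.zeros((N, M))
    for k in trial_idx:
        tr = session.trials[int(k)]
        a, _ = session.trial_slices[int(k)]
        t0 = a * session.dt
        lo = t0 + tr.events["target_on"]
        hi = t0 + tr.events["stop_time"]
        span = max(hi - lo, session.dt)
        for i in range(N):
            st = session.spike_times[i]
            s = st[(st >= lo) & (st < hi)]
            u = (s - lo) / span
            acc[i] += np.histogram(u, bins=M, range=(0, 1))[0] / (span / M)
    acc /= trial_idx.size

    peaks = acc.max(axis=1)
    silent = peaks <= 0
    if silent.any():
        warnings.warn(f"{int(silent.sum())} silent neurons in rate map")
    values = acc.copy()
    if normalize:
        values[~silent] /= peaks[~silent, None]
    order = np.argsort(np.argmax(values, axis=1), kind="stable") if sort \
        else np.arange(N)
    return RateMap(values=values, sort_order=order, group_label=str(label),
                   silent=silent)


def rate_map_from_matrix(values: np.ndarray, normalize: bool = True) -> RateMap:
    """Wrap a precomputed (N, M) activity matrix (e.g. network unit
    activities on a rescaled-time grid) as a RateMap."""
    values = np.array(values, dtype=float)
    peaks = values.max(axis=1)
    silent = peaks <= 0
    if normalize:
        values[~silent] /= peaks[~silent, None]
    order = np.argsort(np.argmax(values, axis=1), kind="stable")
    return RateMap(values=values, sort_order=order, silent=silent)


def sequentiality_index(rate_map: RateMap | np.ndarray) -> float:
    """Sequentiality Sql = sqrt(f_temp * f_peak) in [0, 1].

    f_peak is the entropy of the peak-bin distribution over the M bins,
    normalized by log M; f_temp is one minus the bin-averaged normalized
    entropy of the per-bin across-neuron activity distribution.  Natural
    logs; 0*log(0) = 0; peak ties break to the earliest bin.  Silent neurons
    are excluded.
    """
    values = rate_map.values if isinstance(rate_map, RateMap) else np.asarray(rate_map, float)
    values = values[values.max(axis=1) > 0]
    N, M = values.shape
    if N < 2 or M < 2:
        raise ValueError("need at least 2 active neurons and 2 bins")

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    peak_bins = np.argmax(values, axis=1)
    p_t = np.bincount(peak_bins, minlength=M) / N
    f_peak = entropy(p_t) / np.log(M)

    col_sums = values.sum(axis=0)
    ent = np.zeros(M)
    active = col_sums > 0
    for t in np.flatnonzero(active):
        ent[t] = entropy(values[:, t] / col_sums[t]) / np.log(N)
    # bins with no activity carry no neurons: maximally sparse by convention
    f_temp = 1.0 - float(ent[active].mean()) if active.any() else 0.0
    return float(np.sqrt(max(f_temp, 0.0) * max(f_peak, 0.0)))


def pattern_similarity(
    map_a: RateMap | np.ndarray, map_b: RateMap | np.ndarray
) -> tuple[float, np.ndarray]:
    """Correlation between two rate maps with matching neuron order.

    Returns the overall Pearson correlation of the flattened maps and the
    per-bin timecourse (correlation between the population vectors in each
    rescaled-time column; nan where a column has zero variance).
    """
    A = map_a.values if isinstance(map_a, RateMap) else np.asarray(map_a, float)
    B = map_b.values if isinstance(map_b, RateMap) else np.asarray(map_b, float)
    if A.shape != B.shape:
        raise ValueError("maps must share neuron order and bin count")
    overall = float(np.corrcoef(A.ravel(), B.ravel())[0, 1])
    M = A.shape[1]
    tc = np.full(M, np.nan)
    for t in range(M):
        if np.std(A[:, t]) > 0 and np.std(B[:, t]) > 0:
            tc[t] = np.corrcoef(A[:, t], B[:, t])[0, 1]
    if np.isnan(tc).any():
        warnings.warn("zero-variance columns in pattern similarity timecourse")
    return overall, tc


def cross_correlation(
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    max_lag: int,
    baseline: str = "target",
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-train cross-correlation R_ij(tau) on binned counts.

    With ``baseline='target'`` (as printed in the source formula),
    ``R_ij(tau) = (1/(T rbar_i)) sum_t r_i(t) r_j(t - tau) - rbar_i`` with
    zero padding at the edges and T the total bin count; the i = j case is
    the autocorrelation.  Note this baseline leaves independent trains at
    ``rbar_j - rbar_i`` rather than zero; ``baseline='source'`` subtracts
    ``rbar_j`` instead, which zeroes the independent-train expectation.

    Returns ``(lags, R)``.
    """
    ri = np.asarray(counts_i, dtype=float)
    rj = np.asarray(counts_j, dtype=float)
    T = ri.size
    rbar_i = ri.mean()
    rbar_j = rj.mean()
    if rbar_i == 0:
        raise ValueError("silent reference neuron: R_ij undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    R = np.empty(lags.size)
    for k, tau in enumerate(lags):
        if tau >= 0:
            s = ri[tau:] @ rj[: T - tau]
        else:
            s = ri[: T + tau] @ rj[-tau:]
        R[k] = s / (T * rbar_i)
    R -= rbar_i if baseline == "target" else rbar_j
    return lags, R


def peak_to_trough(R: np.ndarray) -> float:
    return float(np.max(R) - np.min(R))
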