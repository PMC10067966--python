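"""Behavioral performance metrics.

Navigation accuracy is summarized two ways: (i) ordinary least-squares
regression of response location on target location (slope near one indicates
an unbiased subject) and (ii) a shuffle-referenced ROC analysis.  For the ROC,
a psychometric curve gives the proportion of trials whose stopping error falls
within a hypothetical reward boundary swept over 0-4 m; plotting the true
curve against the curve obtained after shuffling target-response pairings
yields an ROC curve whose area (AUC) is 0.5 at chance and 1 for error-free
responses, independent of target difficulty and boundary parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import Trial, active_trials


def _targets_responses(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray]:
    use = active_trials(trials)
    targets = np.array([t.target_polar for t in use])
    responses = np.array([t.response_polar for t in use])
    return targets, responses


@dataclass
class RegressionResult:
    slope_radial: float
    slope_angular: float
    r_radial: float
    r_angular: float
    intercept_radial: float
    intercept_angular: float
    slope_radial_origin: float  # through-origin slope, also reported
    slope_angular_origin: float
    degenerate: bool = False


def response_regression(trials: list[Trial]) -> RegressionResult:
    """OLS slopes and Pearson correlations of response vs target location.

    Radial: response r on target r*; angular: response theta on target
    theta*; origin at the trial start.  An intercept is included, and the
    through-origin slope is reported alongside.
    """
    targets, responses = _targets_responses(trials)
    if len(targets) < 3:
        raise ValueError("need at least 3 non-excluded trials")

    def fit(x, y):
        if np.ptp(x) == 0:
            return np.nan, np.nan, np.nan, np.nan, True
        res = stats.linregress(x, y)
        slope0 = float(np.dot(x, y) / np.dot(x, x))
        return res.slope, res.intercept, res.rvalue, slope0, False

    sr, ir, rr, sr0, d1 = fit(targets[:, 0], responses[:, 0])
    sa, ia, ra, sa0, d2 = fit(targets[:, 1], responses[:, 1])
    return RegressionResult(sr, sa, rr, ra, ir, ia, sr0, sa0, degenerate=d1 or d2)


@dataclass
class PsychometricCurve:
    """Proportion correct vs hypothetical reward boundary, true and shuffled."""

    boundaries: np.ndarray
    p_correct_true: np.ndarray
    p_correct_shuffled: np.ndarray


def _polar_to_xy(polar: np.ndarray) -> np.ndarray:
    th = np.deg2rad(polar[:, 1])
    return np.column_stack([polar[:, 0] * np.sin(th), polar[:, 0] * np.cos(th)])


def _errors(targets: np.ndarray, responses: np.ndarray) -> np.ndarray:
    return np.linalg.norm(_polar_to_xy(responses) - _polar_to_xy(targets), axis=1)


def psychometric_curve(
    trials: list[Trial] | tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | int = 0,
    n_boundaries: int = 200,
    max_boundary: float = 4.0,
    n_shuffles: int = 1,
) -> PsychometricCurve:
    """True and target-shuffled psychometric curves.

    Accepts either a trial list or a ``(targets, responses)`` pair of
    ``(n, 2)`` polar arrays.  The shuffled curve permutes target assignments
    across trials (one permutation by default; ``n_shuffles > 1`` averages).
    A trial is counted correct at boundary b when its stopping error is <= b.
    """
    if isinstance(trials, tuple):
        targets, responses = trials
    else:
        targets, responses = _targets_responses(trials)
    if len(targets) < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    boundaries = np.linspace(0.0, max_boundary, n_boundaries)
    err_true = _errors(targets, responses)
    p_true = np.mean(err_true[None, :] <= boundaries[:, None], axis=1)

    p_shuf = np.zeros_like(boundaries)
    n = len(targets)
    for _ in range(n_shuffles):
        # random derangement (cyclic shift of a random permutation): no trial
        # keeps its own target, so the pairing is fully destroyed
        p = rng.permutation(n)
        perm = np.empty(n, dtype=int)
        perm[p] = p[np.roll(np.arange(n), 1)]
        err_s = _errors(targets[perm], responses)
        p_shuf += np.mean(err_s[None, :] <= boundaries[:, None], axis=1)
    p_shuf /= n_shuffles

    return PsychometricCurve(boundaries, p_true, p_shuf)


def behavioral_auc(curve: PsychometricCurve) -> float:
    """Area under the ROC curve of true vs shuffled proportion correct.

    The curve is anchored at (0, 0) and (1, 1) before trapezoidal
    integration; 0.5 is chance, 1 is error-free performance.
    """
    x = np.concatenate([[0.0], curve.p_correct_shuffled, [1.0]])
    y = np.concatenate([[0.0], curve.p_correct_true, [1.0]])
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def behavioral_auc_from_trials(
    trials: list[Trial] | tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | int = 0,
    **kwargs,
) -> float:
    return behavioral_auc(psychometric_curve(trials, rng=rng, **kwargs))
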