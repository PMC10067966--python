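"""Coupled Poisson generalized additive encoding model.

Each neuron's log firing rate is a sum of nonlinear tuning functions of
continuous task variables, temporal filters of discrete events and motor
channels, a causal spike-history filter, and (in the coupled variant) causal
coupling filters from every other recorded neuron.  Fitting maximizes the
Poisson log likelihood plus log priors: Gaussian on the first differences of
tuning-function weights and of temporal-filter values (smoothness), and
Laplace on coupling coefficients (sparseness).  The problem is convex, so the
MAP estimate is unique up to optimizer tolerance.

The penalized objective, with hyperparameters ``lambda_tuning`` for tuning
functions, ``gamma_event`` for event/motor filters, ``alpha_history`` for the
spike-history filter, and ``beta_coupling`` for the L1 coupling term, is

    -loglik + sum_k lambda_k |D f_k|^2 + sum_l gamma_l |D g_l|^2
            + alpha |D h|^2 + beta sum |p|_1

where ``D`` takes first differences (wrapped across the domain edges for the
circular LFP-phase variable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator

from . import basis as _basis
from .design import (
    EVENTS,
    MOTOR_VARS,
    TUNING_VARS,
    Group,
    SpikeConvCache,
    exogenous_design,
    neuron_design,
    tuning_ranges_from_session,
)
from .neural import SessionData

#: coefficients with magnitude below this are treated as numerically zero
ZERO_TOL = 1e-6


@dataclass(frozen=True)
class Hyperparams:
    """Penalty weights of the MAP objective."""

    lambda_tuning: float = 100.0
    gamma_event: float = 10.0
    alpha_history: float = 10.0
    beta_coupling: float = 10.0

    def __post_init__(self) -> None:
        if min(self.lambda_tuning, self.gamma_event,
               self.alpha_history, self.beta_coupling) < 0:
            raise ValueError("hyperparameters must be non-negative")


def _first_diff(n: int, circular: bool = False) -> np.ndarray:
    D = np.zeros((n if circular else n - 1, n))
    for i in range(n - 1):
        D[i, i], D[i, i + 1] = -1.0, 1.0
    if circular:
        D[n - 1, n - 1], D[n - 1, 0] = -1.0, 1.0
    return D


GAUGE_RIDGE = 0.5  # pins the additive gauge between tuning means and baseline


def penalty_matrix(groups: list[Group], n_cols: int, hp: Hyperparams) -> np.ndarray:
    """Block-diagonal quadratic smoothness penalty Q (coupling gets none;
    its Laplace prior is handled as an L1 term in the solver).

    Each boxcar group's columns sum to the intercept, so a constant shift of
    any tuning function is exactly absorbed by the baseline; a small ridge on
    tuning weights fixes this gauge at zero-mean tuning without affecting
    tuning shape.
    """
    Q = np.zeros((n_cols, n_cols))
    for g in groups:
        n = g.sl.stop - g.sl.start
        if g.kind == "tuning":
            D = _first_diff(n, circular=getattr(g.basis, "circular", False))
            Q[g.sl, g.sl] += hp.lambda_tuning * D.T @ D
            Q[g.sl, g.sl] += GAUGE_RIDGE * np.eye(n)
        elif g.kind in ("event", "motor", "history"):
            B = g.basis.B
            DB = np.diff(B, axis=0)
            w = hp.alpha_history if g.kind == "history" else hp.gamma_event
            Q[g.sl, g.sl] += w * DB.T @ DB
    return Q


def _l1_mask(groups: list[Group], n_cols: int) -> np.ndarray:
    m = np.zeros(n_cols, dtype=bool)
    for g in groups:
        if g.kind == "coupling":
            m[g.sl] = True
    return m


def poisson_nll(eta: np.ndarray, y: np.ndarray) -> float:
    """Poisson negative log likelihood up to the log(y!) constant, with the
    rate given by exp(eta) per bin."""
    return float(np.exp(eta).sum() - y @ eta)


def _cd_lasso(
    S: np.ndarray,
    g: np.ndarray,
    w: np.ndarray,
    beta: float,
    n_sweeps: int = 200,
    tol: float = 1e-9,
) -> np.ndarray:
    """Coordinate descent for ``min_d 1/2 d'Sd + g'd + beta*|w + d|_1``.

    Returns ``d``; zeros of ``w + d`` are exact via soft-thresholding.
    """
    n = len(w)
    d = np.zeros(n)
    r = np.zeros(n)  # running S @ d
    diag = np.maximum(np.diag(S), 1e-12)
    for _ in range(n_sweeps):
        max_delta = 0.0
        for j in range(n):
            a = diag[j]
            # gradient of the quadratic part wrt d_j, excluding its own term
            s = g[j] + r[j] - a * d[j]
            target = -s / a  # unpenalized minimizer of d_j
            uj = w[j] + target
            uj = np.sign(uj) * max(abs(uj) - beta / a, 0.0)
            dj_new = uj - w[j]
            delta = dj_new - d[j]
            if delta != 0.0:
                r += S[:, j] * delta
                d[j] = dj_new
                max_delta = max(max_delta, abs(delta) * np.sqrt(a))
        if max_delta < tol:
            break
    return d


def _newton_direction(
    H: np.ndarray,
    grad: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    sm_idx: np.ndarray,
    l1_idx: np.ndarray,
) -> np.ndarray:
    """Minimize the local model ``1/2 d'Hd + grad'd + beta|w+d|_1``.

    The unpenalized (smooth) block is eliminated exactly through its
    Cholesky factor; coordinate descent then runs only on the L1 coordinates
    against the Schur complement, which keeps the subproblem small and
    well-behaved.
    """
    import scipy.linalg as sla

    d = np.zeros_like(w)
    H_ss = H[np.ix_(sm_idx, sm_idx)]
    cho = sla.cho_factor(H_ss, lower=True, check_finite=False)
    g_s = grad[sm_idx]
    if l1_idx.size == 0:
        d[sm_idx] = -sla.cho_solve(cho, g_s, check_finite=False)
        return d
    H_sc = H[np.ix_(sm_idx, l1_idx)]
    Z = sla.cho_solve(cho, H_sc, check_finite=False)        # H_ss^-1 H_sc
    S = H[np.ix_(l1_idx, l1_idx)] - H_sc.T @ Z               # Schur complement
    g_c = grad[l1_idx] - Z.T @ g_s
    beta_c = float(beta[l1_idx[0]])
    d_c = _cd_lasso(S, g_c, w[l1_idx], beta_c)
    d[l1_idx] = d_c
    d[sm_idx] = -sla.cho_solve(cho, g_s + H_sc @ d_c, check_finite=False)
    return d


def fit_map(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[Group],
    hp: Hyperparams = Hyperparams(),
    w0: np.ndarray | None = None,
    max_iter: int = 60,
    ftol: float = 1e-9,
    eta_cap: float = 20.0,
) -> np.ndarray:
    """MAP coefficient estimate (including a trailing intercept).

    Proximal Newton: each outer iteration forms the exact Hessian of the
    smooth part (Poisson likelihood plus quadratic smoothness priors) and
    solves the L1-penalized quadratic model by coordinate descent with
    soft-thresholding, so coupling coefficients shrunk by the Laplace prior
    become exactly zero.  A backtracking line search on the true objective
    guarantees monotone progress; the problem is convex, so the result is
    optimizer-independent to tolerance.  Returns coefficients of length
    ``X.shape[1] + 1``.
    """
    T, p0 = X.shape
    y = np.asarray(y, dtype=np.float64)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    ones = np.ones((T, 1), dtype=np.float32)
    Xa = np.hstack([X32, ones])  # intercept as final column
    p = p0 + 1

    Q = np.zeros((p, p))
    Q[:p0, :p0] = penalty_matrix(groups, p0, hp)
    beta = np.zeros(p)
    beta[: p0][_l1_mask(groups, p0)] = hp.beta_coupling

    l1_idx = np.flatnonzero(beta > 0)
    sm_idx = np.flatnonzero(beta == 0)

    w_cold = np.zeros(p)
    w_cold[-1] = np.log(max(y.mean(), 1e-4))

    def objective(wv):
        eta = np.clip((Xa @ wv.astype(np.float32)).astype(np.float64), -40, eta_cap)
        mu = np.exp(eta)
        return (float(mu.sum() - y @ eta) + wv @ (Q @ wv)
                + float(beta @ np.abs(wv))), eta, mu

    w = w_cold
    F, eta, mu = objective(w)
    if w0 is not None:
        # warm start, unless it is worse than the cold start (a bad start in
        # the rate-clipped regime would stall the Newton model)
        w0 = np.asarray(w0, dtype=np.float64).copy()
        F0, eta0, mu0 = objective(w0)
        if np.isfinite(F0) and F0 < F:
            w, F, eta, mu = w0, F0, eta0, mu0
    converged = False
    for _ in range(max_iter):
        r = (mu - y).astype(np.float32)
        grad = (Xa.T @ r).astype(np.float64) + 2.0 * (Q @ w)
        Xw = Xa * np.sqrt(mu, dtype=np.float64).astype(np.float32)[:, None]
        H = (Xw.T @ Xw).astype(np.float64) + 2.0 * Q
        H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / p

        d = _newton_direction(H, grad, w, beta, sm_idx, l1_idx)
        u = w + d
        # model-predicted decrease (Newton decrement analogue); computed in
        # float64 so it is immune to the float32 objective noise
        pred_dec = -(grad @ d + 0.5 * d @ (H @ d)
                     + beta @ (np.abs(u) - np.abs(w)))
        if pred_dec <= ftol * (abs(F) + 1.0):
            converged = True
            break
        step = 1.0
        for _ in range(30):
            F_new, eta_new, mu_new = objective(w + step * d)
            if F_new <= F + 1e-10 * (abs(F) + 1.0):
                break
            step *= 0.5
        else:
            converged = True  # no further descent possible at machine precision
            break
        w = w + step * d
        F, eta, mu = F_new, eta_new, mu_new
    if not converged:
        raise RuntimeError(
            f"MAP fit did not converge within {max_iter} Newton iterations "
            f"(last objective {F:.6g})")
    w[np.abs(w) < ZERO_TOL] = 0.0
    return w


@dataclass
class GamModel:
    """A fitted encoding model for one neuron."""

    neuron: int
    coef: np.ndarray            # design coefficients + trailing intercept
    groups: list[Group]
    ranges: dict[str, tuple[float, float]]
    dt: float
    hp: Hyperparams
    selected: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def baseline(self) -> float:
        return float(self.coef[-1])

    def group(self, name: str) -> Group:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def group_coef(self, name: str) -> np.ndarray:
        return self.coef[:-1][self.group(name).sl]

    def tuning_curve(self, name: str, x: np.ndarray | None = None,
                     domain: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Tuning function values (log-rate units) on a grid; ``domain``
        overrides the fitted range (e.g. to compare manipulation fits over the
        baseline domain)."""
        g = self.group(name)
        bx = g.basis
        if domain is not None:
            # evaluate on an alternate grid domain while keeping the fitted
            # weights on their own bin structure
            grid_basis = _basis.BoxcarBasis(domain[0], domain[1], bx.n, bx.circular)
            if x is None:
                x = grid_basis.centers
        elif x is None:
            x = bx.centers
        return np.asarray(x), bx.evaluate(self.group_coef(name), np.asarray(x))

    def filter_values(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Reconstructed temporal filter (lags, values) for an event, motor,
        history, or coupling group."""
        g = self.group(name)
        return g.basis.lags, g.basis.reconstruct(self.group_coef(name))

    def coupling_sources(self) -> list[int]:
        return [g.source for g in self.groups if g.kind == "coupling"]

    def predict_lograte(self, X: np.ndarray) -> np.ndarray:
        eta = (X @ self.coef[:-1].astype(X.dtype)).astype(np.float64) + self.baseline
        return np.clip(eta, -40.0, 20.0)

    def predict_rate(self, X: np.ndarray) -> np.ndarray:
        """Expected spikes per bin."""
        return np.exp(self.predict_lograte(X))


class PoissonGAM(BaseEstimator):
    """Sklearn-style estimator wrapping the MAP fit of one neuron.

    ``fit(X, y)`` expects a design matrix from :mod:`latentnav.design` and the
    neuron's spike counts per bin; the group structure is supplied at
    construction (or via ``fit``'s ``groups``).  Fitted attributes:
    ``coef_`` (with trailing intercept), ``model_`` (a :class:`GamModel`).
    """

    def __init__(self, hp: Hyperparams = Hyperparams(), groups: list[Group] | None = None,
                 dt: float = 0.006, max_iter: int = 60, ftol: float = 1e-9):
        self.hp = hp
        self.groups = groups
        self.dt = dt
        self.max_iter = max_iter
        self.ftol = ftol

    def fit(self, X: np.ndarray, y: np.ndarray, groups: list[Group] | None = None,
            w0: np.ndarray | None = None, neuron: int = 0,
            ranges: dict | None = None) -> "PoissonGAM":
        groups = groups if groups is not None else self.groups
        if groups is None:
            raise ValueError("group structure is required")
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        self.coef_ = fit_map(X, y, groups, self.hp, w0=w0,
                             max_iter=self.max_iter, ftol=self.ftol)
        self.model_ = GamModel(neuron=neuron, coef=self.coef_, groups=groups,
                               ranges=ranges or {}, dt=self.dt, hp=self.hp)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_rate(np.asarray(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Per-bin Poisson log likelihood (up to the log y! constant)."""
        eta = self.model_.predict_lograte(np.asarray(X))
        return -poisson_nll(eta, np.asarray(y, dtype=float)) / len(y)


# ---------------------------------------------------------------------------
# session-level fitting and model selection
# ---------------------------------------------------------------------------

def fit_session_gam(
    session: SessionData,
    neuron: int,
    hp: Hyperparams = Hyperparams(),
    coupled: bool = True,
    spike_history: bool = True,
    variables: tuple[str, ...] = TUNING_VARS,
    cache: SpikeConvCache | None = None,
    exo: tuple | None = None,
    ranges: dict | None = None,
    **fit_kwargs,
) -> GamModel:
    """Convenience: build the neuron's design and fit the MAP estimate."""
    if ranges is None:
        ranges = tuning_ranges_from_session(session, variables)
    X, groups = neuron_design(session, neuron, cache=cache, coupled=coupled,
                              spike_history=spike_history, ranges=ranges,
                              variables=variables, exo=exo)
    est = PoissonGAM(hp=hp, dt=session.dt, **fit_kwargs)
    est.fit(X, session.counts[neuron], groups=groups, neuron=neuron, ranges=ranges)
    model = est.model_
    model.ranges = ranges
    return model


def _cv_fold_masks(session: SessionData, trial_idx: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(trial_idx)
    return [session.bins_of_trials(f) for f in np.array_split(perm, n_folds)]


def backward_eliminate(
    session: SessionData,
    neuron: int,
    hp: Hyperparams = Hyperparams(),
    coupled: bool = True,
    variables: tuple[str, ...] = TUNING_VARS,
    n_folds: int = 10,
    test_frac: float = 0.10,
    seed: int = 0,
    cache: SpikeConvCache | None = None,
    se_slack: float = 1.0,
    max_iter: int = 60,
) -> tuple[list[str], GamModel, dict]:
    """Grouped backward elimination with trial-level cross-validation.

    A held-out test split (10% of trials) is set aside for final evaluation;
    the remaining trials form ``n_folds`` cross-validation folds (with ten
    folds each fold holds 9% of all trials, so selection uses 90% of the
    data).  Elimination units are each continuous variable, each event
    filter, each motor kernel, the spike history, and all coupling filters as
    one group.  At each step the group whose removal least harms the mean CV
    log likelihood is dropped if the harm is within ``se_slack`` standard
    errors of zero; the procedure stops when no group is droppable.

    Returns ``(selected group names, final refit on all selection trials,
    info dict)`` with the selection trace and test-set diagnostics.
    """
    n_tr = session.n_trials
    if n_tr < 20:
        raise ValueError("need at least 20 trials for stable folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_tr)
    n_test = max(1, int(round(test_frac * n_tr)))
    test_idx, sel_idx = perm[:n_test], perm[n_test:]
    test_mask = session.bins_of_trials(test_idx)
    fold_masks = _cv_fold_masks(session, sel_idx, n_folds, rng)
    sel_mask = session.bins_of_trials(sel_idx)

    ranges = tuning_ranges_from_session(session, variables)
    X, groups = neuron_design(session, neuron, cache=cache, coupled=coupled,
                              ranges=ranges, variables=variables)
    y = session.counts[neuron].astype(np.float64)

    # elimination units: coupling collapses to a single unit
    unit_of: dict[str, list[Group]] = {}
    for g in groups:
        key = "coupling" if g.kind == "coupling" else g.name
        unit_of.setdefault(key, []).append(g)
    active = list(unit_of)

    def cv_ll(units: list[str]) -> np.ndarray:
        """Per-fold validation log likelihood (per bin) of a unit subset."""
        cols = np.zeros(X.shape[1], dtype=bool)
        sub_groups, p = [], 0
        for u in units:
            for g in unit_of[u]:
                cols[g.sl] = True
                n = g.sl.stop - g.sl.start
                sub_groups.append(Group(g.name, g.kind, slice(p, p + n),
                                        g.basis, g.source))
                p += n
        if not units:
            return cv_ll_intercept(session, y, fold_masks, sel_mask)
        Xu = X[:, cols]
        lls = []
        for vmask in fold_masks:
            tmask = sel_mask & ~vmask
            w = fit_map(Xu[tmask], y[tmask], sub_groups, hp, max_iter=max_iter)
            eta = np.clip((Xu[vmask] @ w[:-1].astype(np.float32)).astype(float)
                          + w[-1], -40, 20)
            lls.append(-poisson_nll(eta, y[vmask]) / max(vmask.sum(), 1))
        return np.asarray(lls)

    trace = []
    cur_lls = cv_ll(active)
    while len(active) > 0:
        # candidate drop: per-fold PAIRED comparison against the current model
        best = None
        for u in active:
            lls = cv_ll([a for a in active if a != u])
            if best is None or lls.mean() > best[1].mean():
                best = (u, lls)
        u, lls = best
        diff = lls - cur_lls
        se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else 0.0
        if diff.mean() >= -se_slack * se:
            active.remove(u)
            trace.append({"dropped": u, "cv_ll": float(lls.mean())})
            cur_lls = lls
        else:
            break

    # final fit on all selection trials with the surviving groups
    cols = np.zeros(X.shape[1], dtype=bool)
    sub_groups, p = [], 0
    for u in active:
        for g in unit_of[u]:
            cols[g.sl] = True
            n = g.sl.stop - g.sl.start
            sub_groups.append(Group(g.name, g.kind, slice(p, p + n), g.basis, g.source))
            p += n
    Xu = X[:, cols]
    w = fit_map(Xu[sel_mask], y[sel_mask], sub_groups, hp, max_iter=max_iter)
    model = GamModel(neuron=neuron, coef=w, groups=sub_groups, ranges=ranges,
                     dt=session.dt, hp=hp, selected=list(active))

    eta_test = model.predict_lograte(Xu[test_mask])
    info = {
        "trace": trace,
        "cv_ll": float(cur_lls.mean()),
        "test_pseudo_r2": pseudo_r2_from_counts(y[test_mask], np.exp(eta_test)),
        "test_mask": test_mask,
    }
    model.diagnostics = info
    return list(active), model, info


def cv_ll_intercept(session, y, fold_masks, sel_mask) -> np.ndarray:
    lls = []
    for vmask in fold_masks:
        tmask = sel_mask & ~vmask
        mu = max(y[tmask].mean(), 1e-8)
        eta = np.full(int(vmask.sum()), np.log(mu))
        lls.append(-poisson_nll(eta, y[vmask]) / max(vmask.sum(), 1))
    return np.asarray(lls)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Full Poisson log likelihood with the convention 0*log(0) = 0."""
    from scipy.special import gammaln

    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
    return float((term - mu - gammaln(y + 1)).sum())


def pseudo_r2(L_model: float, L_saturated: float, L_null: float) -> float:
    """Likelihood-ratio variance explained in [.., 1]: 1 at the saturated
    model, 0 at the constant-rate null."""
    denom = L_saturated - L_null
    if abs(denom) < 1e-12:
        raise ValueError("saturated and null likelihoods coincide")
    if L_model > L_saturated + 1e-6 or L_model < L_null - 1e-6 * abs(L_null) - 1e-6:
        warnings.warn("model likelihood outside [null, saturated] bracket")
    return 1.0 - (L_saturated - L_model) / denom


def pseudo_r2_from_counts(y: np.ndarray, mu: np.ndarray) -> float:
    L_m = poisson_loglik(y, mu)
    L_sat = poisson_loglik(y, y)
    L_0 = poisson_loglik(y, np.full_like(np.asarray(y, float), np.mean(y)))
    return pseudo_r2(L_m, L_sat, L_0)


def smooth_counts(counts: np.ndarray, dt: float,
                  trial_slices: list[tuple[int, int]] | None = None,
                  sigma_s: float = 0.060) -> np.ndarray:
    """Observed rate (Hz): spike counts smoothed with a 60 ms Gaussian."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    out = np.empty_like(counts)
    sig = sigma_s / dt
    if trial_slices is None:
        trial_slices = [(0, counts.shape[1])]
    for (a, b) in trial_slices:
        out[:, a:b] = gaussian_filter1d(counts[:, a:b], sig, axis=1, mode="nearest")
    return np.squeeze(out / dt)


def variance_explained(
    predicted_rate: np.ndarray, observed_rate: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-neuron R^2 = 1 - Var(rhat - r)/Var(r), and the population R^2
    pooling numerator and denominator variance sums across neurons.

    Zero-variance neurons get R^2 = nan and are excluded from the pooled
    value.
    """
    P = np.atleast_2d(predicted_rate)
    O = np.atleast_2d(observed_rate)
    if P.shape != O.shape:
        raise ValueError("rate arrays must be aligned")
    var_err = np.var(P - O, axis=1)
    var_obs = np.var(O, axis=1)
    ok = var_obs > 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} zero-variance neurons excluded")
    r2 = np.full(P.shape[0], np.nan)
    r2[ok] = 1.0 - var_err[ok] / var_obs[ok]
    r2_pop = 1.0 - var_err[ok].sum() / var_obs[ok].sum()
    out = r2 if P.shape[0] > 1 else r2
    return out, float(r2_pop)


# ---------------------------------------------------------------------------
# marginal tuning and coupling summaries
# ---------------------------------------------------------------------------

def marginal_tuning(
    model: GamModel,
    variable: str,
    session: SessionData,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected firing rate (Hz) vs one variable, marginalizing the others.

    exp(f_k) on the grid, times the empirical marginal expectation of
    exp(f_j) for every other fitted continuous variable, times the
    time-averaged gain of each event/motor filter, times exp(b); history and
    coupling gains are treated as unity (their multiplicative modulation of
    the mean rate is close to one).
    """
    names = [g.name for g in model.groups]
    if variable not in names:
        raise KeyError(f"variable '{variable}' not in the fitted model")
    g = model.group(variable)
    if grid is None:
        grid = np.linspace(g.basis.lo, g.basis.hi, 100)
    fk = g.basis.evaluate(model.group_coef(variable), grid)

    gain = np.exp(model.baseline)
    for other in model.groups:
        if other.name == variable:
            continue
        coef = model.group_coef(other.name)
        if other.kind == "tuning":
            vals = other.basis.evaluate(coef, session.signals[other.name])
            gain *= float(np.mean(np.exp(vals)))
        elif other.kind in ("event", "motor"):
            from .design import _conv_columns

            series = (session.events.get(other.name)
                      if other.kind == "event" else session.signals[other.name])
            contrib = _conv_columns(series, session.trial_slices, other.basis) @ coef
            gain *= float(np.mean(np.exp(contrib)))
        # history / coupling: multiplicative modulation treated as unity
    return grid, np.exp(fk) * gain / model.dt  # expected counts/bin -> Hz


def coupling_strength(coef: np.ndarray, cbasis: _basis.CosineBasis) -> float:
    """Gain of a coupling (or history) filter: the time-average of the
    exponentiated filter over its support.  1 means no net effect, >1
    excitatory, <1 inhibitory."""
    return float(np.mean(np.exp(cbasis.reconstruct(coef))))


def coupling_strength_matrix(models: list[GamModel]) -> np.ndarray:
    """(N, N) gain matrix; diagonal holds spike-history gains; entries for
    pairs without a fitted filter are nan."""
    N = len(models)
    S = np.full((N, N), np.nan)
    for m in models:
        i = m.neuron
        for g in m.groups:
            if g.kind == "coupling":
                S[i, g.source] = coupling_strength(m.group_coef(g.name), g.basis)
            elif g.kind == "history":
                S[i, i] = coupling_strength(m.group_coef(g.name), g.basis)
    return S


def refit_exponential_basis(
    filter_values: np.ndarray, dt: float
) -> tuple[np.ndarray, float]:
    """Re-express a reconstructed coupling filter on the seven-exponential
    basis (decay constants 6..384 ms) and fit a power law to the weight
    magnitudes vs decay constant.

    Returns ``(7 weights, power-law exponent)`` where the exponent is the
    log-log slope of |weight| against decay constant.
    """
    lags, B = _basis.exp7_basis(dt, t_max=len(filter_values) * dt)
    n = min(len(filter_values), B.shape[0])
    w, *_ = np.linalg.lstsq(B[:n], np.asarray(filter_values)[:n], rcond=None)
    mag = np.abs(w)
    ok = mag > 1e-12
    if ok.sum() >= 2:
        slope = np.polyfit(np.log(_basis.EXP7_TAUS[ok]), np.log(mag[ok]), 1)[0]
    else:
        slope = np.nan
    return w, float(slope)
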