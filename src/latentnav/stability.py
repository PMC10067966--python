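"""Representation stability under task manipulations, and related indices.

The stability index references the correlation between fits with and without
a manipulation (rho) to a noise ceiling (rho*, odd vs even baseline trials)
and a chance floor (rho0, shuffled pairings):
``SI = (rho - rho0)/(rho* - rho0)``, 0 at chance-level stability and 1 at
the ceiling.  Mixed selectivity and task-relevant dimensionality both use
the participation ratio ``(sum v)^2 / sum v^2``, applied to per-variable
variance contributions and to canonical covariances respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gam import GamModel
from .neural import ELECTRODE_PITCH_UM

#: representation classes -> the tuning variables they comprise
REPR_CLASSES = {
    "sensory": ("linear_velocity", "angular_velocity"),
    "latent": ("dist_to_target", "angle_to_target"),
    "motor": ("motor_1", "motor_2"),
}


def _tuning_vector(model: GamModel, variables: tuple[str, ...],
                   domain_model: GamModel | None = None) -> np.ndarray | None:
    """Concatenated tuning curves (sensory concatenates linear + angular).

    Curves are evaluated over the domain of ``domain_model`` (the baseline
    fit) so fits under a manipulation that shifts a variable's range stay
    comparable.  Motor-channel 'tuning' is the fitted temporal kernel.
    """
    ref = domain_model or model
    parts = []
    for v in variables:
        try:
            g = model.group(v)
        except KeyError:
            return None
        if g.kind == "motor":
            parts.append(g.basis.reconstruct(model.group_coef(v)))
        else:
            dom = (ref.group(v).basis.lo, ref.group(v).basis.hi)
            parts.append(model.tuning_curve(v, domain=dom)[1])
    return np.concatenate(parts)


def filter_similarity(
    fits_a: list[GamModel],
    fits_b: list[GamModel],
    what: str,
    rng: np.random.Generator | None = None,
    shuffled: bool = False,
) -> np.ndarray:
    """Pearson correlations of reconstructed filters/tuning between two fit
    sets of the same neurons.

    ``what``: 'coupling' correlates each directed pair's coupling filter;
    'sensory' | 'latent' | 'motor' correlate per-neuron concatenated tuning
    curves (evaluated over the baseline fits' domain, here ``fits_a``).
    ``shuffled=True`` mispairs the units (coupling pairs, or neurons) to
    build the chance-floor distribution.
    """
    if len(fits_a) != len(fits_b) or any(
            a.neuron != b.neuron for a, b in zip(fits_a, fits_b)):
        raise ValueError("fit sets must cover the same neurons in order")

    if what == "coupling":
        va, vb = [], []
        for a, b in zip(fits_a, fits_b):
            src_b = {g.source: g.name for g in b.groups if g.kind == "coupling"}
            for g in a.groups:
                if g.kind != "coupling" or g.source not in src_b:
                    continue
                va.append(g.basis.reconstruct(a.group_coef(g.name)))
                gb = b.group(src_b[g.source])
                vb.append(gb.basis.reconstruct(b.group_coef(gb.name)))
    else:
        variables = REPR_CLASSES[what]
        va, vb = [], []
        for a, b in zip(fits_a, fits_b):
            ca = _tuning_vector(a, variables)
            cb = _tuning_vector(b, variables, domain_model=a)
            if ca is not None and cb is not None:
                va.append(ca)
                vb.append(cb)
    if not va:
        return np.array([])
    if shuffled:
        rng = rng or np.random.default_rng(0)
        # random derangement (cyclic on a random permutation): no unit is
        # ever paired with itself
        p = rng.permutation(len(vb))
        q = np.empty(len(vb), dtype=int)
        q[p] = p[np.roll(np.arange(len(p)), 1)]
        vb = [vb[k] for k in q]
    out = []
    for x, y in zip(va, vb):
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out.append(np.corrcoef(x, y)[0, 1])
    return np.asarray(out)


@dataclass(frozen=True)
class StabilityInputs:
    rho: float       # median correlation, with vs without manipulation
    rho_star: float  # noise ceiling: odd vs even baseline fits
    rho0: float      # shuffled-pair chance floor


def stability_index(s: StabilityInputs) -> float:
    """SI = (rho - rho0)/(rho* - rho0); 0 = chance, 1 = noise ceiling.

    May fall outside [0, 1] with noisy inputs and is reported unclipped.
    """
    denom = s.rho_star - s.rho0
    if abs(denom) < 1e-12:
        raise ValueError("noise ceiling equals the chance floor: SI undefined")
    return (s.rho - s.rho0) / denom


def stability_report(
    base_a: list[GamModel],
    base_b: list[GamModel],
    base_full: list[GamModel],
    manip: list[GamModel],
    classes: tuple[str, ...] = ("coupling", "sensory", "latent", "motor"),
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """SI per representation class from (odd, even, full-baseline,
    manipulation) fit sets."""
    rng = rng or np.random.default_rng(0)
    out = {}
    for what in classes:
        rho = float(np.median(filter_similarity(base_full, manip, what)))
        rho_star = float(np.median(filter_similarity(base_a, base_b, what)))
        rho0 = float(np.median(
            filter_similarity(base_full, manip, what, rng=rng, shuffled=True)))
        out[what] = stability_index(StabilityInputs(rho, rho_star, rho0))
    return out


def participation_ratio(v: np.ndarray) -> float:
    """(sum v)^2 / sum v^2 for non-negative contributions; in [1, K]."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance contributions must be non-negative")
    s2 = float((v**2).sum())
    if s2 == 0:
        raise ValueError("all-zero contribution vector")
    return float(v.sum() ** 2 / s2)


#: alias matching the index name used for single-neuron variance spread
mixed_selectivity_index = participation_ratio


def cca_dimensionality(
    X: np.ndarray, R: np.ndarray, ridge: float = 1e-8
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray, float]:
    """Task-relevant neural dimensionality via iterative CCA.

    Successive unit-norm pairs (a_i, b_i) maximize Corr(a'X, b'R) subject to
    the new canonical variables being uncorrelated with all previous pairs
    (enforced by residualizing both blocks against earlier canonical
    variables).  D is the participation ratio of |Cov(a_i'X, b_i'R)| over the
    P = min(n_task_vars, n_neurons) pairs.

    Returns ``(pairs, canonical_covariances, D)``.
    """
    X = np.asarray(X, float)
    R = np.asarray(R, float)
    if X.shape[0] != R.shape[0]:
        raise ValueError("X and R must share the time axis")
    Xc = X - X.mean(axis=0)
    Rc = R - R.mean(axis=0)
    rank_x = np.linalg.matrix_rank(Xc)
    P = min(rank_x, Rc.shape[1])
    if rank_x < X.shape[1]:
        warnings.warn(f"rank-deficient task block: P reduced to {P}")

    def first_pair(A, B):
        Ca = A.T @ A / len(A) + ridge * np.eye(A.shape[1])
        Cb = B.T @ B / len(B) + ridge * np.eye(B.shape[1])
        Cab = A.T @ B / len(A)
        La = np.linalg.cholesky(Ca)
        Lb = np.linalg.cholesky(Cb)
        M = np.linalg.solve(La, Cab @ np.linalg.inv(Lb).T)
        U, s, Vt = np.linalg.svd(M)
        a = np.linalg.solve(La.T, U[:, 0])
        b = np.linalg.solve(Lb.T, Vt[0])
        return a / np.linalg.norm(a), b / np.linalg.norm(b)

    pairs, covs = [], []
    Ax, Ar = Xc.copy(), Rc.copy()
    basis_u = []  # canonical variables found so far (for residualization)
    for _ in range(P):
        a, b = first_pair(Ax, Ar)
        # covariance measured on the ORIGINAL (centered) data, unit-norm a, b
        ua, ub = Xc @ a, Rc @ b
        pairs.append((a, b))
        covs.append(float(np.mean(ua * ub)))
        for u in (ua, ub):
            u = u - u.mean()
            n = u @ u
            if n > 0:
                Ax = Ax - np.outer(u, (u @ Ax) / n)
                Ar = Ar - np.outer(u, (u @ Ar) / n)
    covs = np.abs(np.asarray(covs))
    D = participation_ratio(covs)
    return pairs, covs, D


def coupling_vs_distance(
    strengths: np.ndarray,
    electrode_pos: np.ndarray,
    pitch_um: float = ELECTRODE_PITCH_UM,
) -> dict[str, np.ndarray]:
    """Coupling gain as a function of inter-electrode distance.

    ``strengths`` is the (N, N) gain matrix (target row, source column; nan
    where absent).  Distances are Euclidean on the array grid; bins are
    multiples of the electrode pitch.  Excitatory (gain > 1) and inhibitory
    (gain < 1) pairs are summarized separately by the mean |log gain| per
    distance bin.
    """
    S = np.asarray(strengths, float)
    N = S.shape[0]
    pos = np.asarray(electrode_pos, float)
    n_skipped = 0
    dists, gains = [], []
    for i in range(N):
        for j in range(N):
            if i == j or np.isnan(S[i, j]):
                continue
            if np.any(np.isnan(pos[i])) or np.any(np.isnan(pos[j])):
                n_skipped += 1
                continue
            dists.append(np.linalg.norm(pos[i] - pos[j]) * pitch_um)
            gains.append(S[i, j])
    dists = np.asarray(dists)
    gains = np.asarray(gains)
    # distances on the array grid are discrete; bin by exact value
    keys = np.round(dists, 3)
    centers = np.unique(keys)
    exc = np.full(len(centers), np.nan)
    inh = np.full(len(centers), np.nan)
    for k, c in enumerate(centers):
        e = gains[(keys == c) & (gains > 1)]
        i_ = gains[(keys == c) & (gains < 1)]
        if e.size:
            exc[k] = np.abs(np.log(e)).mean()
        if i_.size:
            inh[k] = np.abs(np.log(i_)).mean()
    return {
        "distance_um": centers,
        "excitatory_mean_abs_log_gain": exc,
        "inhibitory_mean_abs_log_gain": inh,
        "n_skipped": np.array([n_skipped]),
    }
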