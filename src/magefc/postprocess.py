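"""Everything downstream of a fitted state-mixture model.

Dual-estimation of subject-level state maps, affine-invariant geometry on
SPD matrices, state matching/recovery scoring, binarized state-dynamics
statistics (fractional occupancy, lifetimes, switching rate), task-evoked
occupancy, meta-state matrices, an autoregressive-surrogate test for FC
dynamics, rank-one FC maps, feature extraction for behavioural prediction,
and split-half reproducibility scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor, gaussian_nll
from .nn import NAdam
from .model import StateBasis, StateTimeCourses, TimeSeriesData

__all__ = [
    "SummaryStats",
    "FeatureMatrix",
    "StateMatch",
    "dual_estimate",
    "riemannian_distance",
    "match_states",
    "binarize_timecourses",
    "summary_stats",
    "task_evoked_occupancy",
    "metastate_matrix",
    "fc_dynamics_test",
    "rank_one_map",
    "fc_features",
    "reproducibility_score",
    "instantaneous_fc",
]


# ---------------------------------------------------------------------------
# Riemannian geometry on SPD matrices
# ---------------------------------------------------------------------------

def riemannian_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance between SPD matrices.

    d(A, B) = sqrt(sum_i ln^2 lambda_i) with lambda_i the generalized
    eigenvalues of (B, A); invariant under congruence A -> M' A M.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if not np.allclose(A, A.T, atol=1e-8) or not np.allclose(B, B.T, atol=1e-8):
        raise ValueError("inputs must be symmetric")
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    n = A.shape[0]
    if np.linalg.eigvalsh(A).min() < 1e-10:
        A = A + 1e-6 * np.eye(n)
    if np.linalg.eigvalsh(B).min() < 1e-10:
        B = B + 1e-6 * np.eye(n)
    lam = eigh(B, A, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def rank_one_map(D: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric matrix as a spatial FC map.

    Unit norm; sign fixed so the largest-magnitude entry is positive.
    Exactly tied leading eigenvalues are degenerate: the first coordinate
    vector is returned (deterministic tie rule) with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    w, v = np.linalg.eigh(0.5 * (D + D.T))
    if D.shape[0] > 1 and abs(w[-1] - w[-2]) <= 1e-10 * max(1.0, abs(w[-1])):
        warnings.warn("tied leading eigenvalues; returning first coordinate vector")
        e = np.zeros(D.shape[0])
        e[0] = 1.0
        return e
    vec = v[:, -1]
    i = np.argmax(np.abs(vec))
    if vec[i] < 0:
        vec = -vec
    return vec / np.linalg.norm(vec)


# ---------------------------------------------------------------------------
# state matching / recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class StateMatch:
    """Optimal pairing of inferred states onto ground-truth states.

    ``permutation[j]`` is the inferred state matched to truth state j.
    """

    permutation: np.ndarray
    correlations: np.ndarray
    mean_correlation: float


def _column_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """corr[i, j] = Pearson r of X[:, i] against Y[:, j] (0 if degenerate)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(sx, sy)
    r[~np.isfinite(r)] = 0.0
    return r


def match_states(
    inferred: StateTimeCourses | np.ndarray, truth: StateTimeCourses | np.ndarray,
    course: str = "beta",
) -> StateMatch:
    """Match inferred to true state time courses by optimal assignment.

    The permutation maximizes the total Pearson correlation between
    matched columns.  Pass arrays directly, or pick ``course`` ("alpha"
    or "beta") from :class:`StateTimeCourses` inputs.
    """
    X = inferred if isinstance(inferred, np.ndarray) else getattr(inferred, course)
    Y = truth if isinstance(truth, np.ndarray) else getattr(truth, course)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"state counts differ: {X.shape[1]} vs {Y.shape[1]}")
    r = _column_correlations(X, Y)  # inferred x truth
    rows, cols = linear_sum_assignment(-r)
    perm = np.empty(X.shape[1], dtype=np.intp)
    perm[cols] = rows
    corrs = r[perm, np.arange(X.shape[1])]
    return StateMatch(
        permutation=perm, correlations=corrs, mean_correlation=float(corrs.mean())
    )


# ---------------------------------------------------------------------------
# binarized dynamics statistics
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLD = 0.3


@dataclass
class SummaryStats:
    fractional_occupancy: np.ndarray  # per state, in [0, 1]
    switching_rate: float  # Hz (pooled state onsets per second)
    lifetimes: list  # per state, array of visit durations in seconds
    threshold: float = DEFAULT_THRESHOLD


def binarize_timecourses(tcs: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold continuous partial-volume time courses: 1 iff value > threshold.

    Multiple states may be simultaneously on; a one-hot input at the
    default threshold 0.3 is returned unchanged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    tcs = np.asarray(tcs, dtype=np.float64)
    return (tcs > threshold).astype(np.int8)


def summary_stats(binary: np.ndarray, dt: float) -> SummaryStats:
    """Occupancy, lifetimes and pooled switching rate of binary time courses.

    Fractional occupancy is the column mean; lifetimes are contiguous-run
    lengths scaled by dt; the switching rate pools 0->1 onsets over all
    states (a run starting at t=0 counts as an onset) per second of data.
    """
    binary = np.asarray(binary)
    if binary.size == 0:
        raise ValueError("empty input")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if binary.ndim == 1:
        binary = binary[:, None]
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("input must be binary")
    T, K = binary.shape
    fo = binary.mean(axis=0).astype(np.float64)
    lifetimes = []
    n_onsets = 0
    for k in range(K):
        col = binary[:, k]
        d = np.diff(np.concatenate(([0], col, [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        n_onsets += len(starts)
        lifetimes.append((ends - starts).astype(np.float64) * dt)
    rate = n_onsets / (T * dt)
    return SummaryStats(
        fractional_occupancy=fo, switching_rate=float(rate), lifetimes=lifetimes
    )


def task_evoked_occupancy(tcs: np.ndarray, epoch_table) -> dict:
    """Mean +/- sd state time courses time-locked to repeated task epochs.

    ``epoch_table`` is an iterable of (condition, onset, length) rows (or
    a DataFrame with those columns), onsets/lengths in timepoints.  All
    epochs of one condition must share a length and must not overlap each
    other.  Returns {condition: {"mean": L x K, "sd": L x K, "n": repeats}}.
    """
    tcs = np.asarray(tcs, dtype=np.float64)
    T = tcs.shape[0]
    rows = (
        epoch_table.itertuples(index=False)
        if hasattr(epoch_table, "itertuples")
        else epoch_table
    )
    epochs: dict[str, list[tuple[int, int]]] = {}
    spans = []
    for row in rows:
        cond, onset, length = row[0], int(row[1]), int(row[2])
        if onset < 0 or onset + length > T:
            raise ValueError(f"epoch ({cond}, {onset}, {length}) outside [0, T)")
        spans.append((onset, onset + length))
        epochs.setdefault(cond, []).append((onset, length))
    spans.sort()
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError("overlapping epochs")
    out = {}
    for cond, lst in epochs.items():
        lengths = {L for _, L in lst}
        if len(lengths) != 1:
            raise ValueError(f"condition {cond!r} has unequal epoch lengths")
        stackd = np.stack([tcs[o : o + L] for o, L in lst])
        out[cond] = {
            "mean": stackd.mean(axis=0),
            "sd": stackd.std(axis=0, ddof=0),
            "n": len(lst),
        }
    return out


def metastate_matrix(fo: np.ndarray) -> np.ndarray:
    """States x states co-fluctuation of fractional occupancy across subjects.

    ``fo`` is states x subjects; each state's occupancy is demeaned across
    subjects before forming v v', so the matrix reflects between-subject
    covariance structure (the hierarchical "meta-state" organization).
    """
    fo = np.atleast_2d(np.asarray(fo, dtype=np.float64))
    if fo.shape[1] == 1:
        warnings.warn("single subject: meta-state matrix has rank 1")
    v = fo - fo.mean(axis=1, keepdims=True)
    return v @ v.T


# ---------------------------------------------------------------------------
# dual estimation
# ---------------------------------------------------------------------------

def dual_estimate(
    group_model,
    subject_data: TimeSeriesData,
    n_epochs: int | None = None,
    seed: int = 0,
):
    """Subject-level state maps with group-level time courses frozen.

    The group encoder provides the subject's state time courses; these are
    held fixed (byte-identical before/after) while S, D, E are re-optimized
    to maximize the window likelihood of the subject's data, warm-started
    from the group basis with the group training configuration at one
    tenth of the epochs.  On divergence the group basis is returned with
    ``basis.meta['failed'] = True``.
    """
    from .inference import _GeneratorBasis, infer_timecourses

    cfg = group_model.config
    tcs = infer_timecourses(group_model, subject_data)
    alpha0, beta0 = tcs.alpha.copy(), tcs.beta.copy()
    W = cfg.window_length
    T = subject_data.n_timepoints
    n_full = T // W
    y = subject_data.values[: n_full * W].reshape(n_full, W, -1)
    a = tcs.alpha[: n_full * W].reshape(n_full, W, -1)
    b = tcs.beta[: n_full * W].reshape(n_full, W, -1)

    rng = np.random.default_rng(seed)
    gen = _GeneratorBasis(cfg.n_states_mean, cfg.n_states_fc, subject_data.n_channels, rng)
    gen.set_from_basis(group_model.basis)
    opt = NAdam(gen.params(), lr=cfg.learning_rate, beta1=cfg.momentum,
                clip_norm=cfg.clip_norm)
    epochs = n_epochs if n_epochs is not None else max(1, cfg.n_epochs // 10)
    B, Wn, N = y.shape
    failed = False
    for _ in range(epochs):
        S, D, E = gen.S, gen.corr_tensor(), gen.std_tensor()
        m = (Tensor(a.reshape(-1, a.shape[-1])) @ S).reshape(B, Wn, N)
        F = (Tensor(b.reshape(-1, b.shape[-1])) @ D.reshape(gen.Q, N * N)).reshape(
            B, Wn, N, N
        )
        g = (Tensor(a.reshape(-1, a.shape[-1])) @ E).reshape(B, Wn, N)
        C = g.reshape(B, Wn, N, 1) * F * g.reshape(B, Wn, 1, N)
        nll = gaussian_nll(y, m, C) * (1.0 / (B * Wn))
        if not np.isfinite(nll.data):
            failed = True
            break
        opt.zero_grad()
        nll.backward()
        opt.step()
    basis = group_model.basis if failed else gen.to_state_basis()
    assert np.array_equal(tcs.alpha, alpha0) and np.array_equal(tcs.beta, beta0)
    basis.meta = {"failed": failed, "timecourses": tcs}
    return basis


# ---------------------------------------------------------------------------
# FC dynamics significance testing
# ---------------------------------------------------------------------------

def instantaneous_fc(model, data: TimeSeriesData) -> np.ndarray:
    """Per-timepoint instantaneous correlation F_t from a fitted model."""
    from .inference import infer_timecourses

    tcs = infer_timecourses(model, data)
    Q, N, _ = model.basis.corr_states.shape
    return (tcs.beta @ model.basis.corr_states.reshape(Q, N * N)).reshape(-1, N, N)


def fc_dynamics_test(
    model,
    data: TimeSeriesData,
    n_surrogates: int = 20,
    order: int = 10,
    seed: int = 0,
) -> dict:
    """Edge-wise test of FC dynamics against autoregressive surrogates.

    For each edge the statistic is the temporal variance of the inferred
    instantaneous FC.  The null distribution refits the model (same
    configuration) on AR(order) surrogates of the data; p-values use the
    add-one permutation convention, so p in (0, 1].
    """
    from .inference import fit
    from .simulate import ar_surrogate

    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for p <= 0.05 resolution")
    N = data.n_channels
    obs = instantaneous_fc(model, data).var(axis=0)
    rng = np.random.default_rng(seed)
    null_vars = []
    n_failed = 0
    for _ in range(n_surrogates):
        sub_seed = int(rng.integers(2**31 - 1))
        sur = ar_surrogate(data, order=order, seed=sub_seed)
        try:
            import copy

            cfg = copy.deepcopy(model.config)
            cfg.seed = sub_seed
            m = fit([sur], cfg)
            null_vars.append(instantaneous_fc(m, sur).var(axis=0))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if not null_vars:
        raise RuntimeError("every surrogate fit failed")
    null = np.stack(null_vars)
    n_eff = len(null_vars)
    pvals = (1.0 + (null >= obs[None]).sum(axis=0)) / (1.0 + n_eff)
    if n_failed:
        warnings.warn(f"{n_failed} surrogate fit(s) failed and were skipped")
    iu = np.triu_indices(N, k=1)
    return {
        "p_matrix": pvals,
        "p_edges": pvals[iu],
        "observed_variance": obs,
        "null_variances": null,
        "n_failed": n_failed,
    }


# ---------------------------------------------------------------------------
# features and reproducibility
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects x (Q * f) state-specific FC features, f = N(N-1)/2."""

    values: np.ndarray
    subject_ids: list
    n_states: int
    n_channels: int
    edge_index: list = field(default_factory=list)


def fc_features(subject_bases: list[StateBasis], subject_ids: list | None = None) -> FeatureMatrix:
    """Vectorize each subject's state-specific FCs for prediction.

    Per subject, the strict upper triangle of every D_q is read out
    row-major and concatenated across states: Q * N(N-1)/2 features.
    """
    if not subject_bases:
        raise ValueError("need at least one subject basis")
    Q = subject_bases[0].Q
    N = subject_bases[0].n_channels
    if any(b.Q != Q or b.n_channels != N for b in subject_bases):
        raise ValueError("all subjects must share Q and N")
    iu = np.triu_indices(N, k=1)
    rows = []
    for b in subject_bases:
        rows.append(np.concatenate([b.corr_states[q][iu] for q in range(Q)]))
    index = [(q, int(i), int(j)) for q in range(Q) for i, j in zip(*iu)]
    ids = subject_ids or [f"subject-{i}" for i in range(len(subject_bases))]
    return FeatureMatrix(
        values=np.stack(rows), subject_ids=list(ids), n_states=Q, n_channels=N,
        edge_index=index,
    )


def devectorize_fc(features: np.ndarray, n_states: int, n_channels: int) -> np.ndarray:
    """Inverse of the fc_features read-out: rebuild Q unit-diagonal matrices."""
    N, Q = n_channels, n_states
    f = N * (N - 1) // 2
    iu = np.triu_indices(N, k=1)
    out = np.empty((Q, N, N))
    for q in range(Q):
        M = np.eye(N)
        M[iu] = features[q * f : (q + 1) * f]
        M.T[iu] = M[iu]
        out[q] = M
    return out


def reproducibility_score(
    bases_run1: StateBasis, bases_run2: StateBasis
) -> dict:
    """Similarity of two runs' state maps after optimal state matching.

    FC states are compared on vectorized strict upper triangles, mean
    states on the raw maps; each is matched by assignment maximizing
    Pearson correlation and the mean matched correlation is reported.
    """
    if bases_run1.Q != bases_run2.Q or bases_run1.P != bases_run2.P:
        raise ValueError("state counts differ between runs")
    N = bases_run1.n_channels
    iu = np.triu_indices(N, k=1)
    fc1 = np.stack([D[iu] for D in bases_run1.corr_states], axis=1)  # f x Q
    fc2 = np.stack([D[iu] for D in bases_run2.corr_states], axis=1)
    r_fc = _column_correlations(fc1, fc2)
    rows, cols = linear_sum_assignment(-r_fc)
    fc_matched = r_fc[rows, cols]
    m1 = bases_run1.mean_maps.T  # N x P
    m2 = bases_run2.mean_maps.T
    r_m = _column_correlations(m1, m2)
    mrows, mcols = linear_sum_assignment(-r_m)
    return {
        "fc": float(fc_matched.mean()),
        "mean": float(r_m[mrows, mcols].mean()),
        "fc_matched": fc_matched,
    }
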