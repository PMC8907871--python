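"""Synthetic ground truths for validating state-mixture FC estimators.

Five generators cover the study designs the estimators are evaluated on:

* ``simulate_categorical`` — one-hot Markov-chain states (the classical
  HMM regime: mutually exclusive states, geometric dwell times);
* ``simulate_partial_volume`` — continuous sum-to-one mixtures with a
  controlled number of simultaneously active states;
* ``simulate_multidynamic`` — *independent* semi-Markov chains for the
  mean states and the correlation states, with gamma-distributed state
  lifetimes (shape k, scale 1 sample, dwell = max(1, round(draw)));
* ``simulate_static`` — a single correlation state held for the whole
  session (no FC dynamics whatsoever);
* ``ar_surrogate`` — stationary autoregressive surrogate data preserving
  a recording's linear autocorrelation and static covariance (the null
  for FC-dynamics testing).

All randomness flows from the spec seed; identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    StateBasis,
    StateTimeCourses,
    TimeSeriesData,
    sample_data,
    to_correlation,
)

__all__ = [
    "SimSpec",
    "GroundTruth",
    "random_basis",
    "simulate_categorical",
    "simulate_partial_volume",
    "simulate_multidynamic",
    "simulate_static",
    "ar_surrogate",
]


@dataclass
class SimSpec:
    """Configuration of a synthetic ground truth.

    ``k_mean``/``k_corr`` are gamma shapes for state lifetimes (samples);
    the gamma scale is fixed at 1 sample and dwells are rounded with a
    floor of 1.  ``corr_strength`` controls the off-diagonal magnitude of
    the random correlation states; ``mean_amplitude`` the scale of the
    mean maps relative to unit noise.
    """

    n_channels: int = 8
    n_timepoints: int = 10_000
    n_states_mean: int = 3  # P (= R)
    n_states_fc: int = 3  # Q
    kind: str = "categorical"
    k_mean: float = 30.0
    k_corr: float = 30.0
    gamma_scale: float = 1.0
    transition: np.ndarray | None = None
    self_transition: float = 0.95
    max_active: int = 2
    mean_amplitude: float = 1.0
    corr_strength: float = 0.8
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2 or self.n_timepoints < 2:
            raise ValueError("need N >= 2 and T >= 2")
        if self.k_mean <= 0 or self.k_corr <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma lifetime parameters must be positive")
        kinds = ("categorical", "partial_volume", "multidynamic_hsmm", "static")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.transition is not None:
            self.transition = np.asarray(self.transition, dtype=np.float64)
            if self.transition.shape != (self.n_states_mean, self.n_states_mean):
                raise ValueError("transition matrix must be P x P")
            if np.any(self.transition < 0) or not np.allclose(
                self.transition.sum(axis=1), 1.0, atol=1e-8
            ):
                raise ValueError("transition rows must be a probability distribution")


@dataclass
class GroundTruth:
    """Basis + time courses + emitted data of one simulation."""

    basis: StateBasis
    timecourses: StateTimeCourses
    data: TimeSeriesData
    spec: SimSpec = field(repr=False, default=None)


def random_basis(spec: SimSpec, rng: np.random.Generator) -> StateBasis:
    """Random state basis: Gaussian mean maps and shrunk Wishart FCs.

    Each correlation state is ``s * C0 + (1 - s) * I`` with C0 a random
    Wishart-derived correlation matrix and s = ``corr_strength``; the
    shrinkage keeps every state well conditioned (eigmin >= 1 - s), as
    correlation matrices of standardized parcel data are in practice,
    while s controls how strong the off-diagonal structure is.
    """
    N, P, Q = spec.n_channels, spec.n_states_mean, spec.n_states_fc
    if not 0.0 <= spec.corr_strength < 1.0:
        raise ValueError("corr_strength must lie in [0, 1)")
    mean_maps = spec.mean_amplitude * rng.standard_normal((P, N))
    corr = np.empty((Q, N, N))
    s = spec.corr_strength
    for q in range(Q):
        W = rng.standard_normal((N, N)) / np.sqrt(N)
        A = W @ W.T
        d = np.sqrt(np.diag(A))
        C0 = A / np.outer(d, d)
        D = s * C0 + (1.0 - s) * np.eye(N)
        np.fill_diagonal(D, 1.0)
        corr[q] = D
    std_maps = np.ones((P, N))
    return StateBasis(mean_maps=mean_maps, corr_states=corr, std_maps=std_maps)


def _default_transition(K: int, self_p: float) -> np.ndarray:
    off = (1.0 - self_p) / (K - 1) if K > 1 else 0.0
    Tm = np.full((K, K), off)
    np.fill_diagonal(Tm, self_p if K > 1 else 1.0)
    return Tm


def _markov_chain(T: int, trans: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    K = trans.shape[0]
    states = np.empty(T, dtype=np.intp)
    cum = trans.cumsum(axis=1)
    states[0] = rng.integers(K)
    u = rng.random(T)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def _semi_markov_onehot(
    T: int, K: int, k_shape: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """One-hot indicator sequence with gamma dwell times, no self-visits."""
    out = np.zeros((T, K))
    t = 0
    state = int(rng.integers(K))
    while t < T:
        dwell = max(1, int(round(rng.gamma(k_shape, scale))))
        out[t : t + dwell, state] = 1.0
        t += dwell
        if K > 1:
            nxt = int(rng.integers(K - 1))
            state = nxt if nxt < state else nxt + 1
    return out


def _onehot(states: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((len(states), K))
    out[np.arange(len(states)), states] = 1.0
    return out


def _emit(spec: SimSpec, basis: StateBasis, tcs: StateTimeCourses, rng) -> GroundTruth:
    data = sample_data(basis, tcs, seed=rng, dt=spec.dt, subject_id=f"sim-{spec.kind}")
    return GroundTruth(basis=basis, timecourses=tcs, data=data, spec=spec)


def simulate_categorical(spec: SimSpec, seed: int | None = None) -> GroundTruth:
    """One-hot single-dynamic states from a Markov chain (HMM regime)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    basis = random_basis(spec, rng)
    if spec.n_states_fc != spec.n_states_mean:
        raise ValueError("categorical simulation is single-dynamic: P must equal Q")
    trans = (
        spec.transition
        if spec.transition is not None
        else _default_transition(spec.n_states_mean, spec.self_transition)
    )
    states = _markov_chain(spec.n_timepoints, trans, rng)
    alpha = _onehot(states, spec.n_states_mean)
    tcs = StateTimeCourses(alpha=alpha, beta=alpha.copy(), gamma=alpha.copy())
    return _emit(spec, basis, tcs, rng)


def simulate_partial_volume(spec: SimSpec, seed: int | None = None) -> GroundTruth:
    """Continuous sum-to-one mixtures with at most ``max_active`` states on.

    Dwell-segmented: each segment activates a random subset of at most
    ``max_active`` states with Dirichlet(1) weights, smoothed by a
    3-sample moving average and renormalized (smoothing never grows the
    active set beyond adjacent segments' union, so overlap control means
    at most ``max_active`` states per *segment*; boundary timepoints mix
    the two adjoining sets but remain on the simplex).
    """
    if not 2 <= spec.max_active <= 4:
        raise ValueError("max_active must be 2, 3 or 4")
    P = spec.n_states_mean
    if spec.max_active > P:
        raise ValueError("max_active cannot exceed the state count")
    if spec.n_states_fc != P:
        raise ValueError("partial-volume simulation is single-dynamic: P must equal Q")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    basis = random_basis(spec, rng)
    T = spec.n_timepoints
    alpha = np.zeros((T, P))
    t = 0
    while t < T:
        dwell = max(1, int(round(rng.gamma(spec.k_mean, spec.gamma_scale))))
        n_active = int(rng.integers(1, spec.max_active + 1))
        active = rng.choice(P, size=n_active, replace=False)
        w = rng.dirichlet(np.ones(n_active))
        alpha[t : t + dwell, active] = w
        t += dwell
    # 3-sample moving average, then renormalize to the simplex
    kernel = np.ones(3) / 3.0
    sm = np.empty_like(alpha)
    for p in range(P):
        sm[:, p] = np.convolve(alpha[:, p], kernel, mode="same")
    sm[0] = alpha[0]
    sm[-1] = alpha[-1]
    sm /= sm.sum(axis=1, keepdims=True)
    tcs = StateTimeCourses(alpha=sm, beta=sm.copy(), gamma=sm.copy())
    return _emit(spec, basis, tcs, rng)


def simulate_multidynamic(spec: SimSpec, seed: int | None = None) -> GroundTruth:
    """Independent semi-Markov chains for mean and correlation states."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    basis = random_basis(spec, rng)
    T = spec.n_timepoints
    alpha = _semi_markov_onehot(T, spec.n_states_mean, spec.k_mean, spec.gamma_scale, rng)
    beta = _semi_markov_onehot(T, spec.n_states_fc, spec.k_corr, spec.gamma_scale, rng)
    tcs = StateTimeCourses(alpha=alpha, beta=beta, gamma=alpha.copy())
    return _emit(spec, basis, tcs, rng)


def simulate_static(spec: SimSpec, seed: int | None = None) -> GroundTruth:
    """Static FC: one correlation state for all t; means may still move."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    basis = random_basis(spec, rng)
    T, Q = spec.n_timepoints, spec.n_states_fc
    trans = (
        spec.transition
        if spec.transition is not None
        else _default_transition(spec.n_states_mean, spec.self_transition)
    )
    states = _markov_chain(T, trans, rng)
    alpha = _onehot(states, spec.n_states_mean)
    beta = np.zeros((T, Q))
    beta[:, 0] = 1.0
    tcs = StateTimeCourses(alpha=alpha, beta=beta, gamma=alpha.copy())
    return _emit(spec, basis, tcs, rng)


def ar_surrogate(
    data: TimeSeriesData, order: int = 10, seed: int = 0
) -> TimeSeriesData:
    """Stationary AR(order) surrogate of a recording.

    Fits a multivariate autoregressive model by least squares and iterates
    it forward with Gaussian innovations drawn from the residual
    covariance.  ``order = 0`` degenerates to white noise with the data's
    sample covariance.  An ill-conditioned design matrix triggers a small
    ridge penalty (with a warning).
    """
    import warnings

    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    Y = data.values
    T, N = Y.shape
    if order == 0:
        cov = np.cov(Y.T)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(N))
        vals = Y.mean(axis=0) + rng.standard_normal((T, N)) @ L.T
        return TimeSeriesData(vals, data.dt, f"{data.subject_id}-surrogate")
    if T <= order * N:
        raise ValueError("need T > order * N for identifiability")
    mu = Y.mean(axis=0)
    Yc = Y - mu
    # design: X[t] = [Yc[t-1], ..., Yc[t-order]]
    X = np.hstack([Yc[order - k - 1 : T - k - 1] for k in range(order)])
    Z = Yc[order:]
    G = X.T @ X
    if np.linalg.cond(G) > 1e10:
        warnings.warn("ill-conditioned AR design matrix; using ridge fallback")
        G = G + 1e-6 * np.trace(G) / G.shape[0] * np.eye(G.shape[0])
    coefs = np.linalg.solve(G, X.T @ Z)  # (order*N, N)
    resid = Z - X @ coefs
    sigma = np.cov(resid.T)
    Ls = np.linalg.cholesky(sigma + 1e-10 * np.eye(N))
    A = coefs.reshape(order, N, N)  # A[k] maps Yc[t-1-k] -> Yc[t]
    burn = 10 * order
    out = np.zeros((burn + T, N))
    innov = rng.standard_normal((burn + T, N)) @ Ls.T
    for t in range(order, burn + T):
        acc = innov[t].copy()
        for k in range(order):
            acc += out[t - 1 - k] @ A[k]
        out[t] = acc
    vals = out[burn:] + mu
    return TimeSeriesData(vals, data.dt, f"{data.subject_id}-surrogate")
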