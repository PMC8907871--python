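"""Generative model for multi-dynamic time-varying functional connectivity.

The observation model is a time-varying multivariate normal,

    y_t ~ N(m_t, C_t),      C_t = G_t F_t G_t,

where m_t is the instantaneous mean activity, G_t a diagonal matrix of
per-channel standard deviations and F_t the instantaneous correlation
("instantaneous FC").  Each of these is a convex, sum-to-one mixture of a
small set of recurring states:

    m_t = sum_p alpha_tp S_p          (P mean states, maps S_p in R^N)
    F_t = sum_q beta_tq  D_q          (Q correlation states, D_q in R^{NxN})
    G_t = sum_r gamma_tr diag(E_r)    (R std-dev states, E_r > 0)

The multi-dynamic variant lets the correlation mixture beta fluctuate
independently of the mean/variance mixture alpha (= gamma, with P = R);
the single-dynamic variant ties all three together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesData",
    "StateBasis",
    "StateTimeCourses",
    "Logits",
    "InstantaneousMoments",
    "standardize",
    "softmax_timecourses",
    "compose_moments",
    "to_correlation",
    "log_likelihood",
    "prior_transition",
    "sample_data",
]

_JITTER = 1e-6
_EIGMIN_TOL = 1e-10


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-channel z-scoring (zero mean, unit variance per column)."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant channel(s) {bad} cannot be standardized")
    return (values - values.mean(axis=0)) / sd


@dataclass
class TimeSeriesData:
    """A single subject's parcel time series (T timepoints x N channels)."""

    values: np.ndarray
    dt: float = 1.0
    subject_id: str = "subject-0"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/Inf")
        T, N = self.values.shape
        if T < 2 or N < 2:
            raise ValueError("need T >= 2 and N >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "TimeSeriesData":
        return TimeSeriesData(standardize(self.values), self.dt, self.subject_id)

    def is_standardized(self, tol: float = 1e-6) -> bool:
        return bool(
            np.all(np.abs(self.values.mean(axis=0)) < tol)
            and np.all(np.abs(self.values.var(axis=0) - 1.0) < tol)
        )


@dataclass
class StateBasis:
    """State-specific maps: means S (PxN), correlations D (QxNxN), stds E (RxN)."""

    mean_maps: np.ndarray
    corr_states: np.ndarray
    std_maps: np.ndarray

    def __post_init__(self):
        self.mean_maps = np.atleast_2d(np.asarray(self.mean_maps, dtype=np.float64))
        self.corr_states = np.asarray(self.corr_states, dtype=np.float64)
        self.std_maps = np.atleast_2d(np.asarray(self.std_maps, dtype=np.float64))
        if self.corr_states.ndim != 3:
            raise ValueError("corr_states must be Q x N x N")
        if self.mean_maps.shape[0] != self.std_maps.shape[0]:
            raise ValueError("state-count constraint P = R violated")
        N = self.mean_maps.shape[1]
        if self.corr_states.shape[1:] != (N, N) or self.std_maps.shape[1] != N:
            raise ValueError("channel counts disagree across basis components")
        if np.any(self.std_maps <= 0):
            raise ValueError("std_maps entries must be positive")
        for q, D in enumerate(self.corr_states):
            if not np.allclose(D, D.T, atol=1e-8):
                raise ValueError(f"corr state {q} is not symmetric")
            if not np.allclose(np.diag(D), 1.0, atol=1e-8):
                raise ValueError(f"corr state {q} has non-unit diagonal")
            if np.linalg.eigvalsh(D).min() < -1e-8:
                raise ValueError(f"corr state {q} is not positive semi-definite")

    @property
    def P(self) -> int:
        return self.mean_maps.shape[0]

    @property
    def Q(self) -> int:
        return self.corr_states.shape[0]

    @property
    def R(self) -> int:
        return self.std_maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mean_maps.shape[1]


def _check_simplex(name: str, x: np.ndarray, tol: float = 1e-6) -> None:
    if np.any(x < -tol) or np.any(x > 1 + tol):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(x.sum(axis=1), 1.0, atol=tol):
        raise ValueError(f"rows of {name} must sum to 1")


@dataclass
class StateTimeCourses:
    """Per-timepoint mixing weights; every row lies on the simplex."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.gamma is None:
            self.gamma = self.alpha  # gamma == alpha when P == R
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if not (len(self.alpha) == len(self.beta) == len(self.gamma)):
            raise ValueError("alpha, beta, gamma must share the time axis")
        _check_simplex("alpha", self.alpha)
        _check_simplex("beta", self.beta)
        _check_simplex("gamma", self.gamma)

    @property
    def n_timepoints(self) -> int:
        return self.alpha.shape[0]


@dataclass
class Logits:
    """Pre-softmax latents theta_m (TxP) and theta_c (TxQ)."""

    theta_m: np.ndarray
    theta_c: np.ndarray
    role: str = "posterior_mean"

    def __post_init__(self):
        self.theta_m = np.asarray(self.theta_m, dtype=np.float64)
        self.theta_c = np.asarray(self.theta_c, dtype=np.float64)
        if self.role not in ("prior_mean", "posterior_mean"):
            raise ValueError("role must be 'prior_mean' or 'posterior_mean'")
        if not (np.all(np.isfinite(self.theta_m)) and np.all(np.isfinite(self.theta_c))):
            raise ValueError("logits contain NaN/Inf")
        if self.theta_m.shape[0] != self.theta_c.shape[0]:
            raise ValueError("theta_m and theta_c must share the time axis")


@dataclass
class InstantaneousMoments:
    """Per-timepoint mean, std, correlation and covariance of the model."""

    mean: np.ndarray  # T x N
    std_diag: np.ndarray  # T x N
    corr: np.ndarray  # T x N x N
    cov: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std_diag = np.asarray(self.std_diag, dtype=np.float64)
        self.corr = np.asarray(self.corr, dtype=np.float64)
        g = self.std_diag
        self.cov = g[:, :, None] * self.corr * g[:, None, :]

    @property
    def n_timepoints(self) -> int:
        return self.mean.shape[0]


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_timecourses(logits: Logits) -> StateTimeCourses:
    """Map pre-softmax latents to simplex-valued state time courses.

    alpha = gamma = softmax(theta_m) row-wise; beta = softmax(theta_c).
    """
    if not (np.all(np.isfinite(logits.theta_m)) and np.all(np.isfinite(logits.theta_c))):
        raise ValueError("NaN/Inf in logits")
    alpha = _softmax_rows(logits.theta_m)
    beta = _softmax_rows(logits.theta_c)
    return StateTimeCourses(alpha=alpha, beta=beta, gamma=alpha)


def compose_moments(tcs: StateTimeCourses, basis: StateBasis) -> InstantaneousMoments:
    """Mix the state basis by the time courses into per-timepoint moments."""
    if tcs.alpha.shape[1] != basis.P:
        raise ValueError(f"alpha has {tcs.alpha.shape[1]} states, basis has P={basis.P}")
    if tcs.beta.shape[1] != basis.Q:
        raise ValueError(f"beta has {tcs.beta.shape[1]} states, basis has Q={basis.Q}")
    if tcs.gamma.shape[1] != basis.R:
        raise ValueError(f"gamma has {tcs.gamma.shape[1]} states, basis has R={basis.R}")
    mean = tcs.alpha @ basis.mean_maps
    Q, N, _ = basis.corr_states.shape
    corr = (tcs.beta @ basis.corr_states.reshape(Q, N * N)).reshape(-1, N, N)
    std = tcs.gamma @ basis.std_maps
    return InstantaneousMoments(mean=mean, std_diag=std, corr=corr)


def to_correlation(raw: np.ndarray) -> np.ndarray:
    """Project an unconstrained square matrix onto valid correlations.

    Uses a normalized lower-triangular factor: L = tril(raw) with each row
    scaled to unit norm, and C = L L'.  The map is smooth almost everywhere,
    so it doubles as the training-time parameterization of the correlation
    states.  An all-zero row (unnormalizable) falls back to the identity row.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("input must be square")
    if not np.all(np.isfinite(raw)):
        raise ValueError("input contains NaN/Inf")
    L = np.tril(raw)
    norms = np.linalg.norm(L, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn("degenerate all-zero row(s); falling back to identity rows")
        for i in np.flatnonzero(zero):
            L[i, i] = 1.0
        norms = np.linalg.norm(L, axis=1)
    L = L / norms[:, None]
    C = L @ L.T
    np.fill_diagonal(C, 1.0)
    return C


def _chol_with_jitter(C: np.ndarray):
    """Cholesky factors of a stack of matrices under the jitter policy."""
    C = np.asarray(C, dtype=np.float64)
    n = C.shape[-1]
    eigmin = np.linalg.eigvalsh(C).min(axis=-1)
    Cj = C.copy()
    needs = eigmin < _EIGMIN_TOL
    if np.any(needs):
        Cj[needs] += _JITTER * np.eye(n)
    try:
        return np.linalg.cholesky(Cj)
    except np.linalg.LinAlgError:
        # identify the offending timepoints for the error message
        bad = []
        for t in range(len(Cj)):
            try:
                np.linalg.cholesky(Cj[t])
            except np.linalg.LinAlgError:
                bad.append(t)
        raise ValueError(f"covariance not PSD after jitter at timepoints {bad}")


def log_likelihood(data: TimeSeriesData, moments: InstantaneousMoments) -> float:
    """Sum over t of log N(y_t; m_t, C_t)."""
    y = data.values
    if y.shape != moments.mean.shape:
        raise ValueError("data and moments disagree in shape")
    n = y.shape[1]
    L = _chol_with_jitter(moments.cov)
    r = y - moments.mean
    z = np.linalg.solve(L, r[..., None])[..., 0]
    logdet = 2.0 * np.log(np.einsum("tii->ti", L)).sum(axis=-1)
    ll = -0.5 * (logdet + (z**2).sum(axis=-1) + n * np.log(2 * np.pi))
    total = float(ll.sum())
    if not np.isfinite(total):
        raise ValueError("non-finite log-likelihood")
    return total


def prior_transition(theta_history: Logits, networks) -> Logits:
    """Predict prior means of the latents from their own history.

    A unidirectional (causal) LSTM consumes theta_{<t} and an affine
    read-out produces the prior mean at t; the prediction at each t
    therefore depends only on strictly earlier inputs.

    ``networks`` is a :class:`magefc.inference.MageNetworks` instance (or
    anything exposing ``prior_logits``).
    """
    T = theta_history.theta_m.shape[0]
    if T < 2:
        raise ValueError("need a history window of at least 2 timepoints")
    mu_m, mu_c = networks.prior_logits(
        theta_history.theta_m[None], theta_history.theta_c[None]
    )
    return Logits(theta_m=mu_m.data[0], theta_c=mu_c.data[0], role="prior_mean")


def sample_data(
    basis: StateBasis,
    tcs: StateTimeCourses,
    seed: int | np.random.Generator = 0,
    dt: float = 1.0,
    subject_id: str = "simulated",
    standardize_output: bool = False,
) -> TimeSeriesData:
    """Draw y_t ~ N(m_t, C_t) for every timepoint (reproducible by seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    moments = compose_moments(tcs, basis)
    L = _chol_with_jitter(moments.cov)
    z = rng.standard_normal(moments.mean.shape)
    y = moments.mean + np.einsum("tij,tj->ti", L, z)
    if standardize_output:
        y = standardize(y)
    return TimeSeriesData(values=y, dt=dt, subject_id=subject_id)
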