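"""Single-dynamic reference estimators: sliding-window correlation with
k-means state extraction, and a mutually exclusive Gaussian-state HMM.

Both baselines tie the mean and correlation dynamics together (their alpha,
beta and gamma time courses are identical by construction), which is
exactly the assumption the multi-dynamic estimator relaxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import StateBasis, StateTimeCourses, TimeSeriesData, to_correlation

__all__ = ["SWCSpec", "swc_states", "hmm_states"]


@dataclass
class SWCSpec:
    """Sliding-window configuration; step = window gives non-overlapping
    square windows (the default simplification)."""

    window: int = 50
    step: int | None = None  # defaults to window (non-overlapping)
    n_clusters: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.step is None:
            self.step = self.window
        if not 1 <= self.step <= self.window:
            raise ValueError("need 1 <= step <= window")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")


def _window_correlation(seg: np.ndarray) -> np.ndarray:
    """Pearson correlation of one window; zero-variance channels -> 0 rows."""
    sd = seg.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn("zero-variance channel inside a window; entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(seg.T)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def _project_correlation(M: np.ndarray) -> np.ndarray:
    """Nearest-by-construction valid correlation for a symmetric centroid."""
    M = 0.5 * (M + M.T)
    w, v = np.linalg.eigh(M)
    w = np.clip(w, 1e-8, None)
    Mpsd = (v * w) @ v.T
    d = np.sqrt(np.diag(Mpsd))
    Mpsd = Mpsd / np.outer(d, d)
    L = np.linalg.cholesky(Mpsd + 1e-10 * np.eye(M.shape[0]))
    return to_correlation(L)


def swc_states(
    data: TimeSeriesData, spec: SWCSpec
) -> tuple[StateBasis, StateTimeCourses]:
    """Windowed correlations clustered into recurring FC states.

    Per-window Pearson correlation matrices are vectorized (strict upper
    triangle) and clustered by seeded k-means; centroids are rebuilt into
    valid correlation states, and hard window assignments are expanded to
    per-timepoint one-hot time courses (the trailing remainder inherits
    the last window's label).
    """
    from sklearn.cluster import KMeans

    Y = data.values
    T, N = Y.shape
    W, step, K = spec.window, spec.step, spec.n_clusters
    if T < W:
        raise ValueError(f"T={T} shorter than the window ({W})")
    starts = list(range(0, T - W + 1, step))
    corrs = np.stack([_window_correlation(Y[s : s + W]) for s in starts])
    iu = np.triu_indices(N, k=1)
    feats = corrs[:, iu[0], iu[1]]
    km = KMeans(n_clusters=K, n_init=10, random_state=spec.seed)
    labels = km.fit_predict(feats)
    states = np.empty((K, N, N))
    for k in range(K):
        M = np.eye(N)
        centre = km.cluster_centers_[k]
        M[iu] = centre
        M.T[iu] = centre
        states[k] = _project_correlation(M)
    # expand hard assignments to timepoints: latest window covering t wins
    tl = np.empty(T, dtype=np.intp)
    tl[:] = labels[0]
    for s, lab in zip(starts, labels):
        tl[s : s + W] = lab
    tl[starts[-1] + W :] = labels[-1]
    onehot = np.zeros((T, K))
    onehot[np.arange(T), tl] = 1.0
    basis = StateBasis(
        mean_maps=np.zeros((K, N)), corr_states=states, std_maps=np.ones((K, N))
    )
    tcs = StateTimeCourses(alpha=onehot, beta=onehot.copy(), gamma=onehot.copy())
    return basis, tcs


def hmm_states(
    data: TimeSeriesData, n_states: int, seed: int = 0, n_restarts: int = 3
) -> tuple[StateBasis, StateTimeCourses]:
    """Gaussian-observation HMM baseline (mutually exclusive states).

    Full-covariance states (mean and covariance coupled) fitted by EM via
    hmmlearn; Viterbi decoding gives one-hot time courses.  Non-converged
    EM falls back to the best-scoring restart with a warning.
    """
    from hmmlearn.hmm import GaussianHMM

    if n_states < 2:
        raise ValueError("need at least two states")
    Y = data.values if data.is_standardized() else data.standardized().values
    best, best_score = None, -np.inf
    any_converged = False
    for r in range(n_restarts):
        hmm = GaussianHMM(
            n_components=n_states,
            covariance_type="full",
            n_iter=200,
            random_state=seed + r,
            min_covar=1e-4,
        )
        try:
            hmm.fit(Y)
        except (ValueError, np.linalg.LinAlgError):
            continue
        score = hmm.score(Y)
        any_converged |= bool(hmm.monitor_.converged)
        if score > best_score:
            best, best_score = hmm, score
    if best is None:
        raise RuntimeError("every HMM restart failed")
    if not any_converged:
        warnings.warn("EM did not converge; returning best-of-restarts")
    labels = best.predict(Y)
    T = len(Y)
    onehot = np.zeros((T, n_states))
    onehot[np.arange(T), labels] = 1.0
    covs = best.covars_
    N = Y.shape[1]
    stds = np.sqrt(np.maximum(np.einsum("kii->ki", covs), 1e-12))
    corrs = covs / (stds[:, :, None] * stds[:, None, :])
    for k in range(n_states):
        corrs[k] = 0.5 * (corrs[k] + corrs[k].T)
        np.fill_diagonal(corrs[k], 1.0)
        if np.linalg.eigvalsh(corrs[k]).min() < -1e-8:
            corrs[k] = _project_correlation(corrs[k])
    basis = StateBasis(mean_maps=best.means_, corr_states=corrs, std_maps=stds)
    tcs = StateTimeCourses(alpha=onehot, beta=onehot.copy(), gamma=onehot.copy())
    return basis, tcs
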