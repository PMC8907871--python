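"""Adversarial generator-encoder inference for the state-mixture model.

Training is a three-player game:

* the **generator** owns the state basis (S, D, E), the latent logits and a
  causal LSTM prior that predicts the logits' prior means from their
  history;
* the **encoder** (bidirectional LSTM) maps a window of data to posterior
  means of the logits — a deterministic amortized posterior;
* the **discriminator** (bidirectional LSTM + sigmoid read-out) classifies
  softmaxed logit sequences as coming from the prior or the posterior.

Each batch is processed in two phases: a *reconstruction* phase updating
generator + encoder on the Gaussian likelihood with the discriminator
frozen, and a *regularization* phase that first updates the discriminator
and then updates encoder + prior to pull posterior and prior dynamics
together.  The total objective is

    F = lam * NLL + (1 - lam)/2 * R

with the likelihood term averaged per timepoint so ``lam`` has the same
meaning regardless of window/batch size.

MAGE carries two independent latent streams (mean/variance vs correlation);
SAGE shares a single stream across all three mixtures.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gaussian_nll, softmax
from .nn import BiLSTM, Dense, LSTM, NAdam
from .model import (
    Logits,
    StateBasis,
    StateTimeCourses,
    TimeSeriesData,
    softmax_timecourses,
)

__all__ = [
    "TrainingConfig",
    "LossReport",
    "MageNetworks",
    "FittedModel",
    "encode",
    "discriminate",
    "compute_losses",
    "fit",
    "infer_timecourses",
]

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """Hyper-parameters of the adversarial trainer.

    Defaults follow the reference settings (window 100, batch 32, NAdam
    with learning rate 1e-4 and momentum 0.9, likelihood weight lam in
    0.85-0.95, 80/20 train/validation split).  Small-scale runs typically
    raise the learning rate and shrink the window; see docs/methods.md.
    """

    n_states_mean: int = 3  # P (= R)
    n_states_fc: int = 3  # Q
    window_length: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    momentum: float = 0.9
    optimizer: str = "nadam"
    lstm_units: int = 16
    loss_weight: float = 0.9  # lam
    n_epochs: int = 100
    seed: int = 0
    val_fraction: float = 0.2
    variant: str = "mage"  # or "sage"
    regularizer: str = "ce"  # "ce" (default) or "adversarial"
    patience: int = 10
    clip_norm: float = 10.0
    init: str = "data"  # "data" (HMM / windowed-correlation) or "random"
    reestimate_fc: bool = True  # final empirical re-estimation of the FC states
    reg_interval: int = 1  # run the regularization phase every n-th batch
    disc_interval: int = 3  # update the discriminator every n-th reg phase

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.loss_weight < 1.0:
            raise ValueError("loss_weight (lam) must lie in (0, 1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        self.variant = self.variant.lower()
        if self.variant not in ("mage", "sage"):
            raise ValueError("variant must be 'mage' or 'sage'")
        if self.variant == "sage" and self.n_states_mean != self.n_states_fc:
            raise ValueError("SAGE shares one latent stream: requires P == Q")
        if self.regularizer not in ("ce", "adversarial"):
            raise ValueError("regularizer must be 'ce' or 'adversarial'")
        if self.init not in ("data", "random"):
            raise ValueError("init must be 'data' or 'random'")
        if self.reg_interval < 1 or self.disc_interval < 1:
            raise ValueError("reg_interval and disc_interval must be >= 1")


@dataclass
class LossReport:
    """Per-epoch traces of the training objective."""

    train_total: list = field(default_factory=list)
    train_recon: list = field(default_factory=list)
    train_reg: list = field(default_factory=list)
    val_total: list = field(default_factory=list)
    val_recon: list = field(default_factory=list)
    val_reg: list = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs_run(self) -> int:
        return len(self.train_total)


class _GeneratorBasis:
    """Trainable parameterization of the state basis.

    Correlation states are stored as unconstrained square factors; the
    normalized lower-triangular map (rows of tril(raw) scaled to unit
    norm, D = L L') keeps every D a valid correlation matrix under
    unconstrained gradient updates.  Standard deviations are stored as
    logs to stay positive.
    """

    def __init__(self, P: int, Q: int, N: int, rng: np.random.Generator):
        self.P, self.Q, self.N = P, Q, N
        self.S = Tensor(0.1 * rng.standard_normal((P, N)), requires_grad=True)
        raw = np.tile(np.eye(N), (Q, 1, 1)) + 0.05 * rng.standard_normal((Q, N, N))
        self.L_raw = Tensor(raw, requires_grad=True)
        self.log_E = Tensor(np.zeros((P, N)), requires_grad=True)
        self._tril_mask = np.tril(np.ones((N, N)))

    def params(self) -> dict:
        return {"basis.S": self.S, "basis.L_raw": self.L_raw, "basis.log_E": self.log_E}

    def corr_tensor(self) -> Tensor:
        L = self.L_raw * self._tril_mask
        norms = ((L * L).sum(axis=-1, keepdims=True) + _EPS).sqrt()
        Ln = L / norms
        return Ln @ Ln.swapaxes(-1, -2)

    def std_tensor(self) -> Tensor:
        return self.log_E.exp()

    def to_state_basis(self) -> StateBasis:
        D = self.corr_tensor().data.copy()
        # exact unit diagonal (unit-norm rows give 1 up to rounding)
        for q in range(self.Q):
            np.fill_diagonal(D[q], 1.0)
        return StateBasis(
            mean_maps=self.S.data.copy(),
            corr_states=D,
            std_maps=self.std_tensor().data.copy(),
        )

    def set_from_basis(self, basis: StateBasis) -> None:
        self.S.data = basis.mean_maps.copy()
        chol = np.linalg.cholesky(
            basis.corr_states + 1e-8 * np.eye(self.N)
        )
        self.L_raw.data = chol
        self.log_E.data = np.log(basis.std_maps)


class MageNetworks:
    """All sequence networks plus the trainable basis, for either variant."""

    def __init__(self, config: TrainingConfig, n_channels: int, rng: np.random.Generator):
        P, Q, H = config.n_states_mean, config.n_states_fc, config.lstm_units
        N = n_channels
        self.variant = config.variant
        self.P, self.Q, self.N, self.units = P, Q, N, H
        self.basis = _GeneratorBasis(P, Q, N, rng)
        # generator prior (causal)
        self.prior_lstm_m = LSTM(P, H, rng)
        self.prior_out_m = Dense(H, P, rng)
        # encoder (bidirectional)
        self.enc_lstm_m = BiLSTM(N, H, rng)
        self.enc_out_m = Dense(2 * H, P, rng)
        # discriminator (bidirectional)
        self.disc_lstm_m = BiLSTM(P, H, rng)
        self.disc_out_m = Dense(2 * H, 1, rng)
        if self.variant == "mage":
            self.prior_lstm_c = LSTM(Q, H, rng)
            self.prior_out_c = Dense(H, Q, rng)
            self.enc_lstm_c = BiLSTM(N, H, rng)
            self.enc_out_c = Dense(2 * H, Q, rng)
            self.disc_lstm_c = BiLSTM(Q, H, rng)
            self.disc_out_c = Dense(2 * H, 1, rng)
        else:  # SAGE: one latent stream shared by alpha, beta, gamma
            self.prior_lstm_c = self.prior_lstm_m
            self.prior_out_c = self.prior_out_m
            self.enc_lstm_c = self.enc_lstm_m
            self.enc_out_c = self.enc_out_m
            self.disc_lstm_c = self.disc_lstm_m
            self.disc_out_c = self.disc_out_m

    # -- parameter groups --------------------------------------------------
    def _named(self, prefix: str, module) -> dict:
        return {f"{prefix}.{k}": v for k, v in module.params().items()}

    def generator_params(self) -> dict:
        out = dict(self.basis.params())
        out.update(self._named("prior_lstm_m", self.prior_lstm_m))
        out.update(self._named("prior_out_m", self.prior_out_m))
        if self.variant == "mage":
            out.update(self._named("prior_lstm_c", self.prior_lstm_c))
            out.update(self._named("prior_out_c", self.prior_out_c))
        return out

    def encoder_params(self) -> dict:
        out = self._named("enc_lstm_m", self.enc_lstm_m)
        out.update(self._named("enc_out_m", self.enc_out_m))
        if self.variant == "mage":
            out.update(self._named("enc_lstm_c", self.enc_lstm_c))
            out.update(self._named("enc_out_c", self.enc_out_c))
        return out

    def discriminator_params(self) -> dict:
        out = self._named("disc_lstm_m", self.disc_lstm_m)
        out.update(self._named("disc_out_m", self.disc_out_m))
        if self.variant == "mage":
            out.update(self._named("disc_lstm_c", self.disc_lstm_c))
            out.update(self._named("disc_out_c", self.disc_out_c))
        return out

    def all_params(self) -> dict:
        out = self.generator_params()
        out.update(self.encoder_params())
        out.update(self.discriminator_params())
        return out

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.all_params().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.all_params()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- forward passes ----------------------------------------------------
    def encode_logits(self, y: Tensor) -> tuple[Tensor, Tensor]:
        """Posterior mean logits for a (B, W, N) window batch."""
        mu_m = self.enc_out_m(self.enc_lstm_m(y))
        if self.variant == "mage":
            mu_c = self.enc_out_c(self.enc_lstm_c(y))
        else:
            mu_c = mu_m
        return mu_m, mu_c

    def prior_logits(self, theta_m, theta_c) -> tuple[Tensor, Tensor]:
        """Causal prediction of prior means from the logits' own history.

        Inputs are (B, W, K) arrays/Tensors; each prediction at t uses the
        history up to t-1 (input shifted right by one step, zeros at t=0).
        """
        tm = theta_m if isinstance(theta_m, Tensor) else Tensor(theta_m)
        tc = theta_c if isinstance(theta_c, Tensor) else Tensor(theta_c)
        mu_m = self.prior_out_m(self.prior_lstm_m(_shift_right(tm)))
        if self.variant == "mage":
            mu_c = self.prior_out_c(self.prior_lstm_c(_shift_right(tc)))
        else:
            mu_c = mu_m
        return mu_m, mu_c

    def discriminate_logits(self, seq: Tensor, which: str) -> Tensor:
        """Per-timepoint probability that a softmaxed sequence is a posterior."""
        if which == "m":
            h = self.disc_lstm_m(seq)
            return self.disc_out_m(h).sigmoid()
        h = self.disc_lstm_c(seq)
        return self.disc_out_c(h).sigmoid()


def _shift_right(x: Tensor) -> Tensor:
    """(B, T, K) -> same shape with a zero row at t=0 and x[:, :-1] after."""
    B, T, K = x.shape
    zeros = Tensor(np.zeros((B, 1, K)))
    from .autodiff import concat

    return concat([zeros, x[:, :-1, :]], axis=1)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _window_nll(y: np.ndarray, theta_m: Tensor, theta_c: Tensor, nets: MageNetworks) -> Tensor:
    """Mean per-timepoint Gaussian NLL of a (B, W, N) batch."""
    B, W, N = y.shape
    alpha = softmax(theta_m)
    beta = softmax(theta_c)
    S = nets.basis.S
    D = nets.basis.corr_tensor()
    E = nets.basis.std_tensor()
    m = alpha.reshape(B * W, nets.P) @ S
    m = m.reshape(B, W, N)
    F = beta.reshape(B * W, nets.Q) @ D.reshape(nets.Q, N * N)
    F = F.reshape(B, W, N, N)
    g = alpha.reshape(B * W, nets.P) @ E
    g = g.reshape(B, W, N)
    C = g.reshape(B, W, N, 1) * F * g.reshape(B, W, 1, N)
    return gaussian_nll(y, m, C) * (1.0 / (B * W))


def _cross_entropy(post: Tensor, prior: Tensor) -> Tensor:
    """Mean per-timepoint CE of softmax(post) against softmax(prior)."""
    p = softmax(post)
    q = softmax(prior)
    ce = -(p * (q + _EPS).log()).sum(axis=-1)
    return ce.mean(axis=None)


def compute_losses(
    data: TimeSeriesData,
    moments,
    prior_logits: Logits,
    posterior_logits: Logits,
    loss_weight: float,
) -> LossReport:
    """Evaluate the two losses and total objective on one window.

    Reconstruction is the negative log-likelihood (per timepoint) of the
    data under the composed moments; regularization is the cross-entropy
    of the softmaxed posterior logits against the softmaxed prior logits,
    summed over the two latent streams.
    """
    if not 0.0 < loss_weight < 1.0:
        raise ValueError("loss_weight (lam) must lie in (0, 1)")
    from .model import log_likelihood

    T = data.n_timepoints
    nll = -log_likelihood(data, moments) / T
    ce_m = _ce_numpy(posterior_logits.theta_m, prior_logits.theta_m)
    ce_c = _ce_numpy(posterior_logits.theta_c, prior_logits.theta_c)
    reg = ce_m + ce_c
    total = loss_weight * nll + 0.5 * (1.0 - loss_weight) * reg
    report = LossReport()
    report.train_recon.append(nll)
    report.train_reg.append(reg)
    report.train_total.append(total)
    return report


def _softmax_np(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _ce_numpy(post: np.ndarray, prior: np.ndarray) -> float:
    p = _softmax_np(post)
    q = _softmax_np(prior)
    return float(-(p * np.log(q + _EPS)).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# public single-window ops
# ---------------------------------------------------------------------------

def encode(data: TimeSeriesData, networks: MageNetworks) -> Logits:
    """Posterior mean logits for one subject window (deterministic)."""
    if data.n_channels != networks.N:
        raise ValueError(
            f"data has {data.n_channels} channels, networks expect {networks.N}"
        )
    mu_m, mu_c = networks.encode_logits(Tensor(data.values[None]))
    return Logits(theta_m=mu_m.data[0], theta_c=mu_c.data[0], role="posterior_mean")


def discriminate(
    prior_logits: Logits, posterior_logits: Logits, networks: MageNetworks
) -> dict:
    """Per-timepoint posterior-probabilities for a prior/posterior pair.

    Both sequences are softmaxed before entering the discriminator.  The
    returned dict holds, for each latent stream, the probabilities the
    discriminator assigns to the prior sequence and the posterior sequence.
    """
    if prior_logits.theta_m.shape != posterior_logits.theta_m.shape:
        raise ValueError("prior and posterior sequences differ in length/width")

    def run(seq: np.ndarray, which: str) -> np.ndarray:
        s = _softmax_np(seq)[None]
        return networks.discriminate_logits(Tensor(s), which).data[0, :, 0]

    return {
        "m": {
            "prior": run(prior_logits.theta_m, "m"),
            "posterior": run(posterior_logits.theta_m, "m"),
        },
        "c": {
            "prior": run(prior_logits.theta_c, "c"),
            "posterior": run(posterior_logits.theta_c, "c"),
        },
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    basis: StateBasis
    networks: MageNetworks
    config: TrainingConfig
    loss_report: LossReport

    @property
    def variant(self) -> str:
        return self.config.variant


def _make_windows(data: list[TimeSeriesData], W: int) -> np.ndarray:
    """Stack non-overlapping windows across subjects -> (n_win, W, N)."""
    wins = []
    for d in data:
        vals = d.values
        n_full = vals.shape[0] // W
        for i in range(n_full):
            wins.append(vals[i * W : (i + 1) * W])
    if not wins:
        raise ValueError("no complete window: T < window_length for all subjects")
    return np.stack(wins)


_INIT_CORR_WLEN = 20  # short-window length for FC-state initialization


def _window_corr_features(seg: np.ndarray, iu) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(seg.T)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return C[iu]


def _init_basis_from_data(gen: _GeneratorBasis, data: np.ndarray, seed: int):
    """Warm-start the state basis from the data before gradient training.

    Mean/std states come from a quick Gaussian HMM (temporal pooling makes
    its state assignment far more reliable than per-timepoint clustering
    when states overlap in signal space); correlation states from k-means
    on short-window correlation matrices (upper-triangle features), so the
    gradient trainer refines informative rather than arbitrary states.
    Returns the two fitted label models for encoder pretraining.
    """
    from hmmlearn.hmm import GaussianHMM
    from sklearn.cluster import KMeans

    P, Q, N = gen.P, gen.Q, gen.N
    if len(data) > 20_000:  # initialization on a subsample is plenty
        data = data[: 20_000]
    hmm = GaussianHMM(
        n_components=P, covariance_type="full", n_iter=50, random_state=seed,
        min_covar=1e-3,
    )
    hmm.fit(data)
    gen.S.data = hmm.means_.copy()
    stds = np.clip(np.sqrt(np.einsum("pii->pi", hmm.covars_)), 0.3, 3.0)
    gen.log_E.data = np.log(stds)
    # windowed correlations for the FC states
    wlen = _INIT_CORR_WLEN
    n_win = len(data) // wlen
    iu = np.triu_indices(N, k=1)
    feats = np.stack(
        [_window_corr_features(data[i * wlen : (i + 1) * wlen], iu) for i in range(n_win)]
    )
    kmq = KMeans(n_clusters=Q, n_init=4, random_state=seed).fit(feats)
    L = np.empty((Q, N, N))
    for q in range(Q):
        M = np.eye(N)
        M[iu] = kmq.cluster_centers_[q]
        M.T[iu] = kmq.cluster_centers_[q]
        w, v = np.linalg.eigh(M)
        M = (v * np.clip(w, 1e-3, None)) @ v.T
        d = np.sqrt(np.diag(M))
        M = M / np.outer(d, d)
        L[q] = np.linalg.cholesky(M + 1e-8 * np.eye(N))
    gen.L_raw.data = L
    return hmm, kmq


def _pretrain_encoders(
    nets: MageNetworks,
    windows: np.ndarray,
    km_mean,
    km_corr,
    seed: int,
    n_epochs: int = 200,
    lr: float = 0.02,
) -> None:
    """Teach the encoders the cluster structure before joint training.

    Each encoder is briefly trained to reproduce *soft* targets derived
    from the unsupervised models used to initialize the basis: the HMM's
    posterior state probabilities for the mean stream, and
    label-smoothed (0.75 confidence) k-means assignments of short-window
    correlation features for the FC stream.  The softness matters: fully
    hard labels would bias the encoder toward mutually exclusive states,
    which is exactly wrong for partial-volume ground truths, while
    distance-derived responsibilities are too diffuse to anchor the FC
    stream (short-window correlation noise swamps the between-cluster
    distances).  This is self-supervised
    (targets derive from the data alone) and only sets the starting point
    of the adversarial optimization; all parameters remain free afterwards.
    """
    n_win, W, N = windows.shape
    P, Q = nets.P, nets.Q
    onehot_m = km_mean.predict_proba(windows.reshape(-1, N)).reshape(n_win, W, P)
    iu = np.triu_indices(N, k=1)
    onehot_c = np.empty((n_win, W, Q))
    wlen = _INIT_CORR_WLEN
    confidence = 0.75
    smooth = (1.0 - confidence) / Q
    for i in range(n_win):
        prev = np.full(Q, 1.0 / Q)
        for s in range(0, W, wlen):
            seg = windows[i, s : s + wlen]
            if len(seg) >= 5:
                f = _window_corr_features(seg, iu)
                lab = int(km_corr.predict(f[None])[0])
                prev = np.full(Q, smooth)
                prev[lab] += confidence
            onehot_c[i, s : s + wlen] = prev
    opt = NAdam(nets.encoder_params(), lr=lr, clip_norm=10.0)
    rng = np.random.default_rng(seed)
    B = min(16, n_win)
    best, since_best = np.inf, 0
    for _ in range(n_epochs):
        idx = rng.permutation(n_win)[:B]
        y = Tensor(windows[idx])
        mu_m, mu_c = nets.encode_logits(y)
        p_m = softmax(mu_m)
        loss = -(Tensor(onehot_m[idx]) * (p_m + _EPS).log()).sum(axis=-1).mean(axis=None)
        if nets.variant == "mage":
            p_c = softmax(mu_c)
            loss = loss - (Tensor(onehot_c[idx]) * (p_c + _EPS).log()).sum(axis=-1).mean(axis=None)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if float(loss.data) < best - 1e-4:
            best, since_best = float(loss.data), 0
        else:
            since_best += 1
            if since_best >= 60:  # target fit converged; stop warming up
                break


def _bce(probs: Tensor, label: float) -> Tensor:
    if label == 1.0:
        return -((probs + _EPS).log()).mean(axis=None)
    return -((1.0 - probs + _EPS).log()).mean(axis=None)


def fit(data: list[TimeSeriesData] | TimeSeriesData, config: TrainingConfig) -> FittedModel:
    """Train MAGE or SAGE on one or more subjects' standardized data."""
    if isinstance(data, TimeSeriesData):
        data = [data]
    if not data:
        raise ValueError("need at least one subject")
    n_channels = data[0].n_channels
    if any(d.n_channels != n_channels for d in data):
        raise ValueError("all subjects must share the channel count")
    data = [d if d.is_standardized() else d.standardized() for d in data]

    W, B = config.window_length, config.batch_size
    total_T = sum(d.n_timepoints for d in data)
    if B * W > total_T:
        raise ValueError(
            f"batch covers {B * W} timepoints but data has only {total_T}"
        )
    windows = _make_windows(data, W)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(windows))
    n_val = max(1, int(round(config.val_fraction * len(windows))))
    if n_val >= len(windows):
        n_val = len(windows) - 1
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_w, val_w = windows[train_idx], windows[val_idx]

    nets = MageNetworks(config, n_channels, rng)
    if config.init == "data":
        km_mean, km_corr = _init_basis_from_data(
            nets.basis, np.concatenate([d.values for d in data]), config.seed
        )
        _pretrain_encoders(nets, train_w, km_mean, km_corr, config.seed)
    lam = config.loss_weight
    opt_kwargs = dict(
        lr=config.learning_rate, beta1=config.momentum, clip_norm=config.clip_norm
    )
    gen_enc = dict(nets.generator_params())
    gen_enc.update(nets.encoder_params())
    opt_recon = NAdam(gen_enc, **opt_kwargs)
    opt_disc = NAdam(nets.discriminator_params(), **opt_kwargs)
    enc_prior = dict(nets.encoder_params())
    enc_prior.update(nets.generator_params())
    opt_reg = NAdam(enc_prior, **opt_kwargs)

    report = LossReport()
    best_val = np.inf
    best_state = nets.state_dict()
    best_epoch = 0
    since_best = 0
    # halve learning rates when held-out reconstruction stalls; stop only
    # after a full patience window at the floor rate
    plateau_wait = max(5, config.patience // 3)
    lr_floor = config.learning_rate / 64.0

    def epoch_eval(wins: np.ndarray) -> tuple[float, float, float]:
        """Forward-only objective on a window set (no gradients)."""
        y = wins
        mu_m, mu_c = nets.encode_logits(Tensor(y))
        nll = float(_window_nll(y, mu_m, mu_c, nets).data)
        pm, pc = nets.prior_logits(mu_m.detach(), mu_c.detach())
        reg = _ce_numpy(mu_m.data, pm.data) + _ce_numpy(mu_c.data, pc.data)
        return lam * nll + 0.5 * (1 - lam) * reg, nll, reg

    global_step = 0
    for epoch in range(config.n_epochs):
        perm = rng.permutation(len(train_w))
        ep_recon, ep_reg, n_batches, n_reg = 0.0, 0.0, 0, 0
        for start in range(0, len(perm), B):
            batch = train_w[perm[start : start + B]]
            # ---- reconstruction phase (discriminator frozen) ----
            y = Tensor(batch)
            mu_m, mu_c = nets.encode_logits(y)
            nll = _window_nll(batch, mu_m, mu_c, nets)
            loss_r = nll * lam
            opt_recon.zero_grad()
            loss_r.backward()
            opt_recon.step()
            ep_recon += float(nll.data)
            n_batches += 1
            global_step += 1

            # ---- regularization phase (every reg_interval-th batch) ----
            if global_step % config.reg_interval != 0:
                continue
            mu_m, mu_c = nets.encode_logits(Tensor(batch))
            post_m, post_c = mu_m.detach(), mu_c.detach()
            pri_m, pri_c = nets.prior_logits(post_m, post_c)
            # (i) discriminator update: prior -> 0, posterior -> 1
            # (detached inputs: this step trains only the discriminator;
            # in the default "ce" mode it does not feed the generator loss,
            # so it runs on a slower schedule)
            n_reg += 1
            if (
                config.regularizer != "ce"
                or n_reg % config.disc_interval == 0
            ):
                d_loss = _bce(
                    nets.discriminate_logits(softmax(pri_m.detach()), "m"), 0.0
                ) + _bce(nets.discriminate_logits(softmax(post_m), "m"), 1.0)
                if nets.variant == "mage":
                    d_loss = (
                        d_loss
                        + _bce(nets.discriminate_logits(softmax(pri_c.detach()), "c"), 0.0)
                        + _bce(nets.discriminate_logits(softmax(post_c), "c"), 1.0)
                    )
                opt_disc.zero_grad()
                d_loss.backward()
                opt_disc.step()
            # (ii) encoder + prior update to close the prior/posterior gap,
            # reusing the live encoder and prior graphs built above
            if config.regularizer == "ce":
                reg = _cross_entropy(mu_m, pri_m)
                if nets.variant == "mage":
                    reg = reg + _cross_entropy(mu_c, pri_c)
                else:
                    reg = reg * 2.0
            else:  # non-saturating adversarial variant
                reg = _bce(nets.discriminate_logits(softmax(pri_m), "m"), 1.0) + _bce(
                    nets.discriminate_logits(softmax(mu_m), "m"), 0.0
                )
                if nets.variant == "mage":
                    reg = (
                        reg
                        + _bce(nets.discriminate_logits(softmax(pri_c), "c"), 1.0)
                        + _bce(nets.discriminate_logits(softmax(mu_c), "c"), 0.0)
                    )
            loss_g = reg * (0.5 * (1 - lam))
            opt_reg.zero_grad()
            loss_g.backward()
            opt_reg.step()
            ep_reg += float(reg.data)

        tr_recon = ep_recon / n_batches
        tr_reg = ep_reg / n_reg if n_reg else 0.0
        tr_total = lam * tr_recon + 0.5 * (1 - lam) * tr_reg
        if not np.isfinite(tr_total):
            raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
        v_total, v_recon, v_reg = epoch_eval(val_w)
        report.train_total.append(tr_total)
        report.train_recon.append(tr_recon)
        report.train_reg.append(tr_reg)
        report.val_total.append(v_total)
        report.val_recon.append(v_recon)
        report.val_reg.append(v_reg)

        # model selection tracks held-out reconstruction (likelihood) loss:
        # the adversarial regularizer is a moving target and its validation
        # value spikes whenever the prior lags the sharpening posterior
        if v_recon < best_val - 1e-9:
            best_val = v_recon
            best_state = nets.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best % plateau_wait == 0:
                at_floor = opt_recon.lr <= lr_floor
                for opt in (opt_recon, opt_disc, opt_reg):
                    opt.lr = max(lr_floor, opt.lr * 0.5)
                nets.load_state_dict(best_state)
                if at_floor and since_best >= config.patience:
                    break
            elif since_best >= config.patience and opt_recon.lr <= lr_floor:
                break

    nets.load_state_dict(best_state)
    report.best_epoch = best_epoch
    model = FittedModel(
        basis=nets.basis.to_state_basis(),
        networks=nets,
        config=copy.deepcopy(config),
        loss_report=report,
    )
    if config.reestimate_fc:
        model.basis = _reestimate_fc_states(model, data)
    return model


def _reestimate_fc_states(model: "FittedModel", data: list) -> StateBasis:
    """Final empirical re-estimation of the correlation states.

    The gradient-trained correlation states compensate for residual
    softness in the mixing weights by extrapolating slightly beyond the
    data, which depresses their smallest eigenvalues.  This step replaces
    each D_q by the beta^2-weighted, conditionally centered sample
    correlation of the data after removing the hard-assigned mean/std
    estimate — an explicit M-step with the inferred time courses frozen.
    A small uniform weight floor (0.01 per timepoint) is added: it is
    negligible for an active state but dominates the sparse, structured
    residual weights of a state the model never activates, so unused
    states inherit (approximately) the global correlation — the best
    available estimate in that case.
    """
    W_FLOOR = 0.01
    N = model.basis.n_channels
    Q = model.basis.Q
    num = np.zeros((Q, N, N))
    mu_num = np.zeros((Q, N))
    wsum = np.zeros(Q)
    chunks = []
    for d in data:
        tcs = infer_timecourses(model, d)
        hard = tcs.alpha.argmax(axis=1)
        T = tcs.alpha.shape[0]
        r = (d.values[:T] - model.basis.mean_maps[hard]) / model.basis.std_maps[hard]
        chunks.append((r, tcs.beta**2 + W_FLOOR))
        for q in range(Q):
            w = tcs.beta[:, q] ** 2 + W_FLOOR
            wsum[q] += w.sum()
            mu_num[q] += (r * w[:, None]).sum(axis=0)
    corr = model.basis.corr_states.copy()
    for q in range(Q):
        if wsum[q] < 1e-8:  # numerical guard only
            continue
        mu = mu_num[q] / wsum[q]
        C = np.zeros((N, N))
        for r, w2 in chunks:
            rc = r - mu
            C += (rc * w2[:, q][:, None]).T @ rc
        C /= wsum[q]
        dstd = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        C = C / np.outer(dstd, dstd)
        C = 0.5 * (C + C.T)
        w_eig, v = np.linalg.eigh(C)
        if w_eig.min() < 1e-8:
            C = (v * np.clip(w_eig, 1e-8, None)) @ v.T
            dd = np.sqrt(np.diag(C))
            C = C / np.outer(dd, dd)
        np.fill_diagonal(C, 1.0)
        corr[q] = C
    return StateBasis(
        mean_maps=model.basis.mean_maps,
        corr_states=corr,
        std_maps=model.basis.std_maps,
    )


def infer_timecourses(model: FittedModel, data: TimeSeriesData) -> StateTimeCourses:
    """Full-length state time courses from consecutive windows.

    The data is split into non-overlapping windows of the training window
    length, each encoded independently, and the softmaxed posteriors are
    concatenated in temporal order.  A trailing remainder is handled by
    encoding the final full window ending at T (left-padding) and keeping
    only its tail; ``tcs.meta['padded']`` records whether this happened.
    """
    if not data.is_standardized():
        data = data.standardized()
    W = model.config.window_length
    T = data.n_timepoints
    vals = data.values
    n_full = T // W
    if n_full == 0:
        raise ValueError(f"T={T} shorter than one window (W={W})")
    segments_m, segments_c = [], []
    for i in range(n_full):
        win = TimeSeriesData(vals[i * W : (i + 1) * W], data.dt, data.subject_id)
        lg = encode(win, model.networks)
        segments_m.append(lg.theta_m)
        segments_c.append(lg.theta_c)
    padded = False
    rem = T - n_full * W
    if rem > 0:
        padded = True
        win = TimeSeriesData(vals[T - W :], data.dt, data.subject_id)
        lg = encode(win, model.networks)
        segments_m.append(lg.theta_m[-rem:])
        segments_c.append(lg.theta_c[-rem:])
    logits = Logits(
        theta_m=np.concatenate(segments_m),
        theta_c=np.concatenate(segments_c),
        role="posterior_mean",
    )
    tcs = softmax_timecourses(logits)
    tcs.meta = {"padded": padded, "window_length": W}
    return tcs
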