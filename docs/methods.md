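# Methods

## The observation model

`magefc` models a standardized multichannel recording `y_t ∈ R^N` (N
parcels, T timepoints) as a time-varying multivariate normal

    y_t ~ N(m_t, C_t),        C_t = G_t F_t G_t,

where `m_t` is the instantaneous mean activity, `G_t = diag(g_t)` holds
per-channel standard deviations, and `F_t` is the instantaneous
correlation matrix ("instantaneous FC").  Estimating these quantities
timepoint-by-timepoint is hopeless without regularization, so each is a
convex, sum-to-one mixture of a small set of recurring states:

    m_t = Σ_p α_tp S_p,   F_t = Σ_q β_tq D_q,   G_t = Σ_r γ_tr diag(E_r),

with mean maps `S_p ∈ R^N` (p = 1..P), correlation states `D_q`
(symmetric, unit-diagonal, PSD; q = 1..Q) and positive standard-deviation
maps `E_r` (r = 1..R).  The mixing weights live on the simplex at every
timepoint (softmax of latent logits), so states are *partial-volume*:
several can be active at once, in contrast to the mutually exclusive
states of a classical Gaussian HMM.

The defining choice is **multi-dynamic** modelling: the correlation
mixture β is inferred on its own latent time course, independent of the
mean/variance mixture α (the mean and variance dynamics stay tied,
γ = α with P = R).  The single-dynamic variant (SAGE) shares one latent
stream across all three mixtures, which is the same coupling assumption
made by sliding-window correlation and the Gaussian HMM.  When the
ground truth has distinct mean and FC dynamics, a single-dynamic
estimator must compromise on one shared time course; the resulting FC
estimate is temporally smeared and looks more homogeneous than it is.
The simulation suite reproduces this effect.

## Inference: adversarial generator-encoder

Latent logits θ^m (T×P) and θ^c (T×Q) generate the mixtures through a
row-wise softmax (temperature 1, no annealing).  Three players interact:

* **Generator** — the state basis (S, D, E) plus a causal single-layer
  LSTM per latent stream that predicts the *prior mean* of θ_t from the
  history θ_{<t} (input shifted one step, zeros at t = 0).
* **Encoder** — a bidirectional single-layer LSTM per stream with an
  affine read-out mapping a data window to *posterior means* of the
  logits.  The posterior is deterministic; stochasticity enters through
  minibatching only.
* **Discriminator** — a bidirectional LSTM + sigmoid read-out that
  classifies softmaxed logit sequences as prior or posterior samples.

Losses: the reconstruction loss is the Gaussian negative log-likelihood
of the window under the composed moments, averaged per timepoint; the
regularization loss is the cross-entropy between the softmaxed posterior
and prior sequences, summed over the two streams.  The total objective
weights them as

    F = Λ · NLL + (1 − Λ)/2 · R,          Λ ∈ (0, 1), default 0.9.

Averaging the NLL per timepoint (rather than summing) keeps Λ's meaning
independent of window and batch size.  Each batch passes through two
phases: a reconstruction phase updating generator + encoder with the
discriminator frozen, and a regularization phase that (i) updates the
discriminator to separate prior from posterior and (ii) updates
encoder + prior to close the gap.  By default step (ii) minimizes the
cross-entropy R directly; a non-saturating adversarial variant (driving
the discriminator's outputs rather than the cross-entropy) is available
via `TrainingConfig.regularizer = "adversarial"`.  In the default mode
the discriminator does not enter the generator's loss, so its update
runs on a slower schedule (every third regularization phase,
`disc_interval`); the frequency of the regularization phase itself is
`reg_interval` (default: every batch — this phase materially drives
state recovery and is not merely cosmetic).

Correlation states are parameterized as normalized Cholesky factors —
`D = L̃ L̃ᵀ` with `L̃` the row-normalized lower triangle of an
unconstrained square matrix — which keeps every `D_q` a valid
correlation matrix under unconstrained gradient updates.  Standard
deviations are stored as logs.

### Initialization and model selection

Joint recovery of basis and encoder from random weights is fragile: the
likelihood surface has broad plateaus in which states merge or the
encoder locks onto a subset of states.  Training therefore warm-starts
from the data (`TrainingConfig.init = "data"`, the default):

* mean/std states from a quick full-covariance Gaussian HMM (temporal
  pooling makes its state assignment far more reliable than
  per-timepoint clustering when state means overlap in signal space);
* correlation states from k-means on short-window (20-sample)
  correlation matrices, the sliding-window-correlation view of the data;
* the encoders are briefly pretrained (up to 200 NAdam steps) to
  reproduce *soft* targets from those models — HMM posterior
  probabilities for the mean stream, label-smoothed (0.75 confidence)
  window-correlation cluster assignments for the FC stream.  The
  softness is deliberate: fully hard labels bias the encoder toward
  mutually exclusive states (wrong for partial-volume ground truths),
  while distance-derived responsibilities are too diffuse to anchor the
  FC stream.  This warm start is self-supervised and only sets the
  starting point; all parameters remain free afterwards.

Optimization uses NAdam (learning rate 1e-4 and momentum 0.9 by
default, matching the reference settings for large cohorts; the
desk-scale studies below use 1e-2, chosen by monitoring validation
loss, which is how these rates are set in this family of models).
Gradients are clipped at norm 10.  Windows are sampled without
replacement each epoch under the run seed; 80% of windows train, 20%
validate.  Model selection and early stopping track the *held-out
reconstruction* loss: the regularizer is a moving target whose
validation value spikes whenever the prior lags the sharpening
posterior, so the total objective is a poor selection signal.  When the
held-out reconstruction stalls for a third of the patience window, all
learning rates halve and the best weights are restored; training stops
after a full patience window at the floor rate (1/64 of the initial
rate).

### Final re-estimation of the FC states

The softmax never fully saturates, so on near-categorical ground truths
the inferred mixtures have maxima around 0.97–0.99 rather than 1.  The
gradient-trained `D_q` compensate for that residual softness by
extrapolating slightly beyond the data; the pattern of each state is
essentially unaffected (edge correlations with truth ≈ 0.99 in the
categorical study) but the smallest eigenvalues collapse toward zero,
which the affine-invariant Riemannian metric punishes heavily.  `fit`
therefore ends with one explicit M-step with the inferred time courses
frozen: each `D_q` is replaced by the β²-weighted, conditionally
centered sample correlation of the data after removing the
hard-assigned mean/std estimate, floored at eigenvalue 1e-8 and
re-normalized.  A uniform weight floor of 0.01 per timepoint is added:
negligible for an active state, but dominant for a state the model
never activates, which therefore inherits (approximately) the global
correlation — the best available estimate for an unused state.  The
step is `TrainingConfig.reestimate_fc` (default on).

## Dual-estimation

Subject-level state maps come from re-optimizing S, D, E against a
subject's data with the group-inferred time courses frozen (the
state-space analogue of dual regression), warm-started at the group
basis with the group optimizer settings at one tenth of the epochs.  On
divergence the group basis is returned with a failure flag.

## Simulators

The synthetic ground truths mirror the study designs the estimators are
validated on.  Common defaults: N = 8 channels, unit-variance noise,
mean maps drawn from N(0, 1) (so mean states overlap substantially in
signal space — state identification must pool over time), and
correlation states `D = 0.8·C₀ + 0.2·I` with C₀ a random
Wishart-derived correlation matrix.  The shrinkage keeps every state
well conditioned (eigmin ≥ 0.2), as empirical FC matrices of
standardized parcel data are, while leaving strong off-diagonal
structure (|r| up to ≈ 0.7).

* **categorical** — one-hot states from a Markov chain, self-transition
  0.95 (geometric dwell, mean 20 samples).
* **partial_volume** — dwell-segmented active subsets of ≤ `max_active`
  states with Dirichlet(1) weights, smoothed by a 3-sample moving
  average and renormalized; single-dynamic (α = β = γ).
* **multidynamic_hsmm** — independent semi-Markov chains for α and β
  with gamma-distributed lifetimes (shape k, scale 1 sample, dwell =
  max(1, round(draw)), no self-visits).  The study grid fixes the FC
  lifetime shape k_corr = 30 and varies the mean lifetime shape.
* **static** — one correlation state held for the whole session; means
  may still fluctuate.
* **ar_surrogate** — least-squares multivariate AR(order) fit (default
  order 10) iterated with Gaussian innovations from the residual
  covariance; preserves linear autocorrelation and static covariance,
  destroying any genuine FC dynamics.  This is the null for the
  edge-wise FC-dynamics test, which compares the temporal variance of
  each inferred instantaneous-FC edge against the same statistic from
  models refitted to surrogates (add-one permutation p-values, never
  exactly 0).

What the simulators do *not* emulate: hemodynamics, spatial structure
of parcels, physiological noise, session effects, or between-subject
variability in the state maps.  Passing the suite shows the estimator
recovers the generative structure it assumes, at realistic SNR and
dwell statistics — not that it is robust to the full complexity of real
recordings.

## Desk-scale study sizes

The reproduction suite (`magefc.reproduce`, `scripts/acceptance.py`)
runs every study on one CPU with deliberately modest sizes: categorical
recovery at T = 10,000 with W = 50, B = 16, 16 LSTM units, up to 150
epochs; the partial-volume and multi-dynamic comparisons at T = 4,000
over 5 seeds each; the static-FC control at T = 8,000 (the residual
between-state spread of a static fit is re-estimation sampling noise and
shrinks with T); null calibration over 3 simulations of T = 1,200 with
20 AR(10) surrogates each and a 20-epoch configuration (calibration
depends on exchangeability of the statistic between data and
surrogates, not on fit quality).  These sizes were chosen once as the
smallest at which the compared effects are stable across seeds.

## Numerical choices

* Covariances receive 1e-6·I jitter before factorization whenever the
  smallest eigenvalue drops below 1e-10; likelihoods and distances
  reject inputs that remain non-PSD.
* The affine-invariant SPD distance is `sqrt(Σ ln² λ_i)` with λ the
  generalized eigenvalues; symmetric inputs are required, 1e-6 jitter is
  applied only to near-singular inputs.
* State matching maximizes total Pearson correlation via the Hungarian
  algorithm (exact; verified against exhaustive search for K ≤ 5).
* `rank_one_map` fixes the eigenvector sign so the largest-magnitude
  entry is positive; exactly tied leading eigenvalues return the first
  coordinate vector with a warning.
* Switching rate counts pooled 0→1 onsets (a run starting at t = 0
  counts) per second; lifetimes are contiguous-run lengths × dt and are
  reported separately for α- and β-derived binarizations.
* The meta-state matrix demeans fractional occupancy per state across
  subjects before forming υυ′, so it reflects covariance structure.
* All randomness flows from explicit integer seeds; identical seed +
  config + data reproduce every artifact bit-for-bit.

## Known limitations

* The recurrent networks are single-layer and small (8–64 units); the
  trainer targets desk-scale problems (T ≲ 10⁵, N ≲ 30), not
  thousand-subject cohorts.
* The deterministic posterior gives no uncertainty on the time courses.
* With Q states and near-static ground truth, unused states retain
  their initialization; between-state distances on such fits reflect
  initialization spread, which the no-spurious-dynamics check accounts
  for by comparing against a dynamic reference fit.
* The FC-dynamics surrogate test refits the full model per surrogate;
  with small surrogate counts (~20) its p-value resolution is 1/21.
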