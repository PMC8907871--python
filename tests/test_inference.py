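"""Encoder/discriminator/loss contracts and trainer plumbing.

Heavier end-to-end recovery checks live in test_acceptance.py; here we
pin the cheap, deterministic behaviour of each inference operation.
"""

import numpy as np
import pytest

from magefc import (
    Logits,
    SimSpec,
    TimeSeriesData,
    TrainingConfig,
    compute_losses,
    discriminate,
    encode,
    fit,
    simulate_categorical,
)
from magefc.autodiff import Tensor, softmax as ad_softmax
from magefc.inference import (
    MageNetworks,
    _bce,
    _make_windows,
    infer_timecourses,
)
from magefc.model import compose_moments, softmax_timecourses
from magefc.nn import NAdam


@pytest.fixture
def nets():
    cfg = TrainingConfig(n_states_mean=3, n_states_fc=4, lstm_units=8)
    return MageNetworks(cfg, n_channels=5, rng=np.random.default_rng(7))


@pytest.fixture
def window(rng):
    return TimeSeriesData(rng.standard_normal((40, 5)))


class TestTrainingConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(window_length=1)
        with pytest.raises(ValueError):
            TrainingConfig(loss_weight=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(val_fraction=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(variant="sage", n_states_mean=3, n_states_fc=4)


class TestEncode:
    def test_deterministic_and_shaped(self, nets, window):
        a = encode(window, nets)
        b = encode(window, nets)
        np.testing.assert_array_equal(a.theta_m, b.theta_m)
        np.testing.assert_array_equal(a.theta_c, b.theta_c)
        assert a.theta_m.shape == (40, 3)
        assert a.theta_c.shape == (40, 4)
        assert a.role == "posterior_mean"

    def test_channel_mismatch_rejected(self, nets, rng):
        with pytest.raises(ValueError):
            encode(TimeSeriesData(rng.standard_normal((40, 3))), nets)

    def test_sage_shares_one_latent_stream(self, rng):
        cfg = TrainingConfig(n_states_mean=3, n_states_fc=3, lstm_units=8,
                             variant="sage")
        nets = MageNetworks(cfg, n_channels=4, rng=np.random.default_rng(1))
        lg = encode(TimeSeriesData(rng.standard_normal((30, 4))), nets)
        np.testing.assert_array_equal(lg.theta_m, lg.theta_c)


class TestDiscriminate:
    def test_probabilities_in_open_interval(self, nets, rng):
        pri = Logits(rng.standard_normal((30, 3)), rng.standard_normal((30, 4)),
                     role="prior_mean")
        post = Logits(rng.standard_normal((30, 3)), rng.standard_normal((30, 4)))
        out = discriminate(pri, post, nets)
        for stream in ("m", "c"):
            for key in ("prior", "posterior"):
                p = out[stream][key]
                assert p.shape == (30,)
                assert np.all((p > 0) & (p < 1))

    def test_untrained_discriminator_is_at_chance(self, rng):
        """AUC over a batch of identically distributed prior/posterior
        sequences stays near 0.5 for a random discriminator."""
        cfg = TrainingConfig(n_states_mean=3, n_states_fc=3, lstm_units=8)
        scores, labels = [], []
        for trial in range(20):
            nets_t = MageNetworks(cfg, 4, np.random.default_rng(100 + trial))
            seq = rng.standard_normal((25, 3))
            pri = Logits(seq, seq.copy(), role="prior_mean")
            post = Logits(rng.standard_normal((25, 3)), seq.copy())
            out = discriminate(pri, post, nets_t)
            scores += [out["m"]["prior"].mean(), out["m"]["posterior"].mean()]
            labels += [0, 1]
        scores, labels = np.asarray(scores), np.asarray(labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        auc = (pos[:, None] > neg[None, :]).mean()
        assert 0.3 <= auc <= 0.7

    def test_length_mismatch_rejected(self, nets, rng):
        pri = Logits(rng.standard_normal((30, 3)), rng.standard_normal((30, 4)),
                     role="prior_mean")
        post = Logits(rng.standard_normal((20, 3)), rng.standard_normal((20, 4)))
        with pytest.raises(ValueError):
            discriminate(pri, post, nets)

    def test_discriminator_is_trainable_on_separable_sequences(self):
        """A few gradient steps should separate obviously different
        prior/posterior sequence distributions."""
        rng = np.random.default_rng(3)
        cfg = TrainingConfig(n_states_mean=2, n_states_fc=2, lstm_units=8)
        nets_t = MageNetworks(cfg, 4, np.random.default_rng(3))
        opt = NAdam(nets_t.discriminator_params(), lr=0.05, clip_norm=10.0)
        T = 20

        def sample_pair():
            # prior: smooth near-uniform; posterior: saturated one-hot-ish
            pri = 0.1 * rng.standard_normal((1, T, 2))
            states = rng.integers(2, size=T)
            post = np.where(states[:, None] == np.arange(2), 4.0, -4.0)[None]
            return pri, post

        for _ in range(60):
            pri, post = sample_pair()
            loss = _bce(nets_t.discriminate_logits(ad_softmax(Tensor(pri)), "m"), 0.0)
            loss = loss + _bce(
                nets_t.discriminate_logits(ad_softmax(Tensor(post)), "m"), 1.0
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
        correct = 0
        n_eval = 40
        for _ in range(n_eval):
            pri, post = sample_pair()
            p_pri = nets_t.discriminate_logits(
                ad_softmax(Tensor(pri)), "m").data.mean()
            p_post = nets_t.discriminate_logits(
                ad_softmax(Tensor(post)), "m").data.mean()
            correct += int(p_pri < 0.5) + int(p_post >= 0.5)
        assert correct / (2 * n_eval) > 0.9


class TestComputeLosses:
    def _inputs(self, rng, theta_post, theta_pri):
        lg_post = Logits(theta_post, theta_post.copy())
        lg_pri = Logits(theta_pri, theta_pri.copy(), role="prior_mean")
        tcs = softmax_timecourses(lg_post)
        from magefc import random_basis

        basis = random_basis(
            SimSpec(n_channels=3, n_timepoints=10, n_states_mean=2, n_states_fc=2),
            rng,
        )
        mom = compose_moments(tcs, basis)
        data = TimeSeriesData(rng.standard_normal((len(theta_post), 3)))
        return data, mom, lg_pri, lg_post

    def test_matched_distributions_give_entropy(self, rng):
        theta = rng.standard_normal((8, 2))
        data, mom, pri, post = self._inputs(rng, theta, theta.copy())
        rep = compute_losses(data, mom, pri, post, 0.9)
        p = np.exp(theta) / np.exp(theta).sum(axis=1, keepdims=True)
        entropy = float(-(p * np.log(p)).sum(axis=1).mean())
        np.testing.assert_allclose(rep.train_reg[0], 2 * entropy, atol=1e-9)

    def test_uniform_cross_entropy_is_ln2(self, rng):
        theta = np.zeros((5, 2))
        data, mom, pri, post = self._inputs(rng, theta, theta.copy())
        rep = compute_losses(data, mom, pri, post, 0.9)
        np.testing.assert_allclose(rep.train_reg[0], 2 * np.log(2), atol=1e-9)

    def test_lambda_weighting_is_linear(self, rng):
        theta = rng.standard_normal((6, 2))
        data, mom, pri, post = self._inputs(rng, theta, theta + 0.5)
        lam = 0.9
        rep = compute_losses(data, mom, pri, post, lam)
        nll, reg, tot = rep.train_recon[0], rep.train_reg[0], rep.train_total[0]
        np.testing.assert_allclose(tot, lam * nll + 0.5 * (1 - lam) * reg, atol=1e-12)

    def test_lambda_out_of_range_rejected(self, rng):
        theta = np.zeros((4, 2))
        data, mom, pri, post = self._inputs(rng, theta, theta.copy())
        with pytest.raises(ValueError):
            compute_losses(data, mom, pri, post, 1.0)


class TestFitPlumbing:
    def test_batch_larger_than_data_rejected(self, rng):
        d = TimeSeriesData(rng.standard_normal((100, 3)))
        cfg = TrainingConfig(n_states_mean=2, n_states_fc=2, window_length=50,
                             batch_size=32, n_epochs=1)
        with pytest.raises(ValueError):
            fit([d], cfg)

    def test_window_stacking(self, rng):
        subjects = [TimeSeriesData(rng.standard_normal((110, 3))),
                    TimeSeriesData(rng.standard_normal((70, 3)))]
        wins = _make_windows(subjects, 50)
        assert wins.shape == (3, 50, 3)  # 2 + 1 full windows

    def test_inferred_timecourses_are_simplex(self):
        gt = simulate_categorical(
            SimSpec(n_channels=4, n_timepoints=400, n_states_mean=2,
                    n_states_fc=2, seed=60)
        )
        cfg = TrainingConfig(n_states_mean=2, n_states_fc=2, window_length=40,
                             batch_size=4, n_epochs=2, lstm_units=8, seed=0)
        model = fit([gt.data], cfg)
        tcs = infer_timecourses(model, gt.data)
        np.testing.assert_allclose(tcs.alpha.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(tcs.beta.sum(axis=1), 1.0, atol=1e-6)


class TestInferTimecourses:
    @pytest.fixture(scope="class")
    def model(self):
        gt = simulate_categorical(
            SimSpec(n_channels=4, n_timepoints=500, n_states_mean=2,
                    n_states_fc=2, seed=61)
        )
        cfg = TrainingConfig(n_states_mean=2, n_states_fc=2, window_length=50,
                             batch_size=4, n_epochs=2, lstm_units=8, seed=0)
        return fit([gt.data], cfg)

    def test_exact_multiple_gives_full_length(self, model, rng):
        d = TimeSeriesData(rng.standard_normal((150, 4)))
        tcs = infer_timecourses(model, d)
        assert tcs.n_timepoints == 150
        assert tcs.meta["padded"] is False

    def test_concatenation_matches_per_window_encoding(self, model, rng):
        d = TimeSeriesData(rng.standard_normal((150, 4)))
        std = d.standardized()
        tcs = infer_timecourses(model, d)
        manual = []
        for i in range(3):
            win = TimeSeriesData(std.values[i * 50 : (i + 1) * 50])
            manual.append(softmax_timecourses(encode(win, model.networks)).alpha)
        np.testing.assert_allclose(tcs.alpha, np.vstack(manual), atol=1e-12)

    def test_identical_windows_identical_outputs(self, model, rng):
        block = rng.standard_normal((50, 4))
        d = TimeSeriesData(np.vstack([block, block]))
        std = d.standardized()
        tcs = infer_timecourses(model, d)
        np.testing.assert_allclose(tcs.alpha[:50], tcs.alpha[50:], atol=1e-12)

    def test_partial_window_flagged_and_full_length(self, model, rng):
        d = TimeSeriesData(rng.standard_normal((130, 4)))
        tcs = infer_timecourses(model, d)
        assert tcs.n_timepoints == 130
        assert tcs.meta["padded"] is True
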