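"""Observation-model operations: softmax courses, moment composition,
correlation projection, likelihood, causal prior, data sampling."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from magefc import (
    Logits,
    SimSpec,
    StateBasis,
    StateTimeCourses,
    TimeSeriesData,
    compose_moments,
    log_likelihood,
    prior_transition,
    random_basis,
    sample_data,
    softmax_timecourses,
    to_correlation,
)
from magefc.inference import MageNetworks, TrainingConfig


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_timeseries_rejects_nan_and_degenerate_shapes(self):
        with pytest.raises(ValueError):
            TimeSeriesData(np.array([[np.nan, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            TimeSeriesData(np.ones((1, 4)))
        with pytest.raises(ValueError):
            TimeSeriesData(np.ones((10, 1)))

    def test_standardized_columns_are_zscored(self, rng):
        d = TimeSeriesData(5 + 3 * rng.standard_normal((200, 4))).standardized()
        assert d.is_standardized(tol=1e-6)

    def test_basis_rejects_invalid_correlations(self, small_basis):
        D = small_basis.corr_states.copy()
        D[0, 0, 1] = 0.9
        D[0, 1, 0] = 0.1  # asymmetric
        with pytest.raises(ValueError):
            StateBasis(small_basis.mean_maps, D, small_basis.std_maps)
        with pytest.raises(ValueError):
            StateBasis(small_basis.mean_maps, small_basis.corr_states,
                       np.zeros_like(small_basis.std_maps))

    def test_timecourses_enforce_simplex(self, rng):
        a = rng.random((10, 3))
        with pytest.raises(ValueError):
            StateTimeCourses(alpha=a, beta=a)


# ---------------------------------------------------------------------------
# softmax_timecourses
# ---------------------------------------------------------------------------

class TestSoftmaxTimecourses:
    def test_equal_logits_give_uniform_weights(self):
        lg = Logits(np.zeros((5, 3)), np.zeros((5, 3)))
        tcs = softmax_timecourses(lg)
        np.testing.assert_allclose(tcs.alpha, 1 / 3)
        np.testing.assert_allclose(tcs.beta, 1 / 3)

    def test_saturation(self):
        lg = Logits(np.array([[50.0, 0.0]]), np.array([[0.0, 0.0]]))
        tcs = softmax_timecourses(lg)
        np.testing.assert_allclose(tcs.alpha[0], [1.0, 0.0], atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        lg = Logits(rng.standard_normal((50, 4)), rng.standard_normal((50, 6)))
        tcs = softmax_timecourses(lg)
        np.testing.assert_allclose(tcs.alpha.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(tcs.beta.sum(axis=1), 1.0, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            Logits(np.array([[np.nan, 0.0]]), np.zeros((1, 2)))


# ---------------------------------------------------------------------------
# compose_moments
# ---------------------------------------------------------------------------

def compose_moments_bruteforce(tcs, basis):
    """Triple-loop oracle for the state-mixture composition."""
    T = tcs.n_timepoints
    N = basis.n_channels
    m = np.zeros((T, N))
    F = np.zeros((T, N, N))
    g = np.zeros((T, N))
    for t in range(T):
        for p in range(basis.P):
            m[t] += tcs.alpha[t, p] * basis.mean_maps[p]
            g[t] += tcs.gamma[t, p] * basis.std_maps[p]
        for q in range(basis.Q):
            F[t] += tcs.beta[t, q] * basis.corr_states[q]
    C = np.stack([np.diag(g[t]) @ F[t] @ np.diag(g[t]) for t in range(T)])
    return m, g, F, C


class TestComposeMoments:
    def test_single_state_identity(self, rng):
        spec = SimSpec(n_channels=3, n_timepoints=10, n_states_mean=1, n_states_fc=1)
        basis = random_basis(spec, rng)
        ones = np.ones((7, 1))
        tcs = StateTimeCourses(alpha=ones, beta=ones.copy(), gamma=ones.copy())
        mom = compose_moments(tcs, basis)
        for t in range(7):
            np.testing.assert_allclose(mom.mean[t], basis.mean_maps[0])
            np.testing.assert_allclose(mom.corr[t], basis.corr_states[0])
            E = np.diag(basis.std_maps[0])
            np.testing.assert_allclose(mom.cov[t], E @ basis.corr_states[0] @ E)

    def test_identity_correlations_give_identity_covariance(self, rng):
        basis = StateBasis(
            mean_maps=np.zeros((2, 3)),
            corr_states=np.stack([np.eye(3), np.eye(3)]),
            std_maps=np.ones((2, 3)),
        )
        b = rng.dirichlet(np.ones(2), size=5)
        tcs = StateTimeCourses(alpha=b, beta=b.copy(), gamma=b.copy())
        mom = compose_moments(tcs, basis)
        for t in range(5):
            np.testing.assert_allclose(mom.cov[t], np.eye(3), atol=1e-12)

    def test_half_half_mixture_equals_average(self, small_basis):
        T = 4
        b = np.full((T, 3), [0.5, 0.5, 0.0])
        tcs = StateTimeCourses(alpha=b, beta=b.copy(), gamma=b.copy())
        mom = compose_moments(tcs, small_basis)
        expected = (small_basis.corr_states[0] + small_basis.corr_states[1]) / 2
        for t in range(T):
            np.testing.assert_allclose(mom.corr[t], expected, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            spec = SimSpec(n_channels=4, n_timepoints=10, n_states_mean=3, n_states_fc=2)
            basis = random_basis(spec, rng)
            a = rng.dirichlet(np.ones(3), size=8)
            b = rng.dirichlet(np.ones(2), size=8)
            tcs = StateTimeCourses(alpha=a, beta=b, gamma=a.copy())
            mom = compose_moments(tcs, basis)
            m, g, F, C = compose_moments_bruteforce(tcs, basis)
            np.testing.assert_allclose(mom.mean, m, atol=1e-12)
            np.testing.assert_allclose(mom.std_diag, g, atol=1e-12)
            np.testing.assert_allclose(mom.corr, F, atol=1e-12)
            np.testing.assert_allclose(mom.cov, C, atol=1e-12)

    def test_convexity_bounds_on_instantaneous_fc(self, small_basis, small_tcs):
        mom = compose_moments(small_tcs, small_basis)
        lo = small_basis.corr_states.min(axis=0)
        hi = small_basis.corr_states.max(axis=0)
        assert np.all(mom.corr >= lo[None] - 1e-12)
        assert np.all(mom.corr <= hi[None] + 1e-12)

    def test_unit_diagonal_preserved(self, small_basis, small_tcs):
        mom = compose_moments(small_tcs, small_basis)
        diags = np.einsum("tii->ti", mom.corr)
        np.testing.assert_allclose(diags, 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, small_basis, rng):
        a = rng.dirichlet(np.ones(5), size=10)
        tcs = StateTimeCourses(alpha=a, beta=a.copy(), gamma=a.copy())
        with pytest.raises(ValueError):
            compose_moments(tcs, small_basis)


# ---------------------------------------------------------------------------
# to_correlation
# ---------------------------------------------------------------------------

class TestToCorrelation:
    def test_identity_maps_to_identity(self):
        np.testing.assert_allclose(to_correlation(np.eye(4)), np.eye(4))

    def test_contract_on_random_input(self, rng):
        for _ in range(10):
            C = to_correlation(rng.standard_normal((5, 5)))
            np.testing.assert_allclose(np.diag(C), 1.0)
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_2x2_closed_form(self):
        a, b = 0.6, 1.7
        raw = np.array([[1.0, 0.0], [a, b]])
        C = to_correlation(raw)
        np.testing.assert_allclose(C[0, 1], a / np.sqrt(a**2 + b**2), atol=1e-12)

    def test_zero_row_falls_back_to_identity_row(self):
        raw = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            C = to_correlation(raw)
        np.testing.assert_allclose(C, np.eye(2))


# ---------------------------------------------------------------------------
# log_likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_standard_normal_value(self):
        T = 6
        data = TimeSeriesData(np.zeros((T, 2)) + 1e-12)
        mom = compose_moments(
            StateTimeCourses(np.ones((T, 1)), np.ones((T, 1))),
            StateBasis(np.zeros((1, 2)), np.eye(2)[None], np.ones((1, 2))),
        )
        ll = log_likelihood(data, mom)
        np.testing.assert_allclose(ll, -0.5 * 2 * T * np.log(2 * np.pi), atol=1e-6)

    def test_matches_dense_algebra_oracle(self, rng):
        for _ in range(5):
            spec = SimSpec(n_channels=3, n_timepoints=5, n_states_mean=2, n_states_fc=2)
            basis = random_basis(spec, rng)
            a = rng.dirichlet(np.ones(2), size=5)
            tcs = StateTimeCourses(alpha=a, beta=a.copy(), gamma=a.copy())
            mom = compose_moments(tcs, basis)
            y = rng.standard_normal((5, 3))
            data = TimeSeriesData(y)
            expected = sum(
                multivariate_normal.logpdf(y[t], mom.mean[t], mom.cov[t])
                for t in range(5)
            )
            np.testing.assert_allclose(log_likelihood(data, mom), expected, atol=1e-8)

    def test_state_permutation_invariance(self, rng):
        spec = SimSpec(n_channels=4, n_timepoints=8, n_states_mean=3, n_states_fc=3)
        basis = random_basis(spec, rng)
        a = rng.dirichlet(np.ones(3), size=8)
        b = rng.dirichlet(np.ones(3), size=8)
        tcs = StateTimeCourses(alpha=a, beta=b, gamma=a.copy())
        y = TimeSeriesData(rng.standard_normal((8, 4)))
        ll1 = log_likelihood(y, compose_moments(tcs, basis))
        perm = [2, 0, 1]
        basis_p = StateBasis(
            basis.mean_maps[perm], basis.corr_states[perm], basis.std_maps[perm]
        )
        tcs_p = StateTimeCourses(a[:, perm], b[:, perm], a[:, perm].copy())
        ll2 = log_likelihood(y, compose_moments(tcs_p, basis_p))
        np.testing.assert_allclose(ll1, ll2, atol=1e-9)


# ---------------------------------------------------------------------------
# prior_transition
# ---------------------------------------------------------------------------

class TestPriorTransition:
    @pytest.fixture
    def nets(self):
        cfg = TrainingConfig(n_states_mean=3, n_states_fc=3, lstm_units=8)
        return MageNetworks(cfg, n_channels=4, rng=np.random.default_rng(0))

    def test_causality(self, nets, rng):
        theta = rng.standard_normal((10, 3))
        lg = Logits(theta, theta.copy())
        out1 = prior_transition(lg, nets)
        theta2 = theta.copy()
        theta2[7] += 5.0  # perturb at t=7
        out2 = prior_transition(Logits(theta2, theta2.copy()), nets)
        np.testing.assert_array_equal(out1.theta_m[:8], out2.theta_m[:8])
        assert not np.allclose(out1.theta_m[8:], out2.theta_m[8:])

    def test_determinism(self, nets, rng):
        theta = rng.standard_normal((6, 3))
        lg = Logits(theta, theta.copy())
        a = prior_transition(lg, nets)
        b = prior_transition(lg, nets)
        np.testing.assert_array_equal(a.theta_m, b.theta_m)
        assert a.role == "prior_mean"

    def test_short_window_rejected(self, nets):
        with pytest.raises(ValueError):
            prior_transition(Logits(np.zeros((1, 3)), np.zeros((1, 3))), nets)

    def test_zero_weights_give_constant_output(self, rng):
        cfg = TrainingConfig(n_states_mean=3, n_states_fc=3, lstm_units=8)
        nets = MageNetworks(cfg, n_channels=4, rng=np.random.default_rng(5))
        for params in (nets.generator_params(),):
            for p in params.values():
                p.data[...] = 0.0
        theta = rng.standard_normal((12, 3))
        out = prior_transition(Logits(theta, theta.copy()), nets)
        assert np.ptp(out.theta_m, axis=0).max() < 1e-12  # same value at every t


# ---------------------------------------------------------------------------
# sample_data
# ---------------------------------------------------------------------------

class TestSampleData:
    def test_zero_noise_limit_returns_mean(self, rng):
        basis = StateBasis(
            mean_maps=np.array([[5.0, -3.0]]),
            corr_states=np.eye(2)[None],
            std_maps=np.full((1, 2), 1e-4),
        )
        tcs = StateTimeCourses(np.ones((20, 1)), np.ones((20, 1)))
        d = sample_data(basis, tcs, seed=0)
        np.testing.assert_allclose(d.values, np.tile([5.0, -3.0], (20, 1)), atol=1e-3)

    def test_static_state_sample_correlation_converges(self, rng):
        spec = SimSpec(n_channels=4, n_timepoints=50_000, n_states_mean=1, n_states_fc=1)
        basis = random_basis(spec, rng)
        T = 50_000
        tcs = StateTimeCourses(np.ones((T, 1)), np.ones((T, 1)))
        d = sample_data(basis, tcs, seed=7)
        C = np.corrcoef(d.values.T)
        assert np.abs(C - basis.corr_states[0]).max() < 0.03

    def test_seed_reproducibility(self, small_basis, small_tcs):
        d1 = sample_data(small_basis, small_tcs, seed=11)
        d2 = sample_data(small_basis, small_tcs, seed=11)
        np.testing.assert_array_equal(d1.values, d2.values)
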