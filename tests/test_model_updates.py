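"""Closed-form update operations against hand-computed and scalar-transcribed
reference values."""

import numpy as np
import pytest

from flare import model
from flare.model import (
    EventMatrix,
    Hyperparameters,
    InvalidStateError,
    update_component_moments,
    update_prototype_means,
    update_prototype_shapes,
    update_responsibilities,
    update_sample_means,
    update_sample_precisions,
    update_weights,
)

from conftest import blank_state, single_event
from oracles import scalar_log_responsibilities, softmax


def rhp(D=1, K=2, **kw):
    return Hyperparameters(K=K, **kw).resolved(D)


class TestResponsibilities:
    def test_single_component_is_certain(self):
        st = blank_state(M=1, K=1, D=2)
        data = [EventMatrix("s", np.random.default_rng(0).normal(size=(7, 2)), ["a", "b"])]
        update_responsibilities(st, data, rhp(D=2, K=1))
        assert np.array_equal(st.r[0], np.ones((7, 1)))

    def test_identical_components_split_evenly(self):
        st = blank_state(M=1, K=2, D=2)
        st.alpha[:] = 5.0
        data = [EventMatrix("s", np.array([[0.3, -1.2], [2.0, 0.5]]), ["a", "b"])]
        update_responsibilities(st, data, rhp(D=2))
        assert np.array_equal(st.r[0], np.full((2, 2), 0.5))

    def test_matches_scalar_transcription(self):
        """1-D, one event, hand-set parameters: the vectorized update equals a
        symbol-by-symbol scalar evaluation of the membership formula."""
        st = blank_state(M=1, K=2, D=1)
        st.omega[0, 0, 0], st.omega[0, 1, 0] = 1.0, -1.0
        st.Psi[0, :, 0, 0] = 1.0
        st.sigma[0, :] = 3.0
        st.Gamma[0, :, 0, 0] = 0.1
        st.alpha[0, :] = 5.0
        data = [single_event(0.0)]
        update_responsibilities(st, data, rhp(beta0=500.0))
        expected_log = scalar_log_responsibilities(
            0.0, alphas=[5.0, 5.0], omegas=[1.0, -1.0], Gammas=[0.1, 0.1],
            Psis=[1.0, 1.0], sigmas=[3.0, 3.0],
        )
        np.testing.assert_allclose(st.log_rho[0][0], expected_log, rtol=0, atol=1e-12)
        np.testing.assert_allclose(st.r[0][0], softmax(expected_log), atol=1e-12)

    def test_underflow_reports_event(self):
        """If every component's log-density underflows for an event, the
        failure names the sample rather than producing NaNs."""
        from flare.model import UnderflowError

        st = blank_state(M=1, K=2, D=1)
        st.omega[0, :, 0] = 1e200  # quadratic term overflows to +inf
        with pytest.raises(UnderflowError, match="sample"):
            update_responsibilities(st, [single_event(0.0)], rhp())

    def test_non_spd_psi_is_rejected(self):
        st = blank_state(M=1, K=2, D=2)
        st.Psi[0, 0] = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(InvalidStateError):
            update_responsibilities(
                st, [EventMatrix("s", np.zeros((1, 2)), ["a", "b"])], rhp(D=2)
            )


class TestDomainTypes:
    def test_event_matrix_validation(self):
        with pytest.raises(ValueError):
            EventMatrix("s", np.array([[np.nan, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            EventMatrix("s", np.ones((2, 2)), ["a", "a"])
        with pytest.raises(ValueError):
            EventMatrix("s", np.ones((0, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            EventMatrix("s", np.ones((2, 2)), ["a"])

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            Hyperparameters(K=0).resolved(2)
        with pytest.raises(ValueError):
            Hyperparameters(K=2, alpha0=-1.0).resolved(2)
        with pytest.raises(ValueError):
            Hyperparameters(K=2, sigma0=0.5).resolved(2)  # needs > D - 1
        with pytest.raises(ValueError):
            Hyperparameters(
                K=2, Phi0=np.array([[1.0, 2.0], [2.0, 1.0]])
            ).resolved(2)
        hp = Hyperparameters(K=2).resolved(3)
        assert hp.sigma0 == 18.0 and hp.nu0 == 18.0
        np.testing.assert_array_equal(hp.Phi0, np.eye(3))
        np.testing.assert_array_equal(hp.xi0, np.zeros(3))


class TestWeights:
    def test_direct_sum(self):
        st = blank_state(M=1, K=2, D=1)
        st.r[0] = np.vstack([np.tile([1.0, 0.0], (10, 1))])
        update_weights(st, rhp(alpha0=1.0))
        np.testing.assert_allclose(st.Nk[0], [10.0, 0.0])
        np.testing.assert_allclose(st.alpha[0], [11.0, 1.0])

    def test_uniform_rows(self):
        K = 4
        st = blank_state(M=1, K=K, D=1)
        st.r[0] = np.full((K, K), 1.0 / K)
        update_weights(st, rhp(K=K))
        np.testing.assert_allclose(st.Nk[0], np.ones(K))

    def test_random_rows_match_loop_sums(self):
        rng = np.random.default_rng(42)
        raw = rng.random((50, 3))
        r = raw / raw.sum(axis=1, keepdims=True)
        st = blank_state(M=1, K=3, D=1)
        st.r[0] = r
        update_weights(st, rhp(K=3))
        expected = [sum(r[n, k] for n in range(50)) for k in range(3)]
        np.testing.assert_allclose(st.Nk[0], expected, atol=1e-12)
        assert abs(st.Nk[0].sum() - 50.0) < 1e-8


class TestComponentMoments:
    def test_full_responsibility_reduces_to_sample_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        st = blank_state(M=1, K=1, D=3)
        st.r[0] = np.ones((40, 1))
        st.Nk[0, 0] = 40.0
        update_component_moments(st, [EventMatrix("s", X, ["a", "b", "c"])])
        np.testing.assert_allclose(st.xbar[0, 0], X.mean(axis=0), atol=1e-12)
        centred = X - X.mean(axis=0)
        np.testing.assert_allclose(st.S[0, 0], centred.T @ centred / 40, atol=1e-12)

    def test_empty_component_falls_back(self):
        st = blank_state(M=1, K=2, D=2)
        st.r[0] = np.tile([1.0, 0.0], (5, 1))
        st.Nk[0] = [5.0, 0.0]
        st.xi[1] = [7.0, -3.0]
        data = [EventMatrix("s", np.ones((5, 2)), ["a", "b"])]
        update_component_moments(st, data)
        assert np.all(np.isfinite(st.xbar)) and np.all(np.isfinite(st.S))
        np.testing.assert_array_equal(st.xbar[0, 1], [7.0, -3.0])
        np.testing.assert_array_equal(st.S[0, 1], np.zeros((2, 2)))

    def test_hand_weighted_two_point_example(self):
        st = blank_state(M=1, K=1, D=1)
        st.r[0] = np.array([[0.25], [0.75]])
        st.Nk[0, 0] = 1.0
        data = [EventMatrix("s", np.array([[0.0], [2.0]]), ["a"])]
        update_component_moments(st, data)
        assert abs(st.xbar[0, 0, 0] - 1.5) < 1e-12
        assert abs(st.S[0, 0, 0, 0] - 0.75) < 1e-12


class TestSampleMeans:
    def test_empty_component_returns_prototype(self):
        st = blank_state(M=1, K=1, D=2, beta0=500.0)
        st.xi[0] = [1.5, -2.0]
        update_sample_means(st, rhp(D=2, K=1, beta0=500.0))
        np.testing.assert_allclose(st.omega[0, 0], [1.5, -2.0], atol=1e-14)
        np.testing.assert_allclose(st.Gamma[0, 0], np.eye(2) / 500.0, atol=1e-14)

    def test_huge_beta0_pins_mean_to_prototype(self):
        st = blank_state(M=1, K=1, D=2)
        st.Nk[0, 0] = 10.0
        st.xbar[0, 0] = [3.0, 3.0]
        st.xi[0] = [1.0, -1.0]
        update_sample_means(st, rhp(D=2, K=1, beta0=1e12))
        np.testing.assert_allclose(st.omega[0, 0], [1.0, -1.0], rtol=1e-6)

    def test_scalar_transcription(self):
        # Nk=4, E[Lambda]=2 (sigma * Psi), xbar=3, beta0=1, xi=0
        st = blank_state(M=1, K=1, D=1)
        st.Nk[0, 0] = 4.0
        st.sigma[0, 0] = 2.0
        st.Psi[0, 0, 0, 0] = 1.0
        st.xbar[0, 0, 0] = 3.0
        st.xi[0, 0] = 0.0
        update_sample_means(st, rhp(K=1, beta0=1.0))
        assert abs(st.omega[0, 0, 0] - 24.0 / 9.0) < 1e-12
        assert abs(st.Gamma[0, 0, 0, 0] - 1.0 / 9.0) < 1e-12


class TestPrototypeMeans:
    def test_single_sample_shrinkage(self):
        st = blank_state(M=1, K=1, D=2)
        st.omega[0, 0] = [2.0, 4.0]
        hp = rhp(D=2, K=1, beta0=500.0, epsilon0=1.0)
        update_prototype_means(st, hp)
        np.testing.assert_allclose(st.xi[0], 500.0 * np.array([2.0, 4.0]) / 501.0)

    def test_identical_samples(self):
        st = blank_state(M=4, K=1, D=2)
        st.omega[:, 0] = [1.0, -2.0]
        hp = rhp(D=2, K=1, beta0=500.0, epsilon0=1.0)
        update_prototype_means(st, hp)
        expected = 500.0 * 4 * np.array([1.0, -2.0]) / (1.0 + 500.0 * 4)
        np.testing.assert_allclose(st.xi[0], expected, atol=1e-12)
        # Upsilon is a positive multiple of the identity
        np.testing.assert_allclose(
            st.Upsilon[0], np.eye(2) / (1.0 + 500.0 * 4), atol=1e-15
        )

    def test_elementwise_scalar_evaluation(self):
        rng = np.random.default_rng(7)
        st = blank_state(M=3, K=2, D=2)
        st.omega[:] = rng.normal(size=(3, 2, 2))
        hp = rhp(D=2, K=2, beta0=500.0, epsilon0=1.0)
        update_prototype_means(st, hp)
        for k in range(2):
            for d in range(2):
                num = sum(500.0 * st.omega[m, k, d] for m in range(3))
                assert abs(st.xi[k, d] - num / (1.0 + 500.0 * 3)) < 1e-12


class TestSamplePrecisions:
    def test_prior_only_component(self):
        st = blank_state(M=1, K=1, D=2, sigma0=6.0)
        st.Phi[0] = 2.0 * np.eye(2)
        st.nu = 12.0
        update_sample_precisions(st, rhp(D=2, K=1, sigma0=6.0))
        # Psi = Phi / (sigma0 * nu), sigma = sigma0
        np.testing.assert_allclose(st.Psi[0, 0], 2.0 * np.eye(2) / 72.0, atol=1e-12)
        assert st.sigma[0, 0] == 6.0

    def test_scalar_transcription(self):
        # D=1: Nk=10, S=2, gap=0.5, sigma0=6, E[Omega^-1]=3, Gamma=0.01
        st = blank_state(M=1, K=1, D=1, sigma0=6.0)
        st.Nk[0, 0] = 10.0
        st.S[0, 0, 0, 0] = 2.0
        st.xbar[0, 0, 0] = 1.0
        st.omega[0, 0, 0] = 0.5
        st.Gamma[0, 0, 0, 0] = 0.01
        st.nu = 6.0
        st.Phi[0, 0, 0] = 2.0  # E[Omega^-1] = nu / Phi = 3
        update_sample_precisions(st, rhp(K=1, sigma0=6.0))
        expected = 1.0 / (6.0 * 3.0 + 10.0 * (2.0 + 0.25 + 0.01))
        assert abs(st.Psi[0, 0, 0, 0] - expected) < 1e-12
        assert st.sigma[0, 0] == 16.0

    def test_precision_scale_shrinks_with_accumulated_scatter(self):
        """Doubling the effective count with fixed scatter shrinks Psi toward
        the halving limit (monotone decrease as evidence accumulates)."""
        vals = []
        for nk in (10.0, 20.0, 40.0, 80.0, 1.6e5, 3.2e5):
            st = blank_state(M=1, K=1, D=2, sigma0=6.0)
            st.Nk[0, 0] = nk
            st.S[0, 0] = np.array([[2.0, 0.3], [0.3, 1.0]])
            st.Gamma[0, 0] = 1e-4 * np.eye(2)
            st.nu = 12.0
            update_sample_precisions(st, rhp(D=2, K=1, sigma0=6.0))
            vals.append(np.linalg.eigvalsh(st.Psi[0, 0]).max())
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-2] / vals[-1] == pytest.approx(2.0, rel=1e-2)


class TestPrototypeShapes:
    def test_zero_precision_limit_keeps_hyperprior_scale(self):
        st = blank_state(M=2, K=1, D=2)
        st.Psi[:] = 1e-300
        hp = rhp(D=2, K=1, sigma0=6.0)
        update_prototype_shapes(st, hp)
        np.testing.assert_allclose(st.Phi[0], np.eye(2), atol=1e-12)

    def test_scalar_transcription(self):
        st = blank_state(M=2, K=1, D=1, sigma0=6.0)
        st.sigma[0, 0], st.Psi[0, 0, 0, 0] = 2.0, 0.5   # E[Lambda] = 1
        st.sigma[1, 0], st.Psi[1, 0, 0, 0] = 6.0, 0.5   # E[Lambda] = 3
        hp = rhp(K=1, sigma0=6.0)
        update_prototype_shapes(st, hp)
        assert abs(st.Phi[0, 0, 0] - (1.0 + 6.0 * 4.0)) < 1e-12

    def test_degrees_of_freedom_direct_sum(self):
        st = blank_state(M=14, K=3, D=6)
        hp = rhp(D=6, K=3, sigma0=36.0, nu0=36.0)
        update_prototype_shapes(st, hp)
        assert st.nu == 36.0 + 14 * 36.0 == 540.0
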