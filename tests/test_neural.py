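import numpy as np
import pytest

import netsde as ns
from netsde.neural import (TransitionPrediction, gaussian_nll, load_checkpoint,
                           predict_transition, save_checkpoint)
from netsde.sde import SDEModelSpec


class TestPredictTransition:
    def test_zero_drift_identity(self, stub_model, small_topo):
        model = stub_model()
        x = np.random.default_rng(0).normal(size=(small_topo.n, 3))
        pred = predict_transition(model, x, small_topo, dt=0.02)
        np.testing.assert_array_equal(pred.mu, x)
        assert np.all(pred.sigma2 > 0)

    def test_star_graph_hub_aggregation(self, stub_model):
        # hub (node 0) receives from all leaves with unit weights
        n = 5
        A = np.zeros((n, n))
        A[0, 1:] = 1.0
        topo = ns.NetworkTopology(n=n, A=A)
        model = stub_model(g=lambda z: z[:, 3:])  # g(x_i, x_j) = x_j
        x = np.arange(n * 3, dtype=float).reshape(n, 3)
        dt = 0.1
        pred = predict_transition(model, x, topo, dt)
        np.testing.assert_allclose(pred.mu[0], x[0] + dt * x[1:].sum(axis=0))
        np.testing.assert_array_equal(pred.mu[1:], x[1:])

    def test_interaction_linear_in_adjacency(self, stub_model, small_topo):
        model = stub_model(g=lambda z: z[:, 3:] ** 2)
        x = np.random.default_rng(1).normal(size=(small_topo.n, 3))
        dt = 0.05
        base = predict_transition(model, x, small_topo, dt).mu - x
        doubled_topo = ns.NetworkTopology(n=small_topo.n, A=2.0 * small_topo.A)
        doubled = predict_transition(model, x, doubled_topo, dt).mu - x
        np.testing.assert_allclose(doubled, 2.0 * base, atol=1e-12)

    def test_invalid_dt(self, stub_model, small_topo):
        x = np.zeros((small_topo.n, 3))
        with pytest.raises(ValueError, match="dt"):
            predict_transition(stub_model(), x, small_topo, dt=0.0)

    def test_permutation_equivariance(self, small_topo):
        """Relabelling nodes consistently permutes the predictions."""
        rng = np.random.default_rng(2)
        series = ns.NodeStateSeries(
            values=rng.normal(size=(12, small_topo.n, 2)), dt=0.01)
        cfg = ns.TrainingConfig(epochs=2, batch_size=4, seed=0, hidden=(8, 8))
        model, _ = ns.fit(series, small_topo, cfg)
        x = rng.normal(size=(small_topo.n, 2))
        perm = rng.permutation(small_topo.n)
        topo_p = ns.NetworkTopology(n=small_topo.n,
                                    A=small_topo.A[np.ix_(perm, perm)])
        mu = predict_transition(model, x, small_topo, 0.01).mu
        mu_p = predict_transition(model, x[perm], topo_p, 0.01).mu
        np.testing.assert_allclose(mu_p, mu[perm], rtol=1e-10, atol=1e-12)


class TestGaussianNLL:
    def test_zero_residual_unit_variance_gives_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 2))
        pred = TransitionPrediction(mu=x.copy(), sigma2=np.ones_like(x))
        assert gaussian_nll(x, pred) == pytest.approx(0.0)

    def test_scalar_case_hand_computed(self):
        pred = TransitionPrediction(mu=np.array([[0.0]]),
                                    sigma2=np.array([[1.0]]))
        assert gaussian_nll(np.array([[1.0]]), pred) == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 3))
        mu = rng.normal(size=(5, 3))
        s2 = rng.uniform(0.5, 2.0, size=(5, 3))
        base = gaussian_nll(x, TransitionPrediction(mu=mu, sigma2=s2))
        shifted = gaussian_nll(x + 3.7, TransitionPrediction(mu=mu + 3.7,
                                                             sigma2=s2))
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_argmin_over_mu_is_x_next(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 2))
        s2 = rng.uniform(0.5, 2.0, size=(3, 2))
        at_x = gaussian_nll(x, TransitionPrediction(mu=x.copy(), sigma2=s2))
        eps = 1e-6
        for _ in range(5):
            delta = rng.normal(size=x.shape) * eps
            perturbed = gaussian_nll(
                x, TransitionPrediction(mu=x + delta, sigma2=s2))
            assert perturbed >= at_x - 1e-14

    def test_full_covariance_reduces_to_diagonal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 3))
        mu = rng.normal(size=(4, 3))
        s2 = rng.uniform(0.5, 2.0, size=(4, 3))
        Sigma = np.zeros((4, 3, 3))
        for i in range(4):
            Sigma[i] = np.diag(s2[i])
        diag = gaussian_nll(x, TransitionPrediction(mu=mu, sigma2=s2))
        full = gaussian_nll(x, TransitionPrediction(mu=mu, Sigma=Sigma))
        assert full == pytest.approx(diag, rel=1e-10)

    def test_nonpositive_variance_rejected(self):
        x = np.zeros((2, 2))
        with pytest.raises(ValueError):
            gaussian_nll(x, TransitionPrediction(mu=x, sigma2=np.zeros((2, 2))))
        bad = -np.eye(2)[None].repeat(2, axis=0)
        with pytest.raises(ValueError):
            gaussian_nll(x, TransitionPrediction(mu=x, Sigma=bad))


class TestFit:
    def test_pure_diffusion_recovery(self):
        """x(t+dt) = x(t) + sigma dW: phi^2 dt within 10%, drift near zero."""
        sigma = 0.4
        n, T, dt = 4, 2000, 0.01
        topo = ns.NetworkTopology(n=n, A=np.zeros((n, n)))
        rng = np.random.default_rng(0)
        incs = sigma * np.sqrt(dt) * rng.standard_normal((T, n, 1))
        values = np.concatenate([np.zeros((1, n, 1)), np.cumsum(incs, axis=0)])
        series = ns.NodeStateSeries(values=values, dt=dt)
        cfg = ns.TrainingConfig(epochs=40, batch_size=128, seed=1,
                                hidden=(16, 16))
        model, log = ns.fit(series, topo, cfg)
        states = values.reshape(-1, 1)[::50]
        phi = model.diffusion_fn(states)
        assert np.median(phi) == pytest.approx(sigma, rel=0.10)
        f = model.self_fn(states)
        assert np.sqrt(np.mean(f ** 2)) < 0.5 * sigma / np.sqrt(dt) * dt * 10

    def test_training_reduces_nll(self, lc_series, small_topo):
        cfg = ns.TrainingConfig(epochs=8, batch_size=64, seed=0, hidden=(16, 16))
        model, log = ns.fit(lc_series, small_topo, cfg)
        assert log["val_nll"][-1] < log["val_nll"][0]

    def test_evaluate_components_pure_function(self, stub_model):
        model = stub_model(f=lambda x: x ** 2)
        states = np.random.default_rng(1).normal(size=(10, 3))
        a = ns.evaluate_components(model, states)
        b = ns.evaluate_components(model, states)
        np.testing.assert_array_equal(a["self"], b["self"])

    def test_oracle_components_reproduce_truth(self, lc_spec):
        oracle = ns.OracleComponents(lc_spec)
        x = np.random.default_rng(2).normal(size=(20, 3))
        np.testing.assert_array_equal(oracle.self_fn(x), lc_spec.drift_self(x))

    def test_extrapolation_fraction_zero_inside_envelope(self, lc_series,
                                                         small_topo):
        cfg = ns.TrainingConfig(epochs=2, batch_size=64, seed=0, hidden=(8, 8))
        model, _ = ns.fit(lc_series, small_topo, cfg)
        inside = lc_series.values.reshape(-1, 3)[::100]
        assert model.extrapolation_fraction(inside) == 0.0
        outside = inside + 100.0
        assert model.extrapolation_fraction(outside) == 1.0


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, lc_series, small_topo,
                                              tmp_path):
        cfg = ns.TrainingConfig(epochs=2, batch_size=64, seed=3, hidden=(8, 8))
        model, _ = ns.fit(lc_series, small_topo, cfg)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, str(path))
        back = load_checkpoint(str(path))
        x = np.random.default_rng(0).normal(size=(small_topo.n, 3))
        np.testing.assert_allclose(
            predict_transition(back, x, small_topo, 0.01).mu,
            predict_transition(model, x, small_topo, 0.01).mu, rtol=1e-12)
        assert back.config.seed == 3
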