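import numpy as np
import pandas as pd
import pytest

import netsde as ns
from netsde.flocking import (DEFAULT_KERNELS, FlockKernelParams,
                             FlockPreprocessConfig, composite_loss,
                             distill_flock, polarization, preprocess_tracks,
                             simulate_second_order)


class TestSimulateSecondOrder:
    def test_force_free_straight_line_motion(self):
        kernels = FlockKernelParams(eps=0.0, d=3)
        r0 = np.random.default_rng(0).normal(size=(3, 3))
        v0 = np.random.default_rng(1).normal(size=(3, 3))
        ser = simulate_second_order(kernels, n=3, steps=50, dt=0.01, seed=0,
                                    init=(r0, v0))
        np.testing.assert_allclose(ser.velocities[-1], v0, atol=1e-12)
        np.testing.assert_allclose(ser.positions[-1], r0 + 50 * 0.01 * v0,
                                   atol=1e-10)

    def test_two_bird_mirror_symmetry(self):
        kernels = FlockKernelParams(a1=0.5, c1=5.0, s1=-0.5, s3=0.5, eps=0.0,
                                    d=2)
        r0 = np.array([[1.0, 0.0], [-1.0, 0.0]])
        v0 = np.array([[0.0, 1.0], [0.0, 1.0]])
        ser = simulate_second_order(kernels, n=2, steps=200, dt=0.01, seed=0,
                                    init=(r0, v0))
        np.testing.assert_allclose(ser.positions[:, 0, 0],
                                   -ser.positions[:, 1, 0], atol=1e-9)
        np.testing.assert_allclose(ser.positions[:, 0, 1],
                                   ser.positions[:, 1, 1], atol=1e-9)

    def test_single_bird_rejected(self):
        with pytest.raises(ValueError):
            simulate_second_order(DEFAULT_KERNELS, n=1, steps=10)

    def test_flocking_onset_raises_polarization(self):
        ser = simulate_second_order(DEFAULT_KERNELS, n=20, steps=3000,
                                    dt=0.01, seed=2)
        pol = polarization(ser.velocities)
        assert pol[-100:].mean() > pol[0] + 0.2

    def test_velocities_consistent_with_positions(self):
        ser = simulate_second_order(DEFAULT_KERNELS, n=5, steps=50, dt=0.01,
                                    seed=3)
        fd = np.diff(ser.positions, axis=0) / ser.dt
        np.testing.assert_allclose(fd, ser.velocities[:-1], atol=1e-9)


def _track(t, fx, fy):
    return pd.DataFrame({"t": t, "x": fx(t), "y": fy(t)})


class TestPreprocessTracks:
    def test_constant_velocity_passthrough(self):
        t = np.linspace(0.0, 2.0, 60)
        raw = {f"b{k}": _track(t, lambda t: 1.5 * t + k, lambda t: -0.5 * t)
               for k in range(3)}
        cfg = FlockPreprocessConfig(dt=0.01, normalize=False, align=False)
        out = preprocess_tracks(raw, cfg)
        np.testing.assert_allclose(out.velocities[:, :, 0], 1.5, atol=1e-8)
        np.testing.assert_allclose(out.accelerations, 0.0, atol=1e-6)

    def test_identity_configuration_passthrough(self):
        t = np.round(np.arange(0.0, 1.0, 0.01), 10)
        raw = {"a": _track(t, np.cos, np.sin),
               "b": _track(t, lambda x: np.cos(x + 1), lambda x: np.sin(x + 1))}
        cfg = FlockPreprocessConfig(dt=0.01, normalize=False, align=False)
        out = preprocess_tracks(raw, cfg)
        np.testing.assert_allclose(out.positions[:, 0, 0], np.cos(t)[:out.positions.shape[0]],
                                   atol=1e-9)

    def test_circular_track_speed_within_one_percent(self):
        R, omega = 3.0, 2.0
        t = np.linspace(0.0, 3.0, 200)
        raw = {"a": _track(t, lambda t: R * np.cos(omega * t),
                           lambda t: R * np.sin(omega * t)),
               "b": _track(t, lambda t: 1 + R * np.cos(omega * t),
                           lambda t: R * np.sin(omega * t))}
        cfg = FlockPreprocessConfig(dt=0.01, normalize=False, align=False)
        out = preprocess_tracks(raw, cfg)
        speed = np.linalg.norm(out.velocities[20:-20, 0], axis=1)
        assert np.max(np.abs(speed - R * omega)) / (R * omega) < 0.01

    def test_idempotent_on_processed_series(self):
        t = np.linspace(0.0, 2.0, 80)
        raw = {f"b{k}": _track(t, lambda t: np.sin(t) + 0.1 * k,
                               lambda t: t ** 2 / 4) for k in range(3)}
        cfg = FlockPreprocessConfig(dt=0.02)
        once = preprocess_tracks(raw, cfg)
        grid = np.round(np.arange(once.positions.shape[0]) * 0.02, 10)
        again_raw = {f"b{k}": pd.DataFrame(
            {"t": grid, "x": once.positions[:, k, 0],
             "y": once.positions[:, k, 1]}) for k in range(3)}
        again = preprocess_tracks(again_raw, cfg)
        lo = min(once.positions.shape[0], again.positions.shape[0])
        np.testing.assert_allclose(again.positions[:lo],
                                   once.positions[:lo], atol=1e-6)

    def test_nonmonotone_time_rejected(self):
        raw = {"a": pd.DataFrame({"t": [0.0, 0.2, 0.1, 0.3],
                                  "x": [0, 1, 2, 3], "y": [0, 0, 0, 0]}),
               "b": _track(np.linspace(0, 0.3, 10), lambda t: t, lambda t: t)}
        with pytest.raises(ValueError, match="increasing"):
            preprocess_tracks(raw, FlockPreprocessConfig())

    def test_outlier_individual_dropped(self):
        t = np.linspace(0.0, 2.0, 120)
        raw = {f"b{k}": _track(t, lambda t: t, lambda t: 0.0 * t)
               for k in range(4)}
        raw["fast"] = _track(t, lambda t: 40.0 * t, lambda t: 0.0 * t)
        out = preprocess_tracks(raw, FlockPreprocessConfig(
            dt=0.05, normalize=False, align=False))
        assert out.meta["dropped"] == ["fast"]
        assert out.n == 4


class TestCompositeLoss:
    def _channels(self, resid=0.0):
        shape = (4, 3, 2)
        truth = {"r": np.zeros(shape), "v": np.zeros(shape),
                 "a": np.zeros(shape)}
        pred = {"r": np.full(shape, resid), "v": np.full(shape, resid),
                "a": np.full(shape, resid), "sigma2": np.ones(shape)}
        return pred, truth

    def test_perfect_prediction_zero(self):
        pred, truth = self._channels(0.0)
        assert composite_loss(pred, truth, (1, 1, 1, 1)) == pytest.approx(0.0)

    def test_displacement_squared_error(self):
        pred, truth = self._channels(0.0)
        pred["r"][0, 0, 0] = 2.0
        loss = composite_loss(pred, truth, (0, 1, 0, 0))
        assert loss == pytest.approx(4.0 / pred["r"].size)

    def test_linear_in_each_beta(self):
        pred, truth = self._channels(0.3)
        base = composite_loss(pred, truth, (0, 0, 1, 0))
        assert composite_loss(pred, truth, (0, 0, 2, 0)) == pytest.approx(2 * base)

    def test_all_zero_betas_rejected(self):
        pred, truth = self._channels()
        with pytest.raises(ValueError):
            composite_loss(pred, truth, (0, 0, 0, 0))

    def test_nl_channel_only_is_velocity_nll(self):
        pred, truth = self._channels(0.5)
        loss = composite_loss(pred, truth, (1, 0, 0, 0))
        assert loss == pytest.approx(np.mean(0.25 / 1.0 + np.log(1.0)))


class StubKernel:
    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))


def _oracle_fitted(kernels: FlockKernelParams):
    from netsde.flocking import FittedFlockModel
    return FittedFlockModel(
        self_net=StubKernel(kernels.self_propulsion),
        cohesion_net=StubKernel(kernels.cohesion),
        align_net=StubKernel(kernels.alignment),
        eps=kernels.eps, r_range=(0.5, 8.0), u_range=(0.0, 4.0), d=3)


class TestDistillFlock:
    def test_oracle_alignment_recovered_exactly(self):
        truth = FlockKernelParams(a1=1.0, a2=0.0, a3=0.0, eps=0.1, d=3)
        params, diag = distill_flock(_oracle_fitted(truth))
        assert params.a1 == pytest.approx(1.0, abs=1e-6)
        assert params.a3 == pytest.approx(0.0, abs=1e-6)
        assert diag["kappa2_alignment"] == pytest.approx(1.0)

    def test_cohesion_form_at_r_two(self):
        truth = FlockKernelParams(c1=5.0, c2=0.3, c3=-0.1, d=3)
        assert truth.cohesion(2.0) == pytest.approx(5.0 * 0.3 - 0.1)

    def test_self_propulsion_at_zero_speed(self):
        truth = FlockKernelParams(s1=2.0, s2=0.5, s3=1.0, d=3)
        assert truth.self_propulsion(0.0) == pytest.approx(2.0 * 0.5 + 1.0)

    def test_fit_shuffled_identities_invariant(self):
        ser = simulate_second_order(DEFAULT_KERNELS, n=8, steps=600, dt=0.01,
                                    seed=4)
        cfg = ns.SecondOrderTrainingConfig(seed=0, max_frames=400)
        model_a, _ = ns.fit_second_order(ser, cfg)
        perm = np.random.default_rng(0).permutation(8)
        shuffled = ns.SecondOrderStateSeries(
            positions=ser.positions[:, perm], velocities=ser.velocities[:, perm],
            dt=ser.dt)
        model_b, _ = ns.fit_second_order(shuffled, cfg)
        r = np.linspace(1.0, 4.0, 20)
        np.testing.assert_allclose(model_b.cohesion(r), model_a.cohesion(r),
                                   rtol=1e-6, atol=1e-9)

    def test_alignment_only_pair_gives_zero_cohesion(self):
        kernels = FlockKernelParams(a1=0.6, s1=-0.5, s3=0.5, eps=0.05, d=3)
        ser = simulate_second_order(kernels, n=4, steps=3000, dt=0.01, seed=5)
        model, _ = ns.fit_second_order(ser, ns.SecondOrderTrainingConfig(seed=1))
        r = model.r_samples[50:-50:20]
        assert np.max(np.abs(model.cohesion(r))) < 0.05
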