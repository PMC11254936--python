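import numpy as np
import pytest

import netsde as ns
from netsde.tau import (distance_transform, pathway_features, regional_loading,
                        TauModel)


class TestDistanceTransform:
    def test_hand_computed_kept_entry(self):
        E = np.array([[0.0, np.e], [np.e, 0.0]])
        D = distance_transform(E)
        assert D[0, 1] == pytest.approx(0.5)

    def test_far_apart_regions_zeroed(self):
        E = np.array([[0.0, 100.0], [100.0, 0.0]])
        D = distance_transform(E)
        assert D[0, 1] == 0.0  # 1/log(1e4) ~ 0.1086 < 0.11

    def test_zero_threshold_keeps_everything(self):
        E = np.array([[0.0, 100.0], [100.0, 0.0]])
        D = distance_transform(E, threshold=0.0)
        assert D[0, 1] == pytest.approx(1.0 / np.log(1e4))
        assert D[0, 0] == 0.0

    def test_unit_distance_strict_raises_lenient_zeroes(self):
        E = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            distance_transform(E, strict=True)
        assert distance_transform(E, strict=False)[0, 1] == 0.0


def _toy_connectome():
    n = 4
    A = np.zeros((n, n))
    A[1, 0] = 2.0   # region 0 projects to region 1 (retrograde A[1,0])
    E = np.full((n, n), 50.0)
    np.fill_diagonal(E, 0.0)
    return ns.ConnectomeData(n=n, A=A, E=E)


class TestPredictPathology:
    def test_all_zero_coefficients_give_zero(self):
        conn = _toy_connectome()
        model = TauModel(b0=np.zeros(4), b1=np.zeros(4), b2=np.zeros(4),
                         b3=np.zeros(4), c_t=1.0)
        x0 = np.array([1.0, 0, 0, 0])
        assert np.all(ns.predict_pathology(model, conn, x0, 3.0) == 0.0)

    def test_isolated_seed_hand_computed(self):
        # seeded region with no in-links, b0 = 1, c_t = 0, t = 2 -> 1 * 3
        conn = _toy_connectome()
        model = TauModel(b0=np.ones(4), b1=np.zeros(4), b2=np.zeros(4),
                         b3=np.zeros(4), c_t=0.0)
        x0 = np.array([1.0, 0, 0, 0])
        y = ns.predict_pathology(model, conn, x0, 2.0)
        assert y[0] == pytest.approx(3.0)
        assert np.all(y[1:] == 0.0)

    def test_no_seeds_no_pathology(self):
        conn = _toy_connectome()
        model = TauModel(b0=np.ones(4), b1=np.ones(4), b2=np.ones(4),
                         b3=np.ones(4), c_t=1.0)
        assert np.all(ns.predict_pathology(model, conn, np.zeros(4), 9.0) == 0.0)

    def test_linear_in_b(self):
        conn, obs, truth = ns.synthesize_connectome_and_pathology(seed=1)
        doubled = TauModel(b0=2 * truth.b0, b1=2 * truth.b1, b2=2 * truth.b2,
                           b3=2 * truth.b3, c_t=truth.c_t)
        y1 = ns.predict_pathology(truth, conn, obs.x0, obs.months)
        y2 = ns.predict_pathology(doubled, conn, obs.x0, obs.months)
        np.testing.assert_allclose(y2, 2 * y1)

    def test_retro_antero_transpose_symmetry(self):
        """Transposing A while swapping b1 and b2 leaves predictions unchanged."""
        conn, obs, truth = ns.synthesize_connectome_and_pathology(seed=2)
        swapped_conn = ns.ConnectomeData(n=conn.n, A=conn.A.T.copy(), E=conn.E)
        swapped = TauModel(b0=truth.b0, b1=truth.b2, b2=truth.b1, b3=truth.b3,
                           c_t=truth.c_t)
        y1 = ns.predict_pathology(truth, conn, obs.x0, obs.months)
        y2 = ns.predict_pathology(swapped, swapped_conn, obs.x0, obs.months)
        np.testing.assert_allclose(y2, y1, rtol=1e-12)


class TestFitTau:
    def test_noiseless_recovery_of_identifiable_parameters(self):
        conn, obs, truth = ns.synthesize_connectome_and_pathology(
            n=40, n_seeds=5, noise=0.0, seed=3)
        rep = ns.fit_tau(obs, conn)
        assert rep.c_t == pytest.approx(truth.c_t, rel=1e-6)
        u_true = regional_loading(truth, conn, obs.x0)
        active = u_true > 0
        np.testing.assert_allclose(rep.loading[active], u_true[active],
                                   rtol=1e-6)

    def test_noisy_recovery_median_error_below_ten_percent(self):
        conn, obs, truth = ns.synthesize_connectome_and_pathology(
            n=40, n_seeds=5, noise=0.10, seed=4)
        rep = ns.fit_tau(obs, conn)
        u_true = regional_loading(truth, conn, obs.x0)
        active = u_true > 0
        rel = np.abs(rep.loading[active] - u_true[active]) / u_true[active]
        assert np.median(rel) < 0.10

    def test_homogeneous_variant_fits_strictly_worse(self):
        conn, obs, truth = ns.synthesize_connectome_and_pathology(
            n=40, n_seeds=5, noise=0.05, seed=5)
        het = ns.fit_tau(obs, conn)
        hom = ns.fit_tau(obs, conn, homogeneous=True)
        assert hom.sse > het.sse
        assert hom.model.homogeneous

    def test_retrograde_preference_readout(self):
        conn, obs, truth = ns.synthesize_connectome_and_pathology(
            n=40, n_seeds=5, noise=0.05, retro_scale=5.0, antero_scale=0.5,
            seed=6)
        rep = ns.fit_tau(obs, conn)
        assert np.abs(rep.model.b1).mean() > np.abs(rep.model.b2).mean()

    def test_all_zero_observations_rejected(self):
        conn, obs, _ = ns.synthesize_connectome_and_pathology(seed=7)
        bad = ns.PathologyObservations(y=np.zeros_like(obs.y),
                                       months=obs.months, x0=obs.x0)
        with pytest.raises(ValueError):
            ns.fit_tau(bad, conn)


class TestSeedSpecificity:
    def test_true_seeds_beat_null_median_everywhere(self):
        conn, obs, _ = ns.synthesize_connectome_and_pathology(
            n=40, n_seeds=5, noise=0.05, seed=8)
        res = ns.seed_specificity_test(obs, conn, n_random=50, seed=9)
        null_median = np.median(res.null_scores, axis=0)
        assert np.all(res.true_scores > null_median)

    def test_deterministic_under_seed(self):
        conn, obs, _ = ns.synthesize_connectome_and_pathology(
            n=30, n_seeds=4, noise=0.05, seed=10)
        a = ns.seed_specificity_test(obs, conn, n_random=10, seed=3)
        b = ns.seed_specificity_test(obs, conn, n_random=10, seed=3)
        np.testing.assert_array_equal(a.null_scores, b.null_scores)

    def test_too_many_seed_sites_rejected(self):
        conn, obs, _ = ns.synthesize_connectome_and_pathology(seed=11)
        with pytest.raises(ValueError):
            ns.seed_specificity_test(obs, conn, n_seeds=conn.n + 1)


class TestSynthesize:
    def test_distance_matrix_is_metric_like(self):
        conn, _, _ = ns.synthesize_connectome_and_pathology(seed=12)
        assert np.allclose(conn.E, conn.E.T)
        assert np.all(np.diag(conn.E) == 0.0)
        off = conn.E[~np.eye(conn.n, dtype=bool)]
        assert np.all(off > 1.0)

    def test_full_scale_design_dimensions(self):
        conn, obs, _ = ns.synthesize_connectome_and_pathology(
            n=160, n_seeds=5, seed=13)
        assert conn.n == 160
        assert int(obs.x0.sum()) == 5
        np.testing.assert_array_equal(obs.months, [1.0, 3.0, 6.0, 9.0])
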