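import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netsde as ns
from netsde.distill import phase1_global, phase2_minimal
from netsde.library import DesignMatrix, evaluate
from netsde.metrics import kappa2, smape
from netsde.symbolic import SymbolicSDE


def _orthonormal_design(m=60, q=5, seed=0):
    rng = np.random.default_rng(seed)
    X, _ = np.linalg.qr(rng.normal(size=(m, q)))
    X *= np.sqrt(m)  # unit column variance
    return DesignMatrix(values=X, term_names=[f"t{k}" for k in range(q)])


class TestPhase1:
    def test_orthonormal_single_signal_ranked_first(self):
        design = _orthonormal_design()
        target = 3.0 * design.values[:, 2]
        ranking = phase1_global(design, target, seed=0)
        assert ranking.term_names[0] == "t2"
        assert ranking.scores[0] == pytest.approx(3.0, abs=0.3)

    def test_null_target_all_zero_relevance(self):
        design = _orthonormal_design()
        ranking = phase1_global(design, np.zeros(design.values.shape[0]),
                                seed=0)
        assert np.all(ranking.scores == 0.0)

    def test_deterministic_under_seed(self):
        design = _orthonormal_design(seed=3)
        rng = np.random.default_rng(1)
        target = design.values @ rng.normal(size=5) + 0.1 * rng.normal(size=60)
        a = phase1_global(design, target, seed=42)
        b = phase1_global(design, target, seed=42)
        assert a.term_names == b.term_names
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_too_few_rows_rejected(self):
        design = DesignMatrix(values=np.ones((3, 2)), term_names=["a", "b"])
        with pytest.raises(ValueError, match="fold"):
            phase1_global(design, np.ones(3), folds=5)


class TestPhase2:
    def test_single_term_target_stops_at_one(self):
        design = _orthonormal_design()
        target = 2.5 * design.values[:, 1]
        ranking = phase1_global(design, target, seed=0)
        sel = phase2_minimal(design, target, ranking)
        assert list(sel.coefficients) == ["t1"]
        assert sel.kappa2_path[-1] == pytest.approx(1.0)

    def test_two_term_noiseless_exact_coefficients(self):
        design = _orthonormal_design(seed=5)
        target = 2.0 * design.values[:, 0] - 1.0 * design.values[:, 3]
        ranking = phase1_global(design, target, seed=0)
        sel = phase2_minimal(design, target, ranking)
        assert sel.coefficients["t0"] == pytest.approx(2.0, abs=1e-8)
        assert sel.coefficients["t3"] == pytest.approx(-1.0, abs=1e-8)
        assert len(sel.coefficients) == 2

    def test_noise_column_does_not_enter(self):
        rng = np.random.default_rng(7)
        design = _orthonormal_design(m=200, q=6, seed=7)
        target = design.values[:, 0] + 0.01 * rng.normal(size=200)
        ranking = phase1_global(design, target, seed=0)
        sel = phase2_minimal(design, target, ranking)
        assert list(sel.coefficients) == ["t0"]

    def test_constant_target_identified_as_constant_term(self):
        lib = ns.TermLibrary(arity="self", d=1)
        for name in ("1", "xi1", "xi1**2"):
            lib.add(name)
        states = np.random.default_rng(0).normal(size=(50, 1))
        design = evaluate(lib, states)
        target = np.full(50, 0.7)
        ranking = phase1_global(design, target, seed=0)
        sel = phase2_minimal(design, target, ranking)
        assert sel.coefficients == {"1": pytest.approx(0.7)}

    def test_zero_target_gives_empty_equation(self):
        design = _orthonormal_design()
        sel = phase2_minimal(design, np.zeros(60),
                             phase1_global(design, np.zeros(60), seed=0))
        assert sel.coefficients == {}


class TestDistillOracle:
    def test_constant_diffusion_single_term(self, lc_spec, small_topo,
                                            lc_series):
        rng = np.random.default_rng(0)
        states, pairs = ns.sample_states(lc_series, rng, 400, small_topo, 800)
        sde = ns.distill(ns.OracleComponents(lc_spec), ns.default_libraries(3),
                         states, pairs, dt=0.01)
        assert set(sde.diffusion_terms) == {"1"}
        np.testing.assert_allclose(sde.diffusion_terms["1"],
                                   [0.1, 0.1, 0.1], atol=1e-8)

    def test_empty_interaction_kept_empty(self, small_topo, lc_series):
        spec = ns.make_model("linear_cubic_test", g1=0.0, g2=0.0)
        rng = np.random.default_rng(1)
        states, pairs = ns.sample_states(lc_series, rng, 400, small_topo, 800)
        sde = ns.distill(ns.OracleComponents(spec), ns.default_libraries(3),
                         states, pairs, dt=0.01)
        assert sde.interaction_terms.get(None, {}) == {}


class TestKappa2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 4.0])
        assert kappa2(y, y) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([0.0, 1.0, 5.0])
        assert kappa2(np.full(3, y.mean()), y) == pytest.approx(0.0)

    def test_hand_computed_negative_case(self):
        assert kappa2(np.zeros(3), np.array([0.0, 1.0, 2.0])) == pytest.approx(-1.5)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            kappa2(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10 ** 6), st.floats(0.1, 10.0), st.floats(-5, 5))
    def test_affine_invariance_and_bound(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=20)
        y_hat = rng.normal(size=20)
        base = kappa2(y_hat, y)
        assert base <= 1.0
        rescaled = kappa2(scale * y_hat + shift, scale * y + shift)
        assert rescaled == pytest.approx(base, rel=1e-8, abs=1e-8)


def _sde_from(parts):
    sde = SymbolicSDE(d=1)
    sde.self_terms = {k: np.array([v]) for k, v in parts.items()}
    return sde


class TestSmape:
    def test_identical_equations_zero(self):
        a = _sde_from({"xi1": 1.0, "xi1**2": 2.0})
        assert smape(a, _sde_from({"xi1": 1.0, "xi1**2": 2.0})) == 0.0

    def test_missing_term_contributes_fully(self):
        inferred = _sde_from({"xi1": 1.0})
        reference = _sde_from({"xi1": 1.0, "xi1**2": 2.0})
        assert smape(inferred, reference) == pytest.approx(0.5)

    def test_coefficient_error_hand_computed(self):
        assert smape(_sde_from({"xi1": 2.0}),
                     _sde_from({"xi1": 1.0})) == pytest.approx(1.0 / 3.0)

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            smape(_sde_from({}), _sde_from({}))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        names = ["xi1", "xi1**2", "xi1**3", "1"]
        a = _sde_from({n: rng.normal() for n in rng.choice(names, 2,
                                                           replace=False)})
        b = _sde_from({n: rng.normal() for n in rng.choice(names, 3,
                                                           replace=False)})
        ab = smape(a, b)
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(smape(b, a))


class TestForceField:
    def test_linear_drift_field_value(self):
        sde = _sde_from({"xi1": -1.0})
        field = ns.reconstruct_force_field(sde, np.array([[2.0]]))
        assert field[0, 0] == pytest.approx(-2.0)

    def test_identical_equation_zero_discrepancy(self, lc_series, small_topo):
        ref = ns.linear_cubic_reference()
        grid = np.random.default_rng(0).normal(size=(20, 3))
        a = ns.reconstruct_force_field(ref, grid, small_topo)
        b = ns.reconstruct_force_field(ref, grid, small_topo)
        np.testing.assert_array_equal(a, b)
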