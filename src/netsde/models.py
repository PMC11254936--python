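"""Built-in ground-truth networked SDE models.

Four named systems, all with d = 3 per-node states:

``hindmarsh_rose``
    Three-variable bursting-neuron dynamics on a signed network.  Per node,

        dx1 = ( x2 - a x1^3 + b x1^2 - x3 + I
                + sum_j A_ij k_syn (V_syn - x1_i) Gamma(x1_j) ) dt + s1 dW
        dx2 = ( c - h x1^2 - x2 ) dt + s2 dW
        dx3 = ( r (s (x1 - x_rest) - x3) ) dt + s3 dW

    with the sigmoidal synaptic gate Gamma(u) = 1 / (1 + exp(-lam (u - theta))).
    Links from excitatory nodes use the excitatory reversal potential
    ``V_syn_exc`` (default 2.0), links from inhibitory nodes ``V_syn_inh``
    (default -1.5); the two interaction maps differ only through V_syn.

``rossler``
    Rossler oscillators with diffusive coupling in the first component:
    dx1 = (-x2 - x3 + eps sum_j A_ij (x1_j - x1_i)) dt + ..., canonical
    a = b = 0.2, c = 5.7.

``lorenz_network``
    Lorenz-63 per node with diffusive x-coupling.  The stochastic intensity is
    1/sqrt(gamma) (smaller gamma = stronger noise) and the diffusion of the
    second component depends linearly on the third:
    phi = (1/sqrt(gamma)) * (1, 1 + c23 x3, 1).

``linear_cubic_test``
    A documented sparse polynomial system whose every term is contained in the
    default elementary-function libraries; it is the oracle for recovery tests.
    Its exact symbolic form is available via `linear_cubic_reference`.
"""

from __future__ import annotations

import numpy as np

from .network import EXCITATORY, INHIBITORY
from .sde import SDEModelSpec
from .symbolic import SymbolicSDE

HR_DEFAULTS = dict(a=1.0, b=3.0, c=1.0, h=5.0, r=0.006, s=4.0, x_rest=-1.6,
                   I=3.2, k_syn=0.3, lam=10.0, theta=1.0,
                   sigma1=0.1, sigma2=0.1, sigma3=0.02)

ROSSLER_DEFAULTS = dict(a=0.2, b=0.2, c=5.7, eps=0.3, sigma=0.05)

LORENZ_DEFAULTS = dict(sigma_l=10.0, rho=28.0, beta=8.0 / 3.0, eps=1.0, c23=0.02)

# sparse linear + cubic polynomial test system.  The (x1, x2) pair is a
# Lienard-form relaxation oscillator (sustained limit cycle, so trajectories
# cover the state range without relying on large noise), x3 is a driven dim:
#   f1 = x1 + x2 - x1^3
#   f2 = -x1 - 0.3 x2
#   f3 = -0.5 x3 + 0.3 x1 x2
# interaction (per link): g1 = 0.3 (x1_j - x1_i), g2 = 0.4 (x2_j - x2_i), g3 = 0
# (diffusive coupling: its contribution to the Jacobian is an in-degree-shifted
# adjacency whose eigenvalues have nonpositive real part, so random topologies
# cannot destabilize the oscillator)
# diffusion: constant (0.1, 0.1, 0.1), ~10% of the drift scale
LINEAR_CUBIC_DEFAULTS = dict(a11=1.0, a12=1.0, a13=-1.0, a21=-1.0, a22=-0.3,
                             a33=-0.5, a312=0.3, g1=0.3, g2=0.4,
                             sigma1=0.1, sigma2=0.1, sigma3=0.1)


def synaptic_gate(u: np.ndarray, lam: float = 10.0, theta: float = 1.0) -> np.ndarray:
    """Sigmoidal gate of the presynaptic fast variable."""
    return 1.0 / (1.0 + np.exp(-lam * (u - theta)))


def _merged(defaults: dict, params: dict, model: str) -> dict:
    unknown = set(params) - set(defaults)
    if unknown:
        raise ValueError(f"{model}: unknown params {sorted(unknown)}; "
                         f"accepted: {sorted(defaults)}")
    out = dict(defaults)
    out.update(params)
    return out


def make_model(name: str, **params) -> SDEModelSpec:
    """Build one of the named ground-truth models (see module docstring).

    Unknown model names or parameters raise ValueError listing what is accepted.
    """
    if name == "hindmarsh_rose":
        p = _merged(dict(HR_DEFAULTS, V_syn_exc=2.0, V_syn_inh=-1.5), params, name)

        def drift_self(x):
            x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
            return np.stack([
                x2 - p["a"] * x1 ** 3 + p["b"] * x1 ** 2 - x3 + p["I"],
                p["c"] - p["h"] * x1 ** 2 - x2,
                p["r"] * (p["s"] * (x1 - p["x_rest"]) - x3),
            ], axis=1)

        def pair_for(v_syn):
            def g(xi, xj):
                out = np.zeros_like(xi)
                out[:, 0] = p["k_syn"] * (v_syn - xi[:, 0]) * synaptic_gate(
                    xj[:, 0], p["lam"], p["theta"])
                return out
            return g

        sig = np.array([p["sigma1"], p["sigma2"], p["sigma3"]])
        return SDEModelSpec(
            d=3, drift_self=drift_self,
            drift_pair={EXCITATORY: pair_for(p["V_syn_exc"]),
                        INHIBITORY: pair_for(p["V_syn_inh"])},
            diffusion=lambda x: np.broadcast_to(sig, x.shape).copy(),
            params=p, name=name)

    if name == "rossler":
        p = _merged(ROSSLER_DEFAULTS, params, name)

        def drift_self(x):
            x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
            return np.stack([-x2 - x3, x1 + p["a"] * x2,
                             p["b"] + x3 * (x1 - p["c"])], axis=1)

        def drift_pair(xi, xj):
            out = np.zeros_like(xi)
            out[:, 0] = p["eps"] * (xj[:, 0] - xi[:, 0])
            return out

        return SDEModelSpec(
            d=3, drift_self=drift_self, drift_pair=drift_pair,
            diffusion=lambda x: np.full_like(x, p["sigma"]),
            params=p, name=name)

    if name == "lorenz_network":
        if "gamma" not in params:
            raise ValueError("lorenz_network requires the stochastic-intensity "
                             "parameter gamma (noise amplitude is 1/sqrt(gamma))")
        p = _merged(dict(LORENZ_DEFAULTS, gamma=None), params, name)
        p["gamma"] = float(params["gamma"])
        amp = 1.0 / np.sqrt(p["gamma"])

        def drift_self(x):
            x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
            return np.stack([p["sigma_l"] * (x2 - x1),
                             x1 * (p["rho"] - x3) - x2,
                             x1 * x2 - p["beta"] * x3], axis=1)

        def drift_pair(xi, xj):
            out = np.zeros_like(xi)
            out[:, 0] = p["eps"] * (xj[:, 0] - xi[:, 0])
            return out

        def diffusion(x):
            out = np.empty_like(x)
            out[:, 0] = amp
            out[:, 1] = amp * (1.0 + p["c23"] * x[:, 2])
            out[:, 2] = amp
            return out

        return SDEModelSpec(d=3, drift_self=drift_self, drift_pair=drift_pair,
                            diffusion=diffusion, params=p, name=name)

    if name == "linear_cubic_test":
        p = _merged(LINEAR_CUBIC_DEFAULTS, params, name)

        def drift_self(x):
            x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
            return np.stack([
                p["a11"] * x1 + p["a12"] * x2 + p["a13"] * x1 ** 3,
                p["a21"] * x1 + p["a22"] * x2,
                p["a33"] * x3 + p["a312"] * x1 * x2,
            ], axis=1)

        def drift_pair(xi, xj):
            out = np.zeros_like(xi)
            out[:, 0] = p["g1"] * (xj[:, 0] - xi[:, 0])
            out[:, 1] = p["g2"] * (xj[:, 1] - xi[:, 1])
            return out

        sig = np.array([p["sigma1"], p["sigma2"], p["sigma3"]])
        return SDEModelSpec(d=3, drift_self=drift_self, drift_pair=drift_pair,
                            diffusion=lambda x: np.broadcast_to(sig, x.shape).copy(),
                            params=p, name=name)

    raise ValueError(
        f"unknown model {name!r}; available: hindmarsh_rose, rossler, "
        "lorenz_network, linear_cubic_test")


def linear_cubic_reference(**params) -> SymbolicSDE:
    """The generating equation of ``linear_cubic_test`` in canonical term names."""
    p = _merged(LINEAR_CUBIC_DEFAULTS, params, "linear_cubic_test")
    sde = SymbolicSDE(d=3, dt=None)
    sde.self_terms = {
        "xi1": np.array([p["a11"], p["a21"], 0.0]),
        "xi1**3": np.array([p["a13"], 0.0, 0.0]),
        "xi2": np.array([p["a12"], p["a22"], 0.0]),
        "xi3": np.array([0.0, 0.0, p["a33"]]),
        "xi1*xi2": np.array([0.0, 0.0, p["a312"]]),
    }
    sde.interaction_terms = {None: {
        "xj1 - xi1": np.array([p["g1"], 0.0, 0.0]),
        "xj2 - xi2": np.array([0.0, p["g2"], 0.0]),
    }}
    sde.diffusion_terms = {
        "1": np.array([p["sigma1"], p["sigma2"], p["sigma3"]]),
    }
    return sde.canonicalized()
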