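"""End-to-end recovery benchmarks: simulate -> train -> distill -> score.

These chain the whole pipeline on the built-in ground-truth systems and are
what the command line's ``recover-benchmark`` runs.  All randomness (network,
initial condition, simulation noise, training, fold shuffling) derives from
the single run seed through a spawned seed tree, so repeated runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .distill import distill, distill_networked, sample_states
from .library import default_libraries
from .metrics import smape
from .models import linear_cubic_reference, make_model
from .network import EXCITATORY, INHIBITORY, generate_network
from .neural import EnsembleComponents, TrainingConfig, fit
from .sde import simulate


def _spawn_seeds(seed: int, k: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(k)]


def recover_linear_cubic(seed: int = 0, n: int = 10, steps: int = 5000,
                         dt: float = 0.01, density: float = 0.2,
                         config: TrainingConfig | None = None,
                         n_ensemble: int = 1) -> dict:
    """Full recovery loop on the cubic-oscillator network test system.

    Trains `n_ensemble` component models from independent initializations and
    distills their average (the averaging cancels part of the approximation
    error that would otherwise leak spurious small terms into the equation).
    Returns the distilled equation, the generating reference, and their sMAPE.
    """
    s_net, s_x0, s_sim, s_train, s_dist = _spawn_seeds(seed, 5)
    topo = generate_network("binary", n=n, density=density, seed=s_net)
    spec = make_model("linear_cubic_test")
    rng = np.random.default_rng(s_x0)
    x0 = rng.normal(size=(n, 3))
    series = simulate(spec, topo, x0, steps=steps, dt=dt, seed=s_sim)
    models, logs = [], []
    for s in _spawn_seeds(s_train, n_ensemble):
        cfg = config or TrainingConfig(epochs=100, batch_size=256,
                                       learning_rate=0.02, patience=10 ** 6)
        cfg.seed = s
        model, log = fit(series, topo, cfg)
        models.append(model)
        logs.append(log)
    ensemble = EnsembleComponents(models) if len(models) > 1 else models[0]
    sde = distill_networked(ensemble, topo, series, default_libraries(3),
                            seed=s_dist)
    ref = linear_cubic_reference()
    return {"sde": sde, "reference": ref, "smape": smape(sde, ref),
            "topology": topo, "series": series, "model": ensemble,
            "training_log": logs[0]}


def recover_signed_hr(seed: int = 0, n: int = 20, steps: int = 2000,
                      dt: float = 0.01, density: float = 0.15,
                      config: TrainingConfig | None = None) -> dict:
    """Sign-recovery loop: bursting-neuron dynamics on a signed network.

    Trains two interaction maps (excitatory / inhibitory links) and distills
    them; reports the distilled interaction coefficient of the synaptic-gate
    term for each link type and the interaction values at a representative
    (resting receiver, spiking sender) state pair, whose signs should mirror
    the generating reversal potentials (excitatory positive, inhibitory
    negative).
    """
    s_net, s_x0, s_sim, s_train, s_dist = _spawn_seeds(seed, 5)
    topo = generate_network("signed", n=n, density=density, seed=s_net)
    spec = make_model("hindmarsh_rose")
    rng = np.random.default_rng(s_x0)
    x0 = np.column_stack([rng.uniform(-1.5, 0.5, n),
                          rng.uniform(-8.0, 0.0, n),
                          rng.uniform(1.8, 2.2, n)])
    series = simulate(spec, topo, x0, steps=steps, dt=dt, seed=s_sim)
    config = config or TrainingConfig(epochs=100, batch_size=256,
                                      learning_rate=0.02, patience=10 ** 6)
    config.seed = s_train
    model, log = fit(series, topo, config)
    # the interaction maps are distilled per component (the trained pair maps
    # are regressed directly on the pair library), which isolates the synaptic
    # gate structure from the much larger self-dynamics
    rng_d = np.random.default_rng(s_dist)
    states, pairs = sample_states(series, rng_d, 2000, topo, 4000)
    sde = distill(model, default_libraries(3), states, pairs, dt=dt,
                  seed=s_dist)

    # sign readout: response of the distilled interaction (at a resting
    # receiver) to the sender moving from rest to a spike; the receiver-state
    # contrast cancels any receiver-only offset the decomposition leaves in g
    xi = np.array([[-1.0, -4.0, 2.0]])
    spike = np.array([[2.0, -4.0, 2.0]])
    rest = np.array([[-1.0, -4.0, 2.0]])
    readout = {lt: float(sde.evaluate_interaction(xi, spike, lt)[0, 0]
                         - sde.evaluate_interaction(xi, rest, lt)[0, 0])
               for lt in (EXCITATORY, INHIBITORY)}
    return {"sde": sde, "interaction_spike_contrast": readout, "series": series,
            "topology": topo, "model": model, "training_log": log,
            "signs_opposite": readout[EXCITATORY] > 0 > readout[INHIBITORY]}
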