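"""Networked stochastic differential equations and their Euler-Maruyama integration.

A networked SDE couples n nodes, each with a d-dimensional state x_i, through

    dx_i = ( F(x_i) + sum_j A_ij G(x_i, x_j) ) dt + Phi(x_i) dW_t,

where F is the self-dynamics, G the pairwise interaction aggregated over the
adjacency A (receiver-first convention), Phi the state-dependent diffusion
amplitude and W_t a d-dimensional Wiener process (increments ~ N(0, dt)).

The integrator is the Euler-Maruyama scheme: the single step is a pure function
of the state and externally supplied standard-normal draws so that its
statistics are directly testable; `simulate` wires a seeded generator through it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .network import NetworkTopology

PairMap = Callable[[np.ndarray, np.ndarray], np.ndarray]


class DivergenceError(RuntimeError):
    """Raised when a simulated trajectory exceeds the blow-up bound."""

    def __init__(self, step: int, bound: float):
        self.step = step
        super().__init__(f"trajectory exceeded |x| = {bound:g} at step {step}")


@dataclass
class SDEModelSpec:
    """Ground-truth model: drift (self + pairwise) and diffusion maps.

    drift_self : callable (m, d) -> (m, d)
    drift_pair : callable (x_i, x_j) -> (m, d), or a dict keyed by link type
        when the interaction depends on the link label (signed networks).
    diffusion : callable (m, d) -> (m, d) diagonal amplitudes, or (m, d, d)
        full matrices.  The implied transition covariance Phi Phi^T dt is
        positive semidefinite by construction.
    """

    d: int
    drift_self: Callable[[np.ndarray], np.ndarray]
    drift_pair: PairMap | dict[str, PairMap] | None
    diffusion: Callable[[np.ndarray], np.ndarray] | None
    params: dict = field(default_factory=dict)
    name: str = "custom"

    def pair_map(self, link_type: str | None) -> PairMap | None:
        if self.drift_pair is None:
            return None
        if isinstance(self.drift_pair, dict):
            if link_type is None:
                raise ValueError("model has per-type interactions; link type required")
            return self.drift_pair[link_type]
        return self.drift_pair


@dataclass
class NodeStateSeries:
    """Activity tensor (time x node x dimension) sampled at fixed dt."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (T, n, d)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two time steps")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite entries")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def d(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps)


def drift_field(spec: SDEModelSpec, topo: NetworkTopology, x_t: np.ndarray) -> np.ndarray:
    """Total drift F(x_i) + sum_j A_ij G(x_i, x_j) for every node, shape (n, d)."""
    drift = spec.drift_self(x_t)
    if spec.drift_pair is not None:
        types = topo.types_present if isinstance(spec.drift_pair, dict) else [None]
        for lt in types:
            recv, send, w = topo.edges(lt)
            if recv.size == 0:
                continue
            g = spec.pair_map(lt)(x_t[recv], x_t[send])
            contrib = np.zeros_like(drift)
            np.add.at(contrib, recv, w[:, None] * g)
            drift = drift + contrib
    return drift


def euler_maruyama_step(
    spec: SDEModelSpec,
    topo: NetworkTopology,
    x_t: np.ndarray,
    dt: float,
    noise: np.ndarray,
) -> np.ndarray:
    """One Euler-Maruyama step; `noise` holds externally drawn N(0,1) variates.

    Returns x_t + drift(x_t) dt + Phi(x_t) sqrt(dt) noise, a pure function of
    its arguments.
    """
    x_t = np.asarray(x_t, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if x_t.shape != (topo.n, spec.d) or noise.shape != x_t.shape:
        raise ValueError("state/noise shape must be (n, d)")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(noise))):
        raise ValueError("non-finite state or noise")
    x_next = x_t + drift_field(spec, topo, x_t) * dt
    if spec.diffusion is not None:
        phi = spec.diffusion(x_t)
        if phi.ndim == 2:
            x_next = x_next + phi * (np.sqrt(dt) * noise)
        else:  # full d x d diffusion matrix per node
            x_next = x_next + np.einsum("nkl,nl->nk", phi, np.sqrt(dt) * noise)
    return x_next


def simulate(
    spec: SDEModelSpec,
    topo: NetworkTopology,
    x0: np.ndarray,
    steps: int,
    dt: float,
    seed: int = 0,
    blowup: float = 1e6,
) -> NodeStateSeries:
    """Integrate the networked SDE from x0 for `steps` Euler-Maruyama steps.

    The returned series has steps+1 snapshots with values[0] = x0.  Identical
    arguments (including seed) yield bit-identical output.  Raises
    DivergenceError naming the offending step if any |x| exceeds `blowup`.
    """
    x0 = np.asarray(x0, dtype=float)
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    rng = np.random.default_rng(seed)
    out = np.empty((steps + 1, topo.n, spec.d))
    out[0] = x0
    x = x0
    for k in range(steps):
        noise = rng.standard_normal((topo.n, spec.d))
        x = euler_maruyama_step(spec, topo, x, dt, noise)
        if np.any(np.abs(x) > blowup) or not np.all(np.isfinite(x)):
            raise DivergenceError(k + 1, blowup)
        out[k + 1] = x
    return NodeStateSeries(values=out, dt=dt,
                           meta={"model": spec.name, "seed": seed, "params": dict(spec.params)})


# ---------------------------------------------------------------------------
# trajectory I/O: long-form CSV and a columnar .npz container
# ---------------------------------------------------------------------------

def write_series_csv(series: NodeStateSeries, path: str) -> None:
    T, n, d = series.values.shape
    t = np.repeat(series.times, n * d)
    node = np.tile(np.repeat(np.arange(n), d), T)
    dim = np.tile(np.arange(d), T * n)
    pd.DataFrame({"t": t, "node": node, "dim": dim,
                  "value": series.values.ravel()}).to_csv(path, index=False)


def read_series_csv(path: str) -> NodeStateSeries:
    df = pd.read_csv(path)
    T = df["t"].nunique()
    n = int(df["node"].max()) + 1
    d = int(df["dim"].max()) + 1
    df = df.sort_values(["t", "node", "dim"])
    values = df["value"].to_numpy().reshape(T, n, d)
    times = np.sort(df["t"].unique())
    dt = float(np.mean(np.diff(times)))
    return NodeStateSeries(values=values, dt=dt, t0=float(times[0]))


def write_series_npz(series: NodeStateSeries, path: str) -> None:
    np.savez_compressed(path, values=series.values, dt=series.dt, t0=series.t0,
                        meta=json.dumps(series.meta))


def read_series_npz(path: str) -> NodeStateSeries:
    with np.load(path, allow_pickle=False) as z:
        return NodeStateSeries(values=z["values"], dt=float(z["dt"]), t0=float(z["t0"]),
                               meta=json.loads(str(z["meta"])))
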