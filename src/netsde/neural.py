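"""Stage 1: likelihood-trained component models of a networked SDE.

Three trainable function approximators — self drift f, pairwise interaction g
(one map per link type on signed networks), and diffusion amplitude phi — are
composed by topology-guided message passing into a Gaussian transition density
for each node,

    mu_i    = x_i + ( f(x_i) + sum_j A_ij g(x_i, x_j) ) dt
    sigma_i^2 = phi(x_i)^2 dt          (diagonal variance mode),

and trained by minimizing the negative log-likelihood of the observed
next-step states over all consecutive snapshot pairs of a single trial.
Positivity of the variance is enforced by passing the diffusion net's raw
output through a softplus.  Training data are z-scored per dimension by
default; the stored inverse transform lets every component be queried in the
original units, which is what stage-2 distillation consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, Adam, sigmoid, softplus
from .network import NetworkTopology
from .sde import NodeStateSeries


@dataclass
class TrainingConfig:
    epochs: int = 80
    batch_size: int = 128          # time steps per minibatch
    learning_rate: float = 1e-2
    hidden: tuple[int, int] = (32, 32)
    seed: int = 0
    patience: int = 20             # early-stop patience, in epochs
    val_fraction: float = 0.1      # held-out tail of the series
    normalization: str = "zscore"  # or "none"

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.normalization not in ("zscore", "none"):
            raise ValueError("normalization must be 'zscore' or 'none'")


@dataclass
class TransitionPrediction:
    """Per-node predicted transition mean and variance (original units)."""

    mu: np.ndarray
    sigma2: np.ndarray | None = None       # (n, d), diagonal mode
    Sigma: np.ndarray | None = None        # (n, d, d), full mode


@dataclass
class ComponentModel:
    """The trained triple (f, g per link type, phi) plus normalization state."""

    d: int
    f_net: MLP
    g_nets: dict
    phi_net: MLP
    norm_mean: np.ndarray
    norm_std: np.ndarray
    envelope: tuple[np.ndarray, np.ndarray] | None = None  # (min, max) original units
    variance_mode: str = "diagonal"
    config: TrainingConfig | None = None

    # components in original units ------------------------------------------

    def _z(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.norm_mean) / self.norm_std

    def self_fn(self, x: np.ndarray) -> np.ndarray:
        """Self drift f(x) on (m, d) states."""
        return self.norm_std * self.f_net(self._z(x))

    def pair_fn(self, xi: np.ndarray, xj: np.ndarray,
                link_type: str | None = None) -> np.ndarray:
        """Interaction drift g(x_i, x_j) on matched (m, d) states."""
        key = link_type if link_type in self.g_nets else None
        if key not in self.g_nets:
            raise KeyError(f"no interaction map for link type {link_type!r}")
        z = np.column_stack([self._z(xi), self._z(xj)])
        return self.norm_std * self.g_nets[key](z)

    def diffusion_fn(self, x: np.ndarray) -> np.ndarray:
        """Positive diffusion amplitude phi(x) on (m, d) states."""
        return self.norm_std * softplus(self.phi_net(self._z(x)))

    def extrapolation_fraction(self, states: np.ndarray) -> float:
        if self.envelope is None:
            return float("nan")
        lo, hi = self.envelope
        outside = np.any((states < lo) | (states > hi), axis=1)
        return float(np.mean(outside))


def predict_transition(model: ComponentModel, x_t: np.ndarray,
                       topo: NetworkTopology, dt: float) -> TransitionPrediction:
    """One-step transition density parameters for every node.

    mu_i = x_i + (f(x_i) + sum_j A_ij g(x_i, x_j)) dt, with the interaction
    aggregated element-wise over sending nodes j weighted by A_ij (and summed
    per link type when typed maps exist); sigma_i^2 = phi(x_i)^2 dt.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (topo.n, model.d):
        raise ValueError("state shape must be (n, d)")
    drift = model.self_fn(x_t)
    if not np.all(np.isfinite(drift)):
        raise FloatingPointError("self component produced non-finite output")
    types = ([None] if set(model.g_nets) == {None}
             else [t for t in topo.types_present if t in model.g_nets])
    for lt in types:
        recv, send, w = topo.edges(lt if lt is not None else None)
        if recv.size == 0:
            continue
        g = model.pair_fn(x_t[recv], x_t[send], lt)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("interaction component produced non-finite output")
        np.add.at(drift, recv, w[:, None] * g)
    mu = x_t + drift * dt
    phi = model.diffusion_fn(x_t)
    if not np.all(np.isfinite(phi)):
        raise FloatingPointError("diffusion component produced non-finite output")
    return TransitionPrediction(mu=mu, sigma2=phi ** 2 * dt)


def gaussian_nll(x_next: np.ndarray, pred: TransitionPrediction) -> float:
    """Negative Gaussian transition log-likelihood, constants dropped.

    Diagonal mode: mean over nodes and dimensions of
    (x_next - mu)^2 / sigma^2 + log sigma^2.  Full mode applies the
    multivariate expression (log|Sigma| + r^T Sigma^-1 r), scaled by 1/d and
    averaged over nodes so a diagonal Sigma reduces to the diagonal mode term
    by term (an affine rescaling that leaves the optimum unchanged).
    """
    x_next = np.asarray(x_next, dtype=float)
    r = x_next - pred.mu
    if pred.sigma2 is not None:
        s2 = np.asarray(pred.sigma2, dtype=float)
        if s2.shape != r.shape:
            raise ValueError("shape mismatch")
        if np.any(s2 <= 0):
            raise ValueError("variances must be strictly positive")
        return float(np.mean(r ** 2 / s2 + np.log(s2)))
    Sigma = np.asarray(pred.Sigma, dtype=float)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.einsum("nkk->nk", L)), axis=1)
    sol = np.linalg.solve(Sigma, r[..., None])[..., 0]
    quad = np.einsum("nk,nk->n", r, sol)
    d = r.shape[1]
    return float(np.mean((logdet + quad) / d))


class TrainingDivergence(RuntimeError):
    pass


def fit(series: NodeStateSeries, topo: NetworkTopology,
        config: TrainingConfig | None = None) -> tuple[ComponentModel, dict]:
    """Train the component models on one trial of activity snapshots.

    Minimizes the mean Gaussian transition NLL over all consecutive pairs and
    nodes with Adam on random minibatches of time indices; the last
    `val_fraction` of transitions is held out and the parameter state with the
    best held-out NLL is returned, together with a per-epoch training log.
    """
    config = config or TrainingConfig()
    if series.n_steps < 2:
        raise ValueError("series must contain at least two snapshots")
    rng = np.random.default_rng(config.seed)
    d = series.d
    dt = series.dt
    x = series.values
    if config.normalization == "zscore":
        mean = x.reshape(-1, d).mean(axis=0)
        std = x.reshape(-1, d).std(axis=0)
        std[std < 1e-12] = 1.0
    else:
        mean = np.zeros(d)
        std = np.ones(d)
    z = (x - mean) / std

    # typed edge structure and dense aggregation operators
    typed = isinstance(topo.link_types, np.ndarray) and topo.types_present
    type_keys = list(topo.types_present) if typed else [None]
    edges = {}
    for lt in type_keys:
        recv, send, w = topo.edges(lt)
        M = np.zeros((topo.n, recv.size))
        M[recv, np.arange(recv.size)] = w
        edges[lt] = (recv, send, w, M)

    f_net = MLP([d, *config.hidden, d], rng)
    g_nets = {lt: MLP([2 * d, *config.hidden, d], rng) for lt in type_keys}
    phi_net = MLP([d, *config.hidden, d], rng)
    nets = [f_net, *g_nets.values(), phi_net]
    opt = Adam([p for net in nets for p in net.params], lr=config.learning_rate)

    Tm1 = series.n_steps - 1
    n_val = max(1, int(np.ceil(config.val_fraction * Tm1)))
    train_idx = np.arange(Tm1 - n_val)
    val_idx = np.arange(Tm1 - n_val, Tm1)
    if train_idx.size == 0:
        train_idx, val_idx = val_idx, val_idx

    def batch_loss_and_grads(t_idx: np.ndarray, want_grads: bool = True):
        B = t_idx.size
        n = topo.n
        zs = z[t_idx]                       # (B, n, d)
        znext = z[t_idx + 1]
        flat = zs.reshape(B * n, d)
        f_out, f_cache = f_net.forward(flat)
        drift = f_out.reshape(B, n, d)
        g_caches = {}
        for lt, (recv, send, w, M) in edges.items():
            if recv.size == 0:
                continue
            pair_in = np.concatenate([zs[:, recv, :], zs[:, send, :]],
                                     axis=2).reshape(B * recv.size, 2 * d)
            g_out, g_cache = g_nets[lt].forward(pair_in)
            g_caches[lt] = g_cache
            drift = drift + np.einsum("ne,bed->bnd", M,
                                      g_out.reshape(B, recv.size, d))
        raw, phi_cache = phi_net.forward(flat)
        phi = softplus(raw).reshape(B, n, d)
        mu = zs + drift * dt
        s2 = phi ** 2 * dt + 1e-12
        r = znext - mu
        N = B * n * d
        loss = float(np.mean(r ** 2 / s2 + np.log(s2)))
        if not want_grads:
            return loss, None
        dmu = (-2.0 * r / s2) / N
        ds2 = (1.0 / s2 - r ** 2 / s2 ** 2) / N
        grads = []
        gf, _ = f_net.backward(f_cache, (dmu * dt).reshape(B * n, d))
        grads.extend(gf)
        for lt, (recv, send, w, M) in edges.items():
            if recv.size == 0:
                grads.extend([np.zeros_like(p) for p in g_nets[lt].params])
                continue
            grad_g = (dmu[:, recv, :] * w[None, :, None] * dt).reshape(-1, d)
            gg, _ = g_nets[lt].backward(g_caches[lt], grad_g)
            grads.extend(gg)
        graw = (ds2 * 2.0 * phi * dt).reshape(B * n, d) * sigmoid(raw)
        gp, _ = phi_net.backward(phi_cache, graw)
        grads.extend(gp)
        return loss, grads

    log = {"train_nll": [], "val_nll": []}
    best_val = np.inf
    best_params = [net.copy_params() for net in nets]
    stall = 0
    bad_streak = 0
    lr0 = config.learning_rate
    for epoch in range(config.epochs):
        # cosine learning-rate decay: late-epoch steps shrink so the drift
        # estimate settles instead of diffusing under minibatch noise
        opt.lr = lr0 * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * epoch / config.epochs)))
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size == 0:
                continue
            loss, grads = batch_loss_and_grads(batch)
            if not np.isfinite(loss):
                bad_streak += 1
                if bad_streak > 5:
                    raise TrainingDivergence(
                        f"non-finite NLL for {bad_streak} consecutive steps at "
                        f"epoch {epoch}")
                continue
            bad_streak = 0
            epoch_losses.append(loss)
            opt.step([p for net in nets for p in net.params], grads)
        val_loss, _ = batch_loss_and_grads(val_idx, want_grads=False)
        log["train_nll"].append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        log["val_nll"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [net.copy_params() for net in nets]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    for net, params in zip(nets, best_params):
        net.set_params(params)

    flat_states = x.reshape(-1, d)
    model = ComponentModel(
        d=d, f_net=f_net, g_nets=g_nets, phi_net=phi_net,
        norm_mean=mean, norm_std=std,
        envelope=(flat_states.min(axis=0), flat_states.max(axis=0)),
        config=config)
    return model, log


class EnsembleComponents:
    """Average of several trained component models.

    Independently initialized training runs carry partially independent
    approximation error; averaging their component functions reduces that
    error before stage-2 distillation.  Exposes the same component surface as
    a single ComponentModel.
    """

    def __init__(self, models: list[ComponentModel]):
        if not models:
            raise ValueError("need at least one model")
        self.models = models
        self.d = models[0].d

    @property
    def g_nets(self) -> dict:
        return self.models[0].g_nets

    def self_fn(self, x: np.ndarray) -> np.ndarray:
        return np.mean([m.self_fn(x) for m in self.models], axis=0)

    def pair_fn(self, xi: np.ndarray, xj: np.ndarray,
                link_type: str | None = None) -> np.ndarray:
        return np.mean([m.pair_fn(xi, xj, link_type) for m in self.models],
                       axis=0)

    def diffusion_fn(self, x: np.ndarray) -> np.ndarray:
        return np.mean([m.diffusion_fn(x) for m in self.models], axis=0)


def evaluate_components(model: ComponentModel, states: np.ndarray,
                        pair_states: np.ndarray | None = None) -> dict:
    """Sample the trained components (original units) for distillation/diagnostics.

    Returns self and diffusion values on `states` and, when `pair_states`
    (m, 2d) is given, interaction values per link type, plus the fraction of
    query states outside the training-data envelope.
    """
    states = np.asarray(states, dtype=float)
    out = {
        "self": model.self_fn(states),
        "diffusion": model.diffusion_fn(states),
        "extrapolation_fraction": model.extrapolation_fraction(states),
    }
    if pair_states is not None:
        pair_states = np.asarray(pair_states, dtype=float)
        xi, xj = pair_states[:, :model.d], pair_states[:, model.d:]
        out["interaction"] = {lt: model.pair_fn(xi, xj, lt) for lt in model.g_nets}
    return out


# ---------------------------------------------------------------------------
# checkpointing (single JSON file, versioned schema)
# ---------------------------------------------------------------------------

def save_checkpoint(model: ComponentModel, path: str) -> None:
    def pack(net: MLP) -> dict:
        return {"dims": net.dims,
                "W": [w.tolist() for w in net.W],
                "b": [b.tolist() for b in net.b]}

    data = {
        "schema": "netsde.checkpoint.v1",
        "d": model.d,
        "variance_mode": model.variance_mode,
        "norm_mean": model.norm_mean.tolist(),
        "norm_std": model.norm_std.tolist(),
        "envelope": None if model.envelope is None else
                    [model.envelope[0].tolist(), model.envelope[1].tolist()],
        "f": pack(model.f_net),
        "phi": pack(model.phi_net),
        "g": {str(lt): pack(net) for lt, net in model.g_nets.items()},
        "config": None if model.config is None else vars(model.config) | {
            "hidden": list(model.config.hidden)},
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_checkpoint(path: str) -> ComponentModel:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema") != "netsde.checkpoint.v1":
        raise ValueError("unrecognized checkpoint schema")

    def unpack(blob: dict) -> MLP:
        net = MLP(blob["dims"], np.random.default_rng(0))
        net.W = [np.asarray(w, dtype=float) for w in blob["W"]]
        net.b = [np.asarray(b, dtype=float) for b in blob["b"]]
        return net

    cfg = None
    if data.get("config"):
        c = dict(data["config"])
        c["hidden"] = tuple(c["hidden"])
        cfg = TrainingConfig(**c)
    env = data.get("envelope")
    return ComponentModel(
        d=int(data["d"]),
        f_net=unpack(data["f"]),
        g_nets={(None if lt == "None" else lt): unpack(blob)
                for lt, blob in data["g"].items()},
        phi_net=unpack(data["phi"]),
        norm_mean=np.asarray(data["norm_mean"], dtype=float),
        norm_std=np.asarray(data["norm_std"], dtype=float),
        envelope=None if env is None else (np.asarray(env[0]), np.asarray(env[1])),
        variance_mode=data["variance_mode"],
        config=cfg)
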