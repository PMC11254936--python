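"""Stage 2: two-phase sparse regression onto elementary-function libraries.

Phase 1 ranks library terms by relevance with an L1-penalized global fit
(LASSO over a log-spaced lambda grid, cross-validated with seeded shuffled
five-fold splits; relevance = |standardized coefficient| at the CV-optimal
lambda).  Phase 2 walks down the ranking, refitting unpenalized least squares
on nested supports, and stops at the minimal term count N_min once adding the
next term no longer improves the regression score kappa^2 by more than a
tolerance.  `distill` applies the two phases independently to the self,
interaction (per link type) and diffusion components, per output dimension,
and assembles the result into a SymbolicSDE with coefficients in the original
data units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold

from .library import DesignMatrix, TermLibrary, drop_duplicate_columns, evaluate
from .metrics import kappa2
from .network import NetworkTopology
from .symbolic import SymbolicSDE


@dataclass
class RelevanceRanking:
    """Library terms ordered by relevance to one regression target."""

    term_names: list[str]
    scores: np.ndarray
    chosen_lambda: float


@dataclass
class SparseCoefficients:
    coefficients: dict  # term name -> float
    kappa2_path: list[float] = field(default_factory=list)
    n_min: int = 0


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_values: int = 50,
                 decades: float = 4.0) -> np.ndarray:
    lam_max = np.max(np.abs(X.T @ y)) / max(len(y), 1)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_values)


def phase1_global(design: DesignMatrix, target: np.ndarray,
                  lambda_grid: np.ndarray | None = None, folds: int = 5,
                  seed: int = 0) -> RelevanceRanking:
    """Global L1 regression ranking every library term by relevance.

    Columns are standardized before the penalized fit (constant columns cannot
    be; the constant term's relevance is |mean(target)| / std(target), the
    standardized effect size of an intercept).  Ties in relevance are broken
    by library order.  Deterministic under a fixed seed.
    """
    y = np.asarray(target, dtype=float).ravel()
    X = design.values
    if X.shape[0] != y.size:
        raise ValueError("design/target length mismatch")
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold validation")
    names = design.term_names
    sd = X.std(axis=0)
    varying = sd > 1e-12
    y_sd = y.std()
    scores = np.zeros(len(names))
    chosen = 0.0
    if y_sd > 1e-14 * max(1.0, abs(y.mean())) and varying.any():
        Xv = (X[:, varying] - X[:, varying].mean(axis=0)) / sd[varying]
        yc = y - y.mean()
        grid = lambda_grid if lambda_grid is not None else _lambda_grid(Xv, yc)
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        model = LassoCV(alphas=grid, cv=cv, fit_intercept=False, max_iter=5000)
        model.fit(Xv, yc)
        chosen = float(model.alpha_)
        primary = np.abs(model.coef_)
        # terms inactive at the CV-optimal lambda are ranked strictly below the
        # active ones by their largest coefficient further down the path, so
        # the sequential phase can still reach a term the optimal-lambda fit
        # shrank away (near-collinear libraries)
        _, path_coefs, _ = lasso_path(Xv, yc, alphas=np.sort(grid)[::-1],
                                      max_iter=2000)
        secondary = np.max(np.abs(path_coefs), axis=1)
        if np.any(primary > 0):
            cap = primary[primary > 0].min()
            sec_max = secondary.max()
            rescale = 1e-9 * cap / sec_max if sec_max > 0 else 0.0
            scores[varying] = np.where(primary > 0, primary,
                                       rescale * secondary)
        else:
            scores[varying] = 1e-9 * secondary
    # the intercept slot: relevance of any constant column
    const_rel = abs(y.mean()) / max(y_sd, 1e-14)
    scores[~varying] = const_rel if abs(y.mean()) > 1e-14 else 0.0
    order = sorted(range(len(names)), key=lambda q: (-scores[q], q))
    return RelevanceRanking(term_names=[names[q] for q in order],
                            scores=scores[order], chosen_lambda=chosen)


def phase2_minimal(design: DesignMatrix, target: np.ndarray,
                   ranking: RelevanceRanking, tolerance: float = 1e-3,
                   prune: float = 0.04,
                   rel_fraction: float = 1.0 / 8.0) -> SparseCoefficients:
    """Sequential term selection by the kappa^2 stopping rule.

    Adds ranked terms one by one, refitting ordinary least squares on each
    nested support; stops once the kappa^2 gain of the next term is at most
    max(tolerance, (1 - kappa^2)/3) — a further term must both add `tolerance`
    absolute score and resolve at least a third of the remaining misfit.  With
    trained approximators the remaining misfit near the plateau is
    approximation noise, and a term explaining only a fraction of it is
    rejected; an exactly representable target still proceeds to kappa^2 = 1
    because each needed term resolves (essentially all of) the remainder.
    After selection, terms whose fitted contribution (|coefficient| x column
    RMS) is below `prune` times the target RMS are dropped and the support
    refitted.

    A target with (numerically) zero variance is either an exactly
    representable constant (returned as the constant term alone) or a domain
    error, since kappa^2 is undefined there.
    """
    y = np.asarray(target, dtype=float).ravel()
    X = design.values
    names = design.term_names
    col = {n: q for q, n in enumerate(names)}
    scale = float(np.max(np.abs(y))) if y.size else 0.0
    if scale < 1e-12:  # identically zero target: empty equation
        return SparseCoefficients(coefficients={}, kappa2_path=[], n_min=0)
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 1e-18 * y.size * max(1.0, y.mean() ** 2):  # constant target
        const = [n for n in names if np.std(X[:, col[n]]) <= 1e-12
                 and abs(np.mean(X[:, col[n]])) > 1e-12]
        if not const:
            raise ValueError("kappa^2 undefined: constant target and no constant term")
        c = y.mean() / np.mean(X[:, col[const[0]]])
        return SparseCoefficients(coefficients={const[0]: float(c)},
                                  kappa2_path=[1.0], n_min=1)
    ranked = [n for n, s in zip(ranking.term_names, ranking.scores) if s > 0.0]
    if not ranked:
        ranked = list(ranking.term_names)

    def ols(support_names: list[str]) -> tuple[np.ndarray, float]:
        support = [col[n] for n in support_names]
        beta, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        return beta, kappa2(X[:, support] @ beta, y)

    path: list[float] = []
    support_names: list[str] = []
    remaining = list(ranked)
    lookahead = 8
    while remaining:
        # among the next few ranked candidates, add the best-gaining one; the
        # lookahead keeps a near-collinear decoy from blocking a needed term
        window = remaining[:lookahead] if path else remaining[:1]
        trials = [(ols(support_names + [name])[1], q, name)
                  for q, name in enumerate(window)]
        best = max(t[0] for t in trials)
        base = path[-1] if path else 0.0
        # among candidates whose gain is within 5% of the best, keep the
        # relevance order (the gain differences are below the noise scale)
        margin = 0.05 * abs(best - base)
        score, _, name = min((t for t in trials if t[0] >= best - margin),
                             key=lambda t: t[1])
        threshold = (max(tolerance, rel_fraction * (1.0 - base))
                     if path else -np.inf)
        if score - base > threshold:
            support_names.append(name)
            remaining.remove(name)
            path.append(score)
            if score > 1.0 - 1e-12:
                break
            continue
        # no single term passes: near-collinear groups (e.g. x and x^3 on a
        # narrow range) only help jointly, so try pairs from the window
        pair_trials = [(ols(support_names + [a, b])[1], a, b)
                       for qa, a in enumerate(window)
                       for b in window[qa + 1:]]
        if not pair_trials:
            break
        p_score, a, b = max(pair_trials, key=lambda t: t[0])
        if p_score - base <= max(2.0 * tolerance,
                                 2.0 * rel_fraction * (1.0 - base)):
            break
        support_names.extend([a, b])
        remaining.remove(a)
        remaining.remove(b)
        path.append(p_score)
        if p_score > 1.0 - 1e-12:
            break
    beta, score = ols(support_names)
    # backward elimination: a term admitted early can be made redundant by
    # later ones (or may have fitted approximator noise); drop any whose
    # removal costs less than the stopping scale
    while len(support_names) > 1:
        trials = [(ols([m for m in support_names if m != name])[1], name)
                  for name in support_names]
        best_score, victim = max(trials, key=lambda t: t[0])
        if score - best_score > max(2.0 * tolerance,
                                    2.0 * rel_fraction * (1.0 - score)):
            break
        support_names.remove(victim)
        beta, score = ols(support_names)
        path.append(score)
    # contribution-based pruning of negligible selected terms; the reference
    # scale is the fitted signal, not the raw target (which may be dominated
    # by transition noise when regressing increments)
    if support_names:
        fitted = X[:, [col[s] for s in support_names]] @ beta
        y_rms = float(np.sqrt(np.mean(fitted ** 2)))
    else:
        y_rms = 0.0
    y_rms = y_rms if y_rms > 0 else float(np.sqrt(np.mean(y ** 2)))
    while len(support_names) > 1:
        contrib = np.array([abs(b) * np.sqrt(np.mean(X[:, col[n]] ** 2))
                            for n, b in zip(support_names, beta)])
        weakest = int(np.argmin(contrib))
        if contrib[weakest] >= prune * y_rms:
            break
        support_names = [n for q, n in enumerate(support_names) if q != weakest]
        beta, score = ols(support_names)
        path.append(score)
    coeffs = {n: float(b) for n, b in zip(support_names, beta)
              if abs(b) > 1e-12 * scale}
    return SparseCoefficients(coefficients=coeffs, kappa2_path=path,
                              n_min=len(coeffs))


@dataclass
class OracleComponents:
    """Adapter exposing known ground-truth functions with the trained-model API.

    Used to bypass stage 1 in recovery tests: distillation then operates on
    the exact self/interaction/diffusion functions.
    """

    spec: object  # SDEModelSpec

    def self_fn(self, x: np.ndarray) -> np.ndarray:
        return self.spec.drift_self(np.asarray(x, dtype=float))

    @property
    def g_nets(self) -> dict:
        if self.spec.drift_pair is None:
            return {}
        if isinstance(self.spec.drift_pair, dict):
            return self.spec.drift_pair
        return {None: self.spec.drift_pair}

    def pair_fn(self, xi: np.ndarray, xj: np.ndarray,
                link_type: str | None = None) -> np.ndarray:
        return self.spec.pair_map(link_type)(np.asarray(xi, dtype=float),
                                             np.asarray(xj, dtype=float))

    def diffusion_fn(self, x: np.ndarray) -> np.ndarray:
        phi = self.spec.diffusion(np.asarray(x, dtype=float))
        if phi.ndim == 3:
            phi = np.sqrt(np.einsum("nkl,nkl->nk", phi, phi))
        return phi


def distill(components, libraries: tuple[TermLibrary, TermLibrary, TermLibrary],
            states: np.ndarray, pair_states: np.ndarray, dt: float | None = None,
            tolerance: float = 1e-3, component_floor: float = 0.05,
            seed: int = 0) -> SymbolicSDE:
    """Distill trained (or oracle) components onto symbolic elementary terms.

    Runs phase 1 + phase 2 independently for the self drift, each interaction
    map, and the diffusion amplitude, one output dimension at a time (the
    Kronecker-lifted problem is block diagonal across output components, so the
    per-dimension regressions are exactly its independent blocks).  The
    diffusion target is the positive amplitude phi, i.e. the transition
    standard deviation rescaled by 1/sqrt(dt).

    component_floor: an output dimension whose sampled component values have an
    RMS below this fraction of the part's largest per-dimension RMS is treated
    as absent (zero terms).  With trained approximators a truly missing
    component is pure approximation noise; without a floor it would pick up
    spurious small terms.  Set to 0 to disable (e.g. with oracle components).
    """
    lf, lg, lphi = libraries
    d = lf.d
    sde = SymbolicSDE(d=d, dt=dt)

    def fit_part(design: DesignMatrix, targets: np.ndarray, part: str):
        design, _ = drop_duplicate_columns(design)
        coeffs: dict[str, np.ndarray] = {}
        n_min = 0
        rms = np.sqrt(np.mean(targets ** 2, axis=0))
        floor = component_floor * rms.max() if rms.size else 0.0
        for k in range(targets.shape[1]):
            if rms[k] < floor:
                continue
            y = targets[:, k]
            ranking = phase1_global(design, y, seed=seed + 7 * k)
            sel = phase2_minimal(design, y, ranking, tolerance=tolerance)
            if sel.kappa2_path:
                sde.fit_kappa2[(part, k)] = sel.kappa2_path[-1]
            n_min = max(n_min, sel.n_min)
            for name, c in sel.coefficients.items():
                vec = coeffs.setdefault(name, np.zeros(d))
                vec[k] = c
        sde.n_min[part] = n_min
        return coeffs

    theta_f = evaluate(lf, states)
    sde.self_terms = fit_part(theta_f, components.self_fn(states), "self")

    xi, xj = pair_states[:, :d], pair_states[:, d:]
    for lt in components.g_nets:
        theta_g = evaluate(lg, pair_states)
        g_vals = components.pair_fn(xi, xj, lt)
        part = "interaction" if lt is None else f"interaction[{lt}]"
        sde.interaction_terms[lt] = fit_part(theta_g, g_vals, part)

    theta_phi = evaluate(lphi, states)
    sde.diffusion_terms = fit_part(theta_phi, components.diffusion_fn(states),
                                   "diffusion")
    return sde.canonicalized()


def distill_networked(model, topo: NetworkTopology, series,
                      libraries: tuple[TermLibrary, TermLibrary, TermLibrary],
                      n_times: int = 1000, tolerance: float = 1e-3,
                      component_floor: float = 0.02, seed: int = 0,
                      drift_target: str = "increments") -> SymbolicSDE:
    """Distill through a joint sparse regression of the total drift.

    The per-component route regresses f and g separately on the network's
    outputs; but the likelihood constrains only their topology-aggregated sum,
    so a receiver-only piece of the interaction can trade off against the self
    term along a nearly flat direction of the training objective.  This
    variant regresses the *total* drift on the concatenation of self-library
    columns and topology-aggregated pair-library columns (per link type):
    in-degree heterogeneity then separates the two parts exactly, making the
    decomposition itself part of the sparse regression.  The diffusion part is
    distilled from the trained amplitude as usual.

    drift_target selects the regression target for the drift:
      "increments" (default) — the observed one-step increments
        (x(t+dt) - x(t))/dt.  Their error is white transition noise, which
        perturbs least-squares coefficients at the O(sigma/sqrt(N dt)) scale;
        the trained drift surface, by contrast, carries smooth approximation
        error that the library can partially express, which is far more
        damaging to support identification.
      "model" — the trained total drift f + sum A g (useful when the
        snapshots are noisy beyond the intrinsic diffusion and the network's
        smoothing is wanted).
    """
    if drift_target not in ("increments", "model"):
        raise ValueError("drift_target must be 'increments' or 'model'")
    lf, lg, lphi = libraries
    d = lf.d
    rng = np.random.default_rng(seed)
    values = series.values
    T = values.shape[0]
    t_max = T - 1 if drift_target == "increments" else T
    t_idx = rng.choice(t_max, size=min(n_times, t_max), replace=False)
    n = topo.n
    xs = values[t_idx]                          # (B, n, d)
    B = xs.shape[0]
    flat = xs.reshape(B * n, d)

    theta_f = evaluate(lf, flat)
    if drift_target == "increments":
        target = (values[t_idx + 1] - xs) / series.dt
    else:
        target = model.self_fn(flat).reshape(B, n, d)
    blocks = [theta_f.values]
    col_part: list[tuple[str, str]] = [("self", name) for name in theta_f.term_names]

    typed = bool(set(model.g_nets) - {None})
    type_keys = [t for t in topo.types_present if t in model.g_nets] if typed else [None]
    for lt in type_keys:
        recv, send, w = topo.edges(lt)
        if recv.size == 0:
            continue
        M = np.zeros((n, recv.size))
        M[recv, np.arange(recv.size)] = w
        pair_in = np.concatenate([xs[:, recv, :], xs[:, send, :]],
                                 axis=2).reshape(B * recv.size, 2 * d)
        theta_g = evaluate(lg, pair_in)
        agg = np.einsum("ne,beq->bnq", M,
                        theta_g.values.reshape(B, recv.size, len(lg)))
        blocks.append(agg.reshape(B * n, len(lg)))
        col_part.extend((f"pair:{lt}", name) for name in theta_g.term_names)
        if drift_target == "model":
            g_vals = model.pair_fn(pair_in[:, :d], pair_in[:, d:], lt)
            target = target + np.einsum("ne,bed->bnd", M,
                                        g_vals.reshape(B, recv.size, d))

    design = DesignMatrix(values=np.concatenate(blocks, axis=1),
                          term_names=[f"{p}|{t}" for p, t in col_part])
    design, _ = drop_duplicate_columns(design)
    target = target.reshape(B * n, d)

    sde = SymbolicSDE(d=d, dt=series.dt)
    sde.interaction_terms = {lt: {} for lt in type_keys}
    rms = np.sqrt(np.mean(target ** 2, axis=0))
    floor = component_floor * rms.max()
    n_min = 0
    for k in range(d):
        if rms[k] < floor:
            continue
        y = target[:, k]
        ranking = phase1_global(design, y, seed=seed + 7 * k)
        # against increment targets kappa^2 saturates at the drift's share of
        # the transition variance, so the remaining-misfit fraction carries no
        # information and the stopping rule falls back to the absolute gain
        rel = 0.0 if drift_target == "increments" else 1.0 / 8.0
        sel = phase2_minimal(design, y, ranking, tolerance=tolerance,
                             rel_fraction=rel)
        if sel.kappa2_path:
            sde.fit_kappa2[("drift", k)] = sel.kappa2_path[-1]
        n_min = max(n_min, sel.n_min)
        for nm, c in sel.coefficients.items():
            part, term = nm.split("|", 1)
            if part == "self":
                vec = sde.self_terms.setdefault(term, np.zeros(d))
            else:
                lt = part.split(":", 1)[1]
                lt = None if lt == "None" else lt
                vec = sde.interaction_terms[lt].setdefault(term, np.zeros(d))
            vec[k] = c
    sde.n_min["drift"] = n_min

    theta_phi = evaluate(lphi, flat)
    phi_target = model.diffusion_fn(flat)
    coeffs: dict[str, np.ndarray] = {}
    for k in range(d):
        ranking = phase1_global(theta_phi, phi_target[:, k], seed=seed + 31 + 7 * k)
        sel = phase2_minimal(theta_phi, phi_target[:, k], ranking,
                             tolerance=tolerance)
        if sel.kappa2_path:
            sde.fit_kappa2[("diffusion", k)] = sel.kappa2_path[-1]
        for nm, c in sel.coefficients.items():
            coeffs.setdefault(nm, np.zeros(d))[k] = c
    sde.diffusion_terms = coeffs
    sde.n_min["diffusion"] = len(coeffs)
    return sde.canonicalized()


def sample_states(series, rng: np.random.Generator, n_samples: int = 2000,
                  topo: NetworkTopology | None = None,
                  n_pair_samples: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """Draw (state, pair-state) samples from a trajectory for distillation.

    States are node snapshots sampled uniformly over (time, node); pair states
    are sampled over (time, linked node pair) so the pair library is probed on
    the jointly observed region.  Without a topology, pairs combine random
    node states.
    """
    values = series.values
    T, n, d = values.shape
    flat = values.reshape(T * n, d)
    idx = rng.choice(T * n, size=min(n_samples, T * n), replace=False)
    states = flat[idx]
    if topo is not None:
        recv, send, _ = topo.edges()
        t_idx = rng.integers(T, size=n_pair_samples)
        e_idx = rng.integers(recv.size, size=n_pair_samples)
        pair = np.concatenate([values[t_idx, recv[e_idx]],
                               values[t_idx, send[e_idx]]], axis=1)
    else:
        t_idx = rng.integers(T * n, size=n_pair_samples)
        s_idx = rng.integers(T * n, size=n_pair_samples)
        pair = np.concatenate([flat[t_idx], flat[s_idx]], axis=1)
    return states, pair


def reconstruct_force_field(sde: SymbolicSDE, grid: np.ndarray,
                            topo: NetworkTopology | None = None,
                            neighbor_state: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the symbolic drift on a grid of states.

    The interaction contribution is aggregated over the topology with every
    sending node held at `neighbor_state` (default: the grid point itself),
    giving a representative-field view suitable for quiver comparisons.
    """
    grid = np.asarray(grid, dtype=float)
    out = sde.evaluate_self(grid)
    if topo is not None and sde.interaction_terms:
        in_weight = {lt: np.mean(np.sum(np.where(
            (topo.link_types == lt) if lt is not None else (topo.A != 0),
            topo.A, 0.0), axis=1)) for lt in sde.interaction_terms}
        for lt, _ in sde.interaction_terms.items():
            xj = grid if neighbor_state is None else np.broadcast_to(
                neighbor_state, grid.shape)
            out = out + in_weight[lt] * sde.evaluate_interaction(grid, xj, lt)
    return out
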