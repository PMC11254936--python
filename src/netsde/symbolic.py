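"""Explicit symbolic SDEs: named elementary terms with per-dimension coefficients.

A SymbolicSDE is the output of stage-2 distillation: for each part (self
drift, one interaction map per link type, diffusion amplitude) it stores a map
term-name -> coefficient vector of length d (one coefficient per output
component, matching the Kronecker-lifted regression).  Term names use the
library grammar (xi1.., xj1.., r) and are canonicalized so identical
expressions unify across equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .library import canonical_name, make_term


@dataclass
class SymbolicSDE:
    d: int
    dt: float | None = None
    self_terms: dict = field(default_factory=dict)
    interaction_terms: dict = field(default_factory=dict)  # link type -> {term: vec}
    diffusion_terms: dict = field(default_factory=dict)
    n_min: dict = field(default_factory=dict)      # part -> minimal term count
    fit_kappa2: dict = field(default_factory=dict)  # (part, dim) diagnostics

    def canonicalized(self) -> "SymbolicSDE":
        """Return a copy with sympy-canonical term names and zero rows dropped."""
        def canon(terms: dict, pair: bool) -> dict:
            out: dict = {}
            for name, vec in terms.items():
                vec = np.atleast_1d(np.asarray(vec, dtype=float))
                if np.all(vec == 0.0):
                    continue
                key = canonical_name(name, self.d, pair)
                out[key] = out.get(key, 0.0) + vec
            return out

        sde = SymbolicSDE(d=self.d, dt=self.dt, n_min=dict(self.n_min),
                          fit_kappa2=dict(self.fit_kappa2))
        sde.self_terms = canon(self.self_terms, pair=False)
        sde.interaction_terms = {lt: canon(terms, pair=True)
                                 for lt, terms in self.interaction_terms.items()}
        sde.diffusion_terms = canon(self.diffusion_terms, pair=False)
        return sde

    # -- evaluation ---------------------------------------------------------

    def _eval(self, terms: dict, states: np.ndarray, arity: str) -> np.ndarray:
        states = np.asarray(states, dtype=float)
        out = np.zeros((states.shape[0], self.d))
        for name, vec in terms.items():
            col = make_term(name, self.d, arity).evaluate(states)
            out += col[:, None] * np.atleast_1d(vec)[None, :]
        return out

    def evaluate_self(self, states: np.ndarray) -> np.ndarray:
        """Self drift f(x) on (m, d) states."""
        return self._eval(self.self_terms, states, "self")

    def evaluate_interaction(self, xi: np.ndarray, xj: np.ndarray,
                             link_type: str | None = None) -> np.ndarray:
        """Pairwise drift g(x_i, x_j) on matched (m, d) receiver/sender states."""
        terms = self.interaction_terms.get(link_type, {})
        pair_states = np.column_stack([xi, xj])
        return self._eval(terms, pair_states, "pair")

    def evaluate_diffusion(self, states: np.ndarray) -> np.ndarray:
        """Diffusion amplitude phi(x) on (m, d) states."""
        return self._eval(self.diffusion_terms, states, "self")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def pack(terms):
            return {name: np.atleast_1d(vec).tolist() for name, vec in terms.items()}

        return {
            "schema": "netsde.symbolic_sde.v1",
            "d": self.d,
            "dt": self.dt,
            "self": pack(self.self_terms),
            "interaction": {str(lt): pack(terms)
                            for lt, terms in self.interaction_terms.items()},
            "diffusion": pack(self.diffusion_terms),
            "n_min": self.n_min,
            "fit_kappa2": {f"{p}|{k}": v for (p, k), v in self.fit_kappa2.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SymbolicSDE":
        def unpack(terms):
            return {name: np.asarray(vec, dtype=float) for name, vec in terms.items()}

        sde = cls(d=int(data["d"]), dt=data.get("dt"))
        sde.self_terms = unpack(data.get("self", {}))
        sde.interaction_terms = {
            (None if lt == "None" else lt): unpack(terms)
            for lt, terms in data.get("interaction", {}).items()}
        sde.diffusion_terms = unpack(data.get("diffusion", {}))
        sde.n_min = dict(data.get("n_min", {}))
        sde.fit_kappa2 = {tuple(k.split("|", 1)): v
                          for k, v in data.get("fit_kappa2", {}).items()}
        return sde

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SymbolicSDE":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- reporting ----------------------------------------------------------

    def report(self) -> str:
        """Human-readable equation listing, one line per output component."""
        lines = []

        def fmt(terms, k):
            parts = [f"{np.atleast_1d(vec)[k]:+.6g}*({name})"
                     for name, vec in terms.items()
                     if np.atleast_1d(vec)[k] != 0.0]
            return " ".join(parts) if parts else "0"

        for k in range(self.d):
            rhs = fmt(self.self_terms, k)
            for lt, terms in self.interaction_terms.items():
                tag = f"[{lt}] " if lt is not None else ""
                inter = fmt(terms, k)
                if inter != "0":
                    rhs += f" + sum_j A_ij {tag}( {inter} )"
            lines.append(f"dx{k + 1} = ( {rhs} ) dt + ( {fmt(self.diffusion_terms, k)} ) dW{k + 1}")
        return "\n".join(lines)
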