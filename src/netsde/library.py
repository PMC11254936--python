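"""Elementary-function libraries and their evaluation into design matrices.

Terms are pure scalar-valued functions of a node state (arity ``self`` /
``diffusion``) or of an ordered state pair (arity ``pair``).  The canonical
grammar uses the variables

    xi1 .. xid   components of the receiving node's state
    xj1 .. xjd   components of the sending node's state (pair terms only)
    r            the pairwise Euclidean distance |x_j - x_i|

and any sympy-parsable expression of them, e.g. ``xi1**2``, ``xj1 - xi1``,
``sin(xi2)``, ``1/(1 + exp(-r))``.  Term names are canonicalized through sympy
so that identical expressions unify, and round-trip through the plain-text
manifest format.

Evaluating a library on m sampled states yields the design matrix Theta
(m x terms); the Kronecker lift Theta (x) I_d maps scalar terms onto
d-dimensional outputs with one coefficient per output component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

_FUNCS = {"sin": sp.sin, "cos": sp.cos, "exp": sp.exp, "tanh": sp.tanh,
          "sqrt": sp.sqrt, "Abs": sp.Abs, "log": sp.log}


def _symbols(d: int, pair: bool) -> list[sp.Symbol]:
    syms = [sp.Symbol(f"xi{k + 1}") for k in range(d)]
    if pair:
        syms += [sp.Symbol(f"xj{k + 1}") for k in range(d)]
        syms.append(sp.Symbol("r"))
    return syms


def canonical_name(expr: str | sp.Expr, d: int, pair: bool) -> str:
    """Canonical string form of a term expression."""
    if isinstance(expr, str):
        local = {s.name: s for s in _symbols(d, pair)}
        local.update(_FUNCS)
        expr = sp.sympify(expr, locals=local)
    return str(sp.expand(expr))


@dataclass(frozen=True)
class Term:
    """A named elementary function of one state or of a state pair."""

    name: str
    arity: str  # "self" or "pair"
    expr: sp.Expr
    d: int

    def evaluate(self, states: np.ndarray) -> np.ndarray:
        """Evaluate on (m, d) self samples or (m, 2d) pair samples."""
        states = np.asarray(states, dtype=float)
        syms = _symbols(self.d, self.arity == "pair")
        args = [states[:, k] for k in range(self.d)]
        if self.arity == "pair":
            if states.shape[1] != 2 * self.d:
                raise ValueError("pair term expects (m, 2d) samples")
            args += [states[:, self.d + k] for k in range(self.d)]
            diff = states[:, self.d:] - states[:, :self.d]
            args.append(np.sqrt(np.sum(diff ** 2, axis=1)))
        elif states.shape[1] != self.d:
            raise ValueError("self term expects (m, d) samples")
        func = sp.lambdify(syms, self.expr, modules="numpy")
        out = np.broadcast_to(np.asarray(func(*args), dtype=float), (states.shape[0],))
        return np.array(out, dtype=float)


def make_term(name: str, d: int, arity: str) -> Term:
    local = {s.name: s for s in _symbols(d, arity == "pair")}
    local.update(_FUNCS)
    expr = sp.sympify(name, locals=local)
    return Term(name=canonical_name(expr, d, arity == "pair"), arity=arity,
                expr=expr, d=d)


@dataclass
class TermLibrary:
    """An ordered collection of uniquely named terms of one arity."""

    arity: str
    d: int
    terms: list[Term] = field(default_factory=list)

    def add(self, name: str) -> None:
        term = make_term(name, self.d, self.arity)
        if term.name not in self.names:
            self.terms.append(term)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class DesignMatrix:
    """Evaluated library: values[k, q] = term q at sample k."""

    values: np.ndarray
    term_names: list[str]
    sample_index: np.ndarray | None = None  # provenance (node, time) per row

    def lifted(self, d: int) -> np.ndarray:
        """Kronecker lift Theta (x) I_d for d-dimensional targets.

        Row k*d + l of the lift pairs sample k's output component l with the
        coefficient slot (q, l) of term q, so a single scalar term carries one
        coefficient per output component.
        """
        return np.kron(self.values, np.eye(d))


def evaluate(lib: TermLibrary, states: np.ndarray, strict: bool = True) -> DesignMatrix:
    """Evaluate every term of `lib` on the sample states.

    strict=True raises on any non-finite term value (domain violation);
    strict=False masks the offending rows out of the returned matrix.
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    states = np.asarray(states, dtype=float)
    if not np.all(np.isfinite(states)):
        raise ValueError("non-finite sample states")
    cols = [t.evaluate(states) for t in lib.terms]
    values = np.column_stack(cols)
    if not np.all(np.isfinite(values)):
        if strict:
            bad = [lib.names[q] for q in np.nonzero(~np.isfinite(values).all(axis=0))[0]]
            raise FloatingPointError(f"terms {bad} undefined on the given samples")
        keep = np.isfinite(values).all(axis=1)
        values = values[keep]
    return DesignMatrix(values=values, term_names=lib.names)


# ---------------------------------------------------------------------------
# default library composition
# ---------------------------------------------------------------------------

def _monomials(var_names: list[str], max_degree: int) -> list[str]:
    out = ["1"]
    for deg in range(1, max_degree + 1):
        for combo in itertools.combinations_with_replacement(var_names, deg):
            out.append("*".join(combo))
    return out


def default_libraries(
    d: int,
    poly_self: int = 3,
    poly_pair: int = 2,
    include_trig: bool = False,
    include_pair_gates: bool = True,
    include_differences: bool = True,
    flocking: bool = False,
    max_degree_cap: int = 5,
) -> tuple[TermLibrary, TermLibrary, TermLibrary]:
    """Construct the default (L_F, L_G, L_Phi) libraries for d-dimensional nodes.

    L_F:   monomials of total degree <= poly_self in xi; optionally sin/cos of
           each component (off by default: on O(1) data ranges sin(x) and cos(x)
           are nearly indistinguishable from low-degree polynomials at any
           realistic training accuracy, which makes support identification
           ill-posed; enable for genuinely trigonometric dynamics).
    L_G:   monomials of total degree <= poly_pair in (xi, xj), pairwise
           differences xj_k - xi_k, sigmoidal gates of the sending components
           (the canonical synaptic form, alone and multiplied by the matching
           receiving component), and distance kernels exp(-r), 1/(1+exp(-r)).
    L_Phi: constant plus monomials of total degree <= 2 in xi.
    """
    if poly_self > max_degree_cap or poly_pair > max_degree_cap:
        raise ValueError(f"polynomial degree above cap {max_degree_cap}")
    xi = [f"xi{k + 1}" for k in range(d)]
    xj = [f"xj{k + 1}" for k in range(d)]

    lf = TermLibrary(arity="self", d=d)
    for name in _monomials(xi, poly_self):
        lf.add(name)
    if include_trig:
        for v in xi:
            lf.add(f"sin({v})")
            lf.add(f"cos({v})")

    lg = TermLibrary(arity="pair", d=d)
    for name in _monomials(xi + xj, poly_pair):
        lg.add(name)
    if include_differences:
        for a, b in zip(xi, xj):
            lg.add(f"{b} - {a}")
    if include_pair_gates:
        for a, b in zip(xi, xj):
            lg.add(f"1/(1 + exp(-10*({b} - 1)))")
            lg.add(f"{a}/(1 + exp(-10*({b} - 1)))")
    if flocking:
        lg.add("exp(-r/3)")
        lg.add("1/(1 + exp(-r))")
        lg.add("r")

    lphi = TermLibrary(arity="self", d=d)
    for name in _monomials(xi, 2):
        lphi.add(name)
    return lf, lg, lphi


# ---------------------------------------------------------------------------
# plain-text manifest: one expression per line under [self]/[pair]/[diffusion]
# ---------------------------------------------------------------------------

_SECTION_ARITY = {"self": "self", "pair": "pair", "diffusion": "self"}


def write_manifest(libs: tuple[TermLibrary, TermLibrary, TermLibrary],
                   path: str, d: int) -> None:
    lf, lg, lphi = libs
    with open(path, "w") as fh:
        fh.write(f"# netsde library manifest v1 (d = {d})\n")
        for section, lib in (("self", lf), ("pair", lg), ("diffusion", lphi)):
            fh.write(f"[{section}]\n")
            for name in lib.names:
                fh.write(name + "\n")


def read_manifest(path: str) -> tuple[TermLibrary, TermLibrary, TermLibrary]:
    d = None
    sections: dict[str, list[str]] = {"self": [], "pair": [], "diffusion": []}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "d =" in line:
                    d = int(line.split("d =")[1].strip(" )"))
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in sections:
                    raise ValueError(f"unknown manifest section [{current}]")
                continue
            if current is None:
                raise ValueError("term listed before any section header")
            sections[current].append(line)
    if d is None:
        raise ValueError("manifest missing dimension header")
    out = []
    for section in ("self", "pair", "diffusion"):
        lib = TermLibrary(arity=_SECTION_ARITY[section], d=d)
        for name in sections[section]:
            lib.add(name)
        out.append(lib)
    return tuple(out)


def drop_duplicate_columns(design: DesignMatrix, tol: float = 1e-10
                           ) -> tuple[DesignMatrix, list[str]]:
    """Drop columns whose pairwise correlation exceeds 1 - tol (keep the first)."""
    X = design.values
    keep: list[int] = []
    dropped: list[str] = []
    for q in range(X.shape[1]):
        col = X[:, q]
        duplicate = False
        for kq in keep:
            a, b = col, X[:, kq]
            sa, sb = a.std(), b.std()
            if sa == 0.0 and sb == 0.0:
                duplicate = True
                break
            if sa == 0.0 or sb == 0.0:
                continue
            c = abs(np.corrcoef(a, b)[0, 1])
            if c > 1.0 - tol:
                duplicate = True
                break
        if duplicate:
            dropped.append(design.term_names[q])
        else:
            keep.append(q)
    out = DesignMatrix(values=X[:, keep],
                       term_names=[design.term_names[q] for q in keep],
                       sample_index=design.sample_index)
    return out, dropped
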