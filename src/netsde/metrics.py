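"""Goodness-of-fit and equation-discrepancy metrics.

kappa2 scores a regression against the mean predictor (1 = perfect, 0 = mean,
negative = worse than the mean).  sMAPE compares two symbolic equations term by
term over the union of their term sets; a term present in only one equation
contributes exactly 1/k, so false positives and false negatives are penalized
symmetrically.  sMAPE always lies in [0, 1] and is 0 iff the equations agree.
"""

from __future__ import annotations

import numpy as np


def kappa2(y_hat: np.ndarray, y: np.ndarray) -> float:
    """kappa^2 = 1 - sum((y_hat - y)^2) / sum((y - mean(y))^2).

    Raises ValueError for a constant target (the score is undefined there).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("kappa^2 undefined for a constant target")
    return 1.0 - float(np.sum((y_hat - y) ** 2)) / tss


def _coefficient_entries(sde) -> dict[tuple, float]:
    """Flatten a SymbolicSDE into {(part, link_type, term, dim): coefficient}."""
    entries: dict[tuple, float] = {}
    for term, vec in sde.self_terms.items():
        for k, c in enumerate(np.atleast_1d(vec)):
            if c != 0.0:
                entries[("self", None, term, k)] = float(c)
    for lt, terms in sde.interaction_terms.items():
        for term, vec in terms.items():
            for k, c in enumerate(np.atleast_1d(vec)):
                if c != 0.0:
                    entries[("interaction", lt, term, k)] = float(c)
    for term, vec in sde.diffusion_terms.items():
        for k, c in enumerate(np.atleast_1d(vec)):
            if c != 0.0:
                entries[("diffusion", None, term, k)] = float(c)
    return entries


def smape(inferred, reference) -> float:
    """Symmetric mean absolute percentage error between two symbolic SDEs.

    The term set is the union of (part, link type, term name, output dimension)
    slots carrying a nonzero coefficient in either equation; a slot missing from
    one side enters with coefficient 0 and contributes |c|/|c| = 1 to the sum.
    """
    ic = _coefficient_entries(inferred)
    rc = _coefficient_entries(reference)
    keys = sorted(set(ic) | set(rc), key=repr)
    if not keys:
        raise ValueError("both equations are empty")
    total = 0.0
    for key in keys:
        i = ic.get(key, 0.0)
        r = rc.get(key, 0.0)
        total += abs(i - r) / (abs(i) + abs(r))
    return total / len(keys)
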