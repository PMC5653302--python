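"""Polynomial term algebra shared by the survey generator and the
predictive richness model.

A *term* is a product of integer powers of named variables, written
``"pH^4"``, ``"clay^2*CN_ratio"`` or ``"1"`` for the intercept.  A model is
a mapping term -> coefficient; evaluation is exact term-wise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["parse_term", "term_to_string", "evaluate_term", "evaluate_terms"]


def parse_term(term: str) -> tuple[tuple[str, int], ...]:
    """Parse ``"clay^2*CN_ratio"`` into ``(("clay", 2), ("CN_ratio", 1))``.

    ``"1"`` (or ``"intercept"``) parses to the empty product ``()``.
    """
    term = term.strip()
    if term in ("1", "intercept", ""):
        return ()
    factors = []
    for piece in term.split("*"):
        piece = piece.strip()
        if "^" in piece:
            var, pow_ = piece.split("^")
            power = int(pow_)
        else:
            var, power = piece, 1
        if not var or power < 1:
            raise ValueError(f"malformed term factor {piece!r}")
        factors.append((var.strip(), power))
    # canonical order: by variable name, merging repeated factors
    merged: dict[str, int] = {}
    for var, power in factors:
        merged[var] = merged.get(var, 0) + power
    return tuple(sorted(merged.items()))


def term_to_string(factors: tuple[tuple[str, int], ...]) -> str:
    if not factors:
        return "1"
    return "*".join(v if p == 1 else f"{v}^{p}" for v, p in factors)


def evaluate_term(term, data) -> np.ndarray:
    """Evaluate one term on a DataFrame (or mapping of column arrays)."""
    factors = parse_term(term) if isinstance(term, str) else tuple(term)
    n = len(next(iter(data.values()))) if isinstance(data, dict) else len(data)
    out = np.ones(n, dtype=float)
    for var, power in factors:
        if var not in data:
            raise KeyError(f"term variable {var!r} missing from data")
        col = np.asarray(data[var], dtype=float)
        out = out * col**power
    if not np.all(np.isfinite(out)):
        raise ValueError(f"non-finite evaluation of term {term!r}")
    return out


def evaluate_terms(coefficients: dict, data) -> np.ndarray:
    """Evaluate ``sum_k coef_k * term_k(data)`` exactly, term by term."""
    n = len(next(iter(data.values()))) if isinstance(data, dict) else len(data)
    total = np.zeros(n, dtype=float)
    for term, coef in coefficients.items():
        total += float(coef) * evaluate_term(term, data)
    return total
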