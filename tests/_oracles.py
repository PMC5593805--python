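"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's parsing and fitting code paths:
the formula oracle walks the string character by character with no regex,
and the hyperbola oracle does a plain grid search over the coefficient.
"""

from __future__ import annotations

import numpy as np

from ligeff.masses import ATOMIC_MASSES


def charwalk_counts(formula: str) -> dict[str, int]:
    """Character-by-character formula reader (no regex)."""
    counts: dict[str, int] = {}
    i = 0
    while i < len(formula):
        ch = formula[i]
        assert ch.isupper(), f"expected element start at {i} in {formula!r}"
        symbol = ch
        i += 1
        if i < len(formula) and formula[i].islower():
            symbol += formula[i]
            i += 1
        digits = ""
        while i < len(formula) and formula[i].isdigit():
            digits += formula[i]
            i += 1
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    return counts


def charwalk_mw(formula: str) -> float:
    return sum(n * ATOMIC_MASSES[s] for s, n in charwalk_counts(formula).items())


def grid_search_hyperbola_c(xs, ys, step: float = 1e-4) -> float:
    """Minimize sum((y - c/x)^2) by scanning c on a grid around the data."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    hi = max(1.0, 2.0 * float(np.max(ys * xs)))
    grid = np.arange(0.0, hi + step, step)
    sse = ((ys[None, :] - grid[:, None] / xs[None, :]) ** 2).sum(axis=1)
    return float(grid[np.argmin(sse)])
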