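"""Local-variance fitness.

The fitness of an agent is the population variance of a five-element
window of the position vector centred on the agent; windows at the edges
are shifted inward so they always hold five valid positions.  Variance of
a window measures how spread-out an agent's neighbourhood is, which is
the quantity the feature transform maximizes.
"""

from __future__ import annotations

import numpy as np

WINDOW = 5

__all__ = ["variance_fitness", "population_fitness", "WINDOW"]


def _window_start(index: int, n: int) -> int:
    return min(max(index - WINDOW // 2, 0), n - WINDOW)


def variance_fitness(positions, index: int) -> float:
    """Population variance (divide by 5) of the 5-window centred at ``index``."""
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n < WINDOW:
        raise ValueError(f"need at least {WINDOW} positions, got {n}")
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range for {n} positions")
    s = _window_start(index, n)
    w = x[s : s + WINDOW]
    return float(np.var(w))


def population_fitness(positions) -> np.ndarray:
    """Vector of variance fitness values, one per agent."""
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n < WINDOW:
        raise ValueError(f"need at least {WINDOW} positions, got {n}")
    # sliding 5-windows over the clamped start positions
    starts = np.clip(np.arange(n) - WINDOW // 2, 0, n - WINDOW)
    windows = x[starts[:, None] + np.arange(WINDOW)]
    return windows.var(axis=1)
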