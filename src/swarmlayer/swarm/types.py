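"""Domain records shared by the swarm optimizers.

One optimizer run operates on a single sample's feature vector: each agent
(gorilla / particle / elephant) is one scalar feature, and the population
size equals the feature dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScalarBounds",
    "SwarmState",
    "MGTOParams",
    "StepCoefficients",
    "PSOParams",
    "PSOState",
    "EHOParams",
]


@dataclass(frozen=True)
class ScalarBounds:
    """Closed interval [lower, upper] that confines agent positions."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(f"lower bound {self.lower} exceeds upper {self.upper}")

    @classmethod
    def of(cls, values: np.ndarray) -> "ScalarBounds":
        """Bounds spanned by a feature vector: [min(values), max(values)]."""
        return cls(float(np.min(values)), float(np.max(values)))


@dataclass
class SwarmState:
    """Positions, fitness and leader of one scalar population."""

    positions: np.ndarray
    fitness: np.ndarray
    silverback_index: int
    iteration: int
    bounds: ScalarBounds

    @property
    def n_agents(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MGTOParams:
    """Tunable constants of GTO and MGTO.

    ``p`` gates the jump-to-random-position exploration branch, ``beta``
    scales the competition step, ``const`` is the initial sine-cosine
    radius (3 by convention) and is unused by plain GTO.  ``g_mode`` and
    ``l_mode`` select between the original-GTO conventions (``pow2`` /
    ``continuous``) and literal alternates (``linear`` / ``integer``).
    """

    p: float = 0.3
    beta: float = 0.7
    max_iter: int = 11
    const: float = 3.0
    g_mode: str = "pow2"
    l_mode: str = "continuous"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.const <= 0:
            raise ValueError("const must be positive")
        if self.g_mode not in ("pow2", "linear"):
            raise ValueError("g_mode must be 'pow2' or 'linear'")
        if self.l_mode not in ("continuous", "integer"):
            raise ValueError("l_mode must be 'continuous' or 'integer'")


@dataclass
class StepCoefficients:
    """Per-iteration coefficients of a GTO/MGTO step.

    Drawn once per iteration (draw order: r4, l, Z, r5, rand, N1/N2).
    ``H`` is normally the per-agent vector Z*X(t); a scalar may be pinned
    for hand-worked checks, as may ``M`` (otherwise recomputed from the
    population mean).
    """

    C: float
    F: float
    L: float
    l: float
    Z: float
    g: float
    Q: float
    A: float
    E: float
    rad: float
    H: Optional[float] = None
    M: Optional[float] = None


@dataclass(frozen=True)
class PSOParams:
    """Inertia ``w`` and acceleration constants ``c1`` (cognitive) and
    ``c2`` (social) of particle swarm optimization."""

    w: float = 0.6
    c1: float = 0.7
    c2: float = 0.9
    max_iter: int = 10

    def __post_init__(self) -> None:
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")


@dataclass
class PSOState:
    """Positions, velocities and best-so-far memory of a particle swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: np.ndarray
    global_best: float
    iteration: int
    bounds: ScalarBounds

    @property
    def n_agents(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EHOParams:
    """Clan-attraction ``alpha`` and centre-scaling ``beta_e`` of elephant
    herding optimization (single clan)."""

    alpha: float = 0.9
    beta_e: float = 0.8
    max_iter: int = 12

    def __post_init__(self) -> None:
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
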