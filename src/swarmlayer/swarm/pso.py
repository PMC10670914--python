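"""Particle swarm optimization over one scalar population.

Each particle keeps a velocity and a personal best; the global best is
the best personal best.  The layer maximizes the local-variance fitness,
so personal bests are replaced on a strict fitness increase.
"""

from __future__ import annotations

import numpy as np

from ..rng import RandomStream
from .fitness import population_fitness
from .gto import clip_positions, select_silverback
from .types import PSOParams, PSOState, ScalarBounds

__all__ = ["init_pso_state", "pso_step"]


def init_pso_state(features: np.ndarray, bounds: ScalarBounds) -> PSOState:
    """Particles start at the feature values with zero velocity."""
    x = np.asarray(features, dtype=float).copy()
    f = population_fitness(x)
    best = select_silverback(f)
    return PSOState(
        positions=x,
        velocities=np.zeros_like(x),
        personal_best=x.copy(),
        personal_best_fitness=f,
        global_best=float(x[best]),
        iteration=0,
        bounds=bounds,
    )


def pso_step(
    state: PSOState, params: PSOParams, fitness_fn, rng: RandomStream
) -> PSOState:
    """One velocity/position update with per-particle draws r1 then r2.

    ``fitness_fn`` maps a position vector to a fitness vector (the
    local-variance fitness of the whole population).
    """
    x, v = state.positions, state.velocities
    n = len(x)
    new_v = np.empty_like(v)
    for i in range(n):
        r1 = rng.uniform()
        r2 = rng.uniform()
        new_v[i] = (
            params.w * v[i]
            + params.c1 * r1 * (state.personal_best[i] - x[i])
            + params.c2 * r2 * (state.global_best - x[i])
        )
    new_x = clip_positions(x + new_v, state.bounds)
    f = np.asarray(fitness_fn(new_x), dtype=float)
    improved = f > state.personal_best_fitness
    pbest = np.where(improved, new_x, state.personal_best)
    pbest_f = np.where(improved, f, state.personal_best_fitness)
    gbest = float(pbest[select_silverback(pbest_f)])
    return PSOState(
        positions=new_x,
        velocities=new_v,
        personal_best=pbest,
        personal_best_fitness=pbest_f,
        global_best=gbest,
        iteration=state.iteration + 1,
        bounds=state.bounds,
    )
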