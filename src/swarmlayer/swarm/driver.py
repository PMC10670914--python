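"""Generic iteration loop that turns a swarm optimizer into a feature
transform.

One run transforms one sample: the population is initialized at the
sample's feature values, the bounds are the sample's own [min, max], and
after ``max_iter`` iterations the final agent positions are the
transformed features.  Output length and order match the input, and every
output value stays inside the input's range.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from ..rng import RandomStream
from .eho import eho_step
from .fitness import WINDOW, population_fitness
from .gto import (
    compute_coefficients,
    gto_update_competition,
    gto_update_exploration,
    gto_update_silverback,
    mgto_update_competition,
    mgto_update_exploration,
    mgto_update_silverback,
    select_silverback,
)
from .pso import init_pso_state, pso_step
from .types import EHOParams, MGTOParams, PSOParams, ScalarBounds, SwarmState

ALGORITHMS = ("gto", "mgto", "pso", "eho")

AlgoParams = Union[MGTOParams, PSOParams, EHOParams]

__all__ = ["run_swarm_transform", "ALGORITHMS", "AlgoParams"]

_UPDATES = {
    "gto": (gto_update_exploration, gto_update_silverback, gto_update_competition),
    "mgto": (mgto_update_exploration, mgto_update_silverback, mgto_update_competition),
}


def _run_troop(features: np.ndarray, algorithm: str, params: MGTOParams,
               rng: RandomStream) -> np.ndarray:
    explore, follow, compete = _UPDATES[algorithm]
    bounds = ScalarBounds.of(features)
    state = SwarmState(
        positions=features.copy(),
        fitness=population_fitness(features),
        silverback_index=select_silverback(population_fitness(features)),
        iteration=0,
        bounds=bounds,
    )
    for t in range(params.max_iter):
        state.iteration = t
        coeffs = compute_coefficients(state, params, rng)
        state.fitness = population_fitness(state.positions)
        state.positions = explore(state, params, coeffs, rng)
        state.fitness = population_fitness(state.positions)
        state.silverback_index = select_silverback(state.fitness)
        if abs(coeffs.C) >= 1.0:
            state.positions = follow(state, coeffs)
        else:
            state.positions = compete(state, params, coeffs, rng)
        state.fitness = population_fitness(state.positions)
        state.silverback_index = select_silverback(state.fitness)
    return state.positions


def run_swarm_transform(
    features, algorithm: str, params: AlgoParams, rng: RandomStream
) -> np.ndarray:
    """Transform one feature vector with the chosen swarm optimizer.

    Parameters
    ----------
    features
        Vector of at least 5 reals; one agent per feature.
    algorithm
        One of ``"gto"``, ``"mgto"``, ``"pso"``, ``"eho"``.
    params
        Parameter record matching the algorithm.
    rng
        Draw stream; identical seeds give bitwise-identical outputs.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 1:
        raise ValueError("features must be one-dimensional")
    if len(x) < WINDOW:
        raise ValueError(f"need at least {WINDOW} features, got {len(x)}")
    algorithm = algorithm.lower()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")

    if algorithm in ("gto", "mgto"):
        if not isinstance(params, MGTOParams):
            raise TypeError("gto/mgto require MGTOParams")
        if params.max_iter == 0:
            return x.copy()
        return _run_troop(x, algorithm, params, rng)

    bounds = ScalarBounds.of(x)
    if algorithm == "pso":
        if not isinstance(params, PSOParams):
            raise TypeError("pso requires PSOParams")
        pstate = init_pso_state(x, bounds)
        for _ in range(params.max_iter):
            pstate = pso_step(pstate, params, population_fitness, rng)
        return pstate.positions

    if not isinstance(params, EHOParams):
        raise TypeError("eho requires EHOParams")
    f = population_fitness(x)
    estate = SwarmState(
        positions=x.copy(),
        fitness=f,
        silverback_index=select_silverback(f),
        iteration=0,
        bounds=bounds,
    )
    for _ in range(params.max_iter):
        estate = eho_step(estate, params, population_fitness, rng)
    return estate.positions
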