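"""Elephant herding optimization, single-clan form.

Every elephant moves toward a scaled clan centre; the worst elephant is
then resampled near the lower boundary, which keeps the herd exploring.
"""

from __future__ import annotations

import numpy as np

from ..rng import RandomStream
from .gto import clip_positions
from .types import EHOParams, SwarmState

__all__ = ["eho_step"]


def eho_step(
    state: SwarmState, params: EHOParams, fitness_fn, rng: RandomStream
) -> SwarmState:
    """One clan update: move all agents toward beta*centre with their own
    ``ran`` draw, then replace the lowest-fitness agent by
    xmin + (xmax - xmin + 1)*rand; positions are clipped afterwards."""
    x = state.positions
    xmin, xmax = state.bounds.lower, state.bounds.upper
    xcenter = float(np.mean(x))
    xbest = params.beta_e * xcenter
    out = np.empty_like(x)
    for i in range(len(x)):
        ran = rng.uniform()
        out[i] = x[i] + params.alpha * (xbest - x[i]) * ran
    f = np.asarray(fitness_fn(out), dtype=float)
    worst = int(np.argmin(f))
    rand = rng.uniform()
    out[worst] = xmin + (xmax - xmin + 1.0) * rand
    out = clip_positions(out, state.bounds)
    f = np.asarray(fitness_fn(out), dtype=float)
    return SwarmState(
        positions=out,
        fitness=f,
        silverback_index=int(np.argmax(f)),
        iteration=state.iteration + 1,
        bounds=state.bounds,
    )
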