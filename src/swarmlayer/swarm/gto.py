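"""Position-update mathematics of the Gorilla Troops Optimizer (GTO) and
its sine-cosine modification (MGTO).

Both algorithms move a population of scalar agents inside fixed bounds.
One iteration has three phases: an exploration update applied to every
agent, selection of the silverback (the best-fitness agent), and either a
silverback-follow step (when |C| >= 1) or a competition step (otherwise).
MGTO replaces the three position updates with sine/cosine forms whose
amplitude ``rad`` decays linearly from ``const`` to zero over the run.

Per-iteration coefficients are drawn once (order: r4, l, Z, r5, rand,
N1/N2); during an agent update the stream supplies, in equation order,
the branch selector ``rand``, the branch randoms r1/r2/r3 and the index
of the randomly chosen partner Xr.
"""

from __future__ import annotations

import math

import numpy as np

from ..rng import RandomStream
from .types import MGTOParams, ScalarBounds, StepCoefficients, SwarmState

__all__ = [
    "compute_rad",
    "compute_coefficients",
    "select_silverback",
    "clip_positions",
    "compute_m",
    "gto_update_exploration",
    "gto_update_silverback",
    "gto_update_competition",
    "mgto_update_exploration",
    "mgto_update_silverback",
    "mgto_update_competition",
]


def compute_rad(crnt_iter: int, max_iter: int, const: float) -> float:
    """Linearly decaying sine-cosine radius: const at iteration 0, zero at
    the final iteration."""
    if max_iter == 0:
        raise ZeroDivisionError("max_iter must be at least 1")
    return const - crnt_iter * (const / max_iter)


def compute_coefficients(
    state: SwarmState, params: MGTOParams, rng: RandomStream
) -> StepCoefficients:
    """Draw one iteration's shared coefficients.

    F = cos(2 r4) + 1;  C = F (1 - t/max_iter);  L = C l;  Z ~ U[-C, C];
    g = 2**L (or 2L);  rad decays linearly;  Q = 2 r5 - 1;  E is either
    uniform on the position bounds or a [0,1]-truncated standard normal,
    selected by a fair coin;  A = beta * E.
    """
    t, maxit = state.iteration, params.max_iter
    r4 = rng.uniform()
    F = math.cos(2.0 * r4) + 1.0
    C = F * (1.0 - t / maxit)
    if params.l_mode == "integer":
        l = float(rng.integer(3) - 1)  # {-1, 0, 1}
    else:
        l = rng.signed_unit()
    L = C * l
    Z = rng.symmetric(C)
    g = 2.0**L if params.g_mode == "pow2" else 2.0 * L
    rad = compute_rad(t, maxit, params.const)
    r5 = rng.uniform()
    Q = 2.0 * r5 - 1.0
    rand = rng.uniform()
    if rand >= 0.5:
        E = rng.uniform_range(state.bounds.lower, state.bounds.upper)
    else:
        E = rng.normal_trunc01()
    A = params.beta * E
    return StepCoefficients(C=C, F=F, L=L, l=l, Z=Z, g=g, Q=Q, A=A, E=E, rad=rad)


def select_silverback(fitness) -> int:
    """Index of the maximum fitness; ties go to the lowest index."""
    f = np.asarray(fitness, dtype=float)
    if f.size == 0:
        raise ValueError("fitness vector is empty")
    if not np.all(np.isfinite(f)):
        raise ValueError("fitness contains non-finite values")
    return int(np.argmax(f))


def clip_positions(positions, bounds: ScalarBounds) -> np.ndarray:
    """Element-wise clamp into [lower, upper]."""
    return np.clip(np.asarray(positions, dtype=float), bounds.lower, bounds.upper)


def compute_m(positions, g: float) -> float:
    """Silverback-follow magnitude M = (|mean(X)|**g)**(1/g).

    Defined as 0 when the population mean is exactly zero (the power chain
    is otherwise singular for non-integer exponents).
    """
    mean = float(np.mean(positions))
    if mean == 0.0:
        return 0.0
    return (abs(mean) ** g) ** (1.0 / g)


def _agent_h(coeffs: StepCoefficients, x: float) -> float:
    return coeffs.H if coeffs.H is not None else coeffs.Z * x


def gto_update_exploration(
    state: SwarmState,
    params: MGTOParams,
    coeffs: StepCoefficients,
    rng: RandomStream,
) -> np.ndarray:
    """GTO exploration: jump to a random point (prob. p), move toward a
    random partner, or take a partner-difference step."""
    x = state.positions
    lo, hi = state.bounds.lower, state.bounds.upper
    C, L = coeffs.C, coeffs.L
    out = np.empty_like(x)
    for i in range(len(x)):
        rand = rng.uniform()
        if rand < params.p:
            r1 = rng.uniform()
            out[i] = (hi - lo) * r1 + lo
        elif rand >= 0.5:
            r2 = rng.uniform()
            xr = x[rng.integer(len(x))]
            out[i] = (r2 - C) * xr + L * _agent_h(coeffs, x[i])
        else:
            xr = x[rng.integer(len(x))]
            r3 = rng.uniform()
            d = x[i] - xr
            out[i] = x[i] - L * (L * d + r3 * d)
    return clip_positions(out, state.bounds)


def gto_update_silverback(state: SwarmState, coeffs: StepCoefficients) -> np.ndarray:
    """Follow-the-silverback step: X + L*M*(X - Xsb)."""
    x = state.positions
    xsb = x[state.silverback_index]
    M = coeffs.M if coeffs.M is not None else compute_m(x, coeffs.g)
    out = coeffs.L * M * (x - xsb) + x
    return clip_positions(out, state.bounds)


def gto_update_competition(
    state: SwarmState,
    params: MGTOParams,
    coeffs: StepCoefficients,
    rng: RandomStream,
) -> np.ndarray:
    """Competition-for-females step: Xsb - (Xsb*Q - X*Q)*A."""
    x = state.positions
    xsb = x[state.silverback_index]
    out = xsb - (xsb * coeffs.Q - x * coeffs.Q) * coeffs.A
    return clip_positions(out, state.bounds)


def mgto_update_exploration(
    state: SwarmState,
    params: MGTOParams,
    coeffs: StepCoefficients,
    rng: RandomStream,
) -> np.ndarray:
    """MGTO exploration: branches 1-2 as in GTO; branch 3 replaces the
    partner-difference step with a sine-cosine move of amplitude rad."""
    x = state.positions
    lo, hi = state.bounds.lower, state.bounds.upper
    C, L, rad = coeffs.C, coeffs.L, coeffs.rad
    out = np.empty_like(x)
    for i in range(len(x)):
        rand = rng.uniform()
        if rand < params.p:
            r1 = rng.uniform()
            out[i] = (hi - lo) * r1 + lo
        elif rand >= 0.5:
            r2 = rng.uniform()
            xr = x[rng.integer(len(x))]
            out[i] = (r2 - C) * xr + L * _agent_h(coeffs, x[i])
        else:
            xr = x[rng.integer(len(x))]
            d = x[i] - xr
            out[i] = x[i] - L * rad * math.sin(d) + rad * math.cos(d)
    return clip_positions(out, state.bounds)


def mgto_update_silverback(state: SwarmState, coeffs: StepCoefficients) -> np.ndarray:
    """Sine-form follow step: L*M*rad*sin(X - Xsb) + X."""
    x = state.positions
    xsb = x[state.silverback_index]
    M = coeffs.M if coeffs.M is not None else compute_m(x, coeffs.g)
    out = coeffs.L * M * coeffs.rad * np.sin(x - xsb) + x
    return clip_positions(out, state.bounds)


def mgto_update_competition(
    state: SwarmState,
    params: MGTOParams,
    coeffs: StepCoefficients,
    rng: RandomStream,
) -> np.ndarray:
    """Cosine-form competition step: Xsb - rad*cos(Xsb*Q - X*Q)*A."""
    x = state.positions
    xsb = x[state.silverback_index]
    out = xsb - coeffs.rad * np.cos(xsb * coeffs.Q - x * coeffs.Q) * coeffs.A
    return clip_positions(out, state.bounds)
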