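"""Independent transcriptions of the update equations, used as oracles.

Each function re-derives an update with plain scalar arithmetic, drawing
from the supplied stream in the same order as the implementation's
contract (branch selector first, then the branch randoms and the partner
index in equation order).  They share no code with the package's update
functions.
"""

import math

import numpy as np


def naive_variance_window(positions, index):
    """Two-pass population variance of the shifted 5-window."""
    xs = list(positions)
    n = len(xs)
    start = index - 2
    start = max(start, 0)
    start = min(start, n - 5)
    w = xs[start : start + 5]
    mean = sum(w) / 5.0
    return sum((v - mean) ** 2 for v in w) / 5.0


def clip(v, lo, hi):
    return min(max(v, lo), hi)


def gto_exploration(x, p, C, L, H, Z, lo, hi, rng):
    out = []
    for i, xi in enumerate(x):
        rand = rng.uniform()
        if rand < p:
            r1 = rng.uniform()
            new = (hi - lo) * r1 + lo
        elif rand >= 0.5:
            r2 = rng.uniform()
            xr = x[rng.integer(len(x))]
            h = H if H is not None else Z * xi
            new = (r2 - C) * xr + L * h
        else:
            xr = x[rng.integer(len(x))]
            r3 = rng.uniform()
            new = xi - L * (L * (xi - xr) + r3 * (xi - xr))
        out.append(clip(new, lo, hi))
    return np.array(out)


def mgto_exploration(x, p, C, L, H, Z, rad, lo, hi, rng):
    out = []
    for i, xi in enumerate(x):
        rand = rng.uniform()
        if rand < p:
            r1 = rng.uniform()
            new = (hi - lo) * r1 + lo
        elif rand >= 0.5:
            r2 = rng.uniform()
            xr = x[rng.integer(len(x))]
            h = H if H is not None else Z * xi
            new = (r2 - C) * xr + L * h
        else:
            xr = x[rng.integer(len(x))]
            new = xi - L * rad * math.sin(xi - xr) + rad * math.cos(xi - xr)
        out.append(clip(new, lo, hi))
    return np.array(out)


def m_value(x, g):
    mean = sum(x) / len(x)
    if mean == 0.0:
        return 0.0
    return (abs(mean) ** g) ** (1.0 / g)


def gto_silverback(x, sb, L, M, lo, hi):
    xsb = x[sb]
    return np.array([clip(L * M * (xi - xsb) + xi, lo, hi) for xi in x])


def mgto_silverback(x, sb, L, M, rad, lo, hi):
    xsb = x[sb]
    return np.array(
        [clip(L * M * rad * math.sin(xi - xsb) + xi, lo, hi) for xi in x]
    )


def gto_competition(x, sb, Q, A, lo, hi):
    xsb = x[sb]
    return np.array([clip(xsb - (xsb * Q - xi * Q) * A, lo, hi) for xi in x])


def mgto_competition(x, sb, Q, A, rad, lo, hi):
    xsb = x[sb]
    return np.array(
        [clip(xsb - rad * math.cos(xsb * Q - xi * Q) * A, lo, hi) for xi in x]
    )


def pso_velocity_position(x, v, pbest, gbest, w, c1, c2, lo, hi, rng):
    new_v, new_x = [], []
    for i in range(len(x)):
        r1 = rng.uniform()
        r2 = rng.uniform()
        vi = w * v[i] + c1 * r1 * (pbest[i] - x[i]) + c2 * r2 * (gbest - x[i])
        new_v.append(vi)
        new_x.append(clip(x[i] + vi, lo, hi))
    return np.array(new_v), np.array(new_x)


def eho_move(x, alpha, beta_e, lo, hi, rng):
    """Clan move + worst replacement, with fitness = local variance."""
    xcenter = sum(x) / len(x)
    xbest = beta_e * xcenter
    moved = []
    for xi in x:
        ran = rng.uniform()
        moved.append(xi + alpha * (xbest - xi) * ran)
    fits = [naive_variance_window(moved, i) for i in range(len(moved))]
    worst = fits.index(min(fits))
    rand = rng.uniform()
    moved[worst] = lo + (hi - lo + 1.0) * rand
    return np.array([clip(v, lo, hi) for v in moved])
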