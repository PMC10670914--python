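"""Random-draw streams with a fixed draw-order contract.

Every stochastic operation in the swarm layer pulls its numbers from a
:class:`RandomStream`, and within one update the draws happen in the order
the symbols appear in the governing equation.  This makes a run fully
reproducible from a seed and lets tests replay a hand-picked sequence of
draws through :class:`ScriptedStream`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RandomStream", "ScriptedStream", "sample_stream"]


class RandomStream:
    """Seeded uniform/normal draw source backed by numpy's PCG64.

    Parameters
    ----------
    seed
        An integer, or a sequence of integers (entropy tuple).  Two streams
        built from equal seeds produce identical draw sequences.
    """

    def __init__(self, seed) -> None:
        self._gen = np.random.default_rng(seed)

    def uniform(self) -> float:
        """One draw from U[0, 1)."""
        return float(self._gen.random())

    def uniform_range(self, lower: float, upper: float) -> float:
        """One draw from U[lower, upper]."""
        return float(lower + (upper - lower) * self._gen.random())

    def signed_unit(self) -> float:
        """One draw from the continuous uniform on [-1, 1]."""
        return float(self._gen.random() * 2.0 - 1.0)

    def symmetric(self, c: float) -> float:
        """One draw from U[-|c|, |c|]."""
        c = abs(c)
        return float(self._gen.random() * 2.0 * c - c)

    def integer(self, n: int) -> int:
        """One draw from the discrete uniform on {0, ..., n-1}."""
        return int(self._gen.integers(n))

    def normal_trunc01(self) -> float:
        """Standard normal truncated to [0, 1], by rejection."""
        while True:
            x = float(self._gen.standard_normal())
            if 0.0 <= x <= 1.0:
                return x


class ScriptedStream(RandomStream):
    """Replays a fixed sequence of draw values, for pinned-draw tests.

    Values are consumed in call order regardless of the draw kind, so a
    transcription of an equation that makes the same draws in the same
    order sees exactly the same numbers.
    """

    def __init__(self, values) -> None:  # noqa: D107 - no entropy needed
        self._values = list(values)
        self._cursor = 0

    def _next(self) -> float:
        if self._cursor >= len(self._values):
            raise IndexError("scripted stream exhausted")
        v = self._values[self._cursor]
        self._cursor += 1
        return float(v)

    def uniform(self) -> float:
        return self._next()

    def uniform_range(self, lower: float, upper: float) -> float:
        return self._next()

    def signed_unit(self) -> float:
        return self._next()

    def symmetric(self, c: float) -> float:
        return self._next()

    def integer(self, n: int) -> int:
        return int(self._next())

    def normal_trunc01(self) -> float:
        return self._next()


def sample_stream(global_seed: int, sample_index: int) -> RandomStream:
    """Per-sample stream seeded by ``(global_seed, sample_index)``.

    Transforming a subset of rows therefore reproduces the corresponding
    rows of a full-table transform run under the same global seed.
    """
    return RandomStream([int(global_seed), int(sample_index)])
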