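"""GTO/MGTO coefficient and position-update mathematics.

Pinned-draw hand examples plus equivalence against the independent
equation transcriptions in ``_oracles`` under a shared scripted stream.
"""

import math

import numpy as np
import pytest

from swarmlayer import MGTOParams, RandomStream, ScalarBounds, ScriptedStream
from swarmlayer.swarm import (
    clip_positions,
    compute_coefficients,
    compute_m,
    compute_rad,
    gto_update_competition,
    gto_update_exploration,
    gto_update_silverback,
    mgto_update_competition,
    mgto_update_exploration,
    mgto_update_silverback,
    population_fitness,
    select_silverback,
)
from swarmlayer.swarm.types import StepCoefficients, SwarmState

import _oracles


def make_state(positions, lo=None, hi=None, iteration=0, silverback=None):
    x = np.asarray(positions, dtype=float)
    lo = float(x.min()) if lo is None else lo
    hi = float(x.max()) if hi is None else hi
    f = population_fitness(x) if len(x) >= 5 else np.zeros(len(x))
    return SwarmState(
        positions=x,
        fitness=f,
        silverback_index=select_silverback(f) if silverback is None else silverback,
        iteration=iteration,
        bounds=ScalarBounds(lo, hi),
    )


def coeffs(**kw):
    base = dict(C=0.0, F=0.0, L=0.0, l=0.0, Z=0.0, g=1.0, Q=0.0, A=0.0, E=0.0, rad=0.0)
    base.update(kw)
    return StepCoefficients(**base)


class TestRad:
    @pytest.mark.parametrize(
        "crnt, maxit, const, expected",
        [(0, 11, 3, 3.0), (11, 11, 3, 0.0), (5, 10, 3, 1.5)],
    )
    def test_values(self, crnt, maxit, const, expected):
        assert compute_rad(crnt, maxit, const) == pytest.approx(expected)

    def test_zero_max_iter_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            compute_rad(0, 0, 3)

    def test_linear_decrement(self):
        """rad(k+1) - rad(k) = -const/max_iter exactly."""
        const, maxit = 3.0, 11
        vals = [compute_rad(k, maxit, const) for k in range(maxit + 1)]
        diffs = np.diff(vals)
        np.testing.assert_allclose(diffs, -const / maxit, atol=1e-12)


class TestCoefficients:
    def test_pinned_draws(self):
        """r4=0, l=1 at iteration 0 of 10: F=2, C=2, L=2, g=4."""
        state = make_state(np.arange(5.0), iteration=0)
        # draw order: r4, l, Z, r5, rand(E-selector), E draw
        stream = ScriptedStream([0.0, 1.0, 0.5, 0.75, 0.9, 2.5])
        c = compute_coefficients(state, MGTOParams(max_iter=10), stream)
        assert c.F == pytest.approx(2.0)
        assert c.C == pytest.approx(2.0)
        assert c.L == pytest.approx(2.0)
        assert c.g == pytest.approx(4.0)
        assert c.Q == pytest.approx(0.5)  # 2*0.75 - 1
        assert c.E == pytest.approx(2.5)

    def test_final_iteration_forces_chain_to_zero(self):
        state = make_state(np.arange(5.0), iteration=10)
        c = compute_coefficients(state, MGTOParams(max_iter=10), RandomStream(0))
        assert c.C == 0.0 and c.L == 0.0 and c.Z == 0.0

    def test_midpoint_r5_gives_zero_q(self):
        state = make_state(np.arange(5.0))
        stream = ScriptedStream([0.1, 0.2, 0.0, 0.5, 0.9, 1.0])
        c = compute_coefficients(state, MGTOParams(max_iter=10), stream)
        assert c.Q == 0.0

    def test_invariants_over_random_streams(self):
        """|Z| <= |C|, rad in [0, const], Q in [-1, 1]."""
        params = MGTOParams(max_iter=7)
        for seed in range(50):
            state = make_state(np.arange(5.0), iteration=seed % 8)
            c = compute_coefficients(state, params, RandomStream(seed))
            assert abs(c.Z) <= abs(c.C) + 1e-12
            assert 0.0 <= c.rad <= params.const
            assert -1.0 <= c.Q <= 1.0


class TestSelection:
    @pytest.mark.parametrize(
        "fitness, expected", [([0.4], 0), ([0.1, 0.9, 0.3], 1), ([0.5, 0.5, 0.2], 0)]
    )
    def test_highest_fitness_lowest_index(self, fitness, expected):
        assert select_silverback(fitness) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            select_silverback([])
        with pytest.raises(ValueError):
            select_silverback([0.1, np.nan])


class TestClip:
    def test_cases(self):
        b = ScalarBounds(0, 5)
        np.testing.assert_array_equal(clip_positions([1, 2, 3], b), [1, 2, 3])
        np.testing.assert_array_equal(clip_positions([-1, 6], b), [0, 5])
        degenerate = ScalarBounds(2, 2)
        np.testing.assert_array_equal(clip_positions([2.0, 2.0], degenerate), [2.0, 2.0])


class TestExplorationExamples:
    def test_branch1_collapses_to_lower_bound(self):
        state = make_state([0.5, 0.6, 0.7, 0.8, 0.9], lo=0.0, hi=1.0)
        # per agent: rand(<p), r1=0
        stream = ScriptedStream([0.0, 0.0] * 5)
        out = gto_update_exploration(state, MGTOParams(p=0.4, max_iter=5), coeffs(), stream)
        np.testing.assert_allclose(out, 0.0)

    def test_branch3_fixed_point_when_partner_equals_self(self):
        x = [1.0, 1.0, 1.0, 1.0, 1.0]
        state = make_state(x, lo=0.0, hi=2.0)
        # per agent: rand in [p, 0.5) -> branch 3; partner index; r3
        stream = ScriptedStream([0.45, 0.0, 0.3] * 5)
        out = gto_update_exploration(state, MGTOParams(p=0.1, max_iter=5), coeffs(L=0.7), stream)
        np.testing.assert_allclose(out, x)

    def test_branch2_hand_value(self):
        """(r2 - C)*Xr + L*H with r2=0.6, C=0.1, Xr=2, L=2, H=1 gives 3."""
        state = make_state([2.0, 2.0, 2.0, 2.0, 2.0], lo=-10.0, hi=10.0)
        stream = ScriptedStream([0.6, 0.6, 0] * 5)  # rand>=0.5 -> branch 2; r2; partner
        c = coeffs(C=0.1, L=2.0, H=1.0)
        out = gto_update_exploration(state, MGTOParams(p=0.1, max_iter=5), c, stream)
        np.testing.assert_allclose(out, 3.0)

    def test_mgto_branch1_collapses_to_upper_bound(self):
        state = make_state([0.5, 0.5, 0.5, 0.5, 0.5], lo=0.0, hi=1.0)
        stream = ScriptedStream([0.0, 1.0] * 5)  # rand<p; r1=1
        out = mgto_update_exploration(state, MGTOParams(p=0.4, max_iter=5), coeffs(), stream)
        np.testing.assert_allclose(out, 1.0)

    def test_mgto_branch3_sine_cosine_offset(self):
        """X = Xr makes the sine vanish and adds rad*cos(0) = rad."""
        x = [1.0, 1.0, 1.0, 1.0, 1.0]
        state = make_state(x, lo=0.0, hi=5.0)
        stream = ScriptedStream([0.45, 0] * 5)  # branch 3; partner index
        c = coeffs(L=0.7, rad=1.5)
        out = mgto_update_exploration(state, MGTOParams(p=0.1, max_iter=5), c, stream)
        np.testing.assert_allclose(out, 2.5)

    def test_mgto_branch2_matches_gto_branch2(self):
        state = make_state([2.0] * 5, lo=-10.0, hi=10.0)
        c = coeffs(C=0.1, L=2.0, H=1.0)
        out = mgto_update_exploration(
            state, MGTOParams(p=0.1, max_iter=5), c, ScriptedStream([0.6, 0.6, 0] * 5)
        )
        np.testing.assert_allclose(out, 3.0)


class TestSilverbackExamples:
    def test_agent_at_silverback_is_unchanged(self):
        x = [3.0, 1.0, 2.0, 0.5, 1.5]
        state = make_state(x, lo=-10, hi=10, silverback=0)
        c = coeffs(L=1.0, M=2.0)
        out = gto_update_silverback(state, c)
        assert out[0] == pytest.approx(3.0)

    def test_hand_value(self):
        """L=1, M=2, X=3, Xsb=1 -> 1*2*(3-1) + 3 = 7."""
        x = [3.0, 1.0, 2.0, 0.5, 1.5]
        state = make_state(x, lo=-10, hi=10, silverback=1)
        out = gto_update_silverback(state, coeffs(L=1.0, M=2.0))
        assert out[0] == pytest.approx(7.0)

    def test_zero_l_freezes_population(self):
        x = np.array([3.0, 1.0, 2.0, 0.5, 1.5])
        state = make_state(x, lo=-10, hi=10, silverback=1)
        out = gto_update_silverback(state, coeffs(L=0.0, M=5.0))
        np.testing.assert_allclose(out, x)

    def test_mgto_hand_value(self):
        """L=2, M=1, rad=1.5, X=0, Xsb=-pi/2 -> 3."""
        x = [0.0, -math.pi / 2, 0.0, 0.0, 0.0]
        state = make_state(x, lo=-10, hi=10, silverback=1)
        out = mgto_update_silverback(state, coeffs(L=2.0, M=1.0, rad=1.5))
        assert out[0] == pytest.approx(3.0)

    def test_mgto_zero_rad_freezes_population(self):
        x = np.array([3.0, 1.0, 2.0, 0.5, 1.5])
        state = make_state(x, lo=-10, hi=10, silverback=1)
        out = mgto_update_silverback(state, coeffs(L=2.0, M=1.0, rad=0.0))
        np.testing.assert_allclose(out, x)

    def test_m_zero_mean_convention(self):
        assert compute_m([1.0, -1.0], g=0.37) == 0.0
        assert compute_m([2.0, 4.0], g=2.0) == pytest.approx(3.0)


class TestCompetitionExamples:
    def test_zero_q_moves_everyone_to_silverback(self):
        x = [3.0, 1.0, 2.0, 0.5, 1.5]
        state = make_state(x, lo=-10, hi=10, silverback=0)
        out = gto_update_competition(state, MGTOParams(), coeffs(Q=0.0, A=0.8), None)
        np.testing.assert_allclose(out, 3.0)

    def test_hand_value(self):
        """Xsb=2, X=1, Q=1, A=0.5 -> 2 - (2-1)*0.5 = 1.5."""
        x = [1.0, 2.0, 1.0, 1.0, 1.0]
        state = make_state(x, lo=-10, hi=10, silverback=1)
        out = gto_update_competition(state, MGTOParams(), coeffs(Q=1.0, A=0.5), None)
        assert out[0] == pytest.approx(1.5)

    def test_mgto_zero_rad_collapses_to_silverback(self):
        x = [3.0, 1.0, 2.0, 0.5, 1.5]
        state = make_state(x, lo=-10, hi=10, silverback=0)
        out = mgto_update_competition(state, MGTOParams(), coeffs(Q=0.7, A=0.4, rad=0.0), None)
        np.testing.assert_allclose(out, 3.0)

    def test_mgto_hand_value(self):
        """Q=0, rad=1, A=1, Xsb=5 -> 5 - cos(0) = 4."""
        x = [5.0, 1.0, 2.0, 0.5, 1.5]
        state = make_state(x, lo=-10, hi=10, silverback=0)
        out = mgto_update_competition(state, MGTOParams(), coeffs(Q=0.0, A=1.0, rad=1.0), None)
        assert out[1] == pytest.approx(4.0)


class TestOracleEquivalence:
    """Each update agrees with an independent equation transcription under
    a shared draw stream, populations of size 5-10."""

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("mgto", [False, True])
    def test_exploration(self, seed, mgto):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        x = rng.normal(size=n) * 3
        state = make_state(x)
        c = coeffs(
            C=float(rng.uniform(0, 2)),
            L=float(rng.uniform(-2, 2)),
            Z=float(rng.uniform(-1, 1)),
            rad=float(rng.uniform(0, 3)),
        )
        params = MGTOParams(p=0.3, max_iter=5)
        draws = list(np.random.default_rng(seed + 100).uniform(size=4 * n))
        lo, hi = state.bounds.lower, state.bounds.upper
        if mgto:
            got = mgto_update_exploration(state, params, c, ScriptedStream(draws))
            want = _oracles.mgto_exploration(
                x, params.p, c.C, c.L, c.H, c.Z, c.rad, lo, hi,
                ScriptedStream(draws),
            )
        else:
            got = gto_update_exploration(state, params, c, ScriptedStream(draws))
            want = _oracles.gto_exploration(
                x, params.p, c.C, c.L, c.H, c.Z, lo, hi, ScriptedStream(draws)
            )
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_silverback_and_competition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        x = rng.normal(size=n) * 2
        state = make_state(x)
        g = float(rng.uniform(0.5, 3))
        c = coeffs(
            L=float(rng.uniform(-1.5, 1.5)),
            g=g,
            Q=float(rng.uniform(-1, 1)),
            A=float(rng.uniform(0, 1)),
            rad=float(rng.uniform(0, 3)),
        )
        lo, hi = state.bounds.lower, state.bounds.upper
        sb = state.silverback_index
        M = _oracles.m_value(list(x), g)
        np.testing.assert_allclose(
            gto_update_silverback(state, c),
            _oracles.gto_silverback(x, sb, c.L, M, lo, hi),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            mgto_update_silverback(state, c),
            _oracles.mgto_silverback(x, sb, c.L, M, c.rad, lo, hi),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            gto_update_competition(state, MGTOParams(), c, None),
            _oracles.gto_competition(x, sb, c.Q, c.A, lo, hi),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            mgto_update_competition(state, MGTOParams(), c, None),
            _oracles.mgto_competition(x, sb, c.Q, c.A, c.rad, lo, hi),
            atol=1e-10,
        )
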