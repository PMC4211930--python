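import math

import numpy as np
import pytest

import odorsearch as osx
from odorsearch.infotaxis import (ACTIONS, Belief, InfotaxisConfig,
                                  admissible_actions, choose_action, entropy,
                                  expected_entropy_gain, update_belief)

from reference_infotaxis import bf_choose, bf_entropy, bf_update


def toy_params():
    # broad-lambda likelihood model on a small grid
    return osx.PlumeParams(emission_rate=0.2, patch_lifetime=400.0,
                           diffusivity=0.25, wind_speed=0.88, agent_size=0.1)


def grid5():
    xs = np.arange(5) * 0.1
    ys = np.arange(5) * 0.1
    return xs, ys


class TestBelief:
    def test_uniform_excludes_start_cell(self):
        xs, ys = grid5()
        b = Belief.uniform(xs, ys, exclude=(0.2, 0.2))
        assert b.prob[2, 2] == 0.0
        assert b.prob.sum() == pytest.approx(1.0)
        assert np.all(b.prob[b.prob > 0] == pytest.approx(1 / 24))

    def test_rejects_negative_or_empty(self):
        xs, ys = grid5()
        with pytest.raises(ValueError):
            Belief(xs, ys, -np.ones((5, 5)))
        with pytest.raises(ValueError):
            Belief(xs, ys, np.zeros((5, 5)))


class TestUpdateBelief:
    def test_hand_computed_three_cell_posterior(self):
        # uniform prior over 3 cells with expected counts (0.1, 0.2, 0.3)
        # and one observed detection, observer away from all cells
        xs = np.array([0.0, 1.0, 2.0])
        ys = np.array([0.0])
        b = Belief(xs, ys, np.ones((1, 3)) / 3)
        rates = np.array([[0.1, 0.2, 0.3]])
        out = update_belief(b, (10.0, 10.0), 1.0, 1, toy_params(), rates=rates)
        raw = np.array([0.1 * math.exp(-0.1), 0.2 * math.exp(-0.2),
                        0.3 * math.exp(-0.3)])
        assert np.allclose(out.prob[0], raw / raw.sum(), atol=1e-12)

    def test_zero_rate_zero_count_only_zeroes_visited_cell(self):
        xs, ys = grid5()
        b = Belief.uniform(xs, ys)
        rates = np.zeros((5, 5))
        out = update_belief(b, (0.2, 0.2), 1.0, 0, toy_params(), rates=rates)
        assert out.prob[2, 2] == 0.0
        off = np.ones((5, 5), bool)
        off[2, 2] = False
        assert np.allclose(out.prob[off], 1 / 24)

    def test_always_renormalized(self):
        xs, ys = grid5()
        b = Belief.uniform(xs, ys)
        p = toy_params()
        rng = np.random.default_rng(3)
        for _ in range(10):
            pos = (0.1 * rng.integers(5), 0.1 * rng.integers(5))
            b = update_belief(b, pos, 3.5, int(rng.integers(0, 2)), p)
            assert b.prob.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(b.prob >= 0)

    def test_inconsistent_history_raises(self):
        # all belief mass sits in the visited cell: zeroing it leaves nothing
        xs = np.array([0.0, 0.1])
        ys = np.array([0.0])
        b = Belief(xs, ys, np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError):
            update_belief(b, (0.0, 0.0), 1.0, 0, toy_params())


class TestEntropy:
    def test_uniform_point_mass_and_mixed(self):
        xs, ys = grid5()
        assert entropy(Belief.uniform(xs, ys)) == pytest.approx(math.log2(25))
        point = np.zeros((5, 5))
        point[1, 3] = 1.0
        assert entropy(Belief(xs, ys, point)) == 0.0
        mixed = Belief(np.arange(3.0), np.zeros(1),
                       np.array([[0.5, 0.25, 0.25]]))
        assert entropy(mixed) == pytest.approx(1.5)

    def test_bounded_by_log_n(self):
        xs, ys = grid5()
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = Belief(xs, ys, rng.random((5, 5)))
            assert 0.0 <= entropy(b) <= math.log2(25) + 1e-12


class TestExpectedGain:
    def test_mirror_symmetric_belief_ties_left_right(self):
        xs, ys = grid5()
        prob = np.ones((5, 5))
        prob[:, 0] = prob[:, 4] = 3.0  # symmetric about the center column
        b = Belief(xs, ys, prob)
        p = osx.PlumeParams(emission_rate=0.2, patch_lifetime=400.0,
                            diffusivity=0.25, wind_speed=0.0, agent_size=0.1)
        cfg = InfotaxisConfig()
        gl = expected_entropy_gain(b, "left", (0.2, 0.2), 3.5, p, cfg)
        gr = expected_entropy_gain(b, "right", (0.2, 0.2), 3.5, p, cfg)
        assert gl == pytest.approx(gr, abs=1e-12)

    def test_outside_landing_raises(self):
        xs, ys = grid5()
        b = Belief.uniform(xs, ys)
        with pytest.raises(IndexError):
            expected_entropy_gain(b, "left", (0.0, 0.2), 3.5, toy_params())


class TestChooseAction:
    def test_near_point_mass_ahead_attracts(self):
        xs, ys = grid5()
        prob = np.full((5, 5), 1e-9)
        prob[3, 2] = 1.0  # directly forward of (0.2, 0.2)
        b = Belief(xs, ys, prob)
        a = choose_action(b, (0.2, 0.2), toy_params(), np.random.default_rng(0))
        assert a == "forward"

    def test_chosen_action_has_maximal_gain(self):
        xs, ys = grid5()
        rng = np.random.default_rng(5)
        p = toy_params()
        cfg = InfotaxisConfig()
        for trial in range(10):
            b = Belief(xs, ys, rng.random((5, 5)))
            pos = (0.1 * rng.integers(5), 0.1 * rng.integers(5))
            a = choose_action(b, pos, p, rng, cfg)
            gains = {
                act: expected_entropy_gain(b, act, pos, cfg.action_dt(act), p, cfg)
                for act in admissible_actions(b, pos)
            }
            assert gains[a] == pytest.approx(max(gains.values()), abs=1e-12)

    def test_tie_break_reproducible_per_seed(self):
        xs, ys = grid5()
        prob = np.zeros((5, 5))
        prob[2, 0] = prob[2, 4] = 0.5  # symmetric two-peak belief
        b = Belief(xs, ys, prob)
        p = osx.PlumeParams(emission_rate=0.2, patch_lifetime=400.0,
                            diffusivity=0.25, wind_speed=0.0, agent_size=0.1)
        picks = {choose_action(b, (0.2, 0.2), p, np.random.default_rng(s))
                 for s in range(20)}
        assert picks <= {"left", "right"}
        assert len(picks) == 2  # both sides occur across seeds
        again = [choose_action(b, (0.2, 0.2), p, np.random.default_rng(3))
                 for _ in range(3)]
        assert len(set(again)) == 1

    def test_explores_even_with_silent_world(self):
        # with (numerically) zero detection rate the agent must still move:
        # zeroing visited cells is the only information source
        xs = np.arange(9) * 0.1
        ys = np.arange(9) * 0.1
        b = Belief.uniform(xs, ys, exclude=(0.4, 0.4))
        p = osx.PlumeParams(emission_rate=1e-12, patch_lifetime=400.0,
                            diffusivity=0.25, wind_speed=0.88, agent_size=0.1)
        rng = np.random.default_rng(1)
        pos = np.array([0.4, 0.4])
        visited = {tuple(np.round(pos, 3))}
        for _ in range(50):
            a = choose_action(b, pos, p, rng)
            step = osx.infotaxis.ACTION_STEPS[a]
            pos = pos + 0.1 * np.array(step)
            b = update_belief(b, pos, 3.5, 0, p)
            visited.add(tuple(np.round(pos, 3)))
        assert len(visited) >= 2

    def test_visited_cells_stay_zero(self):
        xs, ys = grid5()
        b = Belief.uniform(xs, ys, exclude=(0.2, 0.2))
        p = toy_params()
        rng = np.random.default_rng(2)
        pos = np.array([0.2, 0.2])
        seen = []
        for _ in range(12):
            a = choose_action(b, pos, p, rng)
            pos = pos + 0.1 * np.array(osx.infotaxis.ACTION_STEPS[a])
            b = update_belief(b, pos, 3.5, 0, p)
            seen.append(b.cell_index(pos))
            for iy, ix in seen:
                assert b.prob[iy, ix] == 0.0


class TestBruteForceEquivalence:
    def test_episode_matches_reference_action_for_action(self):
        """A full 20-step episode on a 5x5 grid with scripted detections must
        match the naive reference implementation: same actions, same beliefs,
        same entropies."""
        xs, ys = grid5()
        spacing = 0.1
        cells = [(x, y) for y in ys for x in xs]
        params = toy_params()
        cfg = InfotaxisConfig()

        belief = Belief.uniform(xs, ys, exclude=(0.2, 0.0))
        prob = {c: (0.0 if c == (0.2, 0.0) else 1 / 24) for c in cells}

        rng_impl = np.random.default_rng(42)
        rng_ref = np.random.default_rng(42)
        pos = (0.2, 0.0)
        k_script = [1, 0, 0, 1, 0, 0, 0, 1, 0, 0] * 2

        for step in range(20):
            a_impl = choose_action(belief, pos, params, rng_impl, cfg)
            a_ref = bf_choose(prob, pos, params, cells, spacing, rng_ref,
                              cfg.action_dt)
            assert a_impl == a_ref, f"step {step}: {a_impl} != {a_ref}"
            dx, dy = osx.infotaxis.ACTION_STEPS[a_impl]
            pos = (round(pos[0] + dx * spacing, 10),
                   round(pos[1] + dy * spacing, 10))
            dt = cfg.action_dt(a_impl)
            k = k_script[step]
            belief = update_belief(belief, pos, dt, k, params)
            prob = bf_update(prob, pos, dt, k, params, cells, spacing)
            ref_grid = np.array([[prob[(x, y)] for x in xs] for y in ys])
            assert np.allclose(belief.prob, ref_grid, atol=1e-10)
            assert entropy(belief) == pytest.approx(bf_entropy(prob), abs=1e-9)
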