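"""Cellular-automata movement rules, stuck/fall-back behaviour and cohort runs."""

import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import classified_from_array, uniform_field
from eelpass.ca import (AgentRecord, CAConfig, CAPassageModel,
                        prioritized_neighbors, run_ca, spawn_agents,
                        step_agent, update_stuck_state)
from eelpass.classify import BOUNDARY, IMPASSABLE, classify_field, has_continuous_path


class TestConfig:
    def test_defaults_match_operating_point(self):
        c = CAConfig()
        assert (c.n_agents, c.max_timesteps) == (1000, 10_000)
        assert (c.stuck_window, c.stuck_threshold, c.fallback_moves) == (20, 2, 30)

    def test_threshold_below_window(self):
        with pytest.raises(ValueError):
            CAConfig(stuck_window=20, stuck_threshold=20)


class TestSpawn:
    def test_single_open_edge_cell_collects_everyone(self):
        c = np.zeros((5, 4), dtype=np.int8)
        c[4, :] = BOUNDARY
        c[4, 2] = 0
        cf = classified_from_array(c)
        js = spawn_agents(cf, 50, np.random.default_rng(0))
        assert (js == 2).all()

    def test_all_boundary_edge_errors(self):
        c = np.zeros((5, 4), dtype=np.int8)
        c[4, :] = BOUNDARY
        with pytest.raises(ValueError, match="spawn"):
            spawn_agents(classified_from_array(c), 10, np.random.default_rng(0))

    def test_uniform_edge_spawn_is_uniform(self):
        cf = classified_from_array(np.zeros((5, 8), dtype=np.int8))
        js = spawn_agents(cf, 10_000, np.random.default_rng(123))
        counts = np.bincount(js, minlength=8)
        assert chisquare(counts).pvalue > 1e-3

    def test_seeded_reproducibility(self):
        cf = classified_from_array(np.zeros((5, 8), dtype=np.int8))
        a = spawn_agents(cf, 100, np.random.default_rng(9))
        b = spawn_agents(cf, 100, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestNeighbors:
    def test_interior_groups_sizes(self):
        cf = classified_from_array(np.zeros((5, 5), dtype=np.int8))
        up, cross, down = prioritized_neighbors((2, 2), cf, "normal")
        assert (len(up), len(cross), len(down)) == (3, 2, 3)
        assert all(i == 1 for i, _ in up)
        assert all(i == 3 for i, _ in down)

    def test_wall_cell_drops_offgrid(self):
        cf = classified_from_array(np.zeros((5, 5), dtype=np.int8))
        up, cross, down = prioritized_neighbors((2, 0), cf, "normal")
        assert (len(up), len(cross), len(down)) == (2, 1, 2)

    def test_fallback_reverses_group_order(self):
        cf = classified_from_array(np.zeros((5, 5), dtype=np.int8))
        normal = prioritized_neighbors((2, 2), cf, "normal")
        fallback = prioritized_neighbors((2, 2), cf, "fallback")
        assert fallback == normal[::-1]

    def test_impassable_and_boundary_removed(self):
        c = np.zeros((5, 5), dtype=np.int8)
        c[1, :] = IMPASSABLE
        c[2, 1] = BOUNDARY
        cf = classified_from_array(c)
        up, cross, down = prioritized_neighbors((2, 2), cf, "normal")
        assert up == [] and cross == [(2, 3)]


class TestStepAndStuck:
    def test_forced_corridor_reaches_top_in_exact_moves(self):
        cf = classified_from_array(np.zeros((10, 1), dtype=np.int8))
        agent = AgentRecord(position=(9, 0), history=[9])
        rng = np.random.default_rng(0)
        for _ in range(9):
            assert agent.outcome == "active"
            step_agent(agent, cf, rng)
        assert agent.outcome == "passed" and agent.moves == 9

    def test_surrounded_agent_holds_but_move_counts(self):
        c = np.full((3, 3), IMPASSABLE, dtype=np.int8)
        c[1, 1] = 0
        cf = classified_from_array(c)
        agent = AgentRecord(position=(1, 1), history=[1])
        step_agent(agent, cf, np.random.default_rng(0))
        assert agent.position == (1, 1) and agent.moves == 1

    def test_two_equal_candidates_chosen_evenly(self):
        c = np.full((3, 3), IMPASSABLE, dtype=np.int8)
        c[1, 1] = 0
        c[0, 0] = 0
        c[0, 2] = 0
        cf = classified_from_array(c)
        rng = np.random.default_rng(99)
        picks = []
        for _ in range(10_000):
            agent = AgentRecord(position=(1, 1), history=[1])
            step_agent(agent, cf, rng)
            picks.append(agent.position[1])
        frac = np.mean(np.array(picks) == 0)
        assert frac == pytest.approx(0.5, abs=0.02)   # ~4 binomial sigma

    def test_oscillation_triggers_fallback_and_reverts(self):
        cfg = CAConfig(stuck_window=20, stuck_threshold=2, fallback_moves=30)
        agent = AgentRecord(position=(5, 0), history=[5])
        for k in range(20):   # oscillate between rows 5 and 6
            agent.history.append(6 if k % 2 == 0 else 5)
            agent.moves += 1
            update_stuck_state(agent, cfg)
        assert agent.mode == "fallback"
        assert agent.fallback_remaining == 30
        for _ in range(30):
            update_stuck_state(agent, cfg)
        assert agent.mode == "normal"
        assert agent.history == [agent.position[0]]   # window buffer reset

    def test_steady_progress_never_stuck(self):
        cfg = CAConfig()
        agent = AgentRecord(position=(50, 0), history=[50])
        for k in range(40):
            agent.history.append(50 - 1 - k)
            agent.moves += 1
            update_stuck_state(agent, cfg)
        assert agent.mode == "normal"


class TestRunCA:
    def test_all_passable_grid_everyone_passes(self):
        cf = classified_from_array(np.zeros((50, 20), dtype=np.int8))
        res = run_ca(cf, CAConfig(n_agents=200, max_timesteps=2000, seed=0))
        assert res.efficiency == 100.0
        assert res.n_passed == 200

    def test_blocked_grid_efficiency_zero(self, blocked_10x6):
        assert not has_continuous_path(blocked_10x6).connected
        res = run_ca(blocked_10x6, CAConfig(n_agents=100, max_timesteps=2000,
                                            seed=1))
        assert res.efficiency == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_cul_de_sac_escaped_via_fallback(self, cul_de_sac_10x6, seed):
        """Agents entering the dead-end channel must fall back and re-route;
        with the default stuck/fall-back rules all eventually pass."""
        res = run_ca(cul_de_sac_10x6,
                     CAConfig(n_agents=50, max_timesteps=10_000, seed=seed))
        assert res.efficiency == 100.0

    def test_same_seed_bit_identical_results(self, cul_de_sac_10x6):
        cfg = CAConfig(n_agents=100, max_timesteps=3000, seed=7)
        a = run_ca(cul_de_sac_10x6, cfg)
        b = run_ca(cul_de_sac_10x6, cfg)
        np.testing.assert_array_equal(a.outcomes, b.outcomes)
        np.testing.assert_array_equal(a.moves, b.moves)
        assert a.to_json() == b.to_json()

    def test_efficiency_monotone_in_timesteps(self, cul_de_sac_10x6):
        # a longer budget extends the same trajectories, so the passed set
        # can only grow
        effs = [run_ca(cul_de_sac_10x6,
                       CAConfig(n_agents=100, max_timesteps=t, seed=3)).efficiency
                for t in (50, 200, 1000, 5000)]
        assert effs == sorted(effs)

    def test_efficiency_monotone_in_threshold(self):
        # larger elvers (higher threshold) do at least as well on a field
        # spanning the threshold range
        rng = np.random.default_rng(12)
        f = uniform_field(0.2, 30, 10)
        f.speed[:] = rng.uniform(0.1, 0.5, size=f.speed.shape)
        effs = []
        for t in (0.12, 0.3, 0.55):
            cf = classify_field(f, t)
            effs.append(run_ca(cf, CAConfig(n_agents=150, max_timesteps=4000,
                                            seed=5)).efficiency)
        assert effs[0] <= effs[1] <= effs[2]
        assert effs[-1] == 100.0

    def test_model_wrapper_seed_override(self, all_passable_10x6):
        model = CAPassageModel(all_passable_10x6,
                               CAConfig(n_agents=50, max_timesteps=500))
        a = model.run(seed=2)
        b = model.run(seed=2)
        assert a.to_json() == b.to_json()
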