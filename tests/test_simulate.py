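"""Synthetic-agent choice generation and the simulation grid."""

import numpy as np
import pytest

from ordrisk import (
    AgentParams,
    SimulationGrid,
    build_design,
    draw_agents,
    run_simulation_grid,
    simulate_choices,
)
from ordrisk.simulate import ALPHA_RANGE, BETA_RANGE, DEFAULT_GRID_CELLS


class TestDrawAgents:
    def test_parameters_within_constraint_ranges(self):
        agents = draw_agents(300, seed=1)
        assert all(ALPHA_RANGE[0] <= a.alpha <= ALPHA_RANGE[1] for a in agents)
        assert all(BETA_RANGE[0] <= a.beta <= BETA_RANGE[1] for a in agents)

    def test_seeded_determinism(self):
        assert draw_agents(1, seed=7) == draw_agents(1, seed=7)

    def test_uniform_means_match_range_midpoints(self):
        agents = draw_agents(10_000, seed=3)
        alphas = np.array([a.alpha for a in agents])
        betas = np.array([a.beta for a in agents])
        # midpoints 0.85 and 0.0 within ~4 Monte-Carlo standard errors
        assert abs(alphas.mean() - 0.85) < 4 * alphas.std() / 100
        assert abs(betas.mean() - 0.0) < 4 * betas.std() / 100

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            draw_agents(0, seed=0)

    def test_agent_validation(self):
        with pytest.raises(ValueError):
            AgentParams(alpha=2.0, beta=0.0, noise_sd=0.1)
        with pytest.raises(ValueError):
            AgentParams(alpha=1.0, beta=-2.0, noise_sd=0.1)
        with pytest.raises(ValueError):
            AgentParams(alpha=1.0, beta=0.0, noise_sd=-0.1)


def _choice_for(agent, data, level, P, A):
    rows = data.table[
        (data.table["level"] == level)
        & (data.table["win_prob"] == P)
        & (data.table["ambiguity"] == A)
        & (~data.table["is_catch"])
    ]
    return rows["chose_lottery"].unique()


class TestSimulateChoices:
    def test_noise_free_policy_is_utility_argmax(self, in_person_monetary):
        # alpha=1, beta=0: picks the $12 lottery at P=.5 (SV 6 > 5) and
        # rejects the $8 lottery at P=.25 (SV 2 < 5)
        agent = AgentParams(alpha=1.0, beta=0.0, noise_sd=0.0)
        data = simulate_choices([agent], in_person_monetary, seed=0)
        assert list(_choice_for(agent, data, 3, 0.5, 0.0)) == [True]
        assert list(_choice_for(agent, data, 2, 0.25, 0.0)) == [False]

    @pytest.mark.parametrize("beta", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("alpha", [0.1, 1.0, 1.6])
    def test_catch_trials_dominated_at_zero_noise(
        self, in_person_monetary, alpha, beta
    ):
        agent = AgentParams(alpha=alpha, beta=beta, noise_sd=0.0)
        data = simulate_choices([agent], in_person_monetary, seed=0)
        catch = data.table[data.table["is_catch"]]
        assert not catch["chose_lottery"].any()

    def test_catch_failures_increase_with_noise(self, in_person_monetary):
        rates = []
        for noise in (0.0, 0.3, 1.0):
            agents = [AgentParams(1.0, 0.0, noise) for _ in range(50)]
            data = simulate_choices(agents, in_person_monetary, seed=11)
            catch = data.table[data.table["is_catch"]]
            rates.append(catch["chose_lottery"].mean())
        # the smallest dominated margin is 1.25 SV units, so failures are
        # essentially absent at noise 0.3 and appreciable only at noise 1.0
        assert rates[0] == 0.0
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.0

    def test_lottery_choice_monotone_in_outcome_level(self, in_person_monetary):
        agents = [AgentParams(0.8, 0.3, 0.5) for _ in range(200)]
        data = simulate_choices(agents, in_person_monetary, seed=5)
        df = data.table[~data.table["is_catch"]]
        rates = df[df["win_prob"] == 0.5].groupby("level")["chose_lottery"].mean()
        assert rates.is_monotonic_increasing

    def test_true_params_stored(self, in_person_monetary):
        agents = draw_agents(3, seed=0, noise_sd=0.2)
        data = simulate_choices(agents, in_person_monetary, seed=1)
        assert list(data.true_params["alpha"]) == [a.alpha for a in agents]

    def test_medical_domain_rejected(self):
        design = build_design("in_person", "medical")
        with pytest.raises(ValueError, match="amounts"):
            simulate_choices([AgentParams(1.0, 0.0, 0.0)], design, seed=0)


class TestSimulationGrid:
    def test_default_grid_shapes(self, in_person_monetary):
        grid = SimulationGrid(seed=9)
        datasets = run_simulation_grid(grid, in_person_monetary)
        assert set(datasets) == set(DEFAULT_GRID_CELLS)
        for (n, _), data in datasets.items():
            assert len(data.table) == n * 84
            assert data.n_subjects == n

    def test_grid_determinism(self, in_person_monetary):
        grid = SimulationGrid(cells=((30, 0.1),), seed=4)
        a = run_simulation_grid(grid, in_person_monetary)[(30, 0.1)]
        b = run_simulation_grid(grid, in_person_monetary)[(30, 0.1)]
        assert a.table.equals(b.table)
        assert a.true_params.equals(b.true_params)
        assert a.table["subject_id"].nunique() == 30
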