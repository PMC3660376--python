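"""Tests of the population iteration loop and its per-cell reference ops."""

import numpy as np
import pytest
from scipy import stats

from amitosim import (
    CellState,
    Population,
    SimParams,
    attempt_conjugation,
    attempt_division,
    chromosome_number_from_elimination,
    cull,
    initialize_population,
    mutate_clamped,
    run_simulation,
    summaries_to_frame,
    total_fitness,
)
from amitosim.engine import step
from amitosim.model import AssortmentModel


class TestInitialization:
    def test_founding_population(self):
        params = SimParams()
        pop = initialize_population(params)
        assert len(pop) == 1000
        assert np.all(pop.X == 10) and np.all(pop.E == 0) and np.all(pop.N == 50)
        assert np.all(pop.G == 0) and np.all(pop.A == 0)
        for cell in Population(pop.X[:3], pop.E[:3], pop.N[:3], pop.G[:3], pop.A[:3]).cells():
            assert total_fitness(cell, params) == 1.0

    def test_single_cell_population(self):
        assert len(initialize_population(SimParams(pop_size=1))) == 1


class TestMutateClamped:
    def test_zero_sd_still_clamps(self, rng):
        assert mutate_clamped(0.99, 0.0, 0.0, 0.98, rng) == 0.98
        assert mutate_clamped(0.5, 0.0, 0.0, 0.98, rng) == 0.5

    def test_draws_respect_bounds(self, rng):
        draws = [mutate_clamped(0.0, 5.0, 0.0, np.inf, rng) for _ in range(500)]
        assert min(draws) == 0.0  # about half the draws hit the lower bound
        assert all(d >= 0 for d in draws)
        e_draws = [mutate_clamped(0.975, 0.05, 0.0, 0.98, rng) for _ in range(500)]
        assert max(e_draws) == 0.98 and all(d <= 0.98 for d in e_draws)

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            mutate_clamped(1.0, -1.0, 0.0, 2.0, rng)
        with pytest.raises(ValueError):
            mutate_clamped(1.0, 1.0, 2.0, 0.0, rng)


class TestConjugation:
    def test_immature_cell_never_conjugates(self, rng):
        params = SimParams(S=1.0)
        cell = CellState(X=10, E=0.0, N=50, G=14, A=30)
        for _ in range(200):
            flag, out = attempt_conjugation(cell, params, rng)
            assert not flag and out is cell

    def test_conjugation_resets_ages_and_recomputes_N(self, rng):
        params = SimParams(S=1.0)
        cell = CellState(X=40, E=0.5, N=chromosome_number_from_elimination(0.5, 50), G=20, A=60)
        flag, out = attempt_conjugation(cell, params, rng)
        assert flag
        assert out.G == 0 and out.A == 0
        assert out.N == chromosome_number_from_elimination(out.E, params.N0)
        assert 0 <= out.E <= 0.98 and out.X >= 0

    def test_conjugation_probability_is_S(self, rng):
        params = SimParams(S=0.3)
        cell = CellState(X=10, E=0.0, N=50, G=20, A=40)
        hits = sum(attempt_conjugation(cell, params, rng)[0] for _ in range(4000))
        assert stats.binomtest(hits, 4000, 0.3).pvalue > 1e-4


class TestDivision:
    def test_young_cell_only_ages(self, rng):
        params = SimParams(I=2)
        cell = CellState(X=10, E=0.0, N=50, G=0, A=0)
        daughter, out = attempt_division(cell, params, rng)
        assert daughter is None and out.A == 1 and out.G == 0

    def test_division_clones_cell(self, rng):
        params = SimParams(I=2)
        cell = CellState(X=10, E=0.0, N=50, G=0, A=2)  # fitness exactly 1
        daughter, out = attempt_division(cell, params, rng)
        assert daughter is not None
        assert (daughter.X, daughter.E, daughter.N) == (out.X, out.E, out.N)
        assert daughter.G == out.G == 1 and daughter.A == out.A == 3

    def test_zero_fitness_cell_never_divides(self, rng):
        params = SimParams()
        cell = CellState(X=0, E=0.0, N=50, G=1, A=5)
        for expected_age in range(6, 26):
            daughter, cell = attempt_division(cell, params, rng)
            assert daughter is None and cell.A == expected_age and cell.G == 1


class TestCulling:
    @staticmethod
    def _uniform_pop(n):
        return Population(
            X=np.arange(n, dtype=float), E=np.zeros(n), N=np.full(n, 50.0),
            G=np.zeros(n, dtype=np.int64), A=np.zeros(n, dtype=np.int64),
        )

    def test_cull_to_target_size(self, rng):
        pop = cull(self._uniform_pop(1300), SimParams(), rng)
        assert len(pop) == 1000
        assert len(np.unique(pop.X)) == 1000  # without replacement

    def test_small_pool_survives_intact(self, rng):
        pop = self._uniform_pop(1000)
        assert cull(pop, SimParams(), rng) is pop

    def test_selection_is_uniform(self, rng):
        # chi-square over survival counts of repeated culls of a 200->100 pool
        n, keep, trials = 200, 100, 400
        counts = np.zeros(n)
        params = SimParams(pop_size=keep)
        for _ in range(trials):
            surv = cull(self._uniform_pop(n), params, rng)
            counts[surv.X.astype(int)] += 1
        p = stats.chisquare(counts, f_exp=np.full(n, trials * keep / n)).pvalue
        assert p > 1e-4


class TestRunSimulation:
    def test_population_size_constant_every_iteration(self, tiny_params):
        rng = np.random.default_rng(tiny_params.seed)
        assortment = AssortmentModel()
        pop = initialize_population(tiny_params)
        for _ in range(150):
            pop = step(pop, tiny_params, rng, assortment)
            assert len(pop) == tiny_params.pop_size
            assert np.all(pop.A >= pop.G)
            assert np.allclose(
                pop.N, chromosome_number_from_elimination(pop.E, tiny_params.N0)
            )

    def test_no_mutation_leaves_heritable_state_invariant(self):
        params = SimParams(Sd_copy=0.0, Sd_elim=0.0, pop_size=100, n_iter=400, seed=3)
        df = summaries_to_frame(run_simulation(params, record_every=50))
        assert (df.mean_X == 10.0).all() and (df.std_X == 0.0).all()
        assert (df.mean_E == 0.0).all() and (df.mean_N == 50.0).all()

    def test_no_conjugation_means_no_change(self):
        # M unreachable within the iteration budget: X, E, N frozen
        params = SimParams(M=10**6, pop_size=100, n_iter=200, seed=4)
        df = summaries_to_frame(run_simulation(params, record_every=20))
        assert (df.mean_X == 10.0).all() and (df.mean_E == 0.0).all()
        assert (df.mean_N == 50.0).all()

    def test_zero_iterations_reports_founding_state(self, tiny_params):
        summaries = run_simulation(tiny_params.with_(n_iter=0))
        assert len(summaries) == 1
        s = summaries[0]
        assert (s.mean_X, s.mean_E, s.mean_N, s.mean_F) == (10.0, 0.0, 50.0, 1.0)

    def test_identical_seeds_identical_trajectories(self, tiny_params):
        a = summaries_to_frame(run_simulation(tiny_params))
        b = summaries_to_frame(run_simulation(tiny_params))
        assert a.equals(b)

    def test_different_seeds_diverge(self, tiny_params):
        a = summaries_to_frame(run_simulation(tiny_params))
        b = summaries_to_frame(run_simulation(tiny_params.with_(seed=8)))
        assert not a.equals(b)

    def test_imbalance_declines_with_vegetative_age(self):
        # before any conjugation is possible, mean F_imb decays as G grows
        params = SimParams(M=10**6, pop_size=200, n_iter=100, seed=5)
        df = summaries_to_frame(run_simulation(params, record_every=10))
        fimb = df.mean_Fimb.to_numpy()
        assert fimb[0] == 1.0
        # declining trend; culling noise may produce tiny upward blips
        assert np.all(np.diff(fimb) <= 0.02)
        assert fimb[-1] < 0.9
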