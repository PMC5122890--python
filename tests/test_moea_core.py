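import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moeanet as mn
from moeanet.moea_core import (
    crowding_distance,
    evaluate,
    evaluate_batch,
    init_population,
    soft_threshold,
    variation,
)

from conftest import brute_force_fronts


class TestEvaluate:
    def test_truth_has_zero_error_on_noise_free_system(self, small_net, small_system):
        x_true = small_net.adjacency[0][small_system.candidate_ids]
        f1, f2 = evaluate(x_true, small_system)
        assert f1 == pytest.approx(0.0, abs=1e-9)
        assert f2 == pytest.approx(x_true.sum())

    def test_zero_vector(self, small_system):
        f1, f2 = evaluate(np.zeros(small_system.n_candidates), small_system)
        assert f1 == pytest.approx(np.linalg.norm(small_system.Y))
        assert f2 == 0.0

    def test_l1_objective(self, small_system):
        w = np.zeros(small_system.n_candidates)
        w[:3] = [2.0, 0.0, 1.0]
        assert evaluate(w, small_system)[1] == pytest.approx(3.0)

    def test_dimension_mismatch(self, small_system):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), small_system)

    def test_batch_matches_scalar(self, small_system):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 2, size=(7, small_system.n_candidates))
        F = evaluate_batch(W, small_system)
        for k in range(7):
            assert F[k].tolist() == pytest.approx(list(evaluate(W[k], small_system)))


class TestDominance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 1), (2, 2), True), ((1, 2), (2, 1), False),
         ((2, 1), (1, 2), False), ((1, 1), (1, 1), False),
         ((1, 1), (1, 2), True)],
    )
    def test_textbook_cases(self, a, b, expected):
        assert mn.dominates(a, b) is expected

    @given(st.tuples(st.floats(0, 10), st.floats(0, 10)),
           st.tuples(st.floats(0, 10), st.floats(0, 10)))
    def test_antisymmetry(self, a, b):
        assert not (mn.dominates(a, b) and mn.dominates(b, a))


class TestNondominatedSort:
    def test_matches_brute_force_on_random_point_sets(self):
        rng = np.random.default_rng(3)
        for t in range(40):
            n = int(rng.integers(2, 50))
            F = (rng.integers(0, 6, (n, 2)).astype(float) if t % 2
                 else rng.random((n, 2)))
            got = [list(f) for f in mn.nondominated_sort(F)]
            assert got == brute_force_fronts(F)

    def test_identical_points_form_single_front(self):
        F = np.ones((5, 2))
        fronts = mn.nondominated_sort(F)
        assert len(fronts) == 1 and len(fronts[0]) == 5

    def test_strictly_decreasing_curve_is_one_front(self):
        x = np.linspace(0, 1, 12)
        F = np.column_stack([x, 1 - x])
        fronts = mn.nondominated_sort(F)
        assert len(fronts) == 1

    def test_crowding_boundaries_infinite(self):
        x = np.linspace(0, 1, 8)
        F = np.column_stack([x, 1 - x])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[-1])
        assert np.all(np.isfinite(d[1:-1]))


class TestSoftThreshold:
    def test_zero_theta_is_identity(self):
        w = np.array([0.5, 2.0])
        assert np.array_equal(soft_threshold(w, 0.0), w)

    def test_theta_above_max_zeroes_everything(self):
        assert np.all(soft_threshold(np.array([0.5, 2.0]), 2.5) == 0)

    def test_elementwise_shrinkage(self):
        got = soft_threshold(np.array([2.0, 0.3, 1.1]), 0.5)
        assert got.tolist() == pytest.approx([1.5, 0.0, 0.6])


class TestInitialization:
    def test_ipl_contains_zero_and_dense_seeds(self, small_system):
        pop = init_population(small_system, mn.MOEAConfig(pop_size=30, seed=2))
        has_zero = any(np.all(m.weights == 0) for m in pop.members)
        f1 = np.array([m.f1 for m in pop.members])
        assert has_zero
        assert f1.min() < 0.05 * np.linalg.norm(small_system.Y)  # dense low-error seed

    def test_same_seed_same_population(self, small_system):
        cfg = mn.MOEAConfig(pop_size=20, init="IPR", seed=5)
        a = init_population(small_system, cfg)
        b = init_population(small_system, cfg)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.weights, mb.weights)

    def test_lambda_grid_length_validated(self):
        with pytest.raises(ValueError):
            mn.MOEAConfig(pop_size=10, lambda_grid=np.ones(5))


class TestVariation:
    def test_offspring_nonnegative(self, small_system, fast_moea):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 3, size=(20, small_system.n_candidates))
        children = variation(W, fast_moea, rng)
        assert np.all(children >= 0)
        assert children.shape == W.shape

    def test_identical_parents_unchanged_without_mutation(self, small_system):
        cfg = mn.MOEAConfig(pop_size=20, mutation_prob=0.0, soft_threshold_prob=0.0)
        w = np.full((20, small_system.n_candidates), 1.5)
        children = variation(w, cfg, np.random.default_rng(2))
        assert np.allclose(children, 1.5)


class TestRunMoeanet:
    def test_zero_generations_is_nondominated_init(self, small_system):
        cfg = mn.MOEAConfig(pop_size=20, generations=0, seed=3)
        front = mn.run_moeanet(small_system, cfg)
        pop = init_population(small_system, cfg)
        F = np.array([[m.f1, m.f2] for m in pop.members])
        want = {tuple(F[i]) for i in mn.nondominated_sort(F)[0]}
        got = {(s.f1, s.f2) for s in front.solutions}
        assert got == want

    def test_identical_seeds_identical_fronts(self, small_system, fast_moea):
        a = mn.run_moeanet(small_system, fast_moea)
        b = mn.run_moeanet(small_system, fast_moea)
        assert np.array_equal(a.objectives, b.objectives)
        assert np.array_equal(a.weight_matrix, b.weight_matrix)

    def test_front_members_feasible_and_consistent(self, small_system, fast_moea):
        front = mn.run_moeanet(small_system, fast_moea)
        assert len(front) > 0
        for sol in front.solutions:
            assert np.all(sol.weights >= 0)
            f1, f2 = evaluate(sol.weights, small_system)
            assert sol.f1 == pytest.approx(f1, abs=1e-10)
            assert sol.f2 == pytest.approx(f2, abs=1e-10)

    def test_front_sorted_and_mutually_nondominated(self, small_system, fast_moea):
        F = mn.run_moeanet(small_system, fast_moea).objectives
        assert np.all(np.diff(F[:, 0]) >= 0)
        assert len(mn.nondominated_sort(F)) == 1

    def test_elitism_front_extremes_never_degrade(self, small_system):
        base = dict(pop_size=24, seed=4)
        f0 = mn.run_moeanet(small_system, mn.MOEAConfig(generations=0, **base)).objectives
        f30 = mn.run_moeanet(small_system, mn.MOEAConfig(generations=30, **base)).objectives
        assert f30[:, 0].min() <= f0[:, 0].min() + 1e-12
        assert f30[:, 1].min() <= f0[:, 1].min() + 1e-12

    def test_noise_free_front_reaches_true_support(self, payoff_matrix):
        net = mn.gen_er(15, 4, seed=8)
        trace = mn.simulate(net, mn.SimulationConfig(rounds=24, seed=9))
        sys0 = mn.build_local_system(trace, 0, payoff_matrix)
        x_true = net.adjacency[0][sys0.candidate_ids]
        front = mn.run_moeanet(sys0, mn.MOEAConfig(pop_size=40, generations=40, seed=10))
        best = front.solutions[0]  # smallest f1
        # error at the smallest-penalty seed level (~1e-4 x null threshold)
        assert best.f1 < 0.01 * np.linalg.norm(sys0.Y)
        assert set(np.flatnonzero(best.weights > 0.5)) == set(np.flatnonzero(x_true))


class TestHypervolume:
    def test_rectangle_area(self):
        F = np.array([[1.0, 1.0]])
        assert mn.hypervolume_2d(F, np.array([3.0, 2.0])) == pytest.approx(2.0)

    def test_staircase(self):
        F = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        # areas: (3-0)*(3-2) + (3-1)*(2-1) + (3-2)*(1-0) = 3 + 2 + 1
        assert mn.hypervolume_2d(F, np.array([3.0, 3.0])) == pytest.approx(6.0)

    def test_points_beyond_reference_ignored(self):
        F = np.array([[5.0, 5.0]])
        assert mn.hypervolume_2d(F, np.array([3.0, 3.0])) == 0.0
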