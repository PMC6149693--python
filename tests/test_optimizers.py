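import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pasvm.optimizers import (
    ABCConfig,
    FoodSource,
    OptimizationResult,
    Particle,
    PSOConfig,
    SearchSpace,
    abc_neighborhood_move,
    abc_scout_position,
    abc_selection_probabilities,
    pso_position_update,
    pso_velocity_update,
    run_abc,
    run_pa,
    run_pso,
)


def sphere(x):
    return -float(np.sum(np.asarray(x) ** 2))


def square_space(half_width=5.12):
    return SearchSpace(
        np.array([-half_width, -half_width]), np.array([half_width, half_width])
    )


class TestSearchSpace:
    def test_default_velocity_clamps_half_range(self):
        space = square_space(5.0)
        np.testing.assert_array_equal(space.v_max, [5.0, 5.0])
        np.testing.assert_array_equal(space.v_min, [-5.0, -5.0])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, 0.0]), np.array([1.0, 0.0]))


class TestVelocityAndPosition:
    def test_stationary_at_consensus(self):
        space = square_space()
        x = np.array([1.0, -2.0])
        p = Particle(x.copy(), np.zeros(2), x.copy(), 0.0)
        v = pso_velocity_update(p, x, PSOConfig(), 0.3, 0.7, space)
        np.testing.assert_array_equal(v, 0.0)

    def test_hand_substitution(self):
        # v=1, x=0, P_i=1, P_g=2, omega=0.5, c1=c2=2, r1=r2=1 -> 6.5
        space = SearchSpace(
            np.array([-10.0]), np.array([10.0]),
            v_min=np.array([-10.0]), v_max=np.array([10.0]),
        )
        p = Particle(np.array([0.0]), np.array([1.0]), np.array([1.0]), 0.0)
        cfg = PSOConfig(inertia=0.5, c1=2.0, c2=2.0)
        v = pso_velocity_update(p, np.array([2.0]), cfg, 1.0, 1.0, space)
        assert v[0] == pytest.approx(6.5)

    def test_velocity_clamped(self):
        space = SearchSpace(
            np.array([-5.0]), np.array([5.0]),
            v_min=np.array([-0.1]), v_max=np.array([0.1]),
        )
        p = Particle(np.array([0.0]), np.array([5.0]), np.array([4.0]), 0.0)
        v = pso_velocity_update(p, np.array([4.0]), PSOConfig(), 0.9, 0.9, space)
        assert -0.1 <= v[0] <= 0.1

    def test_position_moves_and_clamps(self):
        space = square_space(5.0)
        p = Particle(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2), 0.0)
        np.testing.assert_array_equal(
            pso_position_update(p, np.array([1.0, -1.0]), space), [1.0, -1.0]
        )
        p2 = Particle(np.array([4.9, 0.0]), np.zeros(2), np.zeros(2), 0.0)
        np.testing.assert_array_equal(
            pso_position_update(p2, np.array([1.0, 0.0]), space), [5.0, 0.0]
        )
        np.testing.assert_array_equal(
            pso_position_update(p, np.zeros(2), space), p.position
        )


class TestRunPSO:
    def test_sphere_recovered(self):
        space = square_space()
        res = run_pso(sphere, space, PSOConfig(seed=0))
        assert res.best_fitness >= -1e-3

    def test_constant_objective_flat_history(self):
        space = square_space()
        res = run_pso(lambda x: 3.5, space, PSOConfig(n_particles=5, n_iterations=10, seed=1))
        assert res.best_fitness == 3.5
        assert set(res.history) == {3.5}

    def test_evaluation_count_contract(self):
        cfg = PSOConfig(n_particles=7, n_iterations=13, seed=2)
        res = run_pso(sphere, square_space(), cfg)
        assert res.n_evaluations == 7 * (13 + 1)

    def test_fixed_seed_bit_identical(self):
        cfg = PSOConfig(n_particles=8, n_iterations=20, seed=5)
        a = run_pso(sphere, square_space(), cfg)
        b = run_pso(sphere, square_space(), cfg)
        assert a.history == b.history
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_non_finite_objective_aborts_with_position(self):
        def bad(x):
            return float("nan")

        with pytest.raises(FloatingPointError, match="position"):
            run_pso(bad, square_space(), PSOConfig(n_particles=3, n_iterations=2, seed=0))


class TestSelectionProbabilities:
    def test_uniform_under_equal_fitness(self):
        np.testing.assert_allclose(
            abc_selection_probabilities([2.0, 2.0, 2.0, 2.0]), [0.25] * 4
        )

    def test_direct_evaluation(self):
        np.testing.assert_allclose(abc_selection_probabilities([1.0, 3.0]), [0.25, 0.75])

    def test_all_zero_gives_uniform(self):
        np.testing.assert_allclose(abc_selection_probabilities([0.0, 0.0]), [0.5, 0.5])

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False, allow_infinity=False),
            min_size=1, max_size=20,
        )
    )
    def test_probability_vector_for_any_input(self, fits):
        p = abc_selection_probabilities(fits)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)


class TestNeighborhoodAndScout:
    def test_zero_step_and_zero_difference(self):
        space = square_space(5.0)
        a = FoodSource(np.array([1.0, 2.0]), 0.0)
        b = FoodSource(np.array([3.0, -1.0]), 0.0)
        np.testing.assert_array_equal(
            abc_neighborhood_move(a, b, 0.0, space, dim=0), a.position
        )
        c = FoodSource(a.position.copy(), 0.0)
        np.testing.assert_array_equal(
            abc_neighborhood_move(a, c, 0.7, space, dim=1), a.position
        )

    def test_direct_evaluation(self):
        space = SearchSpace(np.array([-5.0]), np.array([5.0]))
        a = FoodSource(np.array([1.0]), 0.0)
        b = FoodSource(np.array([0.0]), 0.0)
        out = abc_neighborhood_move(a, b, 0.5, space, dim=0)
        assert out[0] == pytest.approx(1.5)

    def test_identical_source_rejected(self):
        a = FoodSource(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            abc_neighborhood_move(a, a, 0.5, square_space(), dim=0)

    def test_only_one_dimension_perturbed(self):
        space = square_space(5.0)
        a = FoodSource(np.array([1.0, 2.0]), 0.0)
        b = FoodSource(np.array([-3.0, 4.0]), 0.0)
        out = abc_neighborhood_move(a, b, 0.9, space, dim=0)
        assert out[1] == a.position[1]
        assert out[0] != a.position[0]

    def test_scout_bounds(self):
        space = square_space(5.0)
        np.testing.assert_array_equal(
            abc_scout_position(space, np.zeros(2)), space.lower
        )
        np.testing.assert_array_equal(
            abc_scout_position(space, np.ones(2)), space.upper
        )
        mid = abc_scout_position(space, np.array([0.25, 0.75]))
        assert space.contains(mid)


class TestRunABC:
    def test_sphere_recovered(self):
        res = run_abc(sphere, square_space(), ABCConfig(seed=0))
        assert res.best_fitness >= -1e-3

    def test_incumbent_optimum_never_lost(self):
        cfg = ABCConfig(n_food_sources=5, n_iterations=20, limit=5, seed=3)
        res = run_abc(sphere, square_space(), cfg, initial_positions=[np.zeros(2)])
        assert res.best_fitness == 0.0
        assert res.history[0] == 0.0

    def test_stagnant_source_replaced_by_scout(self):
        # objective with a unique spike: every neighborhood move fails, so
        # trial counters exceed the tiny limit and scouts must fire
        calls = []

        def spiky(x):
            calls.append(np.asarray(x).copy())
            return 1.0 if np.allclose(x, 0.0) else 0.0

        cfg = ABCConfig(n_food_sources=3, n_iterations=10, limit=2, seed=4)
        res = run_abc(spiky, square_space(), cfg)
        # scout replacements add evaluations beyond employed+onlooker phases
        assert res.n_evaluations > 3 + 10 * 6
        assert len(res.history) == 11

    def test_fixed_seed_bit_identical(self):
        cfg = ABCConfig(n_food_sources=6, n_iterations=15, limit=5, seed=8)
        a = run_abc(sphere, square_space(), cfg)
        b = run_abc(sphere, square_space(), cfg)
        assert a.history == b.history

    def test_initial_positions_validated(self):
        with pytest.raises(ValueError):
            run_abc(
                sphere, square_space(), ABCConfig(seed=0),
                initial_positions=[np.array([99.0, 0.0])],
            )


class TestRunPA:
    def test_final_at_least_pso_stage(self):
        space = square_space()
        pso_cfg = PSOConfig(n_particles=10, n_iterations=20, seed=7)
        abc_cfg = ABCConfig(n_food_sources=10, n_iterations=20, limit=10, seed=8)
        pso_only = run_pso(sphere, space, pso_cfg)
        pa = run_pa(sphere, space, pso_cfg, abc_cfg)
        assert pa.best_fitness >= pso_only.best_fitness

    def test_optimum_found_by_pso_not_regressed(self):
        def peak(x):
            return -float(np.sum((np.asarray(x) - 1.0) ** 2))

        space = square_space()
        pso_cfg = PSOConfig(seed=11)
        abc_cfg = ABCConfig(n_iterations=10, seed=12)
        pa = run_pa(peak, space, pso_cfg, abc_cfg)
        assert pa.best_fitness >= run_pso(peak, space, pso_cfg).best_fitness
        np.testing.assert_allclose(pa.best_position, [1.0, 1.0], atol=1e-2)

    def test_merged_history_and_evaluations(self):
        space = square_space()
        pso_cfg = PSOConfig(n_particles=6, n_iterations=8, seed=1)
        abc_cfg = ABCConfig(n_food_sources=6, n_iterations=8, limit=50, seed=2)
        pa = run_pa(sphere, space, pso_cfg, abc_cfg)
        assert len(pa.history) == (8 + 1) + (8 + 1)
        assert pa.n_evaluations >= 6 * 9 + 6 + 2 * 6 * 8
        assert pa.best_fitness == pa.history[-1]

    def test_equal_budget_matches_pso_only_evaluations(self):
        space = square_space()
        pso_cfg = PSOConfig(seed=3)
        abc_cfg = ABCConfig(seed=4)
        pa = run_pa(sphere, space, pso_cfg, abc_cfg, equal_budget=True)
        pso_budget = 30 * 101
        assert pa.n_evaluations <= pso_budget + 60  # scout slack


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_histories_non_decreasing_all_optimizers(seed):
    space = square_space()
    rng = np.random.default_rng(seed)
    center = rng.uniform(-3, 3, size=2)

    def obj(x):
        return -float(np.sum((np.asarray(x) - center) ** 2))

    pso_cfg = PSOConfig(n_particles=8, n_iterations=25, seed=seed)
    abc_cfg = ABCConfig(n_food_sources=8, n_iterations=25, limit=6, seed=seed + 1)
    for res in (
        run_pso(obj, space, pso_cfg),
        run_abc(obj, space, abc_cfg),
        run_pa(obj, space, pso_cfg, abc_cfg),
    ):
        hist = np.asarray(res.history)
        assert np.all(np.diff(hist) >= 0)
        assert res.best_fitness == hist[-1]
        assert space.contains(res.best_position)


def test_trace_csv_has_one_row_per_iteration(tmp_path):
    res = run_pso(sphere, square_space(), PSOConfig(n_particles=5, n_iterations=7, seed=0))
    path = tmp_path / "trace.csv"
    res.to_csv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "iteration,best_fitness,x0,x1"
    assert len(lines) == 1 + len(res.history)
    last = lines[-1].split(",")
    assert float(last[1]) == res.best_fitness
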