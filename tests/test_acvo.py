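"""Unit and property tests for the anti-coronavirus optimizer."""

import numpy as np
import pytest

from acvoanfis.acvo import (
    AcvoConfig,
    ConfigurationError,
    ObjectiveError,
    Person,
    Status,
    initialize_population,
    isolation,
    optimize,
    quarantine,
    social_distancing,
)


def sphere(x):
    return float(np.sum(x * x))


class TestInitialization:
    def test_degenerate_bounds_single_person(self):
        cfg = AcvoConfig(population_size=1, bounds=((0.0, 0.0), (0.0, 0.0)))
        pop = initialize_population(cfg, sphere)
        assert len(pop) == 1
        np.testing.assert_array_equal(pop[0].position, [0.0, 0.0])

    def test_same_seed_same_population(self):
        cfg = AcvoConfig(population_size=10, bounds=((-1, 1),) * 3, rng_seed=42)
        p1 = initialize_population(cfg, sphere)
        p2 = initialize_population(cfg, sphere)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.position, b.position)
            assert a.fitness == b.fitness

    def test_fitness_is_negated_cost(self):
        cfg = AcvoConfig(population_size=30, bounds=((-2, 2),) * 2, rng_seed=0)
        pop = initialize_population(cfg, sphere)
        assert all(p.fitness <= 0 for p in pop)  # sphere cost is nonnegative

    def test_non_finite_objective_rejected(self):
        cfg = AcvoConfig(population_size=2, bounds=((-1, 1),))
        with pytest.raises(ObjectiveError):
            initialize_population(cfg, lambda x: float("nan"))


class TestOperators:
    def _population(self, positions, objective, cfg):
        return [
            Person(position=np.array(p, dtype=float), fitness=-objective(np.array(p)))
            for p in positions
        ]

    def test_social_distancing_never_degrades(self):
        cfg = AcvoConfig(population_size=4, bounds=((-5, 5),) * 2, rng_seed=3)
        rng = np.random.default_rng(3)
        pop = self._population([(1, 1), (2, 2), (-3, 0.5), (0.1, 0.2)], sphere, cfg)
        before = [p.fitness for p in pop]
        best = max(pop, key=lambda p: p.fitness)
        social_distancing(pop, best, cfg, sphere, rng)
        for b, p in zip(before, pop):
            assert p.fitness >= b
        for p in pop:
            assert np.all(p.position >= -5) and np.all(p.position <= 5)

    def test_social_distancing_at_optimum_unchanged(self):
        cfg = AcvoConfig(population_size=3, bounds=((-5, 5),) * 2, rng_seed=0)
        rng = np.random.default_rng(0)
        pop = self._population([(0, 0)] * 3, sphere, cfg)
        best = pop[0]
        social_distancing(pop, best, cfg, sphere, rng)
        assert all(p.fitness == 0 for p in pop)

    def test_quarantine_collapsed_bounds_returns_healthy(self):
        # Mutation cannot move anyone, so fitness is unchanged and the
        # inclusive (>=) release rule returns everyone healthy.
        cfg = AcvoConfig(
            population_size=3, quarantine_count=2, bounds=((1.0, 1.0),),
            mutation_fraction=1.0, rng_seed=0,
        )
        rng = np.random.default_rng(0)
        pop = self._population([(1.0,), (1.0,), (1.0,)], sphere, cfg)
        pop, infected = quarantine(pop, cfg, sphere, rng)
        assert infected == []
        assert all(p.status == Status.HEALTHY for p in pop)

    def test_quarantine_records_entry_and_classifies(self):
        cfg = AcvoConfig(
            population_size=4, quarantine_count=2, bounds=((0.0, 1.0),),
            mutation_fraction=1.0, rng_seed=9,
        )
        rng = np.random.default_rng(9)
        pop = self._population([(0.05,), (0.2,), (0.6,), (0.9,)], sphere, cfg)
        entry = {id(p): p.fitness for p in pop}
        pop, infected = quarantine(pop, cfg, sphere, rng)
        for p in pop:
            if p.status == Status.INFECTED:
                assert p.fitness < entry[id(p)]
                assert p.quarantine_entry_fitness == entry[id(p)]
            else:
                assert p.quarantine_entry_fitness is None

    def test_quarantine_count_must_be_less_than_population(self):
        cfg = AcvoConfig(population_size=3, quarantine_count=3,
                         bounds=((0, 1),))
        rng = np.random.default_rng(0)
        pop = self._population([(0.1,), (0.2,), (0.3,)], sphere, cfg)
        with pytest.raises(ConfigurationError):
            quarantine(pop, cfg, sphere, rng)

    def test_isolation_full_injection_copies_best(self):
        cfg = AcvoConfig(
            population_size=2, bounds=((-5, 5),) * 2,
            injection_fraction=1.0, rng_seed=0,
        )
        rng = np.random.default_rng(0)
        pop = self._population([(0.0, 0.0), (3.0, 4.0)], sphere, cfg)
        best, worst = pop
        worst.status = Status.INFECTED
        isolation(pop, [worst], best, cfg, sphere, rng)
        np.testing.assert_array_equal(worst.position, best.position)
        assert worst.status == Status.HEALTHY

    def test_isolation_empty_list_noop(self):
        cfg = AcvoConfig(population_size=2, bounds=((-5, 5),), rng_seed=0)
        rng = np.random.default_rng(0)
        pop = self._population([(1.0,), (2.0,)], sphere, cfg)
        before = [p.position.copy() for p in pop]
        isolation(pop, [], pop[0], cfg, sphere, rng)
        for b, p in zip(before, pop):
            np.testing.assert_array_equal(b, p.position)

    def test_isolation_never_degrades_fitness(self):
        cfg = AcvoConfig(
            population_size=3, bounds=((-5, 5),) * 4,
            injection_fraction=0.5, rng_seed=2,
        )
        rng = np.random.default_rng(2)
        pop = self._population(
            [(0, 0, 0, 0), (1, -2, 3, 0.5), (4, 4, -4, 1)], sphere, cfg
        )
        infected = pop[1:]
        for p in infected:
            p.status = Status.INFECTED
        before = [p.fitness for p in infected]
        isolation(pop, infected, pop[0], cfg, sphere, rng)
        for b, p in zip(before, infected):
            assert p.fitness >= b


class TestOptimize:
    def test_identical_seeds_identical_traces(self):
        cfg = AcvoConfig(population_size=15, max_iterations=30,
                         bounds=((-3, 3),) * 2, rng_seed=7)
        r1 = optimize(sphere, cfg)
        r2 = optimize(sphere, cfg)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.position, r2.position)

    def test_constant_objective_constant_trace(self):
        cfg = AcvoConfig(population_size=10, max_iterations=20,
                         bounds=((-1, 1),) * 2, rng_seed=1)
        r = optimize(lambda x: 2.5, cfg)
        np.testing.assert_array_equal(r.trace, np.full(20, 2.5))

    def test_trace_non_increasing_and_bounds_respected(self):
        seen = []

        def recording_sphere(x):
            seen.append(x.copy())
            return sphere(x)

        cfg = AcvoConfig(population_size=12, max_iterations=40,
                         bounds=((-0.5, 2.0),) * 3, rng_seed=5)
        r = optimize(recording_sphere, cfg)
        assert np.all(np.diff(r.trace) <= 0)
        assert len(r.trace) == 40
        for x in seen:
            assert np.all(x >= -0.5 - 1e-12) and np.all(x <= 2.0 + 1e-12)

    def test_elitist_random_search_degeneration_still_monotone(self):
        # q = N - 1 with full mutation degenerates to elitist random search
        cfg = AcvoConfig(
            population_size=6, max_iterations=50, quarantine_count=5,
            mutation_fraction=1.0, bounds=((-2, 2),) * 2, rng_seed=0,
        )
        r = optimize(sphere, cfg)
        assert np.all(np.diff(r.trace) <= 0)

    def test_quadratic_optimum_located(self):
        cfg = AcvoConfig(population_size=20, max_iterations=100,
                         bounds=((-10.0, 10.0),), rng_seed=3)
        r = optimize(lambda x: float((x[0] - 3.0) ** 2), cfg)
        assert abs(r.position[0] - 3.0) <= 0.01

    def test_trace_csv_export(self):
        cfg = AcvoConfig(population_size=8, max_iterations=5,
                         bounds=((-1, 1),), rng_seed=0)
        r = optimize(sphere, cfg)
        lines = r.trace_csv().strip().splitlines()
        assert lines[0] == "iteration,best_cost"
        assert len(lines) == 6

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            optimize(sphere, AcvoConfig(population_size=0, bounds=((-1, 1),)))
        with pytest.raises(ConfigurationError):
            optimize(sphere, AcvoConfig(bounds=((1.0, -1.0),)))
        with pytest.raises(ConfigurationError):
            optimize(sphere, AcvoConfig(bounds=None))
        with pytest.raises(ConfigurationError):
            optimize(sphere, AcvoConfig(mutation_fraction=0.0,
                                        bounds=((-1, 1),)))
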