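"""Anti-coronavirus optimization (ACVO).

A bound-constrained population metaheuristic whose operators mimic epidemic
containment protocols.  Each candidate solution is a *person*; an iteration
applies three operators:

* **social distancing** — every non-best person takes a step attracted to
  the fittest person and repelled from a randomly chosen weaker one, and
  keeps the move only if it does not lower fitness;
* **quarantine** — the ``q`` weakest persons are marked suspected, a random
  subset of their variables is resampled uniformly within bounds, and each
  is released as healthy if its fitness recovered to at least its value on
  entering quarantine, otherwise marked infected;
* **isolation** — infected persons receive a random subset of the best
  person's variables, accepted greedily, and everyone returns to healthy.

The package minimizes a cost function; internally fitness = -cost, so the
"healthiest" person is the one with the lowest cost.  Greedy acceptance plus
elitism make the best-ever cost non-increasing across iterations, and the
whole trajectory is a pure function of (objective, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]


class ConfigurationError(ValueError):
    """An optimizer configuration violates its invariants."""


class ObjectiveError(ValueError):
    """The objective returned a non-finite value."""


class Status(str, Enum):
    HEALTHY = "healthy"
    SUSPECTED = "suspected"
    INFECTED = "infected"


@dataclass
class Person:
    """One candidate solution with its health bookkeeping."""

    position: np.ndarray
    fitness: float
    status: Status = Status.HEALTHY
    quarantine_entry_fitness: float | None = None


@dataclass(frozen=True)
class AcvoConfig:
    """Optimizer knobs.

    ``bounds`` is a sequence of per-dimension ``(low, high)`` pairs and
    fixes the search box (positions are clipped to it after every
    operator).  ``quarantine_count`` defaults to ``max(1, ceil(0.2 N))``
    when left ``None``.
    """

    population_size: int = 40
    max_iterations: int = 400
    quarantine_count: int | None = None
    mutation_fraction: float = 0.3
    injection_fraction: float = 0.5
    bounds: tuple[tuple[float, float], ...] | None = None
    rng_seed: int = 0

    def resolved_quarantine_count(self) -> int:
        q = self.quarantine_count
        if q is None:
            q = max(1, math.ceil(0.2 * self.population_size))
        return q

    def validate(self) -> None:
        if self.population_size < 1:
            raise ConfigurationError("population_size must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        q = self.resolved_quarantine_count()
        if not (1 <= q < self.population_size):
            raise ConfigurationError(
                f"quarantine_count must satisfy 1 <= q < N, got q={q}, "
                f"N={self.population_size}"
            )
        if not (0 < self.mutation_fraction <= 1):
            raise ConfigurationError("mutation_fraction must be in (0, 1]")
        if not (0 < self.injection_fraction <= 1):
            raise ConfigurationError("injection_fraction must be in (0, 1]")
        if self.bounds is None or len(self.bounds) == 0:
            raise ConfigurationError("bounds must be provided")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ConfigurationError(f"bad bound ({lo}, {hi}): low > high")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for b in self.bounds], dtype=float)
        hi = np.array([b[1] for b in self.bounds], dtype=float)
        return lo, hi


def _evaluate(objective: Objective, position: np.ndarray) -> float:
    cost = float(objective(position))
    if not math.isfinite(cost):
        raise ObjectiveError(
            f"objective returned non-finite value {cost} at {position!r}"
        )
    return -cost  # fitness orientation: higher is healthier


def initialize_population(
    config: AcvoConfig,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> list[Person]:
    """Uniformly sample and evaluate N persons within the bounds."""
    if config.bounds is None or len(config.bounds) == 0:
        raise ConfigurationError("bounds must be provided")
    if config.population_size < 1:
        raise ConfigurationError("population_size must be positive")
    lo, hi = config.bounds_arrays()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    persons = []
    for _ in range(config.population_size):
        pos = rng.uniform(lo, hi)
        persons.append(Person(position=pos, fitness=_evaluate(objective, pos)))
    return persons


def _best_index(population: Sequence[Person]) -> int:
    return int(np.argmax([p.fitness for p in population]))


def social_distancing(
    population: list[Person],
    best: Person,
    config: AcvoConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> list[Person]:
    """Move each non-best person toward the best and away from a weaker
    person, keeping the move only if fitness does not decrease."""
    lo, hi = config.bounds_arrays()
    D = lo.size
    for p in population:
        if p is best:
            continue
        weaker = [o for o in population if o.fitness < p.fitness]
        if weaker:
            xw = weaker[rng.integers(len(weaker))].position
        else:
            xw = rng.uniform(lo, hi)
        r1 = rng.uniform(size=D)
        r2 = rng.uniform(size=D)
        proposal = p.position + r1 * (best.position - p.position) + r2 * (
            p.position - xw
        )
        np.clip(proposal, lo, hi, out=proposal)
        fit = _evaluate(objective, proposal)
        if fit >= p.fitness:
            p.position = proposal
            p.fitness = fit
    return population


def quarantine(
    population: list[Person],
    config: AcvoConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> tuple[list[Person], list[Person]]:
    """Mutate the q weakest persons and sort them into healthy/infected.

    Each suspected person has ``ceil(mutation_fraction * D)`` uniformly
    chosen variables resampled uniformly within bounds.  A person whose
    post-mutation fitness is at least its fitness on entering quarantine
    (the comparison is inclusive) returns healthy; otherwise it is infected
    and handed to :func:`isolation`.
    """
    q = config.resolved_quarantine_count()
    if q >= len(population):
        raise ConfigurationError("quarantine_count must be < population size")
    lo, hi = config.bounds_arrays()
    D = lo.size
    n_mut = math.ceil(config.mutation_fraction * D)
    order = np.argsort([p.fitness for p in population])
    infected: list[Person] = []
    for idx in order[:q]:
        p = population[idx]
        p.status = Status.SUSPECTED
        p.quarantine_entry_fitness = p.fitness
        idxs = rng.choice(D, size=n_mut, replace=False)
        pos = p.position.copy()
        pos[idxs] = rng.uniform(lo[idxs], hi[idxs])
        p.position = pos
        p.fitness = _evaluate(objective, pos)
        if p.fitness >= p.quarantine_entry_fitness:
            p.status = Status.HEALTHY
            p.quarantine_entry_fitness = None
        else:
            p.status = Status.INFECTED
            infected.append(p)
    return population, infected


def isolation(
    population: list[Person],
    infected: list[Person],
    best: Person,
    config: AcvoConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> list[Person]:
    """Inject variables of the best person into each infected person,
    accepting the transplant only if fitness does not decrease; all
    statuses reset to healthy afterwards."""
    if infected:
        lo, _ = config.bounds_arrays()
        D = lo.size
        n_inj = math.ceil(config.injection_fraction * D)
        for p in infected:
            idxs = rng.choice(D, size=n_inj, replace=False)
            pos = p.position.copy()
            pos[idxs] = best.position[idxs]
            fit = _evaluate(objective, pos)
            if fit >= p.fitness:
                p.position = pos
                p.fitness = fit
    for p in population:
        p.status = Status.HEALTHY
        p.quarantine_entry_fitness = None
    return population


@dataclass
class OptimizeResult:
    """Best-ever solution and per-iteration best-cost trace."""

    position: np.ndarray
    cost: float
    trace: np.ndarray  # shape (max_iterations,), non-increasing

    def trace_csv(self) -> str:
        lines = ["iteration,best_cost"]
        lines += [f"{i},{c!r}" for i, c in enumerate(self.trace)]
        return "\n".join(lines) + "\n"


def optimize(objective: Objective, config: AcvoConfig) -> OptimizeResult:
    """Run ACVO: social distancing, quarantine and isolation per iteration.

    Returns the best-ever position, its cost, and a non-increasing trace of
    the best-ever cost after each iteration.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    population = initialize_population(config, objective, rng)
    best_idx = _best_index(population)
    best_ever_pos = population[best_idx].position.copy()
    best_ever_fit = population[best_idx].fitness
    trace = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        best = population[_best_index(population)]
        social_distancing(population, best, config, objective, rng)
        population, infected = quarantine(population, config, objective, rng)
        best = population[_best_index(population)]
        isolation(population, infected, best, config, objective, rng)
        best = population[_best_index(population)]
        if best.fitness > best_ever_fit:
            best_ever_fit = best.fitness
            best_ever_pos = best.position.copy()
        trace[it] = -best_ever_fit
    return OptimizeResult(position=best_ever_pos, cost=-best_ever_fit, trace=trace)
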