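"""Box-constrained swarm optimizers: PSO, ABC, and the PSO→ABC hybrid.

All three optimizers *maximize* a user-supplied objective over a rectangular
box.  The intended application is tuning the two RBF-SVM hyperparameters
(log2 C, log2 gamma) against a cross-validated accuracy objective, but the
module is dimension-generic and is exercised on analytic benchmarks in the
test suite.

The hybrid ("PA") runs particle swarm optimization to completion and uses
its best solution to initialize the artificial bee colony's food sources,
combining PSO's exploitation with ABC's scout-driven exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "PSOConfig",
    "ABCConfig",
    "Particle",
    "FoodSource",
    "OptimizationResult",
    "pso_velocity_update",
    "pso_position_update",
    "run_pso",
    "abc_selection_probabilities",
    "abc_neighborhood_move",
    "abc_scout_position",
    "run_abc",
    "run_pa",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Rectangular search domain with per-dimension velocity clamps.

    Velocity clamps default to half the box range per dimension, a common
    PSO convention that keeps single-step moves below the domain diameter.
    """

    lower: np.ndarray
    upper: np.ndarray
    v_min: np.ndarray = None  # type: ignore[assignment]
    v_max: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lower < upper):
            raise ValueError("require lower < upper elementwise")
        v_max = self.v_max
        if v_max is None:
            v_max = 0.5 * (upper - lower)
        v_max = np.asarray(v_max, dtype=float)
        v_min = self.v_min
        if v_min is None:
            v_min = -v_max
        v_min = np.asarray(v_min, dtype=float)
        if not np.all(v_max > 0):
            raise ValueError("v_max must be strictly positive")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "v_min", v_min)
        object.__setattr__(self, "v_max", v_max)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip_position(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def clip_velocity(self, v: np.ndarray) -> np.ndarray:
        return np.clip(v, self.v_min, self.v_max)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class PSOConfig:
    """Particle swarm settings.

    Defaults follow the constriction-equivalent standard (omega = 0.729,
    c1 = c2 = 1.49445) with a population of 30 and 100 iterations.  A small
    per-iteration mutation re-randomizes one particle's position to guard
    against premature convergence; set ``mutation_prob`` to 0 to disable.
    """

    n_particles: int = 30
    n_iterations: int = 100
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    mutation_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.inertia < 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("inertia, c1, c2 must be non-negative")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")


@dataclass(frozen=True)
class ABCConfig:
    """Artificial bee colony settings (population 30, 100 iterations,
    scout limit 50 by default)."""

    n_food_sources: int = 30
    n_iterations: int = 100
    limit: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_food_sources < 2:
            raise ValueError("n_food_sources must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: float


@dataclass
class FoodSource:
    position: np.ndarray
    fitness: float
    trial_counter: int = 0


@dataclass
class OptimizationResult:
    """Best solution found, plus the per-iteration best-fitness trace.

    ``history`` is non-decreasing (maximization) and its last entry equals
    ``best_fitness``.  ``n_evaluations`` counts objective calls including
    initialization.
    """

    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    history_positions: list[np.ndarray] = field(default_factory=list)

    def to_csv(self, path) -> None:
        """Write the trace as CSV: iteration, best_fitness, best position."""
        dim = len(self.best_position)
        header = "iteration,best_fitness," + ",".join(f"x{d}" for d in range(dim))
        lines = [header]
        for i, fit in enumerate(self.history):
            pos = (
                self.history_positions[i]
                if i < len(self.history_positions)
                else self.best_position
            )
            coords = ",".join(repr(float(v)) for v in pos)
            lines.append(f"{i},{fit!r},{coords}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _check_finite(value: float, position: np.ndarray) -> float:
    if not math.isfinite(value):
        raise FloatingPointError(
            f"objective returned non-finite value {value!r} at position {position.tolist()}"
        )
    return float(value)


def pso_velocity_update(
    particle: Particle,
    global_best: np.ndarray,
    config: PSOConfig,
    r1: float,
    r2: float,
    space: SearchSpace,
) -> np.ndarray:
    """New velocity: inertia term plus cognitive and social attractions,
    clamped to [v_min, v_max]."""
    v = (
        config.inertia * particle.velocity
        + config.c1 * r1 * (particle.personal_best - particle.position)
        + config.c2 * r2 * (np.asarray(global_best) - particle.position)
    )
    return space.clip_velocity(v)


def pso_position_update(
    particle: Particle, new_velocity: np.ndarray, space: SearchSpace
) -> np.ndarray:
    """New position: current position plus velocity, clipped to the box."""
    return space.clip_position(particle.position + new_velocity)


def run_pso(
    objective: Objective, space: SearchSpace, config: PSOConfig
) -> OptimizationResult:
    """Particle swarm maximization.

    Positions and velocities are initialized uniformly within their bounds.
    Each iteration updates every particle's velocity and position, evaluates
    the objective, and refreshes personal and global bests.  With probability
    ``mutation_prob`` one uniformly chosen particle is re-randomized at the
    end of an iteration (its personal-best memory is retained); the mutated
    position is scored on the following iteration so the evaluation count
    stays at n_particles * (n_iterations + 1).
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_particles, space.dim

    positions = space.lower + rng.uniform(size=(n, d)) * space.range
    velocities = space.v_min + rng.uniform(size=(n, d)) * (space.v_max - space.v_min)
    particles = []
    n_eval = 0
    for i in range(n):
        f = _check_finite(objective(positions[i]), positions[i])
        n_eval += 1
        particles.append(
            Particle(positions[i].copy(), velocities[i].copy(), positions[i].copy(), f)
        )
    g_idx = max(range(n), key=lambda i: particles[i].personal_best_fitness)
    g_best = particles[g_idx].personal_best.copy()
    g_fit = particles[g_idx].personal_best_fitness
    history = [g_fit]
    positions = [g_best.copy()]

    for _ in range(config.n_iterations):
        for p in particles:
            r1, r2 = rng.uniform(), rng.uniform()
            p.velocity = pso_velocity_update(p, g_best, config, r1, r2, space)
            p.position = pso_position_update(p, p.velocity, space)
            f = _check_finite(objective(p.position), p.position)
            n_eval += 1
            if f > p.personal_best_fitness:
                p.personal_best = p.position.copy()
                p.personal_best_fitness = f
                if f > g_fit:
                    g_fit = f
                    g_best = p.position.copy()
        if config.mutation_prob > 0 and rng.uniform() < config.mutation_prob:
            m = int(rng.integers(n))
            particles[m].position = space.lower + rng.uniform(size=d) * space.range
            particles[m].velocity = space.v_min + rng.uniform(size=d) * (
                space.v_max - space.v_min
            )
        history.append(g_fit)
        positions.append(g_best.copy())

    return OptimizationResult(g_best, g_fit, history, n_eval, positions)


def abc_selection_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Fitness-proportional onlooker selection probabilities.

    Non-positive fitness values are handled by shifting the whole vector by
    (-min + epsilon) before normalizing; an all-equal vector (including
    all-zero) yields uniform probabilities.
    """
    fit = np.asarray(fitnesses, dtype=float)
    if fit.size == 0:
        raise ValueError("empty fitness vector")
    if np.any(fit < 0) or np.all(fit == 0):
        lo = fit.min()
        if np.all(fit == lo):
            return np.full(fit.size, 1.0 / fit.size)
        fit = fit - lo + 1e-12
    total = fit.sum()
    if total <= 0:
        return np.full(fit.size, 1.0 / fit.size)
    return fit / total


def abc_neighborhood_move(
    source_i: FoodSource,
    source_j: FoodSource,
    r: float,
    space: SearchSpace,
    dim: int | None = None,
) -> np.ndarray:
    """Candidate position x_i + r * (x_i - x_j) on one dimension.

    Only the chosen dimension is perturbed (canonical ABC); the rest are
    copied from x_i.  The result is clipped into the box.
    """
    if source_i is source_j:
        raise ValueError("neighborhood move requires two distinct food sources")
    candidate = source_i.position.copy()
    if dim is None:
        dim = 0
    candidate[dim] = source_i.position[dim] + r * (
        source_i.position[dim] - source_j.position[dim]
    )
    return space.clip_position(candidate)


def abc_scout_position(space: SearchSpace, draws: np.ndarray) -> np.ndarray:
    """Scout replacement: lower + u * (upper - lower) elementwise."""
    u = np.asarray(draws, dtype=float)
    return space.lower + u * space.range


def run_abc(
    objective: Objective,
    space: SearchSpace,
    config: ABCConfig,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizationResult:
    """Artificial bee colony maximization.

    Each iteration runs the employed phase (one greedy neighborhood proposal
    per food source), the onlooker phase (n_food_sources proposals allocated
    by fitness-proportional roulette), and the scout phase (sources whose
    trial counter exceeds ``limit`` are replaced by uniform re-sampling).
    The best-so-far solution is tracked across scout replacements.
    ``initial_positions`` may seed up to n_food_sources starting points; the
    remainder are sampled uniformly.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_food_sources, space.dim

    seeds: list[np.ndarray] = []
    if initial_positions is not None:
        if len(initial_positions) > n:
            raise ValueError("more initial positions than food sources")
        for pos in initial_positions:
            pos = np.asarray(pos, dtype=float)
            if not space.contains(pos):
                raise ValueError(f"initial position {pos.tolist()} outside the box")
            seeds.append(pos.copy())
    while len(seeds) < n:
        seeds.append(abc_scout_position(space, rng.uniform(size=d)))

    sources = []
    n_eval = 0
    for pos in seeds:
        f = _check_finite(objective(pos), pos)
        n_eval += 1
        sources.append(FoodSource(pos, f))
    g_idx = max(range(n), key=lambda i: sources[i].fitness)
    g_best = sources[g_idx].position.copy()
    g_fit = sources[g_idx].fitness
    history = [g_fit]
    positions_trace = [g_best.copy()]

    def propose(i: int) -> None:
        nonlocal n_eval, g_best, g_fit
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        r = rng.uniform(-1.0, 1.0)
        dim = int(rng.integers(d))
        cand = abc_neighborhood_move(sources[i], sources[j], r, space, dim)
        f = _check_finite(objective(cand), cand)
        n_eval += 1
        if f > sources[i].fitness:
            sources[i] = FoodSource(cand, f, 0)
            if f > g_fit:
                g_fit = f
                g_best = cand.copy()
        else:
            sources[i].trial_counter += 1

    for _ in range(config.n_iterations):
        for i in range(n):  # employed phase
            propose(i)
        probs = abc_selection_probabilities([s.fitness for s in sources])
        cum = np.cumsum(probs)
        for _ in range(n):  # onlooker phase
            i = int(np.searchsorted(cum, rng.uniform(), side="right"))
            i = min(i, n - 1)
            propose(i)
        for i in range(n):  # scout phase
            if sources[i].trial_counter > config.limit:
                pos = abc_scout_position(space, rng.uniform(size=d))
                f = _check_finite(objective(pos), pos)
                n_eval += 1
                sources[i] = FoodSource(pos, f, 0)
                if f > g_fit:
                    g_fit = f
                    g_best = pos.copy()
        history.append(g_fit)
        positions_trace.append(g_best.copy())

    return OptimizationResult(g_best, g_fit, history, n_eval, positions_trace)


def pa_seed_positions(
    best: np.ndarray, space: SearchSpace, n_sources: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Food-source seeds for the hybrid: source 0 is the PSO best verbatim;
    sources 1..ceil(N/2) perturb it by up to +/-10% of each dimension's
    range; the remainder is left for uniform scout sampling."""
    seeds = [np.asarray(best, dtype=float).copy()]
    n_perturbed = math.ceil(n_sources / 2)
    for _ in range(n_perturbed):
        delta = rng.uniform(-0.1, 0.1, size=space.dim) * space.range
        seeds.append(space.clip_position(best + delta))
    return seeds[:n_sources]


def run_pa(
    objective: Objective,
    space: SearchSpace,
    pso_config: PSOConfig,
    abc_config: ABCConfig,
    equal_budget: bool = False,
) -> OptimizationResult:
    """PSO→ABC hybrid: PSO runs to completion and its best solution seeds
    the ABC food sources; the combined best is returned.

    By default the two stages run their full configured budgets
    (n_iterations each).  With ``equal_budget=True`` the stages are scaled
    so the hybrid's total evaluation count approximately matches a
    PSO-only run of ``pso_config`` (PSO gets half its iterations, ABC the
    evaluations that remain), which makes head-to-head benchmark
    comparisons evaluation-fair.

    The merged history (PSO trace then ABC trace) is non-decreasing because
    the incumbent PSO best enters ABC as food source 0 and greedy
    acceptance never discards the best-so-far.
    """
    if equal_budget:
        budget = pso_config.n_particles * (pso_config.n_iterations + 1)
        pso_iters = max(1, pso_config.n_iterations // 2)
        pso_config = PSOConfig(
            pso_config.n_particles,
            pso_iters,
            pso_config.inertia,
            pso_config.c1,
            pso_config.c2,
            pso_config.mutation_prob,
            pso_config.seed,
        )
        pso_evals = pso_config.n_particles * (pso_iters + 1)
        n = abc_config.n_food_sources
        abc_iters = max(1, (budget - pso_evals - n) // (2 * n))
        abc_config = ABCConfig(n, abc_iters, abc_config.limit, abc_config.seed)

    pso_result = run_pso(objective, space, pso_config)
    rng = np.random.default_rng(abc_config.seed)
    seeds = pa_seed_positions(
        pso_result.best_position, space, abc_config.n_food_sources, rng
    )
    abc_result = run_abc(objective, space, abc_config, initial_positions=seeds)

    best_fit = abc_result.best_fitness
    best_pos = abc_result.best_position
    if pso_result.best_fitness > best_fit:  # defensive; seeding makes this impossible
        best_fit = pso_result.best_fitness
        best_pos = pso_result.best_position
    return OptimizationResult(
        best_pos,
        best_fit,
        pso_result.history + abc_result.history,
        pso_result.n_evaluations + abc_result.n_evaluations,
        pso_result.history_positions + abc_result.history_positions,
    )
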