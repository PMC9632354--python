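"""Real-coded genetic algorithm for the GRNN smoothing factor.

The chromosome is the single real gene sigma, searched on a bounded
interval (default (0, 2], opened at zero because the Gaussian kernel is
undefined there).  One generation applies tournament selection (k = 3),
arithmetic blend crossover, Gaussian mutation with standard deviation 5%
of the bound width (clipped back into bounds) and elitism of one, so the
best fitness seen is non-increasing across generations.

Two stopping rules are available.  The default ``threshold_and_stall``
stops at the generation cap, or earlier once the best fitness is at or
below the threshold and has not improved for ``stall_generations``.  The
``literal`` rule instead insists on *both* reaching the generation cap and
driving the population's mean fitness below the threshold, continuing past
the cap (up to a 10x hard ceiling) until the mean condition holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OptimizationError

__all__ = ["GAConfig", "GAResult", "optimize", "evolve_generation"]


@dataclass(frozen=True)
class GAConfig:
    population: int = 80
    p_crossover: float = 0.7
    p_mutation: float = 0.25
    max_generations: int = 200
    bounds: tuple[float, float] = (0.0, 2.0)
    epsilon: float = 1e-6  # opens the lower bound
    fitness_threshold: float = 0.03
    stall_generations: int = 25
    stopping: str = "threshold_and_stall"  # or "literal"
    tournament_k: int = 3
    mutation_sd_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0.0 <= self.p_crossover <= 1.0 and 0.0 <= self.p_mutation <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.stopping not in ("threshold_and_stall", "literal"):
            raise ValueError("stopping must be 'threshold_and_stall' or 'literal'")

    @property
    def low(self) -> float:
        return self.bounds[0] + self.epsilon

    @property
    def high(self) -> float:
        return self.bounds[1]


@dataclass
class GAResult:
    best_sigma: float
    best_fitness: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (best, mean)
    generations_run: int = 0


def _evaluate(fitness, sigma: float, cache: dict) -> float:
    if sigma in cache:
        return cache[sigma]
    value = float(fitness(sigma))
    if not np.isfinite(value):
        raise OptimizationError(f"fitness returned non-finite value at sigma={sigma}")
    cache[sigma] = value
    return value


def evolve_generation(
    population: np.ndarray,
    fitnesses: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce the next population: elitism of one plus selected, crossed
    and mutated children.  Population size is preserved."""
    pop = np.asarray(population, dtype=float)
    fit = np.asarray(fitnesses, dtype=float)
    if len(pop) != len(fit):
        raise ValueError("population and fitnesses must align")
    n = len(pop)

    def tournament() -> float:
        idx = rng.integers(0, n, size=config.tournament_k)
        return pop[idx[np.argmin(fit[idx])]]

    children = [pop[np.argmin(fit)]]  # elite survives unchanged
    while len(children) < n:
        p1, p2 = tournament(), tournament()
        if rng.random() < config.p_crossover:
            alpha = rng.random()
            child = alpha * p1 + (1.0 - alpha) * p2
        else:
            child = p1
        if rng.random() < config.p_mutation:
            child = child + rng.normal(
                0.0, config.mutation_sd_frac * (config.high - config.bounds[0])
            )
        children.append(float(np.clip(child, config.low, config.high)))
    return np.array(children)


def optimize(fitness, config: GAConfig | None = None) -> GAResult:
    """Search the smoothing-factor interval for the fitness minimum.

    ``fitness`` maps sigma to a finite mean squared error.  Evaluations are
    memoized, the same seed reproduces the identical run, and every
    individual stays inside the (epsilon-opened) bounds.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    cache: dict[float, float] = {}

    pop = rng.uniform(config.low, config.high, size=config.population)
    best_sigma, best_fit = np.nan, np.inf
    stall = 0
    history: list[tuple[float, float]] = []
    hard_cap = (
        config.max_generations
        if config.stopping == "threshold_and_stall"
        else 10 * config.max_generations
    )

    gen = 0
    while gen < hard_cap:
        fits = np.array([_evaluate(fitness, s, cache) for s in pop])
        gen += 1
        gen_best = float(fits.min())
        if gen_best < best_fit:
            best_fit = gen_best
            best_sigma = float(pop[np.argmin(fits)])
            stall = 0
        else:
            stall += 1
        history.append((best_fit, float(fits.mean())))

        if config.stopping == "threshold_and_stall":
            if best_fit <= config.fitness_threshold and stall >= config.stall_generations:
                break
        else:  # literal: generation cap AND mean below threshold
            if gen >= config.max_generations and float(fits.mean()) < config.fitness_threshold:
                break
        if gen >= hard_cap:
            break
        pop = evolve_generation(pop, fits, config, rng)

    return GAResult(
        best_sigma=best_sigma,
        best_fitness=best_fit,
        history=history,
        generations_run=gen,
    )
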