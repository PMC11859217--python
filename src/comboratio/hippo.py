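"""Hippopotamus Optimization (HO) for bound-constrained minimization.

A population metaheuristic with two phases per iteration:

* **Exploration** — the first half of the herd ("male" hippos) moves toward
  the dominant (best-fitness) member; the second half ("female/immature")
  moves relative to the mean position of a random sub-herd, switching
  between a mean-seeking move and uniform re-sampling of the search box
  once the schedule variable T = exp(-iter/iterations) falls below the
  threshold (default 0.6).
* **Predator defense** — each hippo reacts to a predator sampled uniformly
  in the box, combining a Levy-flight step around the predator with an
  inverse-distance repulsion whose strength depends on whether the
  predator's fitness beats the hippo's.

Moves are greedily accepted (a candidate replaces a hippo only if its
fitness improves), so the best-so-far fitness is monotone non-increasing.
All positions are clamped to the bounds after every move, and every draw
comes from a single seeded generator, making runs fully deterministic.

The original algorithm's third (escape) phase — a shrinking local search
around each member — is available behind ``enable_escape_phase`` and off by
default.

The module also provides a hyperparameter-tuning adapter searching
(learning rate, epoch count) for the dose-effect classifier, with the
learning rate explored on a log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOConfig",
    "Hippo",
    "OptimizeResult",
    "initialize_population",
    "exploration_phase",
    "defense_phase",
    "optimize",
    "tune_hyperparameters",
    "LEARNING_RATE_BOUNDS",
    "EPOCH_BOUNDS",
]

#: hyperparameter search ranges for the tuning adapter
LEARNING_RATE_BOUNDS = (1e-5, 1e-2)
EPOCH_BOUNDS = (100, 1000)


@dataclass(frozen=True)
class HOConfig:
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]
    population: int = 30
    iterations: int = 100
    t_threshold: float = 0.6
    seed: int = 0
    levy_beta: float = 1.5
    enable_escape_phase: bool = False

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower_bounds), np.asarray(self.upper_bounds)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D and of equal length")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if self.population < 2:
            raise ValueError(f"population must be >= 2, got {self.population}")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")

    @property
    def dim(self) -> int:
        return len(self.lower_bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower_bounds, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.upper_bounds, dtype=float)


@dataclass
class Hippo:
    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: tuple[float, ...]  # per-iteration best fitness
    evaluations: int

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.history) + 1),
             "best_fitness": self.history}
        )


Objective = Callable[[np.ndarray], float]


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    try:
        return float(objective(x))
    except Exception as exc:  # re-raise with position context
        raise RuntimeError(f"objective failed at position {x!r}") from exc


def _clamp(x: np.ndarray, config: HOConfig) -> np.ndarray:
    return np.minimum(np.maximum(x, config.lo), config.hi)


def initialize_population(
    config: HOConfig,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> list[Hippo]:
    """Uniform initialization within the bounds, fitness evaluated per member."""
    rng = rng or np.random.default_rng(config.seed)
    pop = []
    for _ in range(config.population):
        x = config.lo + rng.uniform(size=config.dim) * (config.hi - config.lo)
        pop.append(Hippo(position=x, fitness=_evaluate(objective, x)))
    return pop


def _h_scenario(rng: np.random.Generator, dim: int) -> np.ndarray:
    """Random move-scale vector drawn from the reference scenario set."""
    scenario = rng.integers(0, 5)
    i_rand = rng.integers(1, 3)  # in {1, 2}
    q = rng.integers(0, 2)
    if scenario == 0:
        return i_rand * rng.uniform(size=dim) + (1 - q)
    if scenario == 1:
        return 2.0 * rng.uniform(size=dim) - 1.0
    if scenario == 2:
        return rng.uniform(size=dim)
    if scenario == 3:
        return i_rand * rng.uniform(size=dim) + q
    return np.full(dim, rng.uniform())


def _mean_of_random_subgroup(population: list[Hippo], rng: np.random.Generator) -> np.ndarray:
    size = int(rng.integers(1, len(population) + 1))
    idx = rng.choice(len(population), size=size, replace=False)
    return np.mean([population[i].position for i in idx], axis=0)


def _greedy(hippo: Hippo, candidate: np.ndarray, objective: Objective,
            config: HOConfig) -> int:
    """Accept a candidate move only if it improves fitness; returns evals used."""
    cand = _clamp(candidate, config)
    f = _evaluate(objective, cand)
    if f < hippo.fitness:
        hippo.position = cand
        hippo.fitness = f
    return 1


def exploration_phase(
    population: list[Hippo],
    best: Hippo,
    objective: Objective,
    config: HOConfig,
    rng: np.random.Generator,
    t_value: float = 1.0,
) -> int:
    """One exploration sweep; mutates the population in place, returns evals."""
    evals = 0
    dim = config.dim
    d_pos = best.position
    half = len(population) // 2
    for i, hippo in enumerate(population):
        x = hippo.position
        if i < half:
            # dominant-seeking move of the male herd
            y1 = rng.uniform(size=dim)
            i1 = rng.integers(1, 3)
            candidate = x + y1 * (d_pos - i1 * x)
        else:
            mg = _mean_of_random_subgroup(population, rng)
            if t_value > config.t_threshold:
                h1 = _h_scenario(rng, dim)
                i2 = rng.integers(1, 3)
                candidate = x + h1 * (d_pos - i2 * mg)
            else:
                if rng.uniform() > 0.5:
                    h2 = _h_scenario(rng, dim)
                    candidate = x + h2 * (mg - d_pos)
                else:
                    candidate = config.lo + rng.uniform(size=dim) * (config.hi - config.lo)
        evals += _greedy(hippo, candidate, objective, config)
    return evals


def _levy(rng: np.random.Generator, dim: int, beta: float) -> np.ndarray:
    """Mantegna Levy-flight step of index beta."""
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma_u = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return 0.05 * u / np.abs(v) ** (1 / beta)


def defense_phase(
    population: list[Hippo],
    objective: Objective,
    config: HOConfig,
    rng: np.random.Generator,
) -> int:
    """One predator-defense sweep; mutates the population, returns evals."""
    evals = 0
    dim = config.dim
    for hippo in population:
        predator = config.lo + rng.uniform(size=dim) * (config.hi - config.lo)
        f_pred = _evaluate(objective, predator)
        evals += 1
        dist = np.maximum(np.abs(predator - hippo.position), 1e-12)
        rl = _levy(rng, dim, config.levy_beta)
        c = rng.uniform(2.0, 4.0)
        d = rng.uniform(1.0, 1.5)
        g = rng.uniform(-1.0, 1.0)
        gain = 1.0 / (c - d * math.cos(2 * math.pi * g))
        if f_pred < hippo.fitness:
            candidate = rl * predator + gain * (1.0 / dist)
        else:
            r9 = rng.uniform(size=dim)
            candidate = rl * predator + gain * (1.0 / (2.0 * dist + r9))
        evals += _greedy(hippo, candidate, objective, config)
    return evals


def _escape_phase(
    population: list[Hippo],
    objective: Objective,
    config: HOConfig,
    rng: np.random.Generator,
    iteration: int,
) -> int:
    """Shrinking local search around each member (off by default)."""
    evals = 0
    dim = config.dim
    width = (config.hi - config.lo) / iteration
    for hippo in population:
        s1 = rng.uniform(size=dim)
        candidate = hippo.position + rng.uniform() * (-width / 2 + s1 * width)
        evals += _greedy(hippo, candidate, objective, config)
    return evals


def optimize(objective: Objective, config: HOConfig) -> OptimizeResult:
    """Run the full HO loop; history is the per-iteration best fitness."""
    rng = np.random.default_rng(config.seed)
    population = initialize_population(config, objective, rng)
    best = min(population, key=lambda h: h.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    evals = len(population)
    history: list[float] = []
    for it in range(1, config.iterations + 1):
        t_value = math.exp(-it / max(config.iterations, 1))
        evals += exploration_phase(population, Hippo(best_pos, best_fit),
                                   objective, config, rng, t_value)
        evals += defense_phase(population, objective, config, rng)
        if config.enable_escape_phase:
            evals += _escape_phase(population, objective, config, rng, it)
        it_best = min(population, key=lambda h: h.fitness)
        if it_best.fitness < best_fit:
            best_pos, best_fit = it_best.position.copy(), it_best.fitness
        history.append(best_fit)
    return OptimizeResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=tuple(history),
        evaluations=evals,
    )


def tune_hyperparameters(
    train_and_score: Callable[[float, int], float],
    population: int = 30,
    iterations: int = 50,
    seed: int = 0,
) -> tuple[float, int, OptimizeResult]:
    """Search (learning rate, epochs) minimizing a validation score.

    The learning-rate dimension is explored on a log10 scale over
    [1e-5, 1e-2]; the epoch dimension over [100, 1000] and rounded to an
    integer before each evaluation.
    """
    lr_lo, lr_hi = LEARNING_RATE_BOUNDS
    ep_lo, ep_hi = EPOCH_BOUNDS

    def objective(x: np.ndarray) -> float:
        lr = 10.0 ** x[0]
        epochs = int(round(x[1]))
        return train_and_score(lr, epochs)

    config = HOConfig(
        lower_bounds=(math.log10(lr_lo), float(ep_lo)),
        upper_bounds=(math.log10(lr_hi), float(ep_hi)),
        population=population,
        iterations=iterations,
        seed=seed,
    )
    result = optimize(objective, config)
    lr = float(10.0 ** result.best_position[0])
    epochs = int(round(result.best_position[1]))
    return lr, epochs, result
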