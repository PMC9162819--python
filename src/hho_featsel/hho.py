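"""Harris hawks optimization (HHO).

A population-based, gradient-free metaheuristic modelled on the cooperative
hunting behaviour of Harris' hawks.  A flock of M "hawks" (candidate
solutions) pursues a "victim" (the best solution found so far) inside a
bounded search box.  Each iteration the victim's *escaping energy*

    G = 2 * G0 * (1 - i / I),        G0 ~ U[-1, 1]

decays toward zero; its magnitude selects the search regime:

* ``|G| >= 1``   exploration — hawks perch at random or relative locations;
* ``|G| >= 0.5`` soft besiege — circle the victim, optionally with
  Lévy-flight "progressive rapid dives";
* ``|G| < 0.5``  hard besiege — pounce directly at the victim, again with a
  dive variant when the victim is still likely to escape (q < 0.5).

Absolute-value bars in the update rules follow the original HHO
formulation.  Positions leaving the box are clipped componentwise.  Greedy
acceptance inside the dive strategies uses strict ``<`` (ties keep the
incumbent); the plain exploration/besiege rules replace the hawk's position
unconditionally, as in the original algorithm.

All randomness flows through one ``numpy.random.Generator`` per optimizer
run, with a fixed draw order (documented on each operation), so a seed fully
determines the trajectory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "HawkPopulation",
    "OptimizationResult",
    "escaping_energy",
    "levy_sigma",
    "levy_flight",
    "init_population",
    "mean_position",
    "exploration_step",
    "soft_besiege",
    "hard_besiege",
    "soft_besiege_dives",
    "hard_besiege_dives",
    "hho_optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box ``[lower, upper]`` that candidate positions live in."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.ndim != 1 or upper.shape != lower.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def cube(cls, dim: int, lower: float, upper: float) -> "SearchSpace":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters: population size M, iteration budget I, box, Lévy β."""

    pop_size: int
    max_iter: int
    space: SearchSpace
    beta: float = 1.5
    seed: int | None = None
    lf_scale: float = 0.01
    track_branches: bool = False

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if not (1.0 < self.beta <= 2.0):
            raise ValueError("beta must lie in (1, 2]")


@dataclass
class HawkPopulation:
    """M hawk positions with their fitness and the best ("victim") solution."""

    positions: np.ndarray  # (M, D)
    fitness: np.ndarray  # (M,)
    best_position: np.ndarray  # (D,)
    best_fitness: float

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def update_best(self, position: np.ndarray, fitness: float) -> None:
        # strict improvement only: ties keep the incumbent victim
        if fitness < self.best_fitness:
            self.best_position = position.copy()
            self.best_fitness = float(fitness)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray  # best-so-far after each iteration, length I
    evaluations: int
    branch_log: list[tuple[int, int, str, float]] = field(default_factory=list)
    # branch_log entries: (iteration, hawk, branch name, escaping energy G)

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_position": self.best_position.tolist(),
                "best_fitness": self.best_fitness,
                "fitness_history": self.fitness_history.tolist(),
                "evaluations": self.evaluations,
            }
        )


def escaping_energy(g0: float, iteration: int, max_iter: int) -> float:
    """Victim escaping energy ``G = 2*G0*(1 - i/I)``.

    ``G0`` is the initial energy in [-1, 1]; the linear decay drives the
    exploration→exploitation handover.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    if not 0 <= iteration <= max_iter:
        raise ValueError(f"iteration {iteration} outside [0, {max_iter}]")
    return 2.0 * g0 * (1.0 - iteration / max_iter)


def levy_sigma(beta: float) -> float:
    """Mantegna scale sigma for a Lévy-stable step of index beta."""
    if not (1.0 < beta <= 2.0):
        raise ValueError("beta must lie in (1, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_flight(
    dim: int, rng: np.random.Generator, beta: float = 1.5, scale: float = 0.01
) -> np.ndarray:
    """Heavy-tailed Lévy-flight step vector via the Mantegna construction.

    Per component: ``scale * u / |v|**(1/beta)`` with ``u ~ N(0, sigma^2)``
    and ``v ~ N(0, 1)``.  Draw order: the u vector, then the v vector.
    """
    sigma = levy_sigma(beta)
    u = sigma * rng.standard_normal(dim)
    v = rng.standard_normal(dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


def init_population(
    config: OptimizerConfig,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> HawkPopulation:
    """Draw M positions uniformly in the box and evaluate each."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = config.space.sample(rng, config.pop_size)
    fitness = np.empty(config.pop_size)
    for k in range(config.pop_size):
        f = float(objective(positions[k]))
        if not math.isfinite(f):
            raise ValueError(
                f"objective returned non-finite value {f!r} at initial point "
                f"{positions[k].tolist()}"
            )
        fitness[k] = f
    best = int(np.argmin(fitness))
    return HawkPopulation(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
    )


def mean_position(pop: HawkPopulation) -> np.ndarray:
    """Average location of the current flock (used by exploration and the
    hard-besiege dive)."""
    if pop.positions.shape[0] < 1:
        raise ValueError("population is empty")
    return pop.positions.mean(axis=0)


def exploration_step(
    pop: HawkPopulation,
    hawk_index: int,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploration (perching) update, taken while ``|G| >= 1``.

    With chance c >= 0.5 the hawk perches relative to a random flock member,
    otherwise relative to the victim and the flock mean.  Draw order: random
    hawk index, then the five uniforms c, n1..n4.
    """
    r_idx = int(rng.integers(pop.size))
    c, n1, n2, n3, n4 = rng.random(5)
    current = pop.positions[hawk_index]
    if c >= 0.5:
        c_rand = pop.positions[r_idx]
        new = c_rand - n1 * np.abs(c_rand - 2.0 * n2 * current)
    else:
        c_avg = mean_position(pop)
        new = (pop.best_position - c_avg) - n3 * (
            space.lower + n4 * (space.upper - space.lower)
        )
    return space.clip(new)


def soft_besiege(
    current: np.ndarray,
    victim: np.ndarray,
    energy: float,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Soft besiege (``|G| >= 0.5``, q >= 0.5): circle the still-energetic
    victim.  S = 2(1 - n5) models the victim's jump strength; one uniform n5
    is drawn."""
    n5 = rng.random()
    s = 2.0 * (1.0 - n5)
    delta = victim - current
    new = delta - energy * np.abs(s * victim - current)
    return space.clip(new)


def hard_besiege(
    current: np.ndarray,
    victim: np.ndarray,
    energy: float,
    space: SearchSpace,
) -> np.ndarray:
    """Hard besiege (``|G| < 0.5``, q >= 0.5): pounce straight at the
    exhausted victim.  Deterministic given G."""
    delta = victim - current
    new = victim - energy * np.abs(delta)
    return space.clip(new)


def _eval_or_inf(objective: Objective, x: np.ndarray) -> float:
    f = float(objective(x))
    return f if math.isfinite(f) else math.inf


def soft_besiege_dives(
    current: np.ndarray,
    current_fitness: float,
    victim: np.ndarray,
    energy: float,
    objective: Objective,
    space: SearchSpace,
    rng: np.random.Generator,
    beta: float = 1.5,
    lf_scale: float = 0.01,
) -> tuple[np.ndarray, float, int]:
    """Soft besiege with progressive rapid dives (``|G| >= 0.5``, q < 0.5).

    The hawk first tries the direct move A; if that does not strictly improve
    its own fitness it tries a Lévy-flight dive B around A; if neither
    improves, it stays put.  Draw order: n5, then (only if A is rejected) the
    componentwise dive weights V ~ U[0,1]^D, then the Lévy vector.

    Returns ``(position, fitness, objective evaluations used)``.  A non-finite
    objective value at A or B is treated as worse than the current position.
    """
    n5 = rng.random()
    s = 2.0 * (1.0 - n5)
    a = space.clip(victim - energy * np.abs(s * victim - current))
    f_a = _eval_or_inf(objective, a)
    if f_a < current_fitness:
        return a, f_a, 1
    v = rng.random(current.size)
    b = space.clip(a + v * levy_flight(current.size, rng, beta, lf_scale))
    f_b = _eval_or_inf(objective, b)
    if f_b < current_fitness:
        return b, f_b, 2
    return current, current_fitness, 2


def hard_besiege_dives(
    current: np.ndarray,
    current_fitness: float,
    victim: np.ndarray,
    flock_mean: np.ndarray,
    energy: float,
    objective: Objective,
    space: SearchSpace,
    rng: np.random.Generator,
    beta: float = 1.5,
    lf_scale: float = 0.01,
) -> tuple[np.ndarray, float, int]:
    """Hard besiege with progressive rapid dives (``|G| < 0.5``, q < 0.5).

    Identical to the soft variant except the direct move A is anchored on the
    flock mean rather than the hawk's own position: the flock closes in on
    the victim collectively.
    """
    n5 = rng.random()
    s = 2.0 * (1.0 - n5)
    a = space.clip(victim - energy * np.abs(s * victim - flock_mean))
    f_a = _eval_or_inf(objective, a)
    if f_a < current_fitness:
        return a, f_a, 1
    v = rng.random(current.size)
    b = space.clip(a + v * levy_flight(current.size, rng, beta, lf_scale))
    f_b = _eval_or_inf(objective, b)
    if f_b < current_fitness:
        return b, f_b, 2
    return current, current_fitness, 2


def hho_optimize(objective: Objective, config: OptimizerConfig) -> OptimizationResult:
    """Run the full HHO loop and return the best solution found.

    Per iteration i and hawk k: draw G0 ~ U[-1, 1], compute the escaping
    energy G; if ``|G| >= 1`` take an exploration step, otherwise draw the
    escape chance q ~ U[0, 1] and dispatch to one of the four besiege
    strategies.  Draw order per hawk: G0, then (exploitation only) q, then the
    strategy's own draws.  Best-so-far fitness is recorded after every
    iteration; the history is monotonically non-increasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    space = config.space
    pop = init_population(config, objective, rng)
    evaluations = pop.size
    history = np.empty(config.max_iter)
    branch_log: list[tuple[int, int, str, float]] = []

    for i in range(config.max_iter):
        for k in range(pop.size):
            g0 = rng.uniform(-1.0, 1.0)
            g = escaping_energy(g0, i, config.max_iter)
            if abs(g) >= 1.0:
                branch = "exploration"
                new = exploration_step(pop, k, space, rng)
                f_new = _eval_or_inf(objective, new)
                evaluations += 1
            else:
                q = rng.random()
                if abs(g) >= 0.5 and q >= 0.5:
                    branch = "soft_besiege"
                    new = soft_besiege(pop.positions[k], pop.best_position, g, space, rng)
                    f_new = _eval_or_inf(objective, new)
                    evaluations += 1
                elif abs(g) < 0.5 and q >= 0.5:
                    branch = "hard_besiege"
                    new = hard_besiege(pop.positions[k], pop.best_position, g, space)
                    f_new = _eval_or_inf(objective, new)
                    evaluations += 1
                elif abs(g) >= 0.5:
                    branch = "soft_dive"
                    new, f_new, used = soft_besiege_dives(
                        pop.positions[k],
                        float(pop.fitness[k]),
                        pop.best_position,
                        g,
                        objective,
                        space,
                        rng,
                        config.beta,
                        config.lf_scale,
                    )
                    evaluations += used
                else:
                    branch = "hard_dive"
                    new, f_new, used = hard_besiege_dives(
                        pop.positions[k],
                        float(pop.fitness[k]),
                        pop.best_position,
                        mean_position(pop),
                        g,
                        objective,
                        space,
                        rng,
                        config.beta,
                        config.lf_scale,
                    )
                    evaluations += used
            if math.isfinite(f_new):
                pop.positions[k] = new
                pop.fitness[k] = f_new
                pop.update_best(new, f_new)
            if config.track_branches:
                branch_log.append((i, k, branch, g))
        history[i] = pop.best_fitness

    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        fitness_history=history,
        evaluations=evaluations,
        branch_log=branch_log,
    )
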