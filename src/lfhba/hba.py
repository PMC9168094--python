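"""Continuous Honey Badger Algorithm (HBA).

The honey badger algorithm is a population metaheuristic that mimics the
foraging behaviour of the honey badger.  Each candidate solution ("badger")
is updated either by a *digging* move — a cardioid-shaped exploitation step
around the best solution found so far (the "prey"), scaled by a scent
intensity that follows an inverse-square law — or by a *honey* move, a
guided step toward the prey.  A density factor ``alpha = C * exp(-t/t_max)``
decays over iterations, shifting the search from exploration to
exploitation.  The algorithm minimizes; callers wanting maximization negate
their objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "HbaConfig",
    "Population",
    "init_population",
    "intensity",
    "density_factor",
    "direction_flag",
    "digging_update",
    "honey_update",
    "hba_minimize",
]

#: Floor for the squared prey distance in the intensity inverse-square law.
EPS_DISTANCE = 1e-12


@dataclass(frozen=True)
class Bounds:
    """Box constraints ``[lower, upper]^dim`` for the search space.

    ``lower`` and ``upper`` may be scalars (broadcast over ``dim``) or
    per-dimension arrays.
    """

    lower: np.ndarray
    upper: np.ndarray
    dim: int

    def __init__(self, lower, upper, dim: int | None = None):
        lo = np.atleast_1d(np.asarray(lower, dtype=float))
        hi = np.atleast_1d(np.asarray(upper, dtype=float))
        if dim is None:
            dim = max(lo.size, hi.size)
        if dim < 1:
            raise ValueError(f"dim must be >= 1, got {dim}")
        lo = np.broadcast_to(lo, (dim,)).copy()
        hi = np.broadcast_to(hi, (dim,)).copy()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "dim", int(dim))

    def clamp(self, x: np.ndarray) -> np.ndarray:
        """Project positions back into the box (element-wise clip)."""
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class HbaConfig:
    """Tuning knobs of the honey badger search.

    pop_size
        Number of badgers ``N`` (default 50).
    max_iters
        Iteration budget ``t_max`` (default 1000).
    density_constant
        ``C >= 1`` in the decay ``alpha = C * exp(-t/t_max)`` (default 2).
    ability
        Food-finding ability ``beta >= 1`` scaling the digging pull toward
        the prey (default 6).  Distinct from the Levy tail exponent.
    """

    pop_size: int = 50
    max_iters: int = 1000
    density_constant: float = 2.0
    ability: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if self.density_constant < 1:
            raise ValueError("density_constant must be >= 1")
        if self.ability < 1:
            raise ValueError("ability must be >= 1")


@dataclass
class Population:
    """Optimizer state: positions, their fitnesses, and the incumbent best."""

    positions: np.ndarray  # (N, dim)
    fitnesses: np.ndarray  # (N,)
    best_position: np.ndarray = field(default=None)  # type: ignore[assignment]
    best_fitness: float = np.inf

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        if self.best_position is None:
            i = int(np.argmin(self.fitnesses))
            self.best_position = self.positions[i].copy()
            self.best_fitness = float(self.fitnesses[i])

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def update_best(self) -> None:
        """Pull the incumbent best forward if any member improved on it."""
        i = int(np.argmin(self.fitnesses))
        if self.fitnesses[i] < self.best_fitness:
            self.best_fitness = float(self.fitnesses[i])
            self.best_position = self.positions[i].copy()


def init_population(
    bounds: Bounds,
    config: HbaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the initial N x dim position matrix, ``x = lb + r1 * (ub - lb)``.

    Each coordinate uses a fresh uniform(0, 1) draw, so the population is
    uniform over the box.
    """
    r1 = rng.uniform(size=(config.pop_size, bounds.dim))
    return bounds.lower + r1 * (bounds.upper - bounds.lower)


def intensity(
    positions: np.ndarray,
    prey: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scent intensity of the prey as perceived by each badger, per coordinate.

    ``I_ij = r2_i * S_ij / (4 pi d_ij^2)`` with attention force
    ``S_ij = (x_ij - x_{i+1,j})^2`` (the neighbour index wraps cyclically),
    ``d_ij = prey_j - x_ij``, and one fresh uniform ``r2`` per badger.  All
    squares are element-wise, so the intensity is an N x dim matrix and
    each coordinate carries its own scent signal — the form of the source
    honey badger algorithm.  Squared distances are floored at
    ``EPS_DISTANCE`` so a badger sitting on the prey still sees finite
    intensity.
    """
    positions = np.atleast_2d(positions)
    s = (positions - np.roll(positions, -1, axis=0)) ** 2
    d2 = (prey - positions) ** 2
    r2 = rng.uniform(size=positions.shape[0])[:, None]
    return r2 * s / (4.0 * np.pi * np.maximum(d2, EPS_DISTANCE))


def density_factor(t: int, t_max: int, C: float = 2.0) -> float:
    """Time-decaying randomness scale ``alpha = C * exp(-t / t_max)``.

    Strictly decreasing in ``t``; equals ``C`` at t=0 and ``C/e`` at t=t_max.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    return C * np.exp(-t / t_max)


def direction_flag(rng: np.random.Generator) -> int:
    """Fair coin for the search direction: +1 iff r6 <= 0.5, else -1."""
    return 1 if rng.uniform() <= 0.5 else -1


def digging_update(
    x: np.ndarray,
    prey: np.ndarray,
    I: float,
    alpha: float,
    flag: int,
    ability: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cardioid digging move around the prey.

    ``x_new = prey + F*beta*I*prey + F*r3*alpha*d*|cos(2 pi r4)*(1 - cos(2 pi r5))|``
    with ``d = prey - x``.  The uniforms r3, r4, r5 are drawn fresh per
    coordinate (the element-wise form of the source algorithm), and ``I``
    may be scalar or per-coordinate; the trigonometric factor is taken in
    absolute value so the direction flag F alone carries the sign.  The
    caller clamps the result to bounds.
    """
    x = np.asarray(x, dtype=float)
    r3, r4, r5 = rng.uniform(size=(3,) + x.shape)
    d = prey - x
    trig = np.abs(np.cos(2 * np.pi * r4) * (1 - np.cos(2 * np.pi * r5)))
    return prey + flag * ability * I * prey + flag * r3 * alpha * d * trig


def honey_update(
    x: np.ndarray,
    prey: np.ndarray,
    alpha: float,
    flag: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Honey-guided move toward the prey: ``x_new = prey + F*r7*alpha*d``.

    ``r7`` is drawn fresh per coordinate, matching the element-wise source
    formulation.
    """
    x = np.asarray(x, dtype=float)
    r7 = rng.uniform(size=x.shape)
    return prey + flag * r7 * alpha * (prey - x)


def hba_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: HbaConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over the box with the honey badger algorithm.

    Per iteration and per badger, a fair coin selects the digging or the
    honey move; a new position replaces the old one only if it improves the
    objective (greedy acceptance), and the incumbent best ("prey") tracks
    the global minimum seen so far.

    Returns ``(best_position, best_fitness, history)`` where ``history`` has
    ``max_iters + 1`` non-increasing entries (initial best plus one per
    iteration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = init_population(bounds, config, rng)
    fitnesses = _evaluate_all(objective, positions, iteration=0)
    pop = Population(positions, fitnesses)

    history = [pop.best_fitness]
    t_max = config.max_iters
    for t in range(1, t_max + 1):
        alpha = density_factor(t, t_max, config.density_constant)
        intens = intensity(pop.positions, pop.best_position, rng)
        for i in range(pop.size):
            flag = direction_flag(rng)
            if rng.uniform() < 0.5:
                cand = digging_update(
                    pop.positions[i], pop.best_position, intens[i],
                    alpha, flag, config.ability, rng,
                )
            else:
                cand = honey_update(
                    pop.positions[i], pop.best_position, alpha, flag, rng,
                )
            cand = bounds.clamp(cand)
            f = float(objective(cand))
            if not np.isfinite(f):
                raise RuntimeError(
                    f"objective returned non-finite value at iteration {t}"
                )
            if f < pop.fitnesses[i]:
                pop.positions[i] = cand
                pop.fitnesses[i] = f
        pop.update_best()
        history.append(pop.best_fitness)

    return pop.best_position.copy(), pop.best_fitness, np.asarray(history)


def _evaluate_all(
    objective: Callable[[np.ndarray], float],
    positions: np.ndarray,
    iteration: int,
) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        f = float(objective(x))
        if not np.isfinite(f):
            raise RuntimeError(
                f"objective returned non-finite value at iteration {iteration}"
            )
        out[i] = f
    return out
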