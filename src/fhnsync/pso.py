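"""Particle swarm optimization over a bounded box of controller gains.

Standard global-best PSO.  Each particle carries a position X and velocity V
in gain space; per step and per dimension two fresh uniform(0, 1) draws scale
the cognitive (personal-best) and social (global-best) attraction terms:

    V <- W V + C1 Rand (Pbest - X) + C2 Rand (Gbest - X)
    X <- X + V

Positions are clipped to the search box and the clipped velocity components
zeroed.  The optimizer is fully deterministic given the seed and evaluates
particles in a fixed order, so results never depend on scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Particle",
    "SwarmConfig",
    "OptimizationResult",
    "ObjectiveFailureError",
    "init_swarm",
    "pso_step",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


class ObjectiveFailureError(RuntimeError):
    """The objective returned a non-finite value."""

    def __init__(self, position: np.ndarray, value: float):
        super().__init__(f"objective returned {value!r} at position {position.tolist()}")
        self.position = position
        self.value = value


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_value: float


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters and search box.

    Defaults follow common PSO practice: inertial weight W = 0.7, learning
    constants C1 = C2 = 1.5, 30 particles, 100 iterations.  ``bounds`` is a
    per-dimension (low, high) sequence; the default box is symmetric,
    [-2, 2] per gain, so gains of either sign are reachable.  ``tolerance``
    stops early once the global-best improvement over one iteration falls
    below it (0 disables early stopping).
    """

    n_particles: int = 30
    bounds: Sequence[tuple[float, float]] = ((-2.0, 2.0), (-2.0, 2.0), (-2.0, 2.0))
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    max_iters: int = 100
    seed: int = 0
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError(f"n_particles must be >= 1, got {self.n_particles}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")
        if min(self.w, self.c1, self.c2) < 0:
            raise ValueError("W, C1, C2 must be >= 0")
        for d, (lo, hi) in enumerate(self.bounds):
            if lo > hi:
                raise ValueError(f"bounds[{d}]: low {lo} > high {hi}")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    def low(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    def high(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)


@dataclass(frozen=True)
class OptimizationResult:
    """Best position/value found plus the per-iteration global-best history."""

    gbest_position: np.ndarray
    gbest_value: float
    history: pd.DataFrame  # columns: iteration, gbest_j, then one per gain
    n_evaluations: int

    def history_to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    value = float(objective(x))
    if not np.isfinite(value):
        raise ObjectiveFailureError(x, value)
    return value


def init_swarm(cfg: SwarmConfig, rng: np.random.Generator) -> list[Particle]:
    """Uniform positions inside the box, velocities uniform in +/-(high-low).

    Personal bests start at the initial positions with value +inf; the first
    evaluation pass fills them in.  A zero-width box is permitted (every
    particle sits at the single feasible point).
    """
    lo, hi = cfg.low(), cfg.high()
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("bounds must be finite")
    span = hi - lo
    swarm = []
    for _ in range(cfg.n_particles):
        x = lo + span * rng.random(cfg.ndim)
        v = span * (2.0 * rng.random(cfg.ndim) - 1.0)
        swarm.append(Particle(position=x, velocity=v, pbest_position=x.copy(), pbest_value=np.inf))
    return swarm


def _global_best(swarm: list[Particle]) -> tuple[np.ndarray, float]:
    best = min(swarm, key=lambda p: p.pbest_value)
    return best.pbest_position.copy(), best.pbest_value


def _evaluate_swarm(swarm: list[Particle], objective: Objective) -> int:
    """Score current positions and refresh personal bests. Returns eval count."""
    for p in swarm:
        value = _evaluate(objective, p.position)
        if value < p.pbest_value:
            p.pbest_value = value
            p.pbest_position = p.position.copy()
    return len(swarm)


def pso_step(
    swarm: list[Particle],
    cfg: SwarmConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> list[Particle]:
    """One synchronous velocity/position update of the whole swarm.

    The global best used for the social term is the one entering the step;
    personal and global bests are refreshed after all particles have moved.
    """
    gbest, _ = _global_best(swarm)
    lo, hi = cfg.low(), cfg.high()
    moved = []
    for p in swarm:
        r_cog = rng.random(cfg.ndim)
        r_soc = rng.random(cfg.ndim)
        v = (
            cfg.w * p.velocity
            + cfg.c1 * r_cog * (p.pbest_position - p.position)
            + cfg.c2 * r_soc * (gbest - p.position)
        )
        x = p.position + v
        clipped = (x < lo) | (x > hi)
        x = np.clip(x, lo, hi)
        v = np.where(clipped, 0.0, v)
        moved.append(replace(p, position=x, velocity=v))
    _evaluate_swarm(moved, objective)
    return moved


def optimize(objective: Objective, cfg: SwarmConfig) -> OptimizationResult:
    """Minimize ``objective`` over the box; reproducible given cfg.seed.

    Iteration 0 of the history records the global best after the initial
    evaluation; the recorded global-best values are non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(cfg, rng)
    n_evals = _evaluate_swarm(swarm, objective)
    gbest_x, gbest_v = _global_best(swarm)

    gain_cols = [f"x{d}" for d in range(cfg.ndim)]
    rows = [{"iteration": 0, "gbest_j": gbest_v, **dict(zip(gain_cols, gbest_x))}]

    for it in range(1, cfg.max_iters + 1):
        swarm = pso_step(swarm, cfg, objective, rng)
        n_evals += len(swarm)
        new_x, new_v = _global_best(swarm)
        improvement = gbest_v - new_v
        gbest_x, gbest_v = new_x, new_v
        rows.append({"iteration": it, "gbest_j": gbest_v, **dict(zip(gain_cols, gbest_x))})
        if cfg.tolerance > 0 and improvement < cfg.tolerance:
            break

    return OptimizationResult(
        gbest_position=gbest_x,
        gbest_value=gbest_v,
        history=pd.DataFrame(rows),
        n_evaluations=n_evals,
    )
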