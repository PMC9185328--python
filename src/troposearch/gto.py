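"""Artificial Gorilla Troops Optimizer (GTO) for box-constrained minimization.

The troop is a population of N candidate positions ("gorillas") in
``[LB, UB]^D``; the incumbent best is the "silverback".  Each iteration runs an
exploration move, a greedy fitness-based replacement, an exploitation move, and
a second greedy replacement.

Exploration (per member, with a fresh uniform draw ``rand``):

* ``rand < p``          — migration to an unknown place:
  ``GX = (UB - LB) * r1 + LB``
* ``rand >= 0.5``       — movement toward another gorilla:
  ``GX = (r2 - C) * Xr + L * H`` with ``H = Z * X_i``, ``Z ~ U(-C, C)^D``
* otherwise             — migration to a known place:
  ``GX = X_i - L * (L * (X_i - Xr) + r3 * (X_i - Xr))``

Exploitation, switched on the decaying coefficient ``C`` against threshold
``w``:

* ``C >= w``            — follow the silverback:
  ``GX = L * M * (X_i - X_sb) + X_i``
* ``C < w``             — competition for adult females:
  ``GX = X_sb - (X_sb * Q - X_i * Q) * A``

Auxiliary coefficients: ``F = cos(2 r4) + 1``; ``C = F * (1 - t / Tmax)``;
``l ~ U(-1, 1)``; ``L = C * l``; ``g = 2^L``;
``M = (|mean_i X_i|^g)^(1/g)`` elementwise; ``Q = 2 r5 - 1``;
``A = beta * E`` with ``E`` a per-dimension standard normal vector when a
fresh U(0,1) draw is >= 0.5, else a broadcast scalar standard normal.

Randomness is consumed in a documented fixed order so that seeded runs are
bit-reproducible and small instances can be checked against a straight-line
transcription of the update rules: per step, first ``r4`` then ``l`` (giving
F, C, L), then a member-major loop drawing, per member, the branch selector
followed by the branch's own draws (partner index before per-dimension draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GTOParams",
    "GorillaPopulation",
    "initialize_population",
    "exploration_step",
    "exploitation_step",
    "greedy_update",
    "optimize",
]


@dataclass
class GTOParams:
    """Run parameters for the optimizer.

    ``p`` is the migration probability, ``beta`` scales the violence
    coefficient in the competition move, and ``w`` is the exploitation switch
    threshold compared against the decaying coefficient ``C``.
    """

    N: int = 10
    Tmax: int = 10
    D: int = 16
    p: float = 0.03
    beta: float = 3.0
    w: float = 0.8
    lower_bounds: np.ndarray | float = 0.0
    upper_bounds: np.ndarray | float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.Tmax < 0:
            raise ValueError("Tmax must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("migration probability p must be in [0, 1]")
        self.lower_bounds = np.broadcast_to(
            np.asarray(self.lower_bounds, dtype=float), (self.D,)
        ).copy()
        self.upper_bounds = np.broadcast_to(
            np.asarray(self.upper_bounds, dtype=float), (self.D,)
        ).copy()
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower_bounds must be <= upper_bounds elementwise")


@dataclass
class GorillaPopulation:
    """Current troop state: positions, candidates, fitness, and the trace."""

    X: np.ndarray
    GX: np.ndarray
    fitness: np.ndarray
    silverback: int = 0
    history: list[float] = field(default_factory=list)
    flagged: list[int] = field(default_factory=list)

    @property
    def best_solution(self) -> np.ndarray:
        return self.X[self.silverback].copy()

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.silverback])


def _coefficients(t: int, Tmax: int, rng: np.random.Generator):
    """Draw r4 then l; return (C, L) for iteration t of Tmax."""
    r4 = rng.random()
    F = np.cos(2.0 * r4) + 1.0
    C = F * (1.0 - t / max(Tmax, 1))
    l = rng.uniform(-1.0, 1.0)
    return C, C * l


def initialize_population(
    params: GTOParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GorillaPopulation:
    """Scatter the troop uniformly: ``X = rand * (UB - LB) + LB``."""
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    LB, UB = params.lower_bounds, params.upper_bounds
    X = rng.random((params.N, params.D)) * (UB - LB) + LB
    return GorillaPopulation(
        X=X, GX=X.copy(), fitness=np.full(params.N, np.nan)
    )


def exploration_step(
    pop: GorillaPopulation, params: GTOParams, t: int, rng: np.random.Generator
) -> np.ndarray:
    """One exploration move; fills and returns ``pop.GX`` (clipped to bounds)."""
    LB, UB = params.lower_bounds, params.upper_bounds
    C, L = _coefficients(t, params.Tmax, rng)
    X = pop.X
    N, D = X.shape
    for i in range(N):
        rand = rng.random()
        if rand < params.p:
            r1 = rng.random(D)
            cand = (UB - LB) * r1 + LB
        elif rand >= 0.5:
            r2 = rng.random()
            j = int(rng.integers(N))
            Z = rng.uniform(-C, C, D)
            H = Z * X[i]
            cand = (r2 - C) * X[j] + L * H
        else:
            r3 = rng.random()
            j = int(rng.integers(N))
            diff = X[i] - X[j]
            cand = X[i] - L * (L * diff + r3 * diff)
        pop.GX[i] = np.clip(cand, LB, UB)
    return pop.GX


def exploitation_step(
    pop: GorillaPopulation, params: GTOParams, t: int, rng: np.random.Generator
) -> np.ndarray:
    """One exploitation move; fills and returns ``pop.GX`` (clipped to bounds)."""
    LB, UB = params.lower_bounds, params.upper_bounds
    C, L = _coefficients(t, params.Tmax, rng)
    X = pop.X
    N, D = X.shape
    X_sb = X[pop.silverback]
    if C >= params.w:
        g = 2.0 ** L
        M = (np.abs(X.mean(axis=0)) ** g) ** (1.0 / g)
        for i in range(N):
            pop.GX[i] = np.clip(L * M * (X[i] - X_sb) + X[i], LB, UB)
    else:
        for i in range(N):
            r5 = rng.random()
            Q = 2.0 * r5 - 1.0
            if rng.random() >= 0.5:
                A = params.beta * rng.standard_normal(D)
            else:
                A = params.beta * rng.standard_normal()
            pop.GX[i] = np.clip(X_sb - (X_sb * Q - X[i] * Q) * A, LB, UB)
    return pop.GX


def _evaluate(fitness_fn, row: np.ndarray) -> float:
    val = float(fitness_fn(row))
    return val


def greedy_update(pop: GorillaPopulation, fitness_fn) -> GorillaPopulation:
    """Replace ``X_i`` by ``GX_i`` when the candidate has strictly lower cost.

    Members whose candidate fitness is non-finite are skipped and recorded in
    ``pop.flagged``.  The silverback is reassigned to the global minimum and
    the best fitness is appended to the history trace.
    """
    N = pop.X.shape[0]
    for i in range(N):
        if np.isnan(pop.fitness[i]):
            base = _evaluate(fitness_fn, pop.X[i])
            pop.fitness[i] = base if np.isfinite(base) else np.inf
        cand = _evaluate(fitness_fn, pop.GX[i])
        if not np.isfinite(cand):
            pop.flagged.append(i)
            continue
        if cand < pop.fitness[i]:
            pop.X[i] = pop.GX[i]
            pop.fitness[i] = cand
    pop.silverback = int(np.argmin(pop.fitness))
    pop.history.append(pop.best_fitness)
    return pop


def optimize(fitness_fn, params: GTOParams):
    """Run the full optimizer; returns ``(best_solution, best_fitness, history)``.

    Initialization runs once; every iteration then performs exploration,
    evaluation with greedy replacement, exploitation, and a second evaluation
    with greedy replacement.  With ``Tmax = 0`` the best member of the initial
    population is returned.
    """
    rng = np.random.default_rng(params.seed)
    pop = initialize_population(params, rng=rng)
    for i in range(params.N):
        val = _evaluate(fitness_fn, pop.X[i])
        pop.fitness[i] = val if np.isfinite(val) else np.inf
    pop.silverback = int(np.argmin(pop.fitness))
    pop.history.append(pop.best_fitness)
    for t in range(1, params.Tmax + 1):
        exploration_step(pop, params, t, rng)
        greedy_update(pop, fitness_fn)
        exploitation_step(pop, params, t, rng)
        greedy_update(pop, fitness_fn)
    return pop.best_solution, pop.best_fitness, pop


def sphere(x: np.ndarray) -> float:
    """Benchmark objective: sum of squares (global minimum 0 at the origin)."""
    return float(np.sum(np.square(x)))
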