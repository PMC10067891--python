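"""Moth-flame optimization with Levy-flight and opposition-based mutations.

The moth-flame optimizer (MFO) is a population metaheuristic: *moths*
(candidate positions Q) spiral around *flames* (R, the best positions
found so far).  Each iteration the flame list is rebuilt by sorting the
union of previous flames and current moths by fitness and keeping the
best N, the number of flames in use is annealed from N down to 1, and
every moth takes a logarithmic-spiral step around its assigned flame:

    q_new = D * exp(b*t) * cos(2*pi*t) + r,      D = |r - q|

with ``t`` drawn per coordinate from [r_anneal, 1] and r_anneal moving
linearly from -1 to -2 over the run, so late iterations exploit tightly
around the surviving flames.

The synergistic variant (MFOS) adds three per-iteration operators:

* **Levy-flight mutation** — heavy-tailed steps (Mantegna generator,
  beta = 1.5, scale 0.01*(ub-lb)) applied to a random subset of moths,
  giving occasional long jumps out of local basins;
* **opposition-based learning (OBL) mutation** — a random subset of
  moths is compared against the boundary-reflected opposite point
  lb + ub - q and greedily replaced when the opposite is fitter;
* **arithmetic crossover** — with probability 0.8 a convex combination
  of the two best individuals replaces the worst moth when fitter.

Elitism is unconditional: flames never lose the best-so-far, so the
best-value trace is monotonically non-increasing.  Disabling all three
operators recovers the plain MFO baseline.

Objectives are evaluated **in batch**: ``f(X)`` receives an (N, v)
array and returns N fitness values.  Use :func:`batchify` to wrap a
scalar function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "OptimizeResult",
    "batchify",
    "initialize",
    "spiral_move",
    "levy_step",
    "levy_sigma",
    "obl_mutate",
    "step",
    "minimize",
]

Objective = Callable[[np.ndarray], np.ndarray]


def batchify(f: Callable[[np.ndarray], float]) -> Objective:
    """Wrap a scalar objective f(x)->float into the batch protocol."""

    def batched(X: np.ndarray) -> np.ndarray:
        return np.array([float(f(x)) for x in np.atleast_2d(X)])

    return batched


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters; defaults follow the standard experimental setup
    (population 50, 500 iterations, crossover 0.8, mutation 0.05,
    Levy + OBL mutations)."""

    dimension: int
    lb: float | Sequence[float] = -100.0
    ub: float | Sequence[float] = 100.0
    population_size: int = 50
    iterations: int = 500
    crossover_probability: float = 0.8
    mutation_probability: float = 0.05
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    b_shape: float = 1.0
    use_levy: bool = True
    use_obl: bool = True
    use_crossover: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for p in (self.crossover_probability, self.mutation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lb, ub = self.bounds()
        if not np.all(lb < ub):
            raise ValueError("need lb < ub in every dimension")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lb, float), (self.dimension,))
        ub = np.broadcast_to(np.asarray(self.ub, float), (self.dimension,))
        return lb.copy(), ub.copy()

    def plain_mfo(self) -> "OptimizerConfig":
        """Baseline configuration: all auxiliary operators off."""
        from dataclasses import replace

        return replace(self, use_levy=False, use_obl=False, use_crossover=False)


@dataclass
class OptimizerState:
    """Mutable iteration state: moth/flame matrices and bookkeeping."""

    cfg: OptimizerConfig
    rng: np.random.Generator
    moths: np.ndarray          # (N, v) positions Q
    moth_fitness: np.ndarray   # (N,) Qf
    flames: np.ndarray         # (N, v) sorted best positions R
    flame_fitness: np.ndarray  # (N,) Rf, non-decreasing
    best_position: np.ndarray
    best_value: float
    iteration: int = 0
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    sort_comparisons: int = 0


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray
    n_iterations: int
    n_evaluations: int
    sort_comparisons: int
    state: OptimizerState


def _quicksort_order(values: np.ndarray, state: OptimizerState) -> np.ndarray:
    """Quicksort (median-of-three pivot) returning the ascending order.

    Instrumented: comparisons are counted into ``state.sort_comparisons``
    so the per-iteration O(N^2) sorting bound can be checked directly.
    """
    idx = list(range(len(values)))

    def less(i: int, j: int) -> bool:
        state.sort_comparisons += 1
        return values[i] < values[j]

    def sort(lst: list[int]) -> list[int]:
        if len(lst) <= 1:
            return lst
        a, b, c = lst[0], lst[len(lst) // 2], lst[-1]
        # median of three as pivot; robust on the pre-sorted flame list
        trio = sorted((a, b, c), key=lambda i: values[i])
        pivot = trio[1]
        lo = [i for i in lst if less(i, pivot)]
        eq = [i for i in lst if values[i] == values[pivot]]
        hi = [i for i in lst if less(pivot, i)]
        return sort(lo) + eq + sort(hi)

    return np.array(sort(idx), dtype=int)


def levy_sigma(beta: float) -> float:
    """Mantegna scale sigma_u for the numerator Gaussian."""
    if not 1.0 < beta <= 2.0:
        raise ValueError(f"levy beta must be in (1, 2], got {beta}")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(
    dimension: int,
    beta: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Heavy-tailed Levy displacement(s) via the Mantegna generator.

    Returns shape (dimension,) or (size, dimension).  Steps are
    u / |w|^(1/beta) with u ~ N(0, sigma_u^2), w ~ N(0, 1); the tail of
    |step| decays like a power law with exponent beta.
    """
    sigma = levy_sigma(beta)
    shape = (dimension,) if size is None else (size, dimension)
    u = rng.normal(0.0, sigma, shape)
    w = rng.normal(0.0, 1.0, shape)
    return u / np.abs(w) ** (1.0 / beta)


def obl_mutate(position: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Opposition-based point: per-coordinate reflection lb + ub - x."""
    return np.asarray(lb) + np.asarray(ub) - np.asarray(position)


def spiral_move(
    moth_position: np.ndarray,
    flame_position: np.ndarray,
    t_param: np.ndarray | float,
    b_shape: float = 1.0,
) -> np.ndarray:
    """Logarithmic-spiral update D*exp(b*t)*cos(2*pi*t) + flame."""
    moth = np.asarray(moth_position, float)
    flame = np.asarray(flame_position, float)
    D = np.abs(flame - moth)
    t = np.asarray(t_param, float)
    return D * np.exp(b_shape * t) * np.cos(2.0 * math.pi * t) + flame


def initialize(
    f: Objective,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> OptimizerState:
    """Uniform random population in the box; flames = sorted copy."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lb, ub = cfg.bounds()
    N = cfg.population_size
    Q = rng.uniform(lb, ub, (N, cfg.dimension))
    Qf = np.asarray(f(Q), float)
    state = OptimizerState(
        cfg=cfg, rng=rng, moths=Q, moth_fitness=Qf,
        flames=Q.copy(), flame_fitness=Qf.copy(),
        best_position=Q[0].copy(), best_value=float("inf"),
    )
    state.n_evaluations += N
    order = _quicksort_order(Qf, state)
    state.flames = Q[order].copy()
    state.flame_fitness = Qf[order].copy()
    state.best_position = state.flames[0].copy()
    state.best_value = float(state.flame_fitness[0])
    return state


def step(f: Objective, state: OptimizerState) -> OptimizerState:
    """One MFOS iteration (in place): flame update, spiral moves,
    mutations, crossover, global-best update."""
    cfg = state.cfg
    rng = state.rng
    lb, ub = cfg.bounds()
    N, v = cfg.population_size, cfg.dimension
    T = cfg.iterations
    state.iteration += 1
    it = state.iteration

    # 1. merge moths + flames, sort by fitness, keep the best N
    pool = np.vstack([state.flames, state.moths])
    pool_f = np.concatenate([state.flame_fitness, state.moth_fitness])
    order = _quicksort_order(pool_f, state)[:N]
    state.flames = pool[order].copy()
    state.flame_fitness = pool_f[order].copy()

    # flame count annealed from N to 1 over the run
    flame_no = max(1, round(N - it * (N - 1) / T))

    # 2. spiral move toward the assigned flame
    r_anneal = -1.0 - it / T  # -1 -> -2
    t = (1.0 - r_anneal) * rng.random((N, v)) + r_anneal  # U[r_anneal, 1]
    assigned = np.minimum(np.arange(N), flame_no - 1)
    flames = state.flames[assigned]
    state.moths = spiral_move(state.moths, flames, t, cfg.b_shape)

    # 3a. Levy-flight mutation on a random subset
    if cfg.use_levy and cfg.mutation_probability > 0:
        mask = rng.random(N) < cfg.mutation_probability
        if mask.any():
            steps = levy_step(v, cfg.levy_beta, rng, size=int(mask.sum()))
            state.moths[mask] += cfg.levy_scale * (ub - lb) * steps

    np.clip(state.moths, lb, ub, out=state.moths)
    state.moth_fitness = np.asarray(f(state.moths), float)
    state.n_evaluations += N

    # 3b. OBL mutation with greedy acceptance
    if cfg.use_obl and cfg.mutation_probability > 0:
        mask = rng.random(N) < cfg.mutation_probability
        if mask.any():
            opp = obl_mutate(state.moths[mask], lb, ub)
            opp_f = np.asarray(f(opp), float)
            state.n_evaluations += int(mask.sum())
            better = opp_f < state.moth_fitness[mask]
            idx = np.flatnonzero(mask)[better]
            state.moths[idx] = opp[better]
            state.moth_fitness[idx] = opp_f[better]

    # 4. arithmetic crossover of the two best individuals
    if cfg.use_crossover and rng.random() < cfg.crossover_probability:
        alpha = rng.random()
        child = alpha * state.flames[0] + (1.0 - alpha) * state.flames[1]
        child = np.clip(child, lb, ub)
        child_f = float(np.asarray(f(child[None, :]), float)[0])
        state.n_evaluations += 1
        worst = int(np.argmax(state.moth_fitness))
        if child_f < state.moth_fitness[worst]:
            state.moths[worst] = child
            state.moth_fitness[worst] = child_f

    # 5. global best (replace only when strictly better)
    i_best = int(np.argmin(state.moth_fitness))
    if state.moth_fitness[i_best] < state.best_value:
        state.best_value = float(state.moth_fitness[i_best])
        state.best_position = state.moths[i_best].copy()
    if state.flame_fitness[0] < state.best_value:
        state.best_value = float(state.flame_fitness[0])
        state.best_position = state.flames[0].copy()
    state.trace.append(state.best_value)
    return state


def minimize(
    f: Objective,
    cfg: OptimizerConfig,
    rng: np.random.Generator | None = None,
    target: float | None = None,
) -> OptimizeResult:
    """Run the optimizer for ``cfg.iterations`` iterations.

    ``target``: optional early stop once the best value is <= target
    (used by the code search, where fitness 0 means a feasible word).
    Fully deterministic under a fixed seed or supplied generator.
    """
    state = initialize(f, cfg, rng=rng)
    for _ in range(cfg.iterations):
        step(f, state)
        if target is not None and state.best_value <= target:
            break
    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_value=state.best_value,
        trace=np.array(state.trace),
        n_iterations=state.iteration,
        n_evaluations=state.n_evaluations,
        sort_comparisons=state.sort_comparisons,
        state=state,
    )
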