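"""Benchmark-function suite, AVG/SD experiment harness and rank-sum test.

Nineteen standard test functions in three categories: F1-F7 unimodal
(sphere, Schwefel 2.22/1.2/2.21, Rosenbrock, step, noisy quartic),
F8-F13 multimodal (Schwefel 2.26, Rastrigin, Ackley, Griewank, two
penalized functions) and F14-F19 composite functions.  The composites
are hybrid compositions of the basic functions with shifted optima and
Gaussian mixing weights; their component shifts are drawn once from a
fixed, recorded seed so every install evaluates identical functions
without external reference data.  Each composite's global optimum sits
exactly at its first component's shift point with value 0 (the maximum-
weight component suppresses all others there).

The experiment protocol repeats each optimizer ``runs`` times (30 by
default) with per-run seeds derived from one master seed — run *r* of
every algorithm shares the same seed stream, giving paired samples —
and reports the average (AVG) and standard deviation (SD) of the final
best values.  Lower AVG = better performance; lower SD = more stable.

:func:`wilcoxon_rank_sum` compares two run samples: exact enumeration
of all rank assignments for combined sizes <= 12 (mid-ranks for ties),
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mfos import Objective, OptimizeResult, OptimizerConfig, minimize

__all__ = [
    "BenchmarkFunction",
    "FUNCTION_IDS",
    "get_function",
    "evaluate",
    "RunSummary",
    "run_experiment",
    "summary_table",
    "WilcoxonResult",
    "wilcoxon_rank_sum",
]

COMPOSITE_SHIFT_SEED = 40320  # recorded once; fixes all composite shifts


# --- basic batch evaluators (X: (N, v) -> (N,)) ---------------------------

def _sphere(X):
    return np.sum(X**2, axis=1)


def _schwefel_222(X):
    a = np.abs(X)
    return np.sum(a, axis=1) + np.prod(a, axis=1)


def _schwefel_12(X):
    return np.sum(np.cumsum(X, axis=1) ** 2, axis=1)


def _schwefel_221(X):
    return np.max(np.abs(X), axis=1)


def _rosenbrock(X):
    return np.sum(
        100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (X[:, :-1] - 1.0) ** 2,
        axis=1,
    )


def _step(X):
    return np.sum(np.floor(X + 0.5) ** 2, axis=1)


def _quartic_noise(X, rng):
    i = np.arange(1, X.shape[1] + 1)
    return np.sum(i * X**4, axis=1) + rng.random(X.shape[0])


def _schwefel_226(X):
    return -np.sum(X * np.sin(np.sqrt(np.abs(X))), axis=1)


def _rastrigin(X):
    return np.sum(X**2 - 10.0 * np.cos(2.0 * np.pi * X) + 10.0, axis=1)


def _ackley(X):
    v = X.shape[1]
    s1 = np.sum(X**2, axis=1)
    s2 = np.sum(np.cos(2.0 * np.pi * X), axis=1)
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(s1 / v))
        - np.exp(s2 / v)
        + 20.0
        + math.e
    )


def _griewank(X):
    i = np.sqrt(np.arange(1, X.shape[1] + 1))
    return (
        np.sum(X**2, axis=1) / 4000.0
        - np.prod(np.cos(X / i), axis=1)
        + 1.0
    )


def _penalty_u(X, a, k, m):
    return np.sum(
        np.where(
            X > a,
            k * (X - a) ** m,
            np.where(X < -a, k * (-X - a) ** m, 0.0),
        ),
        axis=1,
    )


def _penalized_1(X):
    v = X.shape[1]
    y = 1.0 + (X + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[:, 0]) ** 2
        + np.sum(
            (y[:, :-1] - 1.0) ** 2
            * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2),
            axis=1,
        )
        + (y[:, -1] - 1.0) ** 2
    )
    return np.pi / v * term + _penalty_u(X, 10.0, 100.0, 4)


def _penalized_2(X):
    term = (
        np.sin(3.0 * np.pi * X[:, 0]) ** 2
        + np.sum(
            (X[:, :-1] - 1.0) ** 2
            * (1.0 + np.sin(3.0 * np.pi * X[:, 1:]) ** 2),
            axis=1,
        )
        + (X[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * X[:, -1]) ** 2)
    )
    return 0.1 * term + _penalty_u(X, 5.0, 100.0, 4)


# --- composite functions --------------------------------------------------

_COMPOSITE_MIXES: dict[str, list[tuple[Callable, float, float]]] = {
    # fid -> list of (basic function, lambda stretch, sigma) per component;
    # component k carries bias 100*k, so the global optimum is component 0.
    "F14": [(_sphere, 0.05, 1.0)] * 5,
    "F15": [(_griewank, 1.0, 1.0)] * 5,
    "F16": [(_ackley, 0.2, 1.0)] * 5,
    "F17": [
        (_sphere, 0.05, 1.0),
        (_griewank, 1.0, 1.0),
        (_rastrigin, 0.3, 1.0),
        (_ackley, 0.2, 1.0),
        (_schwefel_222, 0.1, 1.0),
    ],
    "F18": [
        (_rastrigin, 0.3, 1.0),
        (_rastrigin, 0.3, 1.0),
        (_griewank, 1.0, 1.0),
        (_ackley, 0.2, 1.0),
        (_sphere, 0.05, 1.0),
    ],
    "F19": [
        (_rastrigin, 0.3, 0.1),
        (_rastrigin, 0.3, 0.2),
        (_griewank, 1.0, 0.3),
        (_ackley, 0.2, 0.4),
        (_sphere, 0.05, 0.5),
    ],
}


def _composite_shifts(fid: str, dim: int, lo: float, hi: float) -> np.ndarray:
    idx = int(fid[1:])
    rng = np.random.default_rng([COMPOSITE_SHIFT_SEED, idx, dim])
    # shifts kept inside the central 60% of the box so optima are interior
    span = (hi - lo) * 0.3
    mid = (hi + lo) / 2.0
    return rng.uniform(mid - span, mid + span, (5, dim))


def _composite_eval(fid: str, X: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mix = _COMPOSITE_MIXES[fid]
    dim = X.shape[1]
    shifts = _composite_shifts(fid, dim, lo, hi)
    raw_w = np.empty((X.shape[0], 5))
    vals = np.empty((X.shape[0], 5))
    for k, (g, lam, sigma) in enumerate(mix):
        Z = X - shifts[k]
        raw_w[:, k] = np.exp(
            -np.sum(Z**2, axis=1) / (2.0 * dim * sigma**2)
        )
        vals[:, k] = g(Z / lam) + 100.0 * k
    # max-weight component dominates; others vanish at each optimum point
    wmax = raw_w.max(axis=1, keepdims=True)
    w = np.where(raw_w == wmax, raw_w, raw_w * (1.0 - wmax**10))
    w_sum = w.sum(axis=1, keepdims=True)
    w = np.where(w_sum > 0, w / w_sum, 1.0 / 5.0)
    return np.sum(w * vals, axis=1)


@dataclass(frozen=True)
class BenchmarkFunction:
    """One suite entry: evaluator plus search box and known optimum."""

    fid: str
    name: str
    category: str  # unimodal | multimodal | composite
    lb: float
    ub: float
    dimension: int
    optimum_value: float
    _evaluate: Callable = field(repr=False)
    _optimum_point: Callable = field(repr=False)
    stochastic: bool = False

    def evaluate(
        self, x: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Batch evaluation; raises on out-of-bounds input."""
        X = np.atleast_2d(np.asarray(x, float))
        if X.shape[1] != self.dimension:
            raise ValueError(
                f"{self.fid}: expected dimension {self.dimension}, "
                f"got {X.shape[1]}"
            )
        if np.any(X < self.lb) or np.any(X > self.ub):
            raise ValueError(f"{self.fid}: input outside [{self.lb}, {self.ub}]")
        if self.stochastic:
            rng = rng if rng is not None else np.random.default_rng()
            return self._evaluate(X, rng)
        return self._evaluate(X)

    def objective(self, rng: np.random.Generator | None = None) -> Objective:
        """Bound-free batch objective for use inside an optimizer."""
        if self.stochastic:
            r = rng if rng is not None else np.random.default_rng()
            return lambda X: self._evaluate(np.atleast_2d(X), r)
        return lambda X: self._evaluate(np.atleast_2d(X))

    def optimum_point(self) -> np.ndarray:
        return self._optimum_point(self.dimension)


_BASIC_SPECS = [
    # fid, name, category, lb, ub, evaluator, optimum point fn, fmin, noisy
    ("F1", "sphere", "unimodal", -100, 100, _sphere,
     lambda v: np.zeros(v), 0.0, False),
    ("F2", "schwefel_2.22", "unimodal", -10, 10, _schwefel_222,
     lambda v: np.zeros(v), 0.0, False),
    ("F3", "schwefel_1.2", "unimodal", -100, 100, _schwefel_12,
     lambda v: np.zeros(v), 0.0, False),
    ("F4", "schwefel_2.21", "unimodal", -100, 100, _schwefel_221,
     lambda v: np.zeros(v), 0.0, False),
    ("F5", "rosenbrock", "unimodal", -30, 30, _rosenbrock,
     lambda v: np.ones(v), 0.0, False),
    ("F6", "step", "unimodal", -100, 100, _step,
     lambda v: np.zeros(v), 0.0, False),
    ("F7", "quartic_noise", "unimodal", -1.28, 1.28, _quartic_noise,
     lambda v: np.zeros(v), 0.0, True),
    ("F8", "schwefel_2.26", "multimodal", -500, 500, _schwefel_226,
     lambda v: np.full(v, 420.9687), None, False),
    ("F9", "rastrigin", "multimodal", -5.12, 5.12, _rastrigin,
     lambda v: np.zeros(v), 0.0, False),
    ("F10", "ackley", "multimodal", -32, 32, _ackley,
     lambda v: np.zeros(v), 0.0, False),
    ("F11", "griewank", "multimodal", -600, 600, _griewank,
     lambda v: np.zeros(v), 0.0, False),
    ("F12", "penalized_1", "multimodal", -50, 50, _penalized_1,
     lambda v: np.full(v, -1.0), 0.0, False),
    ("F13", "penalized_2", "multimodal", -50, 50, _penalized_2,
     lambda v: np.ones(v), 0.0, False),
]

FUNCTION_IDS = [s[0] for s in _BASIC_SPECS] + list(_COMPOSITE_MIXES)


def get_function(fid: str, dimension: int = 10) -> BenchmarkFunction:
    """Suite entry by id F1..F19 at the requested dimension."""
    fid = fid.upper()
    for f, name, cat, lo, hi, ev, opt, fmin, noisy in _BASIC_SPECS:
        if f == fid:
            if fmin is None:  # Schwefel 2.26: optimum scales with dimension
                fmin = -418.9829 * dimension
            return BenchmarkFunction(
                fid=fid, name=name, category=cat, lb=lo, ub=hi,
                dimension=dimension, optimum_value=float(fmin),
                _evaluate=ev, _optimum_point=opt, stochastic=noisy,
            )
    if fid in _COMPOSITE_MIXES:
        lo, hi = -5.0, 5.0
        return BenchmarkFunction(
            fid=fid, name=f"composite_{fid[1:]}", category="composite",
            lb=lo, ub=hi, dimension=dimension, optimum_value=0.0,
            _evaluate=lambda X, _f=fid: _composite_eval(_f, X, lo, hi),
            _optimum_point=lambda v, _f=fid: _composite_shifts(_f, v, lo, hi)[0],
            stochastic=False,
        )
    raise KeyError(f"unknown benchmark function {fid!r}")


def evaluate(
    fid: str,
    x: np.ndarray,
    dimension: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate one function by id at point(s) ``x``."""
    x = np.atleast_2d(np.asarray(x, float))
    fn = get_function(fid, dimension or x.shape[1])
    return fn.evaluate(x, rng=rng)


# --- experiment harness ---------------------------------------------------

@dataclass
class RunSummary:
    """Per-function, per-algorithm record of repeated optimizer runs."""

    function_id: str
    algorithm: str
    finals: list[float]
    traces: list[np.ndarray] = field(default_factory=list)

    @property
    def avg(self) -> float:
        return float(np.mean(self.finals))

    @property
    def sd(self) -> float:
        return float(np.std(self.finals, ddof=1))


VariantMap = Mapping[str, Callable[[OptimizerConfig], OptimizerConfig]]

DEFAULT_VARIANTS: VariantMap = {
    "MFOS": lambda cfg: cfg,
    "MFO": lambda cfg: cfg.plain_mfo(),
}


def run_experiment(
    fid: str,
    variants: VariantMap = DEFAULT_VARIANTS,
    runs: int = 30,
    master_seed: int = 0,
    dimension: int = 10,
    population_size: int = 50,
    iterations: int = 500,
    keep_traces: bool = False,
) -> dict[str, RunSummary]:
    """Repeat each optimizer variant ``runs`` times on one function.

    Run *r* of every variant uses the same derived seed, so the samples
    are paired; the whole experiment is reproducible bit-for-bit from
    ``master_seed``.
    """
    if runs < 2:
        raise ValueError("need runs >= 2 for AVG/SD")
    fn = get_function(fid, dimension)
    base = OptimizerConfig(
        dimension=dimension, lb=fn.lb, ub=fn.ub,
        population_size=population_size, iterations=iterations,
    )
    out: dict[str, RunSummary] = {}
    for name, make_cfg in variants.items():
        cfg = make_cfg(base)
        summary = RunSummary(function_id=fid, algorithm=name, finals=[])
        for r in range(runs):
            rng = np.random.default_rng([master_seed, r])
            noise_rng = np.random.default_rng([master_seed, r, 7])
            result = minimize(fn.objective(rng=noise_rng), cfg, rng=rng)
            summary.finals.append(result.best_value)
            if keep_traces:
                summary.traces.append(result.trace)
        out[name] = summary
    return out


def summary_table(summaries: Sequence[RunSummary]) -> pd.DataFrame:
    """AVG/SD table over a collection of run summaries."""
    return pd.DataFrame(
        [
            {
                "function": s.function_id,
                "algorithm": s.algorithm,
                "runs": len(s.finals),
                "avg": s.avg,
                "sd": s.sd,
            }
            for s in summaries
        ]
    )


# --- Wilcoxon rank-sum ----------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    rank_sum: float     # sum of sample_a's mid-ranks in the pooled ranking
    p_value: float      # two-sided
    method: str         # "exact" | "normal"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), float)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_limit: int = 12,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Exact enumeration over all C(n+m, n) rank assignments (with
    mid-ranks for ties) when the combined size is <= ``exact_limit``;
    otherwise the normal approximation with tie-corrected variance and
    a 0.5 continuity correction.  The null is equal distributions; note
    the study convention this harness serves *reports* raw p-values and
    leaves thresholding to the caller.
    """
    a = np.asarray(list(sample_a), float)
    b = np.asarray(list(sample_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n].sum())

    if n + m <= exact_limit:
        total = 0
        extreme = 0
        mu = n * (n + m + 1) / 2.0
        dev = abs(w_obs - mu)
        for comb in itertools.combinations(range(n + m), n):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-12:
                extreme += 1
        return WilcoxonResult(w_obs, extreme / total, "exact")

    mu = n * (n + m + 1) / 2.0
    # tie correction on the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * (n + m + 1.0 - tie_term)
    if var <= 0:
        return WilcoxonResult(w_obs, 1.0, "normal")
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(max(z, 0.0) / math.sqrt(2.0))
    return WilcoxonResult(w_obs, min(1.0, p), "normal")
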