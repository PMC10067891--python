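"""Construction of constrained DNA code sets with the moth-flame search.

The optimizer works in a continuous box [0, 4)^n; a position decodes to
a DNA word by flooring each coordinate to a quaternary digit under the
storage digit order A-0, T-1, C-2, G-3.  A candidate word is scored by
:func:`candidate_fitness`: zero iff it satisfies every single-sequence
constraint (GC count, homopolymer cap, secondary-structure screen, and
its own RC self-distance when RC is on) *and* keeps Hamming distance
and RC distance >= d to every already-accepted word; otherwise the sum
of integer violation magnitudes (distance deficits plus indicator
penalties).  The search grows a set greedily: run the optimizer to
minimize the candidate score against the current set, accept on score
zero, stop when no attempt finds a feasible extension.  A vanishing
lexicographic tie-break term (< 1, so it can never outweigh a violation
unit) steers the optimizer toward the lexicographically smallest
feasible word, making the greedy order reproducible and empirically
deep.

Every emitted set is validator-clean by construction — acceptance
requires an exact zero score.

Two exact shortcuts apply at small word lengths.  When the candidate
universe after single-sequence filtering fits under ``exact_limit``
words, the greedy heuristic is replaced by a branch-and-bound maximum
clique over the pairwise-compatibility graph, so tiny-n results are
provably maximum rather than heuristic.  Independently, when 4^n is
enumerable the stall check is exact: the search stops as soon as no
feasible extension exists instead of burning the full restart budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codeset import CodeSet, percent_change, validate
from .dna_core import (
    BASES,
    ConstraintSet,
    DnaSequence,
    gc_count,
    hamming_distance,
    has_secondary_structure,
    reverse_complement,
    satisfies_no_runlength,
)
from .mfos import OptimizerConfig, initialize, step
from . import reference

__all__ = [
    "DIGIT_BASES",
    "SearchConfig",
    "BoundsTable",
    "decode_vector",
    "encode_word",
    "candidate_fitness",
    "construct_code_set",
    "build_bounds_table",
]

DIGIT_BASES = "ATCG"  # storage digit order: A-0, T-1, C-2, G-3
_DIGIT_OF = {b: i for i, b in enumerate(DIGIT_BASES)}
_ALPHA_RANK = {b: i for i, b in enumerate(BASES)}  # lexicographic A<C<G<T
# Watson-Crick complement in digit space: A<->T is 0<->1, C<->G is 2<->3
_DIGIT_COMPLEMENT = np.array([1, 0, 3, 2])
_IS_GC = np.array([b in "GC" for b in DIGIT_BASES])


def decode_vector(v: Sequence[float]) -> DnaSequence:
    """Floor-decode a real vector in [0, 4) to a DNA word.

    Out-of-range coordinates are clipped into [0, 4) first, so every
    real vector decodes to a valid word.
    """
    arr = np.clip(np.asarray(v, float), 0.0, np.nextafter(4.0, 0.0))
    digits = np.floor(arr).astype(int)
    return DnaSequence("".join(DIGIT_BASES[d] for d in digits))


def encode_word(word: str) -> np.ndarray:
    """Centre of the decode cell of ``word`` (right inverse of decode)."""
    return np.array([_DIGIT_OF[c] + 0.5 for c in DnaSequence(word)])


def _word_violation(x: DnaSequence, c: ConstraintSet) -> int:
    """Integer violation score of the single-sequence constraints."""
    score = 0
    if c.use_gc:
        g = gc_count(x)
        score += min(abs(g - w) for w in c.gc_tolerance)
    if c.use_nl and not satisfies_no_runlength(x, c.max_run):
        score += sum(a == b for a, b in zip(x, x[1:]))
    if c.use_ss and has_secondary_structure(x, c.ss_min_stem):
        score += 1
    if c.use_rc and c.rc_include_self:
        score += max(0, c.d - hamming_distance(x, reverse_complement(x)))
    return score


def candidate_fitness(
    x: str, accepted: Iterable[str], c: ConstraintSet
) -> int:
    """Violation score of ``x`` as the next word of a growing set.

    Zero iff ``x`` satisfies all single-sequence constraints and is
    compatible (Hamming >= d, and RC distance >= d when RC is on) with
    every accepted word.  Deficits are summed, so the score decreases
    smoothly as a candidate approaches feasibility.
    """
    x = DnaSequence(x)
    if len(x) != c.n:
        raise ValueError(f"word length {len(x)} != constraint n={c.n}")
    score = _word_violation(x, c)
    for a in accepted:
        a = DnaSequence(a)
        score += max(0, c.d - hamming_distance(x, a))
        if c.use_rc:
            # hamming(a, rc(x)) == hamming(x, rc(a)): rc is an isometry
            score += max(0, c.d - hamming_distance(x, reverse_complement(a)))
    return score


# --- vectorised scoring used inside the optimizer -------------------------

def _to_digit_matrix(words: Sequence[str]) -> np.ndarray:
    return np.array([[_DIGIT_OF[c] for c in w] for w in words], int)


class _BatchScorer:
    """Scores whole optimizer populations at once.

    Equals candidate_fitness on every decoded word, plus the
    lexicographic tie-break term in [0, 1).
    """

    def __init__(self, c: ConstraintSet, accepted: Sequence[str]):
        self.c = c
        self.acc = _to_digit_matrix(accepted) if len(accepted) else None
        self.acc_rc = None
        if c.use_rc and len(accepted):
            rcs = [str(reverse_complement(w)) for w in accepted]
            self.acc_rc = _to_digit_matrix(rcs)
        self.gc_levels = np.array(sorted(c.gc_tolerance))
        self.alpha = np.array([_ALPHA_RANK[b] for b in DIGIT_BASES])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        c = self.c
        X = np.atleast_2d(X)
        digits = np.floor(
            np.clip(X, 0.0, np.nextafter(4.0, 0.0))
        ).astype(int)
        N, n = digits.shape
        score = np.zeros(N)
        if c.use_gc:
            g = _IS_GC[digits].sum(axis=1)
            score += np.abs(g[:, None] - self.gc_levels[None, :]).min(axis=1)
        if c.use_nl:
            if c.max_run == 1:
                score += (digits[:, 1:] == digits[:, :-1]).sum(axis=1)
            else:
                for i in range(N):
                    w = "".join(DIGIT_BASES[d] for d in digits[i])
                    if not satisfies_no_runlength(w, c.max_run):
                        score[i] += sum(a == b for a, b in zip(w, w[1:]))
        if c.use_ss:
            for i in range(N):
                w = "".join(DIGIT_BASES[d] for d in digits[i])
                if has_secondary_structure(w, c.ss_min_stem):
                    score[i] += 1
        if c.use_rc and c.rc_include_self:
            rc_self = _DIGIT_COMPLEMENT[digits][:, ::-1]
            h = (digits != rc_self).sum(axis=1)
            score += np.maximum(0, c.d - h)
        if self.acc is not None:
            h = (digits[:, None, :] != self.acc[None, :, :]).sum(axis=2)
            score += np.maximum(0, c.d - h).sum(axis=1)
            if self.acc_rc is not None:
                h = (digits[:, None, :] != self.acc_rc[None, :, :]).sum(axis=2)
                score += np.maximum(0, c.d - h).sum(axis=1)
        powers = 4.0 ** np.arange(n - 1, -1, -1)
        lex = (self.alpha[digits] * powers).sum(axis=1) / 4.0**n
        return score + lex


# --- exact small-universe solver ------------------------------------------

def _pair_ok(x: DnaSequence, y: DnaSequence, c: ConstraintSet) -> bool:
    if hamming_distance(x, y) < c.d:
        return False
    if c.use_rc and hamming_distance(x, reverse_complement(y)) < c.d:
        return False
    return True


def _iter_universe(c: ConstraintSet):
    """Length-n words passing the single-sequence constraints, in
    lexicographic order.  Only called when 4^n is small."""
    for tup in itertools.product(BASES, repeat=c.n):
        w = DnaSequence("".join(tup))
        if _word_violation(w, c) == 0:
            yield w


def _max_clique_exact(
    words: list[DnaSequence], c: ConstraintSet
) -> list[DnaSequence]:
    """Branch-and-bound maximum clique over the compatibility graph.

    Greedy-colouring upper bound (Tomita-style); deterministic given
    the lexicographic node order.  Intended for universes of at most a
    few hundred words.
    """
    n = len(words)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _pair_ok(words[i], words[j], c):
                adj[i].add(j)
                adj[j].add(i)

    best: list[int] = []

    def expand(clique: list[int], cand: list[int]) -> None:
        nonlocal best
        # greedy colouring: bound on the largest clique inside cand
        colours: list[set[int]] = []
        order: list[tuple[int, int]] = []
        for v in cand:
            for ci, cls in enumerate(colours):
                if adj[v].isdisjoint(cls):
                    cls.add(v)
                    order.append((v, ci + 1))
                    break
            else:
                colours.append({v})
                order.append((v, len(colours)))
        # process in ascending colour order so the bound is monotone
        order.sort(key=lambda vc: vc[1])
        cand_sorted = [v for v, _ in order]
        for idx in range(len(order) - 1, -1, -1):
            v, bound = order[idx]
            if len(clique) + bound <= len(best):
                return
            clique.append(v)
            new_cand = [u for u in cand_sorted[:idx] if u in adj[v]]
            if new_cand:
                expand(clique, new_cand)
            elif len(clique) > len(best):
                best = clique.copy()
            clique.pop()

    expand([], list(range(n)))
    return [words[i] for i in sorted(best)]


# --- search configuration and growth loop ---------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Configuration of one code-set construction run."""

    constraints: ConstraintSet
    optimizer: OptimizerConfig | None = None
    restarts: int = 20
    seed: int | None = None
    exact_limit: int = 160       # max filtered-universe size for exact search
    enumerate_limit: int = 4096  # max 4^n for exact stall detection
    patience: int = 50           # extra iterations refining a feasible word

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        opt = self.optimizer
        if opt is None:
            opt = OptimizerConfig(
                dimension=self.constraints.n, lb=0.0, ub=4.0,
                population_size=50, iterations=500, seed=self.seed,
            )
        elif opt.dimension != self.constraints.n:
            raise ValueError("optimizer dimension must equal word length n")
        object.__setattr__(self, "optimizer", opt)


def _extension_exists(accepted: list[DnaSequence], c: ConstraintSet) -> bool:
    taken = set(map(str, accepted))
    for w in _iter_universe(c):
        if str(w) in taken:
            continue
        if all(_pair_ok(w, a, c) for a in accepted):
            return True
    return False


def _run_attempt(
    scorer: _BatchScorer,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    patience: int,
) -> DnaSequence | None:
    """One optimizer attempt at proposing a feasible extension word.

    Runs until the iteration cap, stopping early once a feasible word
    (violation part zero, i.e. total score < 1) has been held for
    ``patience`` iterations with no tie-break improvement.
    """
    state = initialize(scorer, cfg, rng=rng)
    since_improve = 0
    last_best = state.best_value
    for _ in range(cfg.iterations):
        step(scorer, state)
        if state.best_value < last_best - 1e-15:
            last_best = state.best_value
            since_improve = 0
        else:
            since_improve += 1
        if state.best_value < 1.0 and since_improve >= patience:
            break
    if state.best_value < 1.0:
        return decode_vector(state.best_position)
    return None


def construct_code_set(sc: SearchConfig) -> CodeSet:
    """Construct a constraint-satisfying code set.

    Small universes are solved exactly (branch-and-bound maximum
    clique); otherwise the set grows greedily with optimizer-proposed
    words until no restart finds a feasible extension.  The result
    always passes :func:`mothcode.codeset.validate`; if the constraints
    admit no word at all the result is empty.
    """
    c = sc.constraints

    if 4**c.n <= sc.enumerate_limit:
        universe = list(_iter_universe(c))
        if len(universe) <= sc.exact_limit:
            words = _max_clique_exact(universe, c)
            return CodeSet(
                words, constraints=c,
                provenance=f"exact max-clique {c.label}",
            )

    accepted: list[DnaSequence] = []
    enumerable = 4**c.n <= sc.enumerate_limit
    seed_seq = np.random.SeedSequence(sc.seed if sc.seed is not None else 0)
    while True:
        if enumerable and not _extension_exists(accepted, c):
            break
        scorer = _BatchScorer(c, accepted)
        found: DnaSequence | None = None
        for _ in range(sc.restarts):
            rng = np.random.default_rng(seed_seq.spawn(1)[0])
            found = _run_attempt(scorer, sc.optimizer, rng, sc.patience)
            if found is not None:
                break
        if found is None:
            break
        accepted.append(found)
    return CodeSet(
        accepted, constraints=c,
        provenance=f"MFOS greedy {c.label} seed={sc.seed}",
    )


# --- bounds tables --------------------------------------------------------

@dataclass
class BoundsTable:
    """Grid of best found code sizes with reference comparisons."""

    frame: pd.DataFrame
    codes: dict[tuple[int, int], CodeSet] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def build_bounds_table(
    n_range: Iterable[int],
    d_range: Iterable[int],
    use_rc: bool = False,
    seed: int = 0,
    restarts: int = 20,
    optimizer: OptimizerConfig | None = None,
) -> BoundsTable:
    """One construct_code_set call per (n, d) cell with d <= n.

    Adds the published prior/reported sizes (where available) and the
    percent change of the found size against the prior column.
    Deterministic under ``seed``: each cell derives its own seed from
    (seed, n, d).
    """
    ref = reference.GC_NL_RC_BOUNDS if use_rc else reference.GC_NL_BOUNDS
    rows = []
    codes: dict[tuple[int, int], CodeSet] = {}
    for n in n_range:
        for d in d_range:
            if d > n:
                continue
            c = ConstraintSet(n=n, d=d, use_rc=use_rc)
            cell_seed = int(
                np.random.default_rng([seed, n, d]).integers(0, 2**31)
            )
            opt = optimizer
            if opt is not None and opt.dimension != n:
                opt = replace(opt, dimension=n)
            cs = construct_code_set(
                SearchConfig(
                    constraints=c, seed=cell_seed,
                    restarts=restarts, optimizer=opt,
                )
            )
            assert len(cs) == 0 or validate(cs).overall_pass
            codes[(n, d)] = cs
            prior = ref.get((n, d), (None, None))
            row = {
                "n": n, "d": d, "found": len(cs),
                "rate": cs.rate() if len(cs) else 0.0,
                "prior": prior[0], "reported": prior[1],
            }
            if prior[0]:
                row["pct_vs_prior"] = percent_change(len(cs), prior[0])
            rows.append(row)
    return BoundsTable(frame=pd.DataFrame(rows), codes=codes)
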