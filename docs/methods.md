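# Methods

This note records the models implemented in `mothcode`, the parameter
conventions, the numerical choices made where the underlying
descriptions were open, and the limits of what the tests demonstrate.

## Coding constraints

A codeword is a fixed-length word over {A, C, G, T}.  `ConstraintSet`
bundles the membership rules of a coding set C(n, W, d):

- **GC content.**  W defaults to ⌊n/2⌋.  For odd n a perfectly balanced
  count is impossible, so the accepted set defaults to
  {⌊n/2⌋, ⌈n/2⌉}; an exact-W mode is available by passing a singleton
  `gc_tolerance`.
- **No-runlength (NL).**  Interpreted strictly: no two adjacent equal
  bases (maximum homopolymer run 1).  The cap is configurable
  (`max_run`) for laxer regimes.
- **Hamming distance.**  Every unordered pair of words differs in at
  least d positions.
- **Reverse complement (RC).**  Every ordered pair (x, y), *including*
  x = y, must satisfy d_H(x, rc(y)) ≥ d.  Including self-pairs is the
  convention of the combinatorial DNA-code literature; it can be
  disabled (`rc_include_self=False`).  Note d_H(x, rc(y)) =
  d_H(y, rc(x)) because reverse complement is an isometry of the
  Hamming space, so the ordered-pair check costs only one evaluation
  per unordered pair plus the self-pairs.
- **Secondary-structure screen (SS).**  A word is rejected if it
  contains two subsequences of length m ≥ `ss_min_stem` (default 2) at
  1-based starts i, j with |i − j| > m whose contents are mutually
  reverse-complementary — the condition for a fold-back stem of length
  m.  The match predicate is exact reverse-complement identity; no
  free-energy model is used, so this is a conservative combinatorial
  screen, not a folding prediction.

The validator reports *every* violating word and pair rather than a
bare boolean.  The published 23-word example set for (n = 7, d = 5)
ships as reference data; it does not satisfy its own nominal regime
(two words have GC counts 2 and 5, four words contain homopolymer runs,
and one pair sits at Hamming distance 4), and the validator reports
exactly that — a useful fixture precisely because it exercises every
violation listing.

## Coding rate and printed-precision conventions

R = log₄(K)/n.  Published rate and percentage tables in this literature
truncate toward zero rather than round (0.58048… prints as 0.5804,
−0.8368 % as −0.83 %); `truncate` implements that convention and all
printed-value comparisons in the tests use it.  It is the only
convention consistent with every printed value simultaneously.

## The optimizer

Plain MFO: N moths Q with fitness Qf; flames R are the best N positions
of (previous flames ∪ current moths), sorted by fitness each iteration.
Moth i spirals around flame min(i, flame_count−1):

q ← D·e^{bt}·cos(2πt) + r, D = |r − q|, b = 1,

with t drawn per coordinate from U[r_a, 1] and r_a annealed linearly
from −1 to −2 over the run, and flame_count = round(N − it·(N−1)/T).
These constants follow the canonical moth–flame formulation; positions
are clipped to the box after every move.  Flame sorting uses an
instrumented median-of-three quicksort so the per-iteration O(N²)
comparison bound is directly measurable.

MFOS adds, per iteration:

1. **Levy-flight mutation** — with probability 0.05 per moth, add a
   Mantegna-generated heavy-tailed step (β = 1.5, σ_u ≈ 0.6966), scaled
   by 0.01·(ub − lb).  The Mantegna generator is the canonical choice
   for Levy mutations in metaheuristics; β and the scale are exposed in
   the configuration.
2. **Opposition-based learning (OBL)** — with probability 0.05 per
   moth, evaluate the boundary reflection lb + ub − q and keep it only
   if fitter (greedy acceptance).
3. **Arithmetic crossover** — with probability 0.8, a convex
   combination of the two best individuals replaces the worst moth when
   fitter.

Each operator is individually switchable; disabling all three
reproduces the plain-MFO trajectory bit for bit under the same seed,
which is how baseline comparisons are run.  Elitism is unconditional
(flames never discard the incumbent best), so the best-so-far trace is
monotone non-increasing.  The global best is replaced only on strict
improvement.  Defaults (population 50, 500 iterations, crossover 0.8,
mutation 0.05) are the standard operating point used throughout the
experiments.

Objectives are evaluated in batch — `f(X)` receives the (N, v)
population matrix — which keeps the code-search fitness vectorized.

## Benchmark suite and experiment protocol

F1–F7 are the classical unimodal functions (sphere, Schwefel
2.22/1.2/2.21, Rosenbrock, step, noisy quartic), F8–F13 the classical
multimodal set (Schwefel 2.26, Rastrigin, Ackley, Griewank, two
penalized functions) with their standard boxes and optima.  F14–F19 are
composite functions built in-package: five shifted components with
Gaussian mixing weights, component biases 0/100/200/300/400, and the
max-weight suppression rule, so each composite's global optimum is
exactly its first component's shift at value 0.  The shifts are drawn
once from a recorded seed, making the composites reproducible
everywhere without external reference files; they are a documented
stand-in for CEC-style composites, not a reimplementation of any
specific year's set.

Experiments repeat each optimizer 30 times; run r of every algorithm
uses the same derived seed (paired samples).  AVG and SD of the final
best values are the performance and stability metrics; lower is better
for both.  The default experiment dimension is 10, chosen to keep a
full 30-run comparison at the standard operating point around a minute
of CPU; all dimensions are configurable.

`wilcoxon_rank_sum` is a two-sided rank-sum test with mid-ranks for
ties: exact enumeration of all C(n+m, n) rank assignments for combined
sizes ≤ 12, otherwise the normal approximation with tie-corrected
variance and 0.5 continuity correction.  The harness reports raw
p-values and leaves thresholding to the caller.

## Code-set construction

Moth positions live in [0, 4)ⁿ and floor-decode to words under the
storage digit order A-0, T-1, C-2, G-3 (the same mapping as the payload
codec).  This encoding is the minimal bridge between the continuous
optimizer and the discrete search space: every cell of the unit grid is
one word, and decoding is surjective.

`candidate_fitness(x, accepted, c)` sums integer violation magnitudes:
GC distance to the accepted window, homopolymer-run count, an SS
indicator, the RC self-deficit max(0, d − d_H(x, rc(x))), and per
accepted word the deficits max(0, d − d_H) for the Hamming and RC
rules.  The score is 0 iff x is a feasible extension.  Inside the
optimizer a lexicographic tie-break term — the word's alphabetical rank
scaled into [0, 1) — is added; violations are integers, so the term can
never outweigh a violation unit, but among feasible words it steers the
search toward the lexicographically smallest.  This makes the greedy
order reproducible and, empirically, deep: lexicographic-greedy chains
reach 22 words at (n = 5, d = 3), above the published consensus of 20.

The growth loop accepts a word when its violation score reaches exactly
0 (never a near-miss, so emitted sets are unconditionally
validator-clean), re-scores against the enlarged set and repeats.  An
attempt stops early once a feasible word has been held for 50
iterations without tie-break improvement; a stalled set terminates the
search after `restarts` (default 20) failed attempts.

Two exact shortcuts bound the heuristics:

- when the single-sequence-filtered universe has ≤ 160 words (n ≤ 4
  for the GC+NL regime), the search is replaced by an exact
  branch-and-bound maximum clique (greedy-colouring bound) over the
  compatibility graph, so tiny-n results equal the true maximum for
  every d;
- when 4ⁿ ≤ 4096 the stall check enumerates the space directly, so
  termination is exact rather than budget-limited.

Because the tie-break makes the greedy chain semi-deterministic,
restarts mostly rediscover the same maximal set; sizes at larger n are
therefore honest single-chain greedy results and sit below the larger
published table entries (which are themselves unverifiable stochastic
search artifacts — the one published example set does not validate).
The bounds-table generator guarantees only that every emitted cell is
validator-clean, and reports percent comparisons against the published
reference columns.

## Thermodynamics

Melting temperatures use nearest-neighbor ΔH/ΔS sums via Biopython's
`MeltingTemp` with the SantaLucia unified parameter table and the
entropy-based salt correction, at 200 nM primer and 50 mM monovalent
Na⁺ by default.  A nanomolar salt concentration would be physically
implausible for a PCR buffer, so the package treats reported "50 nM
salt" conditions as 50 mM; both concentrations and the parameter table
are configurable.  Under these defaults the 10-mer ACGTATCAGA melts at
25.3 °C.  Tm variance over a code set is the population variance of
per-word Tm; regime comparisons (e.g. GC+NL vs GC+NL+RC) are
*reported*, not asserted — whether RC constraints lower Tm variance is
an empirical observation about particular stochastic sets, not a
theorem, and freshly constructed sets can show either direction.

## Storage codec

Each byte maps MSB-first to four quaternary digits, each digit to a
base (A-0, T-1, C-2, G-3); the round trip is exact for arbitrary byte
strings including the empty one.  The bit-pair order within a byte is
fixed MSB-first for interoperability since either convention would be
self-consistent.  The codec deliberately performs raw payload mapping
only — packaging payloads onto constraint-satisfying codeword sets is
not attempted, and the codec and the code-set machinery remain separate
features.

## Known limitations

- The SS screen is combinatorial stem detection, not thermodynamic
  folding; it neither predicts hairpin stability nor handles bulges.
- Heuristic search sizes at n ≥ 5 depend on the restart budget and the
  greedy order; they certify lower bounds but not maxima.
- The composite benchmark functions are a seeded construction, not the
  CEC reference instances; cross-paper AVG/SD comparisons on F14–F19
  are therefore not meaningful.
- Tm values depend on the chosen NN table and salt correction; only
  relative comparisons under a fixed `ThermoParams` are meaningful.
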