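# mothcode

Design of robust DNA codeword sets for DNA data storage, built around a
moth–flame optimizer (MFO) enhanced with Levy-flight and
opposition-based-learning mutation strategies (MFOS).

## The problem

Storing digital data in synthesized DNA requires *codeword sets*: a set
C(n, W, d) of length-`n` words over {A, C, G, T} in which every word has
GC count `W` (≈ n/2), no homopolymer runs (the **no-runlength**, NL,
constraint), and every pair of words differs in at least `d` positions
(Hamming distance).  A **reverse-complement** (RC) constraint
additionally requires every word to be Hamming-far from the reverse
complement of every word — including itself — which suppresses
non-specific cross-hybridization, and a **secondary-structure** screen
rejects words that can fold back on themselves (two disjoint,
mutually reverse-complementary subsequences forming a stem).  The larger
a valid set, the better: each valid set of size K certifies a lower
bound on the maximum, and its coding rate

&nbsp;&nbsp;&nbsp;&nbsp;R = log₄(K) / n

measures information per nucleotide.

Finding large sets is a hard combinatorial search.  This package drives
it with a continuous metaheuristic: moth positions in [0, 4)ⁿ decode to
DNA words (digit order A-0, T-1, C-2, G-3), a candidate's fitness is the
summed magnitude of its constraint violations against the growing set,
and the set is extended greedily each time the optimizer finds a
zero-violation word.  At tiny n the package instead solves the
compatibility graph exactly (branch-and-bound maximum clique), so small
results are provably maximum.

The optimizer itself — moths spiralling around flames
(q ← D·e^{bt}·cos 2πt + r), flame count annealed from N to 1 — is
augmented with heavy-tailed Levy-flight jumps (Mantegna generator,
β = 1.5), greedy opposition-based mutation (lb + ub − x), and arithmetic
crossover of the two best individuals.  A 19-function benchmark suite
(unimodal / multimodal / composite), an AVG/SD repeated-run harness and
an exact Wilcoxon rank-sum test support optimizer comparisons, and a
nearest-neighbor melting-temperature module (SantaLucia unified
parameters via Biopython) scores the thermodynamic homogeneity of
constructed sets through the variance of per-word Tm.

## Worked example

Construct a code set for n = 7, d = 5 under GC + NL constraints:

```text
$ mothcode search --n 7 --d 5 --seed 1 --restarts 10 --out codes.cod
found 13 words for C^{GC,NL}(7,3,5) in 2.2s
K=13 rate=0.2643 -> codes.cod
```

13 valid words were found, giving coding rate log₄(13)/7 ≈ 0.264 bits of
quaternary information per base.  The output file lists one word per
line under a `#` header carrying (n, d, W, flags); `mothcode validate
codes.cod --n 7 --d 5` confirms the set is constraint-clean (exit
status 0).  Other subcommands expose the remaining machinery:

```text
$ mothcode rate --k 190 --n 12 --paper-precision 3
0.315
$ mothcode tm ACGTATCAGA        # 200 nM primer, 50 mM Na+ defaults
25.35
$ mothcode wilcoxon --a 1,2 --b 3,4
rank_sum=3.0 p=0.333333 method=exact
```

`mothcode table` sweeps (n, d) grids into CSV lower-bound tables with
percent comparisons against published values, `mothcode benchmark`
runs the MFOS-vs-MFO harness on any of F1–F19, and
`mothcode encode-file` / `decode-file` give a lossless binary↔DNA
payload codec (4 bases per byte).

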