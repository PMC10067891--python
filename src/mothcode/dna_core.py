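"""Sequence primitives and the biological coding constraints.

A DNA storage codeword is a fixed-length word over {A, C, G, T}.  Robust
codeword sets restrict membership with combinatorial constraints:

* **GC content** — a fixed (near-balanced) count of G/C bases per word,
  which stabilises synthesis and sequencing chemistry.
* **No-runlength (NL)** — no homopolymer runs (adjacent identical bases),
  the dominant source of insertion/deletion miscalls.
* **Hamming distance** — every pair of words differs in at least ``d``
  positions, bounding substitution-error confusability.
* **Reverse-complement (RC)** — every word is Hamming-far from the
  reverse complement of every word (including itself), suppressing
  non-specific cross-hybridisation between strands.
* **Secondary-structure (SS) screening** — rejects words that can fold
  back on themselves: two disjoint subsequences that are mutually
  reverse-complementary form a stem.

This module provides the word type, the single-sequence predicates and
the pairwise predicates; whole-set validation lives in
:mod:`mothcode.codeset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BASES",
    "DnaSequence",
    "ConstraintSet",
    "reverse",
    "complement",
    "reverse_complement",
    "hamming_distance",
    "gc_count",
    "satisfies_gc",
    "satisfies_no_runlength",
    "satisfies_rc_pair",
    "has_secondary_structure",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DnaSequence(str):
    """An immutable uppercase DNA word over {A, C, G, T}.

    Subclasses :class:`str`, so all string operations (slicing, hashing,
    lexicographic comparison) work directly; construction validates the
    alphabet and canonicalises case.
    """

    __slots__ = ()

    def __new__(cls, seq: str) -> "DnaSequence":
        s = str(seq).upper()
        if not s:
            raise ValueError("empty DNA sequence")
        invalid = set(s) - set(BASES)
        if invalid:
            raise ValueError(
                f"invalid DNA symbol(s) {sorted(invalid)!r} in {s!r}"
            )
        return super().__new__(cls, s)

    @property
    def n(self) -> int:
        return len(self)


def reverse(x: str) -> DnaSequence:
    """Reverse of ``x``: x_n x_{n-1} ... x_1."""
    return DnaSequence(x[::-1])


def complement(x: str) -> DnaSequence:
    """Watson-Crick complement applied per position (A<->T, C<->G)."""
    return DnaSequence(str(DnaSequence(x)).translate(_COMPLEMENT))


def reverse_complement(x: str) -> DnaSequence:
    """Reverse complement: complement of each base, in reverse order."""
    return DnaSequence(str(DnaSequence(x)).translate(_COMPLEMENT)[::-1])


def hamming_distance(x: str, y: str) -> int:
    """Number of positions at which equal-length words differ."""
    if len(x) != len(y):
        raise ValueError(
            f"length mismatch: {len(x)} vs {len(y)} (Hamming distance "
            "is defined for equal-length sequences)"
        )
    return sum(a != b for a, b in zip(x, y))


def gc_count(x: str) -> int:
    """Number of G or C bases in ``x``."""
    return sum(c in "GC" for c in DnaSequence(x))


@dataclass(frozen=True)
class ConstraintSet:
    """Parameters of a coding set C(n, W, d) plus constraint flags.

    ``W`` defaults to floor(n/2).  For odd ``n`` a perfectly balanced GC
    count is impossible, so the accepted GC-count set ``gc_tolerance``
    defaults to {floor(n/2), ceil(n/2)}; pass an explicit singleton for
    exact-W mode.  ``max_run`` is the homopolymer cap for the NL
    constraint (1 = no two adjacent equal bases, the strictest reading).
    ``rc_include_self`` controls whether a word is checked against its
    own reverse complement (the convention in the combinatorial
    DNA-code literature; on by default).
    """

    n: int
    d: int = 3
    W: int | None = None
    gc_tolerance: frozenset[int] | None = None
    use_gc: bool = True
    use_nl: bool = True
    use_rc: bool = False
    use_ss: bool = False
    ss_min_stem: int = 2
    max_run: int = 1
    rc_include_self: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (1 <= self.d <= self.n):
            raise ValueError(f"need 1 <= d <= n, got d={self.d}, n={self.n}")
        W = self.W if self.W is not None else self.n // 2
        if not (0 <= W <= self.n):
            raise ValueError(f"need 0 <= W <= n, got W={W}")
        object.__setattr__(self, "W", W)
        if self.gc_tolerance is None:
            if self.W == self.n // 2 and self.n % 2 == 1:
                tol = frozenset({self.n // 2, (self.n + 1) // 2})
            else:
                tol = frozenset({W})
            object.__setattr__(self, "gc_tolerance", tol)
        else:
            object.__setattr__(
                self, "gc_tolerance", frozenset(self.gc_tolerance)
            )
        if self.ss_min_stem < 2:
            raise ValueError("ss_min_stem must be >= 2 (stem length l > 1)")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")

    @property
    def label(self) -> str:
        flags = [
            name
            for name, on in (
                ("GC", self.use_gc),
                ("NL", self.use_nl),
                ("RC", self.use_rc),
                ("SS", self.use_ss),
            )
            if on
        ]
        sup = ",".join(flags) if flags else "-"
        return f"C^{{{sup}}}({self.n},{self.W},{self.d})"


def satisfies_gc(x: str, c: ConstraintSet) -> bool:
    """True iff the GC count of ``x`` lies in the accepted set."""
    x = DnaSequence(x)
    if len(x) != c.n:
        raise ValueError(f"sequence length {len(x)} != constraint n={c.n}")
    return gc_count(x) in c.gc_tolerance


def satisfies_no_runlength(x: str, max_run: int = 1) -> bool:
    """True iff no homopolymer run in ``x`` exceeds ``max_run`` bases."""
    x = DnaSequence(x)
    run = 1
    for a, b in zip(x, x[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


def satisfies_rc_pair(x: str, y: str, d: int) -> bool:
    """True iff x is Hamming-far (>= d) from the reverse complement of y.

    Applied over all ordered pairs of a code set, including ``x == y``
    (a word versus its own reverse complement).
    """
    return hamming_distance(DnaSequence(x), reverse_complement(y)) >= d


def has_secondary_structure(x: str, l_min: int = 2) -> bool:
    """Stem-existence screen for hairpin-type self-folding.

    Returns True iff ``x`` contains two disjoint subsequences of some
    length ``m >= l_min`` that are mutually reverse-complementary, i.e.
    indices ``i, j`` (1-based starts) with ``|i - j| > m`` such that
    ``x[i : i+m] == reverse_complement(x[j : j+m])``.  Such a pair can
    base-pair into a stem of length ``m`` and fold the strand back on
    itself.  The pairing predicate is exact reverse-complement identity;
    no thermodynamic folding is attempted.
    """
    if l_min < 2:
        raise ValueError("l_min must be >= 2 (stem length l > 1)")
    x = DnaSequence(x)
    n = len(x)
    for m in range(l_min, n + 1):
        subs = [str(x[i : i + m]) for i in range(n - m + 1)]
        rcs = [str(reverse_complement(s)) for s in subs]
        for i in range(len(subs)):
            for j in range(len(subs)):
                if abs(i - j) > m and subs[i] == rcs[j]:
                    return True
    return False
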