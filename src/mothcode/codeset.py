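"""Code-set container, whole-set validation, rate metrics and file I/O.

A :class:`CodeSet` is an ordered collection of equal-length codewords
with the :class:`~mothcode.dna_core.ConstraintSet` it is meant to
satisfy.  :func:`validate` checks every single-word constraint (GC, NL,
SS) and every pairwise constraint (Hamming >= d over unordered pairs;
the RC rule over all ordered pairs including self-pairs) and returns a
full :class:`ValidationReport` rather than a bare boolean, so violating
words and pairs can be inspected or exported.

The coding rate R = log4(K) / n measures information per nucleotide of
a K-word length-n code.  Published rate tables print *truncated* (not
rounded) decimals, so :func:`truncate` implements truncation toward
zero and :func:`coding_rate` exposes it via ``precision``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna_core import (
    ConstraintSet,
    DnaSequence,
    gc_count,
    hamming_distance,
    has_secondary_structure,
    reverse_complement,
    satisfies_gc,
    satisfies_no_runlength,
)

__all__ = [
    "CodeSet",
    "ValidationReport",
    "validate",
    "coding_rate",
    "percent_change",
    "truncate",
    "read_codes",
    "write_codes",
]


class CodeSet:
    """Equal-length, duplicate-free collection of DNA codewords."""

    def __init__(
        self,
        words: Iterable[str],
        constraints: ConstraintSet | None = None,
        provenance: str = "",
    ):
        ws = [DnaSequence(w) for w in words]
        if not ws and constraints is None:
            raise ValueError(
                "empty code set needs an explicit ConstraintSet for its n"
            )
        n = len(ws[0]) if ws else constraints.n
        bad = [w for w in ws if len(w) != n]
        if bad:
            raise ValueError(
                f"mixed word lengths: expected {n}, got {len(bad[0])} "
                f"for {bad[0]!r}"
            )
        seen: set[str] = set()
        for w in ws:
            if w in seen:
                raise ValueError(f"duplicate codeword {w!r}")
            seen.add(w)
        if constraints is not None and constraints.n != n:
            raise ValueError(
                f"constraint n={constraints.n} != word length {n}"
            )
        self.words: list[DnaSequence] = ws
        self.constraints = constraints
        self.provenance = provenance

    @property
    def n(self) -> int:
        return len(self.words[0]) if self.words else self.constraints.n

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __contains__(self, w: object) -> bool:
        return w in set(map(str, self.words))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodeSet) and list(map(str, self.words)) == list(
            map(str, other.words)
        )

    def __repr__(self) -> str:
        tag = f" [{self.provenance}]" if self.provenance else ""
        return f"CodeSet(K={len(self)}, n={self.n}{tag})"

    def rate(self, precision: int | None = None) -> float:
        return coding_rate(len(self), self.n, precision=precision)


@dataclass
class ValidationReport:
    """Outcome of validating a code set against its constraints."""

    constraints: ConstraintSet
    n_words: int
    gc_violations: list[str] = field(default_factory=list)
    nl_violations: list[str] = field(default_factory=list)
    ss_violations: list[str] = field(default_factory=list)
    hamming_violations: list[tuple[str, str, int]] = field(default_factory=list)
    rc_violations: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return not (
            self.gc_violations
            or self.nl_violations
            or self.ss_violations
            or self.hamming_violations
            or self.rc_violations
        )

    def summary(self) -> dict:
        return {
            "constraints": self.constraints.label,
            "n_words": self.n_words,
            "overall_pass": self.overall_pass,
            "gc_violations": list(self.gc_violations),
            "nl_violations": list(self.nl_violations),
            "ss_violations": list(self.ss_violations),
            "hamming_violations": [list(v) for v in self.hamming_violations],
            "rc_violations": [list(v) for v in self.rc_violations],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def validate(cs: CodeSet, constraints: ConstraintSet | None = None) -> ValidationReport:
    """Check every word and pair of ``cs`` against the constraints.

    Single-word rules (GC count, homopolymer cap, secondary-structure
    screen) are applied per flagged constraint; the Hamming rule over
    unordered pairs; the RC rule over ordered pairs plus self-pairs
    (per ``rc_include_self``).
    """
    if len(cs) == 0:
        raise ValueError("cannot validate an empty code set")
    c = constraints or cs.constraints
    if c is None:
        raise ValueError("no ConstraintSet given and code set carries none")
    if c.n != cs.n:
        raise ValueError(f"constraint n={c.n} != word length {cs.n}")
    rep = ValidationReport(constraints=c, n_words=len(cs))
    words = cs.words
    for w in words:
        if c.use_gc and not satisfies_gc(w, c):
            rep.gc_violations.append(str(w))
        if c.use_nl and not satisfies_no_runlength(w, c.max_run):
            rep.nl_violations.append(str(w))
        if c.use_ss and has_secondary_structure(w, c.ss_min_stem):
            rep.ss_violations.append(str(w))
    rcs = {w: reverse_complement(w) for w in words}
    for i, x in enumerate(words):
        for j, y in enumerate(words):
            if j > i:
                h = hamming_distance(x, y)
                if h < c.d:
                    rep.hamming_violations.append((str(x), str(y), h))
            if c.use_rc and (i != j or c.rc_include_self):
                h = hamming_distance(x, rcs[y])
                if h < c.d:
                    rep.rc_violations.append((str(x), str(y), h))
    return rep


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` decimal places.

    Printed rate/percentage tables in the DNA-code literature truncate
    rather than round (0.58048... prints as 0.5804), so comparisons
    against printed values must use this convention.
    """
    factor = 10**decimals
    return math.trunc(value * factor) / factor


def coding_rate(K: int, n: int, precision: int | None = None) -> float:
    """Net coding rate R = log4(K) / n of a K-word length-n code."""
    if K < 1 or n < 1:
        raise ValueError(f"need K >= 1 and n >= 1, got K={K}, n={n}")
    r = math.log(K, 4) / n
    return truncate(r, precision) if precision is not None else r


def percent_change(new_value: float, old_value: float, precision: int | None = None) -> float:
    """Signed percent change 100*(new - old)/old; truncated if asked."""
    if old_value <= 0:
        raise ValueError(f"old_value must be positive, got {old_value}")
    p = 100.0 * (new_value - old_value) / old_value
    return truncate(p, precision) if precision is not None else p


# ---------------------------------------------------------------------------
# File I/O: `.cod` (one word per line, # headers) and FASTA

def _parse_cod(path: Path) -> tuple[list[str], dict]:
    words: list[str] = []
    meta: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        word = line.split()[0].upper()
        if set(word) - set("ACGT"):
            raise ValueError(
                f"{path}:{lineno}: invalid DNA symbol in {word!r}"
            )
        words.append(word)
    return words, meta


def read_codes(
    path: str | Path,
    fmt: str | None = None,
    constraints: ConstraintSet | None = None,
) -> CodeSet:
    """Read a code set from a ``.cod`` or FASTA file.

    ``fmt`` is "cod" or "fasta"; inferred from the suffix when omitted
    (.fa/.fasta/.fna -> fasta, anything else -> cod).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "cod"
    if fmt == "fasta":
        words = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        meta: dict = {}
    elif fmt == "cod":
        words, meta = _parse_cod(path)
    else:
        raise ValueError(f"unknown code-file format {fmt!r}")
    if not words:
        raise ValueError(f"{path}: no codewords found")
    if constraints is None and {"n", "d"} <= meta.keys():
        flags = set(meta.get("constraints", "gc,nl").lower().split(","))
        constraints = ConstraintSet(
            n=int(meta["n"]),
            d=int(meta["d"]),
            W=int(meta["W"]) if "W" in meta else None,
            use_gc="gc" in flags,
            use_nl="nl" in flags,
            use_rc="rc" in flags,
            use_ss="ss" in flags,
        )
    return CodeSet(words, constraints=constraints, provenance=str(path))


def write_codes(cs: CodeSet, path: str | Path, fmt: str | None = None) -> None:
    """Write a code set as ``.cod`` or FASTA (one record per codeword)."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "cod"
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(str(w)), id=f"codeword_{i + 1}", description="")
            for i, w in enumerate(cs.words)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "cod":
        lines = []
        c = cs.constraints
        if c is not None:
            flags = ",".join(
                name
                for name, on in (
                    ("gc", c.use_gc),
                    ("nl", c.use_nl),
                    ("rc", c.use_rc),
                    ("ss", c.use_ss),
                )
                if on
            )
            lines += [f"# n = {c.n}", f"# d = {c.d}", f"# W = {c.W}",
                      f"# constraints = {flags}"]
        if cs.provenance:
            lines.append(f"# provenance = {cs.provenance}")
        lines += [str(w) for w in cs.words]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown code-file format {fmt!r}")
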