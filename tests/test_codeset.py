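"""Code-set container, validator-vs-oracle agreement, rate metrics and
round-trip file I/O."""

import itertools

import pytest
from hypothesis import given, strategies as st

from mothcode.codeset import (
    CodeSet,
    coding_rate,
    percent_change,
    read_codes,
    truncate,
    validate,
    write_codes,
)
from mothcode.dna_core import (
    BASES,
    ConstraintSet,
    gc_count,
    hamming_distance,
    reverse_complement,
    satisfies_no_runlength,
)
from mothcode.reference import TABLE5_WORDS


def brute_force_report(words, c):
    """Independent re-derivation of every violation listing."""
    gc_v = [w for w in words if c.use_gc and gc_count(w) not in c.gc_tolerance]
    nl_v = [w for w in words if c.use_nl and not satisfies_no_runlength(w, c.max_run)]
    ham_v = [
        (x, y, hamming_distance(x, y))
        for x, y in itertools.combinations(words, 2)
        if hamming_distance(x, y) < c.d
    ]
    rc_v = []
    if c.use_rc:
        for x in words:
            for y in words:
                if x == y and not c.rc_include_self:
                    continue
                h = hamming_distance(x, str(reverse_complement(y)))
                if h < c.d:
                    rc_v.append((x, y, h))
    return gc_v, nl_v, ham_v, rc_v


def random_words(rng, n, k):
    seen = []
    while len(seen) < k:
        w = "".join(rng.choice(list(BASES)) for _ in range(n))
        if w not in seen:
            seen.append(w)
    return seen


class TestCodeSetContainer:
    def test_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            CodeSet(["ACGT", "ACGT"])

    def test_rejects_mixed_lengths(self):
        with pytest.raises(ValueError, match="mixed"):
            CodeSet(["ACGT", "ACG"])

    def test_empty_needs_constraints(self):
        with pytest.raises(ValueError):
            CodeSet([])
        cs = CodeSet([], constraints=ConstraintSet(n=4, d=2))
        assert len(cs) == 0 and cs.n == 4

    def test_table5_has_23_words_of_length_7(self, table5):
        assert len(table5) == 23 and table5.n == 7
        assert "CTACGAT" in table5 and "TGAACTG" in table5


class TestValidate:
    def test_table5_gc_window(self, table5):
        # direct count: 21 of the 23 published words have GC in {3, 4};
        # GTACTAT (GC=2) and CTGCCTC (GC=5) fall outside the window
        c = ConstraintSet(n=7, d=1, use_nl=False)
        rep = validate(table5, c)
        assert rep.gc_violations == ["GTACTAT", "CTGCCTC"]
        assert not rep.overall_pass

    def test_table5_fails_full_regime(self, table5):
        # the published set itself violates NL and the d=5 Hamming floor
        c = ConstraintSet(n=7, d=5, use_rc=True)
        rep = validate(table5, c)
        assert not rep.overall_pass
        assert "GAGATTC" in rep.nl_violations
        assert ("CTGTGAC", "ATGTACG", 4) in rep.hamming_violations

    def test_empty_set_rejected(self):
        cs = CodeSet([], constraints=ConstraintSet(n=4, d=2))
        with pytest.raises(ValueError, match="empty"):
            validate(cs)

    @pytest.mark.parametrize("use_rc", [False, True])
    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_random_sets(self, seed, use_rc):
        import random

        rng = random.Random(seed)
        n = rng.randint(4, 8)
        words = random_words(rng, n, rng.randint(2, 20))
        c = ConstraintSet(n=n, d=rng.randint(1, n), use_rc=use_rc)
        rep = validate(CodeSet(words), c)
        gc_v, nl_v, ham_v, rc_v = brute_force_report(words, c)
        assert rep.gc_violations == gc_v
        assert rep.nl_violations == nl_v
        assert sorted(rep.hamming_violations) == sorted(ham_v)
        assert sorted(rep.rc_violations) == sorted(rc_v)
        assert rep.overall_pass == (not (gc_v or nl_v or ham_v or rc_v))

    def test_report_round_trips_to_json(self, tmp_path, table5):
        rep = validate(table5, ConstraintSet(n=7, d=5))
        out = tmp_path / "report.json"
        rep.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["overall_pass"] == rep.overall_pass
        assert data["n_words"] == 23


class TestRates:
    @pytest.mark.parametrize(
        "k,n,prec,expected",
        [
            (5, 2, 4, 0.5804),
            (190, 12, 3, 0.315),
            (124, 11, 3, 0.316),
            (127, 7, 3, 0.499),
            (63, 6, 3, 0.498),
            (23, 7, 3, 0.323),
            (35, 8, 2, 0.32),
            (906, 9, 3, 0.545),
            (419, 8, 3, 0.544),
            (4, 1, None, 1.0),
        ],
    )
    def test_published_rates(self, k, n, prec, expected):
        got = coding_rate(k, n, precision=prec)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_truncates_not_rounds(self):
        assert truncate(0.58048, 4) == 0.5804
        assert truncate(-0.8368, 2) == -0.83

    def test_monotonicity(self):
        ks = [2, 5, 17, 100, 900]
        rates = [coding_rate(k, 9) for k in ks]
        assert rates == sorted(rates) and len(set(rates)) == len(ks)
        ns = [3, 5, 9, 14]
        rates = [coding_rate(50, n) for n in ns]
        assert rates == sorted(rates, reverse=True)

    @pytest.mark.parametrize("k,n", [(0, 4), (4, 0), (-1, 3)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            coding_rate(k, n)


class TestPercentChange:
    @pytest.mark.parametrize(
        "new,old,expected",
        [(11967, 12068, -0.83), (8, 9, -11.11), (248, 189, 31.21), (7, 7, 0.0)],
    )
    def test_published_comparisons(self, new, old, expected):
        assert percent_change(new, old, precision=2) == pytest.approx(expected)

    def test_requires_positive_base(self):
        with pytest.raises(ValueError):
            percent_change(5, 0)


words_strategy = st.lists(
    st.text(alphabet=BASES, min_size=6, max_size=6),
    min_size=1,
    max_size=15,
    unique=True,
)


class TestIO:
    @given(words=words_strategy)
    def test_cod_round_trip(self, words, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("cod")
        cs = CodeSet(words, constraints=ConstraintSet(n=6, d=3))
        path = tmp / "codes.cod"
        write_codes(cs, path)
        back = read_codes(path)
        assert list(map(str, back.words)) == list(map(str, cs.words))
        assert back.constraints.n == 6 and back.constraints.d == 3

    @given(words=words_strategy)
    def test_fasta_round_trip(self, words, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fasta")
        cs = CodeSet(words)
        path = tmp / "codes.fasta"
        write_codes(cs, path)
        back = read_codes(path)
        assert list(map(str, back.words)) == list(map(str, cs.words))

    def test_table5_round_trip(self, tmp_path, table5):
        path = tmp_path / "published.cod"
        write_codes(table5, path)
        assert read_codes(path) == table5

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.cod"
        path.write_text("")
        with pytest.raises(ValueError, match="no codewords"):
            read_codes(path)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.cod"
        path.write_text("ACGT\nACGU\n")
        with pytest.raises(ValueError, match=":2"):
            read_codes(path)

    def test_constraint_header_round_trip(self, tmp_path):
        c = ConstraintSet(n=4, d=2, use_rc=True)
        cs = CodeSet(["ACGT", "GTCA"], constraints=c)
        path = tmp_path / "rc.cod"
        write_codes(cs, path)
        back = read_codes(path)
        assert back.constraints.use_rc and back.constraints.d == 2
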