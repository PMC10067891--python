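"""Code-set construction: vector decoding, candidate scoring against an
independent counter, exact-vs-clique-oracle equality at tiny n, and the
greedy growth contract."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mothcode.code_search import (
    DIGIT_BASES,
    SearchConfig,
    _BatchScorer,
    build_bounds_table,
    candidate_fitness,
    construct_code_set,
    decode_vector,
    encode_word,
)
from mothcode.codeset import validate
from mothcode.dna_core import (
    BASES,
    ConstraintSet,
    gc_count,
    hamming_distance,
    has_secondary_structure,
    reverse_complement,
    satisfies_no_runlength,
)
from mothcode.mfos import OptimizerConfig


class TestDecode:
    def test_digit_order(self):
        assert DIGIT_BASES == "ATCG"

    def test_worked_example(self):
        assert decode_vector([0.2, 1.9, 2.5, 3.01]) == "ATCG"

    def test_low_box_is_poly_a(self):
        assert decode_vector([0.0, 0.5, 0.99]) == "AAA"

    def test_clipping(self):
        assert decode_vector([-3.0, 4.0, 7.2]) == "AGG"

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_surjective_on_small_spaces(self, n):
        words = {"".join(p) for p in itertools.product(BASES, repeat=n)}
        decoded = {str(decode_vector(encode_word(w))) for w in words}
        assert decoded == words


def fitness_oracle(x, accepted, c):
    """Independent violation counter (set arithmetic, no shared code)."""
    score = 0
    if c.use_gc:
        score += min(abs(gc_count(x) - t) for t in c.gc_tolerance)
    if c.use_nl:
        score += sum(1 for i in range(len(x) - 1) if x[i] == x[i + 1]
                     ) if not satisfies_no_runlength(x, c.max_run) else 0
    if c.use_ss and has_secondary_structure(x, c.ss_min_stem):
        score += 1
    if c.use_rc and c.rc_include_self:
        h = hamming_distance(x, str(reverse_complement(x)))
        score += max(0, c.d - h)
    for a in accepted:
        score += max(0, c.d - hamming_distance(x, a))
        if c.use_rc:
            score += max(0, c.d - hamming_distance(x, str(reverse_complement(a))))
    return score


class TestCandidateFitness:
    def test_zero_for_clean_word_empty_set(self):
        c = ConstraintSet(n=4, d=2)
        assert candidate_fitness("ACGT", [], c) == 0

    def test_duplicate_scores_full_deficit(self):
        c = ConstraintSet(n=4, d=3)
        assert candidate_fitness("ACGT", ["ACGT"], c) >= 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            candidate_fitness("ACG", [], ConstraintSet(n=4, d=2))

    @pytest.mark.parametrize("use_rc", [False, True])
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_oracle(self, seed, use_rc):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        c = ConstraintSet(n=n, d=int(rng.integers(1, n + 1)), use_rc=use_rc)
        mk = lambda: "".join(rng.choice(list(BASES), n))
        accepted = [mk() for _ in range(int(rng.integers(0, 6)))]
        for _ in range(20):
            x = mk()
            assert candidate_fitness(x, accepted, c) == fitness_oracle(
                x, accepted, c
            )

    @pytest.mark.parametrize("use_rc", [False, True])
    def test_batch_scorer_matches_scalar_plus_tiebreak(self, use_rc):
        rng = np.random.default_rng(7)
        c = ConstraintSet(n=5, d=3, use_rc=use_rc)
        accepted = ["ACGTA", "GTACG"]
        scorer = _BatchScorer(c, accepted)
        X = rng.uniform(0, 4, (40, 5))
        scores = scorer(X)
        for row, s in zip(X, scores):
            w = str(decode_vector(row))
            base = candidate_fitness(w, accepted, c)
            assert base <= s < base + 1.0  # tie-break term lives in [0, 1)


def clique_oracle(n, d, use_rc):
    """Maximum code size via networkx max clique (independent route)."""
    c = ConstraintSet(n=n, d=d, use_rc=use_rc)
    words = []
    for tup in itertools.product(BASES, repeat=n):
        w = "".join(tup)
        if gc_count(w) not in c.gc_tolerance:
            continue
        if not satisfies_no_runlength(w):
            continue
        if use_rc and hamming_distance(w, str(reverse_complement(w))) < d:
            continue
        words.append(w)
    G = nx.Graph()
    G.add_nodes_from(words)
    for a, b in itertools.combinations(words, 2):
        ok = hamming_distance(a, b) >= d
        if ok and use_rc:
            ok = hamming_distance(a, str(reverse_complement(b))) >= d
        if ok:
            G.add_edge(a, b)
    if not words:
        return 0
    clique, _ = nx.max_weight_clique(G, weight=None)
    return len(clique)


class TestExactSearch:
    @pytest.mark.parametrize("use_rc", [False, True])
    @pytest.mark.parametrize("n,d", [(3, 1), (3, 2), (3, 3),
                                     (4, 2), (4, 3), (4, 4)])
    def test_matches_clique_oracle(self, n, d, use_rc):
        cs = construct_code_set(
            SearchConfig(ConstraintSet(n=n, d=d, use_rc=use_rc), seed=0)
        )
        assert len(cs) == clique_oracle(n, d, use_rc)
        if len(cs):
            assert validate(cs).overall_pass

    @pytest.mark.parametrize("n", [3, 4])
    def test_rc_never_gains_words(self, n):
        for d in range(1, n + 1):
            plain = construct_code_set(
                SearchConfig(ConstraintSet(n=n, d=d), seed=0)
            )
            rc = construct_code_set(
                SearchConfig(ConstraintSet(n=n, d=d, use_rc=True), seed=0)
            )
            assert len(rc) <= len(plain)


class TestGreedySearch:
    def test_small_heuristic_run_is_valid_and_deterministic(self):
        c = ConstraintSet(n=5, d=4)
        sc = SearchConfig(c, seed=3, restarts=5)
        a = construct_code_set(sc)
        b = construct_code_set(sc)
        assert list(map(str, a.words)) == list(map(str, b.words))
        assert len(a) >= 8  # consensus floor for (n=5, d=4)
        assert validate(a).overall_pass

    def test_ss_constraint_respected(self):
        c = ConstraintSet(n=6, d=3, use_ss=True, ss_min_stem=2)
        cs = construct_code_set(SearchConfig(c, seed=0, restarts=3))
        assert len(cs) >= 1
        for w in cs:
            assert not has_secondary_structure(w, 2)
        assert validate(cs).overall_pass


class TestBoundsTable:
    def test_grid_contract(self):
        bt = build_bounds_table([4, 5], [3, 4], seed=0, restarts=3)
        frame = bt.frame
        assert len(frame) == 4
        for (n, d), cs in bt.codes.items():
            assert len(cs) == 0 or validate(cs).overall_pass
        # size non-increasing in d at fixed n
        for n in (4, 5):
            sizes = frame[frame.n == n].sort_values("d")["found"].tolist()
            assert sizes == sorted(sizes, reverse=True)
        # reference comparison columns present where published
        row = frame[(frame.n == 5) & (frame.d == 3)].iloc[0]
        assert row["prior"] == 20 and row["reported"] == 20
        assert "pct_vs_prior" in frame.columns

    def test_deterministic_under_seed(self):
        a = build_bounds_table([4], [3, 4], seed=5, restarts=2)
        b = build_bounds_table([4], [3, 4], seed=5, restarts=2)
        assert a.frame.equals(b.frame)

    def test_csv_export(self, tmp_path):
        bt = build_bounds_table([4], [4], seed=0, restarts=2)
        out = tmp_path / "bounds.csv"
        bt.to_csv(out)
        assert "found" in out.read_text().splitlines()[0]
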