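"""Published reference data for comparison: lower-bound tables and the
23-word example code set.

``GC_NL_BOUNDS`` maps (n, d) -> (best previously published size, size
reported for the moth-flame search) for C^{GC,NL}(n, floor(n/2), d);
``GC_NL_RC_BOUNDS`` likewise for C^{GC,NL,RC}(n, floor(n/2), d) where
the prior column is the earlier MFO-based construction.  These are
*reference points* for percent-improvement columns in bounds tables,
not ground truth: all are stochastic search results.

``TABLE5_WORDS`` is the published 23-word set quoted for (n=7, d=5)
under the full GC/NL/RC regime.  As shipped it does **not** satisfy
that regime (several words contain homopolymer runs and one pair is at
Hamming distance 4); the validator reports this faithfully, which makes
the set a useful validator fixture.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["GC_NL_BOUNDS", "GC_NL_RC_BOUNDS", "TABLE5_WORDS", "bounds_frame"]

# (n, d) -> (best prior published, moth-flame search report)
GC_NL_BOUNDS: dict[tuple[int, int], tuple[int, int]] = {
    (4, 3): (11, 12),
    (5, 3): (20, 20), (5, 4): (8, 8),
    (6, 3): (56, 63), (6, 4): (24, 27), (6, 5): (8, 9),
    (7, 3): (127, 208), (7, 4): (45, 68), (7, 5): (17, 23), (7, 6): (7, 8),
    (8, 3): (324, 469), (8, 4): (106, 171), (8, 5): (35, 42),
    (8, 6): (14, 18), (8, 7): (5, 6),
    (9, 3): (713, 1210), (9, 4): (199, 279), (9, 5): (65, 90),
    (9, 6): (24, 37), (9, 7): (10, 13), (9, 8): (5, 6),
    (10, 3): (2081, 3391), (10, 4): (555, 829), (10, 5): (159, 205),
    (10, 6): (54, 79), (10, 7): (20, 25), (10, 8): (10, 10), (10, 9): (4, 4),
    (11, 3): (4320, 4703), (11, 4): (1235, 1967), (11, 5): (284, 429),
    (11, 6): (82, 124), (11, 7): (29, 41), (11, 8): (9, 8),
    (11, 9): (4, 5), (11, 10): (4, 4),
    (12, 3): (12068, 11967), (12, 4): (3326, 5195), (12, 5): (662, 934),
    (12, 6): (190, 509), (12, 7): (58, 73), (12, 8): (22, 13),
    (12, 9): (8, 9), (12, 10): (4, 6),
    (13, 3): (41867, 42343), (13, 4): (7578, 8392), (13, 5): (1432, 1780),
    (13, 6): (1201, 1519), (13, 7): (123, 197), (13, 8): (39, 51),
    (13, 9): (13, 15), (13, 10): (6, 9),
}

GC_NL_RC_BOUNDS: dict[tuple[int, int], tuple[int, int]] = {
    (4, 3): (11, 11),
    (5, 3): (24, 21), (5, 4): (8, 8),
    (6, 3): (58, 71), (6, 4): (26, 26), (6, 5): (7, 7),
    (7, 3): (148, 134), (7, 4): (49, 63), (7, 5): (19, 23), (7, 6): (6, 5),
    (8, 3): (328, 419), (8, 4): (114, 149), (8, 5): (35, 51),
    (8, 6): (11, 11), (8, 7): (6, 6),
    (9, 3): (906, 1026), (9, 4): (281, 362), (9, 5): (83, 113),
    (9, 6): (30, 49), (9, 7): (9, 9), (9, 8): (4, 4),
    (10, 3): (2254, 2249), (10, 4): (721, 897), (10, 5): (189, 248),
    (10, 6): (79, 127), (10, 7): (17, 27), (10, 8): (5, 5), (10, 9): (5, 5),
}

# published example set for n=7, d=5 under the GC/NL/RC regime
TABLE5_WORDS: list[str] = [
    "CTGTGAC", "ATGTACG", "CATCTGC", "GCAATCT", "AGACATG", "GTCTGAC",
    "TAGCCTA", "TCAGTCA", "GAGATTC", "GTACTAT", "GATGCTA", "CTGCCTC",
    "GAATGCT", "TACGCAG", "GTACGAT", "ACTGACA", "CTACGAT", "GTGACAC",
    "CATCGAG", "GGCACTA", "ACGAGTC", "TGTTACG", "TGAACTG",
]


def bounds_frame(with_rc: bool = False) -> pd.DataFrame:
    """Reference bounds as a tidy DataFrame (n, d, prior, reported)."""
    src = GC_NL_RC_BOUNDS if with_rc else GC_NL_BOUNDS
    return pd.DataFrame(
        [
            {"n": n, "d": d, "prior": prior, "reported": rep}
            for (n, d), (prior, rep) in sorted(src.items())
        ]
    )
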