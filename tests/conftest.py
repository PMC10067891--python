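import itertools

import pytest
from hypothesis import HealthCheck, settings

from mothcode.codeset import CodeSet
from mothcode.dna_core import BASES, ConstraintSet
from mothcode.reference import TABLE5_WORDS

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table5():
    """The published 23-word (n=7) example code set."""
    return CodeSet(TABLE5_WORDS, provenance="published table")


@pytest.fixture(scope="session")
def full_space():
    """All 4^n words for small n, keyed by n."""
    return {
        n: ["".join(p) for p in itertools.product(BASES, repeat=n)]
        for n in (2, 3, 4)
    }


def make_constraints(n, d, **kw):
    return ConstraintSet(n=n, d=d, **kw)
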