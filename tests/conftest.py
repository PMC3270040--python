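import math

import pytest

from famseg.core_model import StudyConfig
from famseg.fixtures import (
    load_reference_pedigrees,
    load_reference_variants,
)


@pytest.fixture(scope="session")
def config():
    return StudyConfig()

@pytest.fixture(scope="session")
def reference_variants():
    return load_reference_variants()


@pytest.fixture(scope="session")
def reference_pedigrees():
    return load_reference_pedigrees()


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over all tables with
    the observed margins: sum of hypergeometric probabilities no larger
    than the observed table's."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)

    def pr(x: int) -> float:
        return math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom

    p_obs = pr(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-9))
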