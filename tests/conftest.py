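import numpy as np
import pytest

from condsimp.gpmaps import MatrixMap
from condsimp.gpmaps.base import Genotype
from condsimp.nullmaps import toy_enumerable_map


@pytest.fixture(scope="session")
def toy_map():
    return toy_enumerable_map()


@pytest.fixture(scope="session")
def toy_genotypes(toy_map):
    """All 64 genotypes of the 6-bit toy map."""
    return [
        Genotype(tuple((i >> b) & 1 for b in range(6)), toy_map.alphabet_sizes)
        for i in range(64)
    ]


@pytest.fixture(scope="session")
def small_matrix_map():
    return MatrixMap(L=8, seed=11)


def naive_lz76_words(s: str) -> int:
    """Brute-force LZ76 exhaustive-history parser (independent oracle).

    Grows each word by one symbol while it can still be reproduced from
    the history (it occurs as a substring ending before the current
    position); the first non-reproducible extension closes the word.  The
    final word is counted even when reproducible.
    """
    w = 0
    start = 0
    while start < len(s):
        j = start + 1
        while j <= len(s) and s[start:j] in s[: j - 1]:
            j += 1
        j = min(j, len(s))
        w += 1
        start = j
    return w
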