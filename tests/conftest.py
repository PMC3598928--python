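import numpy as np
import pytest
from hypothesis import settings

from bandmap.index import IndexConfig, build_index
from bandmap.simulate import random_genome

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# a scaled index geometry that keeps bucket collisions observable in tests
SMALL_GEOMETRY = dict(prefix_bits=8, hash_bits=6)


@pytest.fixture(scope="session")
def genome_10k():
    return random_genome(10_000, rng_seed=101)


@pytest.fixture(scope="session")
def index_10k(genome_10k):
    return build_index(genome_10k, IndexConfig(rng_seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def brute_force_banded(read: str, ref: str, d: int,
                       free_start: bool = True) -> int | None:
    """Independent oracle: enumerate every banded semi-global path.

    Paths start at any (i0, 0) (free leading reference gaps; origin only
    when ``free_start`` is False), consume the read end to end through
    cells with |i - j| <= d, and stop at the last read column (free
    trailing reference gaps).  Returns None when no path exists.
    Exponential; for tiny inputs only.
    """
    n, m = len(read), len(ref)
    best = [10**9]

    def go(i, j, cost):
        if cost >= best[0]:
            return
        if j == n:
            best[0] = cost
            return
        if i < m and abs((i + 1) - (j + 1)) <= d:
            go(i + 1, j + 1, cost + (0 if ref[i] == read[j] else 1))
        if i < m and abs((i + 1) - j) <= d:
            go(i + 1, j, cost + 1)
        if abs(i - (j + 1)) <= d:
            go(i, j + 1, cost + 1)

    for i0 in range(m + 1) if free_start else (0,):
        go(i0, 0, 0)
    return best[0] if best[0] < 10**9 else None
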