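"""Shared fixtures: worked partition pair, random partition factories."""

import numpy as np
import pytest
from hypothesis import settings

from meanpartition import Partition, PosteriorSample

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def worked_pair():
    """The small 5-element pair used as a worked example throughout.

    p1 = {{0,1,2},{3,4}}, p2 = {{0,1},{2,3,4}}; their partition distance is
    1 (delete element 2 from both), their cost matrix [[1,2],[2,0]].
    """
    return Partition([0, 0, 0, 1, 1]), Partition([0, 0, 1, 1, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_partition():
    """Factory: a random partition of n elements with at most max_c clusters."""

    def make(n: int, max_c: int, rng: np.random.Generator) -> Partition:
        return Partition(rng.integers(0, max_c, size=n))

    return make


@pytest.fixture
def random_sample(random_partition):
    """Factory: a random posterior sample (k partitions of n elements)."""

    def make(n: int, k: int, max_c: int,
             rng: np.random.Generator) -> PosteriorSample:
        return PosteriorSample(
            [random_partition(n, max_c, rng) for _ in range(k)])

    return make


def enumerate_set_partitions(n: int):
    """All set partitions of 0..n-1 as label tuples (restricted growth strings).

    Independent oracle for exhaustive mean-partition searches at tiny n
    (Bell(5) = 52).
    """
    def rec(prefix, max_label):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(max_label + 2):
            yield from rec(prefix + [lab], max(max_label, lab))

    yield from rec([0], 0)
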