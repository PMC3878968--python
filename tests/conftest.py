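import itertools

import numpy as np
import pytest

from ordalt import SampleSet


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive, used only in tests)
# ---------------------------------------------------------------------------


def brute_rank(values):
    """Min-rank by literal counting."""
    return [1 + sum(1 for y in values if y < x) for x in values]


def brute_ktmb_kernel(values):
    return sum(1 for i, r in enumerate(brute_rank(values), start=1) if r == i)


def brute_tm_kernel(values):
    asc = all(a <= b for a, b in zip(values, values[1:]))
    strict = any(a < b for a, b in zip(values, values[1:]))
    return int(asc and strict)


def brute_tuple_sum(samples, kernel):
    return sum(kernel(tup) for tup in itertools.product(*samples))


def brute_jt(samples):
    total = 0
    k = len(samples)
    for l in range(k - 1):
        for m in range(l + 1, k):
            total += sum(
                1 for a in samples[l] for b in samples[m] if a < b
            )
    return total


def brute_mjt(samples):
    total = 0
    k = len(samples)
    for l in range(k - 1):
        for m in range(l + 1, k):
            total += (m - l) * sum(
                1 for a in samples[l] for b in samples[m] if a < b
            )
    return total


def rank_partitions(sizes):
    """All assignments of ranks 1..N to groups with the given sizes."""
    from sympy.utilities.iterables import multiset_permutations

    labels = [i for i, n in enumerate(sizes) for _ in range(n)]
    for perm in multiset_permutations(labels):
        groups = [[] for _ in sizes]
        for rank, lab in enumerate(perm, start=1):
            groups[lab].append(float(rank))
        yield groups


@pytest.fixture
def rng():
    return np.random.default_rng(20231205)


@pytest.fixture
def random_sample_set(rng):
    def make(sizes, ties=False):
        if ties:
            data = [rng.integers(0, 4, size=n).astype(float) for n in sizes]
        else:
            data = [rng.permutation(np.arange(sum(sizes), dtype=float))[: n] for n in sizes]
            # ensure disjoint values across groups
            pool = rng.permutation(np.arange(sum(sizes), dtype=float))
            out, i = [], 0
            for n in sizes:
                out.append(pool[i: i + n])
                i += n
            data = out
        return SampleSet(data)

    return make
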