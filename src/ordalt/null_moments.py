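"""Null distributions and null moments of the test statistics.

Under H0 all observations come from one continuous distribution, so the
statistics depend on the data only through the assignment of the pooled ranks
1..N to groups, and every one of the N!/(n1! ... nk!) rank partitions is
equally likely.  Three exact routes and one stochastic route are provided:

enumeration
    Visit every rank partition, compute the statistic, tally an exact PMF
    (rational probabilities) and its moments.  Feasible for small designs.

tie-pattern decomposition
    The variance of a tuple statistic is the sum of covariances between the
    kernels of every ordered pair of tuples.  A pair's covariance depends
    only on which positions share an observation (the "tie pattern"
    S, a subset of {1..k}); tuples sharing no observation are independent.
    For each non-empty S the covariance is computed exactly by enumerating
    all (2k - |S|)! relative orderings of the distinct values involved, and
    multiplied by the number of tuple pairs with that pattern,
    prod_{i in S} n_i * prod_{i not in S} n_i (n_i - 1).  The null mean is
    N* times the kernel's null mean (1 for KTMB, 1/k! for TM, 0 for KTP).
    Exact for arbitrary sample sizes, any k up to the enumeration cap.

closed forms
    Textbook Mann-Whitney moments for JT, and the analogous pairwise-
    covariance closed form for the weighted MJT.

Monte Carlo
    Sample random rank partitions with a seeded generator; fallback when the
    exact routes are out of reach.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import BudgetExceededError, InputError
from .statistics import TUPLE_STATISTICS, batch_statistics

__all__ = [
    "NullDistribution",
    "NullMoments",
    "count_rank_partitions",
    "enumerate_null_pmf",
    "enumeration_moments",
    "exact_null_moments",
    "mc_null_moments",
    "jt_null_moments",
    "mjt_null_moments",
    "null_moments",
    "MomentsCache",
]

DEFAULT_ENUM_BUDGET = 10**6
DEFAULT_RATIONAL_BUDGET = 10**5
DEFAULT_PATTERN_K_CAP = 5


@dataclass
class NullMoments:
    """Exact or estimated (mean, variance) of a statistic under H0."""

    mean: float
    variance: float
    method: str  # closed_form | enumeration | tie_pattern_exact | monte_carlo
    mc_reps: Optional[int] = None
    seed: Optional[int] = None


@dataclass
class NullDistribution:
    """Exact PMF of a statistic over all equally likely rank partitions."""

    sizes: tuple[int, ...]
    statistic_name: str
    support: np.ndarray
    probabilities: list  # Fractions (exact) or floats
    mean: float
    variance: float
    partition_count: int
    # exact rational moments retained for bit-exact checks
    mean_exact: Fraction = field(default=Fraction(0), repr=False)
    variance_exact: Fraction = field(default=Fraction(0), repr=False)

    def pmf_dict(self) -> dict:
        return dict(zip((float(v) for v in self.support), self.probabilities))

    def moments(self) -> NullMoments:
        return NullMoments(self.mean, self.variance, "enumeration")


def _check_sizes(sizes: Sequence[int]) -> tuple[int, ...]:
    sizes = tuple(int(n) for n in sizes)
    if len(sizes) < 2 or any(n < 1 for n in sizes):
        raise InputError("sizes must list k >= 2 group sizes, each >= 1")
    return sizes


def count_rank_partitions(sizes: Sequence[int]) -> int:
    """Exact multinomial coefficient N!/(n1! ... nk!)."""
    sizes = _check_sizes(sizes)
    total = math.factorial(sum(sizes))
    for n in sizes:
        total //= math.factorial(n)
    return total


# ---------------------------------------------------------------------------
# enumeration of rank partitions
# ---------------------------------------------------------------------------


def _iter_partition_chunks(
    sizes: tuple[int, ...], chunk: int = 8192
) -> Iterator[np.ndarray]:
    """Yield (P, N) arrays of group labels, one row per rank partition."""
    from sympy.utilities.iterables import multiset_permutations

    labels = [i for i, n in enumerate(sizes) for _ in range(n)]
    buf: list[list[int]] = []
    for perm in multiset_permutations(labels):
        buf.append(perm)
        if len(buf) >= chunk:
            yield np.asarray(buf, dtype=np.int8)
            buf = []
    if buf:
        yield np.asarray(buf, dtype=np.int8)


def _labels_to_groups(label_chunk: np.ndarray, sizes: tuple[int, ...]):
    """Convert label rows to per-group rank arrays of shape (P, n_i).

    Column j of a label row carries rank j+1; group i receives the ranks at
    the positions labelled i.
    """
    ranks = np.arange(1, label_chunk.shape[1] + 1, dtype=float)
    groups = []
    for i, n in enumerate(sizes):
        rows, cols = np.nonzero(label_chunk == i)
        groups.append(ranks[cols].reshape(-1, n))
    return groups


def _statistic_scale(statistic: str, k: int) -> int:
    """Integer scale making every attainable value of the statistic integral
    (rank data): 1 for counting statistics, k(k^2-1) for KTP."""
    return k * (k * k - 1) if statistic == "KTP" else 1


def enumerate_null_pmf(
    sizes: Sequence[int],
    statistic: str = "KTMB",
    budget: int = DEFAULT_ENUM_BUDGET,
    rational_budget: int = DEFAULT_RATIONAL_BUDGET,
) -> NullDistribution:
    """Exact null PMF by full enumeration of rank partitions.

    Probabilities are rational (``fractions.Fraction``) when the partition
    count is at most ``rational_budget``, floats beyond; moments are computed
    in exact integer arithmetic either way.
    """
    sizes = _check_sizes(sizes)
    k = len(sizes)
    total = count_rank_partitions(sizes)
    if total > budget:
        raise BudgetExceededError(
            f"{total} rank partitions exceed the enumeration budget {budget}; "
            "use exact_null_moments or mc_null_moments instead"
        )
    scale = _statistic_scale(statistic, k)
    tally: Counter = Counter()
    for chunk in _iter_partition_chunks(sizes):
        groups = _labels_to_groups(chunk, sizes)
        vals = batch_statistics(groups, [statistic])[statistic]
        scaled = np.rint(vals * scale).astype(np.int64)
        tally.update(scaled.tolist())
    assert sum(tally.values()) == total
    support_scaled = sorted(tally)
    counts = [tally[v] for v in support_scaled]
    mean_s = Fraction(sum(v * c for v, c in zip(support_scaled, counts)), total)
    ex2_s = Fraction(sum(v * v * c for v, c in zip(support_scaled, counts)), total)
    var_s = ex2_s - mean_s * mean_s
    mean = mean_s / scale
    var = var_s / scale / scale
    if total <= rational_budget:
        probs = [Fraction(c, total) for c in counts]
    else:
        probs = [c / total for c in counts]
    support = np.asarray([v / scale for v in support_scaled], dtype=float)
    return NullDistribution(
        sizes=sizes,
        statistic_name=statistic,
        support=support,
        probabilities=probs,
        mean=float(mean),
        variance=float(var),
        partition_count=total,
        mean_exact=mean,
        variance_exact=var,
    )


def enumeration_moments(
    sizes: Sequence[int],
    statistics: Sequence[str],
    budget: int = DEFAULT_ENUM_BUDGET,
) -> dict[str, NullMoments]:
    """Exact null moments for several statistics in one enumeration sweep.

    Shares the partition generation across statistics; moments are exact
    (integer/rational arithmetic on scaled statistic values).
    """
    sizes = _check_sizes(sizes)
    k = len(sizes)
    total = count_rank_partitions(sizes)
    if total > budget:
        raise BudgetExceededError(
            f"{total} rank partitions exceed the enumeration budget {budget}"
        )
    scales = {s: _statistic_scale(s, k) for s in statistics}
    sums = {s: 0 for s in statistics}
    sqsums = {s: 0 for s in statistics}
    for chunk in _iter_partition_chunks(sizes):
        groups = _labels_to_groups(chunk, sizes)
        vals = batch_statistics(groups, list(statistics))
        for s in statistics:
            scaled = np.rint(vals[s] * scales[s]).astype(np.int64)
            sums[s] += int(scaled.sum())
            sqsums[s] += int((scaled * scaled).sum())
    out = {}
    for s in statistics:
        mean_s = Fraction(sums[s], total)
        var_s = Fraction(sqsums[s], total) - mean_s * mean_s
        out[s] = NullMoments(
            mean=float(mean_s / scales[s]),
            variance=float(var_s / scales[s] / scales[s]),
            method="enumeration",
        )
    return out


# ---------------------------------------------------------------------------
# tie-pattern exact moments for tuple statistics
# ---------------------------------------------------------------------------


def _scaled_kernels(values: np.ndarray, statistic: str, k: int) -> np.ndarray:
    """Integer-scaled kernel values for rows of distinct values."""
    ranks = 1 + (values[:, None, :] < values[:, :, None]).sum(axis=2)
    pos = np.arange(1, k + 1)
    if statistic == "KTMB":
        return (ranks == pos).sum(axis=1).astype(np.int64)
    if statistic == "TM":
        return np.all(np.diff(values, axis=1) > 0, axis=1).astype(np.int64)
    if statistic == "KTP":
        D = k * (k * k - 1)
        return (D - 6 * ((ranks - pos) ** 2).sum(axis=1)).astype(np.int64)
    raise InputError(f"not a tuple statistic: {statistic!r}")


@lru_cache(maxsize=None)
def _kernel_null_moments(k: int, statistic: str) -> tuple[Fraction, Fraction]:
    """Exact (mean, variance) of a tuple kernel over all k! orderings."""
    perms = np.asarray(list(itertools.permutations(range(k))), dtype=np.int64)
    scale = _statistic_scale(statistic, k)
    kv = _scaled_kernels(perms, statistic, k)
    m = math.factorial(k)
    mean = Fraction(int(kv.sum()), m) / scale
    ex2 = Fraction(int((kv * kv).sum()), m) / scale / scale
    return mean, ex2 - mean * mean


@lru_cache(maxsize=None)
def _pattern_covariance(k: int, shared: frozenset, statistic: str) -> Fraction:
    """Exact covariance of the kernels of two tuples sharing exactly the
    positions in ``shared``, by enumerating all orderings of the
    2k - |shared| distinct values involved."""
    s = len(shared)
    m = 2 * k - s
    # slot layout: shared positions first, then tuple-a extras, then tuple-b's
    a_idx = np.empty(k, dtype=np.int64)
    b_idx = np.empty(k, dtype=np.int64)
    nxt = s
    for j, pos in enumerate(sorted(shared)):
        a_idx[pos] = j
        b_idx[pos] = j
    for pos in range(k):
        if pos not in shared:
            a_idx[pos] = nxt
            b_idx[pos] = nxt + (k - s)
            nxt += 1
    perms = np.asarray(list(itertools.permutations(range(m))), dtype=np.int64)
    scale = _statistic_scale(statistic, k)
    ka = _scaled_kernels(perms[:, a_idx], statistic, k)
    kb = _scaled_kernels(perms[:, b_idx], statistic, k)
    mean, _ = _kernel_null_moments(k, statistic)
    e_ab = Fraction(int(ka @ kb), math.factorial(m)) / scale / scale
    return e_ab - mean * mean


def exact_null_moments(
    sizes: Sequence[int],
    statistic: str = "KTMB",
    k_cap: int = DEFAULT_PATTERN_K_CAP,
) -> NullMoments:
    """Exact null moments of a tuple statistic via the tie-pattern
    covariance decomposition; valid for arbitrary sample sizes.

    Raises
    ------
    BudgetExceededError
        When k exceeds the per-pattern enumeration cap; use
        :func:`mc_null_moments` instead.
    """
    sizes = _check_sizes(sizes)
    if statistic not in TUPLE_STATISTICS:
        raise InputError(
            f"tie-pattern moments apply to tuple statistics {TUPLE_STATISTICS}"
        )
    k = len(sizes)
    if k > k_cap:
        raise BudgetExceededError(
            f"k={k} exceeds the tie-pattern enumeration cap {k_cap}; "
            "use mc_null_moments"
        )
    nstar = math.prod(sizes)
    mean_kernel, _ = _kernel_null_moments(k, statistic)
    mean = nstar * mean_kernel
    var = Fraction(0)
    for r in range(1, k + 1):
        for shared in itertools.combinations(range(k), r):
            pairs = 1
            for i in range(k):
                if i in shared:
                    pairs *= sizes[i]
                else:
                    pairs *= sizes[i] * (sizes[i] - 1)
            if pairs == 0:
                continue
            var += pairs * _pattern_covariance(k, frozenset(shared), statistic)
    return NullMoments(mean=float(mean), variance=float(var), method="tie_pattern_exact")


# ---------------------------------------------------------------------------
# Monte Carlo and closed forms
# ---------------------------------------------------------------------------


def mc_null_moments(
    sizes: Sequence[int],
    statistic: str = "KTMB",
    reps: int = 200_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> NullMoments:
    """Seeded Monte Carlo null moments from random rank partitions."""
    sizes = _check_sizes(sizes)
    if reps < 1000:
        raise InputError("mc_null_moments needs reps >= 1000")
    N = sum(sizes)
    rng = np.random.default_rng(seed)
    offsets = np.cumsum((0,) + sizes)
    vals = np.empty(reps, dtype=float)
    done = 0
    while done < reps:
        p = min(chunk, reps - done)
        perms = rng.permuted(
            np.broadcast_to(np.arange(1, N + 1, dtype=float), (p, N)).copy(), axis=1
        )
        groups = [perms[:, offsets[i]: offsets[i + 1]] for i in range(len(sizes))]
        vals[done: done + p] = batch_statistics(groups, [statistic])[statistic]
        done += p
    return NullMoments(
        mean=float(vals.mean()),
        variance=float(vals.var(ddof=1)),
        method="monte_carlo",
        mc_reps=reps,
        seed=seed,
    )


def jt_null_moments(sizes: Sequence[int]) -> NullMoments:
    """Closed-form JT null moments (no ties assumed):
    E = (N^2 - sum n_i^2)/4, V = [N^2(2N+3) - sum n_i^2(2n_i+3)]/72."""
    sizes = _check_sizes(sizes)
    N = sum(sizes)
    sq = sum(n * n for n in sizes)
    mean = Fraction(N * N - sq, 4)
    var = Fraction(N * N * (2 * N + 3) - sum(n * n * (2 * n + 3) for n in sizes), 72)
    return NullMoments(mean=float(mean), variance=float(var), method="closed_form")


def mjt_null_moments(sizes: Sequence[int]) -> NullMoments:
    """Closed-form null moments of MJT = sum_{l<m} (m-l) U_lm.

    Mean: each of the n_l n_m pairs is ascending with probability 1/2.
    Variance: Var U_lm = n_l n_m (n_l + n_m + 1)/12; two Mann-Whitney counts
    sharing one group g contribute n_g n_a n_b / 12 with sign +1 when g sits
    on the same side (smaller-group or larger-group) of both counts and -1
    otherwise; disjoint counts are uncorrelated.
    """
    sizes = _check_sizes(sizes)
    k = len(sizes)
    pairs = [(l, m) for l in range(k) for m in range(l + 1, k)]
    mean = Fraction(
        sum((m - l) * sizes[l] * sizes[m] for l, m in pairs), 2
    )
    var = Fraction(0)
    for l, m in pairs:
        w = m - l
        var += Fraction(w * w * sizes[l] * sizes[m] * (sizes[l] + sizes[m] + 1), 12)
    for (l, m), (l2, m2) in itertools.combinations(pairs, 2):
        shared = {l, m} & {l2, m2}
        if len(shared) != 1:
            continue
        g = shared.pop()
        others = ({l, m} | {l2, m2}) - {g}
        a, b = others
        same_side = (g == l and g == l2) or (g == m and g == m2)
        sign = 1 if same_side else -1
        cov = Fraction(sizes[g] * sizes[a] * sizes[b], 12)
        var += 2 * (m - l) * (m2 - l2) * sign * cov
    return NullMoments(mean=float(mean), variance=float(var), method="closed_form")


# ---------------------------------------------------------------------------
# dispatcher and advisory cache
# ---------------------------------------------------------------------------


def null_moments(
    sizes: Sequence[int],
    statistic: str,
    policy: str = "auto",
    enum_budget: int = DEFAULT_ENUM_BUDGET,
    k_cap: int = DEFAULT_PATTERN_K_CAP,
    mc_reps: int = 200_000,
    seed: int = 0,
    cache: "Optional[MomentsCache]" = None,
) -> NullMoments:
    """Null moments under a method policy.

    ``auto`` picks the most exact feasible route: closed forms for JT and
    MJT; enumeration when the partition count fits the budget; otherwise the
    tie-pattern decomposition (tuple statistics, k within cap); otherwise
    seeded Monte Carlo.
    """
    sizes = _check_sizes(sizes)
    key = None
    if cache is not None:
        key = cache.key(sizes, statistic, policy)
        hit = cache.get(key)
        if hit is not None:
            return hit

    def _compute() -> NullMoments:
        if policy == "closed_form" or (policy == "auto" and statistic in ("JT", "MJT")):
            if statistic == "JT":
                return jt_null_moments(sizes)
            if statistic == "MJT":
                return mjt_null_moments(sizes)
            raise InputError(f"no closed-form moments for {statistic}")
        if policy == "enumeration":
            return enumerate_null_pmf(sizes, statistic, budget=enum_budget).moments()
        if policy == "tie_pattern":
            return exact_null_moments(sizes, statistic, k_cap=k_cap)
        if policy == "monte_carlo":
            return mc_null_moments(sizes, statistic, reps=mc_reps, seed=seed)
        if policy != "auto":
            raise InputError(f"unknown moment policy {policy!r}")
        if count_rank_partitions(sizes) <= enum_budget:
            return enumerate_null_pmf(sizes, statistic, budget=enum_budget).moments()
        if statistic in TUPLE_STATISTICS and len(sizes) <= k_cap:
            return exact_null_moments(sizes, statistic, k_cap=k_cap)
        return mc_null_moments(sizes, statistic, reps=mc_reps, seed=seed)

    result = _compute()
    if cache is not None and key is not None:
        cache.put(key, result)
    return result


class MomentsCache:
    """Advisory plain-text (JSON) cache of computed null moments."""

    def __init__(self, path: str):
        self.path = path
        self._data: dict = {}
        if os.path.exists(path):
            try:
                with open(path) as fh:
                    self._data = json.load(fh)
            except (OSError, json.JSONDecodeError):
                self._data = {}

    @staticmethod
    def key(sizes: Sequence[int], statistic: str, policy: str) -> str:
        return f"{','.join(str(n) for n in sizes)}|{statistic}|{policy}"

    def get(self, key: str) -> Optional[NullMoments]:
        rec = self._data.get(key)
        if rec is None:
            return None
        return NullMoments(**rec)

    def put(self, key: str, moments: NullMoments) -> None:
        self._data[key] = {
            "mean": moments.mean,
            "variance": moments.variance,
            "method": moments.method,
            "mc_reps": moments.mc_reps,
            "seed": moments.seed,
        }
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(self._data, fh, indent=1, sort_keys=True)
        os.replace(tmp, self.path)
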