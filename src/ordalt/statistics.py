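"""Tuple kernels and the five ordered-alternative test statistics.

Three of the tests are *k-tuplet* statistics: a kernel is evaluated on every
one of the N* = n1*...*nk tuples formed by drawing one observation from each
group (in hypothesis order) and summed,

    T = sum over (j1,...,jk) of  kernel(x_{1 j1}, ..., x_{k jk}).

Kernels
-------
KTMB  count of positions i whose within-tuple rank equals i (fixed points of
      the tuple's rank permutation).
TM    indicator that the tuple is non-decreasing with at least one strict
      inequality.
KTP   Spearman rank correlation between the tuple's within-tuple ranks and
      the group indices (1, ..., k).

The remaining two are sums of pairwise Mann-Whitney counts
U_lm = #{(a, b): x_{l a} < x_{m b}} over group pairs l < m:

    JT  = sum U_lm            MJT = sum (m - l) * U_lm.

All five are rank statistics: they are invariant under any strictly
increasing transformation of the data.

Two computation routes are provided.  ``tuple_statistic`` enumerates tuples
literally (lexicographic in the index vector, with a budget guard) and is the
readable reference.  The module-level ``*_statistic`` functions use an
O(k^2 * N) rank-counting route (see ``batch_statistics``) whenever it is
valid, which makes the Monte Carlo power study practical.

The underlying model assumes continuous responses, so ties have probability
zero; when ties do occur the statistics are still computed under documented
conventions (min-rank for KTMB, non-strict comparison for TM, average ranks
for KTP, strict inequality only in U_lm) and a :class:`TieWarning` is issued.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Dict, Sequence

import numpy as np

from .errors import BudgetExceededError, InputError
from .samples import SampleSet

__all__ = [
    "STATISTIC_NAMES",
    "TUPLE_STATISTICS",
    "TieWarning",
    "rank_within_tuple",
    "ktmb_kernel",
    "tm_kernel",
    "ktp_kernel",
    "tuple_statistic",
    "jt_statistic",
    "mjt_statistic",
    "ktmb_statistic",
    "tm_statistic",
    "ktp_statistic",
    "compute_statistic",
    "batch_statistics",
]

#: fixed report order of the test battery
STATISTIC_NAMES = ("KTMB", "KTP", "JT", "MJT", "TM")

#: the statistics defined as sums of a kernel over all k-tuplets
TUPLE_STATISTICS = ("KTMB", "TM", "KTP")

DEFAULT_TUPLE_BUDGET = 10**7


class TieWarning(UserWarning):
    """Exact duplicate values found in data assumed to be continuous."""


def _check_tuple(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InputError("a tuple kernel needs a 1-d vector of length >= 2")
    return v


def rank_within_tuple(values: Sequence[float]) -> np.ndarray:
    """Min-ranks of each element within the tuple.

    The rank of ``x_i`` is ``1 +`` the number of elements strictly below it,
    so a tie-free tuple yields a permutation of 1..k and tied elements share
    the smallest rank of their block.
    """
    v = _check_tuple(values)
    return 1 + (v[None, :] < v[:, None]).sum(axis=1)


def ktmb_kernel(values: Sequence[float]) -> int:
    """Number of fixed points of the tuple's rank permutation.

    For tie-free input the value lies in {0, ..., k} \\ {k-1}: a permutation
    cannot fix exactly k-1 points.
    """
    ranks = rank_within_tuple(values)
    k = ranks.size
    return int(np.sum(ranks == np.arange(1, k + 1)))


def tm_kernel(values: Sequence[float]) -> int:
    """1 iff x1 <= x2 <= ... <= xk with at least one strict inequality."""
    v = _check_tuple(values)
    d = np.diff(v)
    return int(np.all(d >= 0) and np.any(d > 0))


def ktp_kernel(values: Sequence[float]) -> float:
    """Spearman correlation of within-tuple (average) ranks with 1..k.

    A fully tied tuple carries no trend information and returns 0.
    """
    from scipy.stats import rankdata

    v = _check_tuple(values)
    r = rankdata(v)  # average ranks under ties
    k = r.size
    g = np.arange(1, k + 1, dtype=float)
    rc = r - r.mean()
    gc = g - g.mean()
    denom = math.sqrt(float(rc @ rc) * float(gc @ gc))
    if denom == 0.0:
        return 0.0
    return float(rc @ gc) / denom


_KERNELS = {"KTMB": ktmb_kernel, "TM": tm_kernel, "KTP": ktp_kernel}


def _warn_ties(data: SampleSet) -> None:
    if data.has_ties():
        warnings.warn(
            "tied observations present; the tests assume continuous data "
            "(documented tie conventions applied)",
            TieWarning,
            stacklevel=3,
        )


def tuple_statistic(
    data: SampleSet,
    kernel: str,
    budget: int = DEFAULT_TUPLE_BUDGET,
) -> float:
    """Sum a tuple kernel over all N* k-tuplets by explicit enumeration.

    Tuples are visited in lexicographic order of the index vector
    (j1, ..., jk).  This is the reference implementation; the dedicated
    ``*_statistic`` functions are much faster on large designs.
    """
    if kernel not in _KERNELS:
        raise InputError(f"unknown tuple kernel {kernel!r}; choose from {list(_KERNELS)}")
    if data.k < 3:
        raise InputError("tuple statistics require k >= 3 groups")
    if data.n_tuples > budget:
        raise BudgetExceededError(
            f"{data.n_tuples} tuples exceed the enumeration budget {budget}; "
            "raise the budget or use the fast statistic functions"
        )
    _warn_ties(data)
    fn = _KERNELS[kernel]
    total = 0.0
    for tup in itertools.product(*data.samples):
        total += fn(np.asarray(tup))
    if kernel in ("KTMB", "TM"):
        return float(int(round(total)))
    return total


def jt_statistic(data: SampleSet) -> int:
    """Jonckheere-Terpstra statistic: sum of strict ascending pair counts."""
    if data.k < 3:
        raise InputError("JT requires k >= 3 groups")
    _warn_ties(data)
    total = 0
    for l in range(data.k - 1):
        for m in range(l + 1, data.k):
            total += int(np.sum(data.samples[l][:, None] < data.samples[m][None, :]))
    return total


def mjt_statistic(data: SampleSet) -> float:
    """Modified JT statistic: pair counts weighted by group distance m - l."""
    if data.k < 3:
        raise InputError("MJT requires k >= 3 groups")
    _warn_ties(data)
    total = 0
    for l in range(data.k - 1):
        for m in range(l + 1, data.k):
            u = int(np.sum(data.samples[l][:, None] < data.samples[m][None, :]))
            total += (m - l) * u
    return float(total)


# ---------------------------------------------------------------------------
# fast vectorized route
# ---------------------------------------------------------------------------


def _below_counts(groups: Sequence[np.ndarray], i: int) -> list[np.ndarray]:
    """For each group l != i, count of group-l values strictly below each
    observation of group i.  groups[l] has shape (reps, n_l)."""
    out = []
    gi = groups[i][:, :, None]  # (reps, n_i, 1)
    for l, gl in enumerate(groups):
        if l == i:
            continue
        out.append((gl[:, None, :] < gi).sum(axis=2))  # (reps, n_i)
    return out


def _rank_count_polys(groups: Sequence[np.ndarray], i: int, sizes) -> np.ndarray:
    """Coefficient table C of shape (reps, n_i, k): C[..., r-1] is the number
    of tuples in which observation x of group i has within-tuple min-rank r,
    i.e. exactly r-1 of the k-1 companions are strictly below x.  Obtained as
    the coefficients of prod_{l != i} (d_l + c_l z) where c_l counts group-l
    values below x and d_l = n_l - c_l."""
    k = len(groups)
    reps, n_i = groups[i].shape
    coeff = np.zeros((reps, n_i, k), dtype=np.int64)
    coeff[..., 0] = 1
    counts = _below_counts(groups, i)
    others = [l for l in range(k) if l != i]
    for c, l in zip(counts, others):
        d = sizes[l] - c
        new = coeff * d[..., None]
        new[..., 1:] += coeff[..., :-1] * c[..., None]
        coeff = new
    return coeff


def batch_statistics(
    groups: Sequence[np.ndarray], tests: Sequence[str]
) -> Dict[str, np.ndarray]:
    """Compute the requested statistics for a batch of datasets at once.

    Parameters
    ----------
    groups:
        List of k arrays, each of shape (reps, n_i); row r of every array
        belongs to dataset r.  The data are assumed tie-free (the KTMB, JT
        and MJT routes remain exact under ties via their min-rank / strict
        conventions, but TM and KTP here use the strictly-ascending /
        distinct-rank forms valid only for tie-free data).

    Returns
    -------
    dict mapping statistic name to an array of shape (reps,).
    """
    k = len(groups)
    if k < 3:
        raise InputError("tuple statistics require k >= 3 groups")
    sizes = [g.shape[1] for g in groups]
    nstar = int(np.prod(sizes))
    out: Dict[str, np.ndarray] = {}

    if "KTMB" in tests or "KTP" in tests:
        ktmb = None
        ktp_scaled = None
        D = k * (k * k - 1)
        for i in range(k):
            coeff = _rank_count_polys(groups, i, sizes)  # (reps, n_i, k)
            if "KTMB" in tests:
                term = coeff[..., i].sum(axis=1)
                ktmb = term if ktmb is None else ktmb + term
            if "KTP" in tests:
                r = np.arange(1, k + 1)
                w = (r - (i + 1)) ** 2  # squared rank displacement
                term = (coeff * w).sum(axis=(1, 2))
                ktp_scaled = term if ktp_scaled is None else ktp_scaled + term
        if "KTMB" in tests:
            out["KTMB"] = ktmb.astype(float)
        if "KTP" in tests:
            # kernel = 1 - 6*sum d^2 / (k(k^2-1)); summed over N* tuples
            out["KTP"] = (D * nstar - 6 * ktp_scaled) / D

    if "TM" in tests:
        reps = groups[0].shape[0]
        f = np.ones((reps, sizes[0]))
        for l in range(1, k):
            less = groups[l - 1][:, :, None] < groups[l][:, None, :]
            f = np.einsum("rab,ra->rb", less, f)
        out["TM"] = f.sum(axis=1)

    if "JT" in tests or "MJT" in tests:
        jt = 0
        mjt = 0
        for l in range(k - 1):
            for m in range(l + 1, k):
                u = (groups[l][:, :, None] < groups[m][:, None, :]).sum(axis=(1, 2))
                jt = jt + u
                mjt = mjt + (m - l) * u
        if "JT" in tests:
            out["JT"] = jt.astype(float)
        if "MJT" in tests:
            out["MJT"] = mjt.astype(float)

    return out


def ktmb_statistic(data: SampleSet) -> float:
    """KTMB statistic (sum of rank-fixed-point kernels over all tuples).

    Uses the O(k^2 N) rank-counting route, which is exact under the min-rank
    tie convention as well.
    """
    if data.k < 3:
        raise InputError("KTMB requires k >= 3 groups")
    _warn_ties(data)
    groups = [g[None, :] for g in data.samples]
    return float(batch_statistics(groups, ["KTMB"])["KTMB"][0])


def tm_statistic(data: SampleSet, budget: int = DEFAULT_TUPLE_BUDGET) -> float:
    """Terpstra-Magel statistic (count of non-decreasing tuples).

    Tie-free data use the fast route; tied data fall back to kernel
    enumeration because the non-strict comparison differs from the
    strictly-ascending count.
    """
    if data.k < 3:
        raise InputError("TM requires k >= 3 groups")
    if data.has_ties():
        return tuple_statistic(data, "TM", budget=budget)
    groups = [g[None, :] for g in data.samples]
    return float(batch_statistics(groups, ["TM"])["TM"][0])


def ktp_statistic(data: SampleSet, budget: int = DEFAULT_TUPLE_BUDGET) -> float:
    """KTP statistic (sum of Spearman kernels over all tuples).

    Tied data need average ranks per tuple, so they fall back to enumeration.
    """
    if data.k < 3:
        raise InputError("KTP requires k >= 3 groups")
    if data.has_ties():
        return tuple_statistic(data, "KTP", budget=budget)
    groups = [g[None, :] for g in data.samples]
    return float(batch_statistics(groups, ["KTP"])["KTP"][0])


def compute_statistic(data: SampleSet, name: str) -> float:
    """Dispatch on statistic name ("KTMB", "KTP", "JT", "MJT", "TM")."""
    fns = {
        "KTMB": ktmb_statistic,
        "KTP": ktp_statistic,
        "JT": lambda d: float(jt_statistic(d)),
        "MJT": mjt_statistic,
        "TM": tm_statistic,
    }
    if name not in fns:
        raise InputError(f"unknown statistic {name!r}; choose from {STATISTIC_NAMES}")
    return fns[name](data)
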