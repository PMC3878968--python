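"""Ordered collections of k independent samples.

A :class:`SampleSet` holds the observed data for the k-group ordered-alternative
problem.  Group ``i`` (1-based) occupies position ``i`` of the hypothesized
non-decreasing ordering H1: F1 >= F2 >= ... >= Fk (group 1 stochastically
smallest, responses tending to increase with group index).  The ordering is
part of the hypothesis, so groups are never re-sorted by label or by value.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

__all__ = ["SampleSet"]


class SampleSet:
    """k ordered groups of real-valued observations.

    Parameters
    ----------
    samples:
        Sequence of k sequences of numbers, one per group, in hypothesis
        order.  Each group must contain at least one observation.

    Attributes
    ----------
    samples : tuple of 1-d float arrays
    sizes : tuple of int
        Group sizes (n1, ..., nk).
    k : int
        Number of groups (>= 2; the tests themselves require k >= 3).
    """

    def __init__(self, samples: Iterable[Sequence[float]]):
        groups = []
        for i, grp in enumerate(samples):
            arr = np.asarray(grp, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise InputError(
                    f"group {i + 1} must be a non-empty 1-d sequence of numbers"
                )
            if not np.all(np.isfinite(arr)):
                raise InputError(f"group {i + 1} contains non-finite values")
            groups.append(arr)
        if len(groups) < 2:
            raise InputError("a SampleSet needs at least two groups")
        self.samples: tuple[np.ndarray, ...] = tuple(groups)

    @property
    def k(self) -> int:
        return len(self.samples)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(g.size for g in self.samples)

    @property
    def total_n(self) -> int:
        """N = sum of group sizes."""
        return int(sum(self.sizes))

    @property
    def n_tuples(self) -> int:
        """N* = product of group sizes, the number of k-tuplets."""
        return int(np.prod([g.size for g in self.samples], dtype=object))

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(self.samples)

    def has_ties(self) -> bool:
        """True if any exact duplicate value occurs anywhere in the data."""
        pooled = self.pooled
        return np.unique(pooled).size < pooled.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SampleSet(k={self.k}, sizes={self.sizes})"
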