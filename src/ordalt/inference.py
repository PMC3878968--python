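"""Standardized one-sided tests for the non-decreasing ordered alternative.

Each statistic T is standardized by its exact (or Monte Carlo) null moments,

    Z = (T - E0[T]) / sqrt(V0[T]),

and H0 is rejected at level alpha when Z >= z_{1-alpha}, the upper-alpha
standard normal quantile; the reported p-value is the upper tail
probability P(N(0,1) >= Z).  Inference is one-sided by construction: the
alternative is directional (responses increase with group index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from scipy.stats import norm

from .errors import DegenerateVarianceError, InputError
from .null_moments import MomentsCache, null_moments
from .samples import SampleSet
from .statistics import STATISTIC_NAMES, TieWarning, compute_statistic

__all__ = ["TestResult", "run_test", "run_battery"]


@dataclass
class TestResult:
    """Outcome of one standardized ordered-alternative test."""

    statistic_name: str
    observed: float
    null_mean: float
    null_variance: float
    z: float
    p_value: float
    alpha: float
    reject: bool
    moments_method: str
    warnings: List[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_variance": self.null_variance,
            "z": self.z,
            "p_value": self.p_value,
            "reject": self.reject,
            "method": self.moments_method,
        }


def run_test(
    data: SampleSet,
    statistic: str = "KTMB",
    alpha: float = 0.05,
    moment_policy: str = "auto",
    seed: int = 0,
    cache: Optional[MomentsCache] = None,
) -> TestResult:
    """Run one test: statistic, null moments per policy, Z, one-sided p.

    ``moment_policy`` is one of auto | enumeration | tie_pattern |
    closed_form | monte_carlo (see :func:`ordalt.null_moments.null_moments`).
    ``seed`` only matters when Monte Carlo moments are used.
    """
    if data.k < 3:
        raise InputError("ordered-alternative tests require k >= 3 groups")
    if not 0 < alpha <= 0.5:
        raise InputError("alpha must lie in (0, 0.5]")
    notes: List[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", TieWarning)
        observed = compute_statistic(data, statistic)
    for w in caught:
        if issubclass(w.category, TieWarning):
            notes.append(str(w.message))
        else:  # pragma: no cover - pass through others
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    mom = null_moments(
        data.sizes, statistic, policy=moment_policy, seed=seed, cache=cache
    )
    if mom.variance <= 0:
        raise DegenerateVarianceError(
            f"null variance of {statistic} is not positive for sizes {data.sizes}"
        )
    z = (observed - mom.mean) / mom.variance**0.5
    p = float(norm.sf(z))
    reject = bool(z >= norm.ppf(1 - alpha))
    return TestResult(
        statistic_name=statistic,
        observed=float(observed),
        null_mean=mom.mean,
        null_variance=mom.variance,
        z=float(z),
        p_value=p,
        alpha=alpha,
        reject=reject,
        moments_method=mom.method,
        warnings=notes,
    )


def run_battery(
    data: SampleSet,
    alpha: float = 0.05,
    moment_policy: str = "auto",
    seed: int = 0,
    cache: Optional[MomentsCache] = None,
    tests: Sequence[str] = STATISTIC_NAMES,
) -> List[TestResult]:
    """Run the five-test battery (KTMB, KTP, JT, MJT, TM) at a shared level."""
    return [
        run_test(data, name, alpha=alpha, moment_policy=moment_policy, seed=seed, cache=cache)
        for name in tests
    ]
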