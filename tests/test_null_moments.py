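import math
from fractions import Fraction

import numpy as np
import pytest

from ordalt import (
    BudgetExceededError,
    InputError,
    MomentsCache,
    count_rank_partitions,
    enumerate_null_pmf,
    enumeration_moments,
    exact_null_moments,
    jt_null_moments,
    mc_null_moments,
    mjt_null_moments,
    null_moments,
)
from conftest import brute_jt, brute_mjt, rank_partitions


class TestPartitionCount:
    @pytest.mark.parametrize(
        "sizes,expected",
        [((2, 1, 1), 12), ((1, 1, 3), 20), ((2, 1, 2), 30), ((5, 5, 5, 5), 11_732_745_024)],
    )
    def test_examples(self, sizes, expected):
        assert count_rank_partitions(sizes) == expected

    def test_invalid_sizes(self):
        with pytest.raises(InputError):
            count_rank_partitions((0, 1, 1))


class TestExactPmf:
    def test_published_pmf_2_1_1(self):
        """The tabulated exact distribution for sizes (2,1,1), bit-exact."""
        d = enumerate_null_pmf((2, 1, 1), "KTMB")
        pmf = {int(v): p for v, p in zip(d.support, d.probabilities)}
        assert pmf == {
            0: Fraction(2, 12),
            1: Fraction(3, 12),
            2: Fraction(4, 12),
            3: Fraction(1, 12),
            4: Fraction(1, 12),
            6: Fraction(1, 12),
        }
        assert d.mean_exact == 2
        assert d.variance_exact == Fraction(8, 3)
        assert sum(d.probabilities) == 1

    @pytest.mark.parametrize(
        "sizes,mean,var3dp",
        [((2, 1, 1), 2, 2.667), ((2, 1, 2), 4, 6.867), ((1, 1, 3), 3, 5.000)],
    )
    def test_published_moments(self, sizes, mean, var3dp):
        d = enumerate_null_pmf(sizes, "KTMB")
        assert d.mean == mean == math.prod(sizes)
        assert round(d.variance, 3) == var3dp

    def test_single_tuple_design(self):
        """(1,1,1): fixed-point counts of a uniform 3-permutation."""
        d = enumerate_null_pmf((1, 1, 1), "KTMB")
        assert {int(v): p for v, p in zip(d.support, d.probabilities)} == {
            0: Fraction(2, 6),
            1: Fraction(3, 6),
            3: Fraction(1, 6),
        }
        assert d.mean == 1 and d.variance == 1

    def test_budget_error(self):
        with pytest.raises(BudgetExceededError):
            enumerate_null_pmf((5, 5, 5, 5), "KTMB")

    @pytest.mark.parametrize("sizes", [(2, 2, 1), (1, 2, 2), (3, 1, 2)])
    @pytest.mark.parametrize("stat", ["KTMB", "TM", "KTP", "JT", "MJT"])
    def test_mean_ktmb_equals_product(self, sizes, stat):
        d = enumerate_null_pmf(sizes, stat)
        assert sum(d.probabilities) == 1
        if stat == "KTMB":
            assert d.mean == math.prod(sizes)


class TestTiePatternMoments:
    @pytest.mark.parametrize(
        "sizes,mean,var",
        [
            ((2, 1, 1), 2, Fraction(8, 3)),
            ((1, 1, 3), 3, Fraction(5)),
            ((2, 1, 2), 4, Fraction(103, 15)),
        ],
    )
    def test_published_values(self, sizes, mean, var):
        m = exact_null_moments(sizes, "KTMB")
        assert m.mean == mean
        assert m.variance == pytest.approx(float(var), abs=1e-12)
        assert m.method == "tie_pattern_exact"

    @pytest.mark.parametrize("stat", ["KTMB", "TM", "KTP"])
    @pytest.mark.parametrize(
        "sizes", [(2, 2, 2), (1, 3, 2), (4, 1, 2), (2, 1, 1, 2), (2, 2, 2, 1)]
    )
    def test_agrees_with_enumeration(self, sizes, stat):
        enum = enumerate_null_pmf(sizes, stat)
        tp = exact_null_moments(sizes, stat)
        assert tp.mean == pytest.approx(enum.mean, abs=1e-10)
        assert tp.variance == pytest.approx(enum.variance, abs=1e-10)

    def test_single_tuple_variance_is_kernel_variance(self):
        # only the all-shared pattern contributes for sizes (1,1,1)
        m = exact_null_moments((1, 1, 1), "KTMB")
        assert (m.mean, m.variance) == (1.0, 1.0)

    def test_k_cap(self):
        with pytest.raises(BudgetExceededError):
            exact_null_moments((1,) * 7, "KTMB", k_cap=5)

    def test_large_design_feasible(self):
        # far beyond any enumeration: exact moments still instant
        m = exact_null_moments((10, 10, 5), "KTMB")
        assert m.mean == 500
        assert m.variance > 0

    def test_multi_stat_sweep_matches_single(self):
        both = enumeration_moments((2, 2, 2), ["KTMB", "TM", "KTP"])
        for stat, mom in both.items():
            d = enumerate_null_pmf((2, 2, 2), stat)
            assert mom.mean == pytest.approx(d.mean, abs=1e-12)
            assert mom.variance == pytest.approx(d.variance, abs=1e-12)


class TestMonteCarlo:
    def test_mean_within_4se(self):
        m = mc_null_moments((2, 1, 2), "KTMB", reps=100_000, seed=11)
        se = math.sqrt(6.867 / 100_000)
        assert abs(m.mean - 4) < 4 * se

    def test_determinism(self):
        a = mc_null_moments((2, 1, 1), "KTMB", reps=5_000, seed=3)
        b = mc_null_moments((2, 1, 1), "KTMB", reps=5_000, seed=3)
        assert (a.mean, a.variance) == (b.mean, b.variance)
        c = mc_null_moments((2, 1, 1), "KTMB", reps=5_000, seed=4)
        assert (a.mean, a.variance) != (c.mean, c.variance)

    def test_reps_floor(self):
        with pytest.raises(InputError):
            mc_null_moments((2, 1, 1), "KTMB", reps=10, seed=0)


class TestClosedForms:
    def test_jt_small_example(self):
        m = jt_null_moments((1, 1, 1))
        assert m.mean == 1.5  # (9 - 3) / 4

    @pytest.mark.parametrize(
        "sizes", [(1, 1, 1), (2, 1, 1), (2, 2, 2), (3, 2, 2), (2, 2, 1, 1), (1, 2, 3)]
    )
    def test_jt_mjt_match_enumeration(self, sizes):
        """Closed forms vs literal enumeration over all rank partitions."""
        jts, mjts = [], []
        for groups in rank_partitions(sizes):
            jts.append(brute_jt(groups))
            mjts.append(brute_mjt(groups))
        jts, mjts = np.array(jts, float), np.array(mjts, float)
        jm = jt_null_moments(sizes)
        assert jm.mean == pytest.approx(jts.mean(), abs=1e-10)
        assert jm.variance == pytest.approx(jts.var(), abs=1e-10)
        mm = mjt_null_moments(sizes)
        assert mm.mean == pytest.approx(mjts.mean(), abs=1e-10)
        assert mm.variance == pytest.approx(mjts.var(), abs=1e-10)

    def test_mjt_mean_formula(self):
        sizes = (3, 2, 4)
        expected = sum(
            (m - l) * sizes[l] * sizes[m] / 2
            for l in range(3)
            for m in range(l + 1, 3)
        )
        assert mjt_null_moments(sizes).mean == expected


class TestDispatcherAndCache:
    def test_auto_policy_selection(self):
        assert null_moments((2, 2, 2), "KTMB").method == "enumeration"
        assert null_moments((10, 10, 5), "KTMB").method == "tie_pattern_exact"
        assert null_moments((2, 2, 2), "JT").method == "closed_form"
        big = null_moments((40,) * 7, "KTMB", mc_reps=1_000)
        assert big.method == "monte_carlo"

    def test_policy_override(self):
        m = null_moments((2, 1, 1), "KTMB", policy="monte_carlo", mc_reps=2_000, seed=1)
        assert m.method == "monte_carlo" and m.mc_reps == 2_000

    def test_cache_round_trip(self, tmp_path):
        path = str(tmp_path / "moments.json")
        cache = MomentsCache(path)
        first = null_moments((2, 2, 2), "KTMB", cache=cache)
        reloaded = MomentsCache(path)
        hit = null_moments((2, 2, 2), "KTMB", cache=reloaded)
        assert (hit.mean, hit.variance, hit.method) == (
            first.mean,
            first.variance,
            first.method,
        )
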