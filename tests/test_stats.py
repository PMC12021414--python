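"""Group statistics: bootstrap CIs, rank tests, effect sizes, outliers, Fisher."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchkit.stats import (
    classify_activated,
    compare_groups,
    detect_outliers,
    effect_size,
    effect_size_rounded,
    fisher_exact,
    median_ci,
    relative_change,
    sidak_critical,
    wilcoxon_rank_sum,
)


class TestMedianCI:
    def test_constant_sample_zero_width(self):
        med, lo, hi = median_ci(np.full(20, 3.3), seed=0)
        assert med == lo == hi == 3.3

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        assert median_ci(x, seed=5) == median_ci(x, seed=5)

    def test_coverage_near_nominal(self):
        """~95% of bootstrap CIs should cover the true median (reduced reps)."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            x = rng.normal(0.0, 1.0, 50)
            _, lo, hi = median_ci(x, n_boot=300, seed=i)
            hits += lo <= 0.0 <= hi
        assert 0.86 <= hits / n_rep <= 0.995

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            median_ci(np.array([1.0]))


def _rank_sum_p_enumeration(a, b):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    all_ranks = range(1, len(pooled) + 1)
    sums = [sum(combo) for combo in itertools.combinations(all_ranks, n_a)]
    total = len(sums)
    n_le = sum(s <= obs for s in sums)
    n_ge = sum(s >= obs for s in sums)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestWilcoxon:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_extreme_small_sample_exact(self):
        # only 2 of the C(6,3)=20 assignments are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            pooled = rng.permutation(20)[: n_a + n_b].astype(float)  # tie-free
            a, b = pooled[:n_a], pooled[n_a:]
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                _rank_sum_p_enumeration(a, b), abs=1e-12
            )

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 150)
        ps = [wilcoxon_rank_sum(a, a + shift) for shift in (0.1, 0.3, 0.6)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSidak:
    def test_single_test_is_alpha(self):
        assert sidak_critical(1) == pytest.approx(0.05)

    def test_worked_value(self):
        assert sidak_critical(5) == pytest.approx(1 - 0.95 ** 0.2)
        assert sidak_critical(5) == pytest.approx(0.010206, abs=1e-6)

    def test_monotone_decreasing_in_m(self):
        vals = [sidak_critical(m) for m in range(1, 12)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            sidak_critical(0)


class TestEffectSize:
    @pytest.mark.parametrize(
        "control,condition,reference,expected",
        [
            (14.7, 19.0, None, 29),
            (10.0, 13.6, None, 36),
            (-11.7, -11.2, None, -4),
            (14.3, 17.1, None, 20),
            (-9.8, -12.3, None, 26),
            (0.041, 0.018, 0.068, -34),
        ],
    )
    def test_reported_convention(self, control, condition, reference, expected):
        assert effect_size_rounded(control, condition, reference) == expected

    @given(
        c=st.floats(-50.0, 50.0), x=st.floats(-50.0, 50.0),
        r=st.floats(0.1, 50.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_antisymmetric_with_fixed_reference(self, c, x, r):
        assert effect_size(c, x, r) == pytest.approx(-effect_size(x, c, r))

    def test_not_antisymmetric_with_default_reference(self):
        assert effect_size(10.0, 20.0) != -effect_size(20.0, 10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            effect_size(0.0, 1.0)


class TestRelativeChange:
    def test_printed_medians_do_not_round_trip(self):
        # the published normalized change is computed from unrounded medians
        assert relative_change(18.0, 10.0) == pytest.approx(-44.4, abs=0.1)

    def test_no_change(self):
        assert relative_change(7.0, 7.0) == 0.0

    def test_increase(self):
        assert relative_change(10.0, 15.0) == 50.0


class TestOutliers:
    def test_hand_computed_example(self):
        # median 3, MAD 1 -> threshold 4.4478: only 100 deviates more
        mask = detect_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(mask) == [False, False, False, False, True]

    def test_benign_sample_clean(self):
        rng = np.random.default_rng(4)
        assert not detect_outliers(rng.normal(0.0, 1.0, 30)).any()

    def test_mad_zero_degenerate_rule(self):
        mask = detect_outliers([5.0, 5.0, 5.0, 5.0, 6.0])
        assert list(mask) == [False, False, False, False, True]

    def test_repeat_level_medians_clean(self):
        """Repeat-level medians of homogeneous control repeats: no outliers."""
        rng = np.random.default_rng(5)
        medians = [np.median(rng.normal(15.0, 4.0, 800)) for _ in range(15)]
        assert detect_outliers(medians).sum() == 0


def _fisher_p_enumeration(table):
    """Oracle: two-sided Fisher p by exact hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestFisherExact:
    def test_printed_activation_table(self):
        assert fisher_exact([[8, 32], [0, 44]]) == pytest.approx(0.0018, abs=5e-5)

    def test_washout_table_is_one(self):
        assert fisher_exact([[0, 22], [0, 22]]) == 1.0

    def test_identical_rows_always_one(self):
        assert fisher_exact([[5, 9], [5, 9]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            cells = rng.multinomial(int(rng.integers(4, 31)), [0.25] * 4)
            table = cells.reshape(2, 2)
            assert fisher_exact(table) == pytest.approx(
                _fisher_p_enumeration(table), abs=1e-12
            )

    def test_invalid_table(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestActivation:
    @pytest.mark.parametrize("F,F0,flag", [(2.1, 1.0, True), (2.0, 1.0, False), (6.0, 2.0, True)])
    def test_threshold_strict(self, F, F0, flag):
        assert classify_activated(F, F0) is flag

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            classify_activated(1.0, 0.0)


class TestCompareGroups:
    def test_significant_requires_both_criteria(self):
        rng = np.random.default_rng(7)
        control = rng.normal(10.0, 1.0, 500)
        # large shift: tiny p and ~30% effect -> significant
        big = compare_groups("posture", control, control + 3.0, m_tests=4, seed=0)
        assert big.significant and big.p < big.p_critical
        assert abs(big.effect_size_pct) >= 15
        # small shift: p still tiny at n=500 but effect ~3% -> not significant
        small = compare_groups("posture", control, control + 0.3, m_tests=4, seed=0)
        assert small.p < small.p_critical
        assert abs(small.effect_size_pct) < 15
        assert not small.significant

    def test_effect_reference_override(self):
        a = np.full(20, 0.041) + np.linspace(-1e-4, 1e-4, 20)
        b = np.full(20, 0.018) + np.linspace(-1e-4, 1e-4, 20)
        cmp = compare_groups("slope_medium", a, b, effect_reference=0.068, seed=1)
        assert cmp.effect_size_pct_rounded == -34
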