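import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capiflow.stats import (
    BlandAltmanResult,
    ClipMeasurement,
    GroupSummary,
    anova_from_summary,
    anova_oneway,
    bh_adjust,
    bland_altman,
    challenge_report,
    fisher_exact,
    group_summary,
    mann_whitney,
    pairwise_bh,
    pearson_r,
    simulate_challenge_table,
    topical_dose,
)


def mann_whitney_enumeration(x, y):
    """Oracle: exact two-sided p by enumerating all label assignments."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = u_stat(x, y)
    mu = n * m / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in comb]
        ys = [combined[i] for i in range(n + m) if i not in comb]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / total


def fisher_enumeration(table):
    """Oracle: sum hypergeometric probabilities <= observed probability."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, df1, df2, p = anova_oneway([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert f == 0.0 and p == 1.0
        assert (df1, df2) == (2, 3)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        f, _, _, p_f = anova_oneway([x, y])
        # pooled two-sample t computed directly
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])

    def test_summary_equals_raw_anova(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.2, n) for m, n in ((0, 9), (0.5, 14), (1.1, 7))]
        f_raw, d1, d2, p_raw = anova_oneway(groups)
        summaries = [group_summary(g) for g in groups]
        f_sum, e1, e2, p_sum = anova_from_summary(summaries)
        assert f_sum == pytest.approx(f_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)
        assert (d1, d2) == (e1, e2)

    def test_summary_equal_means_give_f_zero(self):
        s = [GroupSummary(10, 3.0, 0.5)] * 3
        f, _, _, p = anova_from_summary(s)
        assert f == 0.0 and p == 1.0

    def test_summary_validation(self):
        with pytest.raises(ValueError):
            GroupSummary(10, 3.0, 0.0)
        with pytest.raises(ValueError):
            GroupSummary(1, 3.0, 0.5)


class TestBenjaminiHochberg:
    def test_hand_stepup_triple(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then cumulative min from the largest
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(deadline=None, max_examples=60)
    def test_stepup_matches_hand_derivation(self, pvals):
        pvals = np.array(pvals)
        m = len(pvals)
        order = np.argsort(pvals)
        stepped = pvals[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(stepped[::-1])[::-1]
        hand = np.minimum(hand, 1.0)
        expected = np.empty(m)
        expected[order] = hand
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        raw = np.array([0.001, 0.2, 0.04, 0.9])
        assert np.all(bh_adjust(raw) >= raw)

    def test_pairwise_single_pair_adjusted_equals_raw(self):
        rng = np.random.default_rng(2)
        res = pairwise_bh([rng.normal(0, 1, 10), rng.normal(1, 1, 10)], ["a", "b"])
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(res[0].p_raw)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p >= 0.99

    def test_large_shift_detected_by_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        _, p = mann_whitney(x, x + 50.0)
        assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st.integers(min_value=0, max_value=2**30))
    @settings(deadline=None, max_examples=25)
    def test_exact_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        m = int(rng.integers(2, 5))
        # distinct values: the exact method applies only without ties
        vals = rng.permutation(np.arange(1.0, n + m + 1))
        x, y = vals[:n], vals[n:]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mann_whitney_enumeration(x, y), abs=1e-9)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[0, 0], [3, 4]]) == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact(np.array([[0.5, 1], [1, 1]]))

    @given(st.integers(min_value=0, max_value=2**30))
    @settings(deadline=None, max_examples=40)
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 6, (2, 2))
        assert fisher_exact(table) == pytest.approx(
            fisher_enumeration(table.tolist()), abs=1e-9
        )


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_moderate_correlation(self):
        rng = np.random.default_rng(5)
        n, rho = 325, 0.42
        x = rng.normal(0, 1, n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(rho, abs=0.1)
        assert p < 0.001


class TestBlandAltman:
    def test_worked_example(self):
        res = bland_altman([12.0, 14.0, 19.0], [10.0, 14.0, 18.0])
        assert res.bias == pytest.approx(1.0)
        assert res.precision == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(1.0 - 1.96)
        assert res.loa_high == pytest.approx(1.0 + 1.96)

    def test_identical_pairs(self):
        res = bland_altman([3.0, 4.0], [3.0, 4.0])
        assert res.bias == 0.0 and res.precision == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_recovers_imposed_offset_and_spread(self):
        rng = np.random.default_rng(6)
        manual = rng.normal(16.0, 3.0, 325)
        auto = manual + rng.normal(2.1, 4.8, 325)
        res = bland_altman(auto, manual)
        assert res.bias == pytest.approx(2.1, abs=0.6)
        assert res.precision == pytest.approx(4.8, abs=0.5)


class TestDoseArithmetic:
    def test_ach_worked_example(self):
        # one 0.05 ml drop of 6.8e-2 M solution
        assert topical_dose(0.05, 6.8e-2) == pytest.approx(3.4, rel=1e-6)

    def test_ng_worked_example(self):
        # one 0.05 ml drop of 4.4e-2 M solution pre-diluted 1:100
        assert topical_dose(0.05, 4.4e-2, dilution=100) == pytest.approx(2.2e-2, rel=1e-6)

    def test_vanishing_concentration_limit(self):
        assert topical_dose(0.05, 1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            topical_dose(0.0, 1e-2)


class TestClipMeasurement:
    def test_condition_validated(self):
        with pytest.raises(ValueError):
            ClipMeasurement(subject_id="s1", condition="placebo")

    def test_gate_on_massey_total(self):
        good = ClipMeasurement(subject_id="s1", condition="native", massey_total=3)
        bad = ClipMeasurement(subject_id="s1", condition="native", massey_total=10)
        assert good.analyzable and not bad.analyzable


class TestChallengeReport:
    def test_report_flags_ng_shift(self):
        rng = np.random.default_rng(7)
        summ = {
            "native": GroupSummary(41, 14.8, 0.65),
            "ACH": GroupSummary(41, 15.0, 0.65),
            "NG": GroupSummary(41, 20.3, 0.50),
        }
        df = simulate_challenge_table(summ, rng, variable="tvd_auto")
        report = challenge_report(df, ["tvd_auto"])
        row = report.iloc[0]
        assert row["anova_p"] < 0.001
        assert "a" in row["NG"]
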