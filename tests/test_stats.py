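"""Nonparametric tests against exhaustive-enumeration oracles; box plots."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from aqueflow.stats import (
    boxplot_summary,
    compare_groups,
    evaluate_group_pattern,
    ks_two_sample,
    mann_whitney_u,
)

# ---------------------------------------------------------------------------
# independent oracles: brute-force enumeration over all group labelings
# ---------------------------------------------------------------------------


def mwu_enumeration_p(x, y):
    """Two-sided exact MWU p by enumerating all C(n+m, n) labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(c)].sum() - n * (n + 1) / 2
            for c in itertools.combinations(range(len(pooled)), n)
        ]
    )
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return u_obs, min(p, 1.0)


def _ks_d(x, y):
    allv = np.sort(np.concatenate([x, y]))
    cx = np.searchsorted(np.sort(x), allv, side="right") / len(x)
    cy = np.searchsorted(np.sort(y), allv, side="right") / len(y)
    return np.abs(cx - cy).max()


def ks_enumeration_p(x, y):
    """Exact two-sample KS p: P(D >= d_obs) over all labelings."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(x) + len(y)
    d_obs = _ks_d(x, y)
    all_idx = set(range(N))
    ds = []
    for c in itertools.combinations(range(N), n):
        xi = pooled[list(c)]
        yi = pooled[list(all_idx - set(c))]
        ds.append(_ks_d(xi, yi))
    return d_obs, (np.asarray(ds) >= d_obs - 1e-12).mean()


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        """x={1,2,3}, y={4,5,6}: U=0 and exact two-sided p = 2/20 = 0.1."""
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert np.isclose(r.pvalue, 0.1)
        assert r.method == "exact"

    def test_identical_samples_p_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isclose(r.pvalue, 1.0)

    def test_u_rank_identity(self, rng):
        """U_x + U_y = n*m for any input."""
        for _ in range(20):
            n, m = rng.integers(1, 12, 2)
            x, y = rng.standard_normal(n), rng.standard_normal(m)
            ux = mann_whitney_u(x, y).statistic
            uy = mann_whitney_u(y, x).statistic
            assert ux + uy == n * m

    def test_exact_p_equals_enumeration_small_samples(self, rng):
        """Exact p agrees with brute-force enumeration for tie-free samples
        with n+m <= 10 (random draws across all size splits)."""
        for n in range(1, 6):
            for m in range(1, 11 - n):
                x = rng.standard_normal(n)
                y = rng.standard_normal(m)
                r = mann_whitney_u(x, y)
                _, p_ref = mwu_enumeration_p(x, y)
                assert r.method == "exact"
                assert np.isclose(r.pvalue, p_ref, atol=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        r = mann_whitney_u([1, 2, 2, 3], [2, 3, 4, 5])
        assert r.method == "asymptotic"
        assert 0 <= r.pvalue <= 1

    def test_large_samples_asymptotic(self, rng):
        r = mann_whitney_u(rng.standard_normal(19), rng.standard_normal(10))
        assert r.method == "asymptotic"

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariance_under_monotone_transform(self, seed):
        """Rank-based p is unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(6)
        y = rng.standard_normal(5) + 0.5
        p0 = mann_whitney_u(x, y).pvalue
        for f in (np.exp, lambda a: a**3, lambda a: np.arctan(a) * 10):
            assert np.isclose(mann_whitney_u(f(x), f(y)).pvalue, p0)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert np.isclose(r.pvalue, 1.0)

    def test_fully_separated_d_is_one(self):
        r = ks_two_sample([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.statistic == 1.0

    def test_exact_p_equals_enumeration(self, rng):
        """n=m=4 mixed samples: exact p equals enumeration over C(8,4)
        labelings; also across other small splits."""
        for n, m in [(4, 4), (3, 5), (2, 6), (5, 5)]:
            x = rng.standard_normal(n)
            y = rng.standard_normal(m)
            r = ks_two_sample(x, y)
            d_ref, p_ref = ks_enumeration_p(x, y)
            assert r.method == "exact"
            assert np.isclose(r.statistic, d_ref)
            assert np.isclose(r.pvalue, p_ref, atol=1e-9)

    def test_asymptotic_uses_kolmogorov_distribution(self, rng):
        """Above the exact-size cutoff the p-value follows the Kolmogorov
        distribution at effective size n*m/(n+m)."""
        from scipy.special import kolmogorov

        x, y = rng.standard_normal(19), rng.standard_normal(10)
        r = ks_two_sample(x, y)
        assert r.method == "asymptotic"
        en = 19 * 10 / 29
        assert np.isclose(r.pvalue, kolmogorov(np.sqrt(en) * r.statistic))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ks_two_sample([1.0], [])


class TestBoxplotSummary:
    def test_simple_sample_no_outliers(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4
        assert s.outside.size == 0 and s.far_out.size == 0

    def test_far_out_classification(self):
        """{1,2,3,4,100}: hinges 2/4, IQR 2, outer fence 10 -> 100 far-out
        and not double-counted as outside."""
        s = boxplot_summary([1, 2, 3, 4, 100])
        assert np.array_equal(s.far_out, [100])
        assert s.outside.size == 0
        assert s.whisker_high == 4

    def test_outside_but_not_far_out(self):
        # hinges 2/4, inner fence 7, outer fence 10
        s = boxplot_summary([1, 2, 3, 4, 8])
        assert np.array_equal(s.outside, [8])
        assert s.far_out.size == 0

    def test_constant_sample(self):
        s = boxplot_summary([7.0] * 6)
        assert s.median == 7.0 and s.iqr == 0.0
        assert s.outside.size == 0 and s.far_out.size == 0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(1, 30))
        a, b = boxplot_summary(x), boxplot_summary(rng.permutation(x))
        assert a.median == b.median and a.q1 == b.q1 and a.q3 == b.q3
        assert np.array_equal(a.outside, b.outside)


class TestCompareGroups:
    def _table(self, rng, shift=0.0):
        vals = {
            "control": rng.standard_normal(19),
            "iNPH": rng.standard_normal(10) + shift,
            "AD": rng.standard_normal(7) + shift,
        }
        return pd.DataFrame(
            [
                {"group": g, "metric": v}
                for g, arr in vals.items()
                for v in arr
            ]
        )

    def test_three_pairwise_comparisons_both_tests(self, rng):
        comp = compare_groups(self._table(rng), "metric")
        assert len(comp.pairwise) == 3
        for tests in comp.pairwise.values():
            assert set(tests) == {"mann-whitney", "ks"}
        assert set(comp.summaries) == {"control", "iNPH", "AD"}
        assert comp.notes["multiplicity_adjustment"] == "none"

    def test_minimal_group_sizes_run_exact(self):
        table = pd.DataFrame(
            {"group": ["a", "b", "c"], "metric": [1.0, 2.0, 3.0]}
        )
        comp = compare_groups(table, "metric")
        for tests in comp.pairwise.values():
            assert tests["mann-whitney"].method == "exact"
            assert tests["mann-whitney"].pvalue >= 0.5  # n=1 cannot reach 0.05

    def test_missing_metric_or_groups_raise(self, rng):
        with pytest.raises(KeyError):
            compare_groups(self._table(rng), "nope")
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(
                pd.DataFrame({"group": ["a", "a"], "metric": [1.0, 2.0]}), "metric"
            )

    def test_pattern_evaluation_on_shifted_cohort(self, rng):
        """A strong patient shift in one metric and none in another
        reproduces the expected claim flags."""
        shifted = compare_groups(self._table(rng, shift=50.0), "metric")
        null = compare_groups(self._table(rng, shift=0.0), "metric")
        comparisons = {
            "pressure_gradient": shifted,
            "rotation": shifted,
            "velocity": null,
        }
        flags = evaluate_group_pattern(comparisons)
        assert flags["pressure_gradient_separates_patients"]
        assert flags["rotation_separates_patients"]
        assert flags["matches_study_pattern"] == (
            flags["velocity_separates_no_patient_group"]
        )
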