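"""Structural-context statistics: normalisation, ANOVA, exact tests."""

import numpy as np
import pytest
from scipy.stats import fisher_exact, hypergeom, norm

import convscan as cs
from convscan.io import SiteReport, SiteRow
from convscan.structure import (
    StructureAnnotation,
    bfactor_anova,
    compare_site_context,
    exact_contingency_test,
    monte_carlo_contingency_test,
    ordered_quantile_normalize,
)


class TestOrderedQuantileNormalize:
    def test_three_values_hit_stated_quantiles(self):
        out = ordered_quantile_normalize([5.0, 1.0, 9.0])
        expect = norm.ppf([0.5, 1 / 6, 5 / 6])
        assert out == pytest.approx(expect, abs=1e-4)

    def test_monotone_input_monotone_output(self, rng):
        x = np.sort(rng.normal(size=50))
        out = ordered_quantile_normalize(x)
        assert np.all(np.diff(out) > 0)

    def test_ties_get_equal_values(self):
        out = ordered_quantile_normalize([2.0, 2.0, 7.0])
        assert out[0] == out[1]

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.exponential(size=40)
        a = ordered_quantile_normalize(x)
        b = ordered_quantile_normalize(np.log(x))
        assert a == pytest.approx(b, abs=1e-12)

    def test_mean_near_zero_without_ties(self, rng):
        x = rng.normal(size=101)
        assert abs(ordered_quantile_normalize(x).mean()) < 1e-9

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            ordered_quantile_normalize([1.0])


def _make_annotations(rng, n, depth_sites, shift=0.0):
    out = []
    for i in range(1, n + 1):
        b = rng.normal() + (shift if i in depth_sites else 0.0)
        out.append(StructureAnnotation(i, "helix", "exposed", float(b)))
    return out


class TestBfactorAnova:
    def test_null_labels_give_nonsignificant_terms(self):
        rng = np.random.default_rng(1)
        n = 200
        annot = _make_annotations(rng, n, set())
        depth = set(rng.choice(np.arange(1, n + 1), 40, replace=False).tolist())
        temp = set(rng.choice(np.arange(1, n + 1), 40, replace=False).tolist())
        table = bfactor_anova(annot, depth, temp)
        for term in ("depth", "temperature", "depth:temperature"):
            assert table.loc[term, "PR(>F)"] > 0.001

    def test_planted_depth_shift_detected(self):
        rng = np.random.default_rng(1)
        n = 200
        depth = set(range(1, 51))
        temp = set(rng.choice(np.arange(1, n + 1), 40, replace=False).tolist())
        annot = _make_annotations(rng, n, depth, shift=1.0)
        table = bfactor_anova(annot, depth, temp)
        assert table.loc["depth", "PR(>F)"] < 0.01

    def test_balanced_design_type3_equals_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(2)
        n = 80
        depth = set(range(1, n // 2 + 1))
        temp = set(range(1, n // 4 + 1)) | set(range(n // 2 + 1, 3 * n // 4 + 1))
        annot = _make_annotations(rng, n, set())
        t3 = bfactor_anova(annot, depth, temp)
        df = pd.DataFrame(
            {
                "qnorm_bfactor": ordered_quantile_normalize(
                    [a.bfactor for a in annot]
                ),
                "depth": ["yes" if a.site_index in depth else "no" for a in annot],
                "temperature": [
                    "yes" if a.site_index in temp else "no" for a in annot
                ],
            }
        )
        fit = smf.ols(
            "qnorm_bfactor ~ C(depth, Sum) * C(temperature, Sum)", data=df
        ).fit()
        t1 = sm.stats.anova_lm(fit, typ=1)
        for term_t3, term_t1 in [
            ("depth", "C(depth, Sum)"),
            ("temperature", "C(temperature, Sum)"),
            ("depth:temperature", "C(depth, Sum):C(temperature, Sum)"),
        ]:
            assert t3.loc[term_t3, "sum_sq"] == pytest.approx(
                t1.loc[term_t1, "sum_sq"], rel=1e-8
            )

    def test_empty_level_error_names_factor(self):
        rng = np.random.default_rng(0)
        annot = _make_annotations(rng, 20, set())
        with pytest.raises(ValueError, match="depth"):
            bfactor_anova(annot, set(), {1, 2, 3})

    def test_null_rejection_rate_calibrated(self):
        # rejection rate of the depth term at alpha=0.05 under permuted labels
        rng = np.random.default_rng(1)
        n = 60
        reps = 300
        hits = 0
        for _ in range(reps):
            annot = _make_annotations(rng, n, set())
            depth = set(rng.choice(np.arange(1, n + 1), 20, replace=False).tolist())
            temp = set(rng.choice(np.arange(1, n + 1), 20, replace=False).tolist())
            table = bfactor_anova(annot, depth, temp)
            if table.loc["depth", "PR(>F)"] < 0.05:
                hits += 1
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


class TestExactContingency:
    def test_proportional_table_p_one(self):
        assert exact_contingency_test([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_crossed_table_34_over_70(self):
        assert exact_contingency_test([[3, 1], [1, 3]]) == pytest.approx(
            34 / 70, abs=1e-12
        )

    def test_matches_hypergeometric_two_sided_sum(self, rng):
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            table = np.array([[a, b], [c, d]])
            if np.any(table.sum(0) == 0) or np.any(table.sum(1) == 0):
                continue
            got = exact_contingency_test(table)
            n1, n0 = a + b, c + d
            m1 = a + c
            N = n1 + n0
            support = np.arange(max(0, m1 - n0), min(n1, m1) + 1)
            pmf = hypergeom.pmf(support, N, m1, n1)
            p_obs = hypergeom.pmf(a, N, m1, n1)
            want = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_fisher(self, rng):
        for _ in range(20):
            table = rng.integers(1, 10, size=(2, 2))
            assert exact_contingency_test(table) == pytest.approx(
                fisher_exact(table)[1], abs=1e-10
            )

    def test_symmetric_under_permutations(self, rng):
        table = np.array([[5, 2, 1], [1, 4, 3]])
        p = exact_contingency_test(table)
        assert exact_contingency_test(table[:, [2, 0, 1]]) == pytest.approx(p, abs=1e-12)
        assert exact_contingency_test(table[::-1]) == pytest.approx(p, abs=1e-12)
        assert exact_contingency_test(table.T) == pytest.approx(p, abs=1e-12)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            exact_contingency_test([[0, 0], [1, 2]])

    def test_large_table_directed_to_monte_carlo(self):
        big = [[300, 10], [200, 40]]
        with pytest.raises(ValueError, match="Monte Carlo"):
            exact_contingency_test(big)
        p = monte_carlo_contingency_test(big, 2000, np.random.default_rng(1))
        assert 0 < p < 0.01  # strongly associated table

    def test_monte_carlo_agrees_with_exact_on_small_table(self):
        table = [[6, 2], [3, 7]]
        exact = exact_contingency_test(table)
        mc = monte_carlo_contingency_test(table, 20000, np.random.default_rng(1))
        assert mc == pytest.approx(exact, abs=0.02)


def _report_with_calls(calls):
    rows = []
    for i, call in enumerate(calls, start=1):
        kwargs = {}
        if call in ("adaptive", "non_adaptive", "unresolved"):
            kwargs = dict(max_pp=0.9, best_cutoff=1.0, best_scenario_id="c1",
                          n_transitions=5, threshold_upper=0.8, threshold_lower=0.2)
        rows.append(SiteRow(site_index=i, call=call, **kwargs))
    return SiteReport(rows)


class TestCompareSiteContext:
    def test_identical_distributions_p_one(self):
        calls = ["adaptive"] * 4 + ["non_adaptive"] * 4
        report = _report_with_calls(calls)
        annot = [
            StructureAnnotation(i, "helix" if i % 2 else "sheet",
                                "exposed" if i % 2 else "buried", 0.0)
            for i in range(1, 9)
        ]
        res = compare_site_context(report, annot)
        assert res["ss_class"]["p_value"] == pytest.approx(1.0)
        assert res["exposure_class"]["p_value"] == pytest.approx(1.0)

    def test_perfect_separation_hypergeometric_p(self):
        calls = ["adaptive"] * 6 + ["non_adaptive"] * 6
        report = _report_with_calls(calls)
        annot = [
            StructureAnnotation(i, "coil",
                                "exposed" if i <= 6 else "buried", 0.0)
            for i in range(1, 13)
        ]
        res = compare_site_context(report, annot)
        from math import comb

        assert res["exposure_class"]["p_value"] == pytest.approx(
            2 / comb(12, 6), abs=1e-12
        )

    def test_unresolved_excluded_below_threshold_in_comparison_group(self):
        calls = (["adaptive"] * 3 + ["non_adaptive"] * 3 + ["unresolved"] * 4
                 + ["below_threshold"] * 2 + ["skipped_gaps"])
        report = _report_with_calls(calls)
        annot = [
            StructureAnnotation(i, "helix", "exposed", 0.0) for i in range(1, 14)
        ]
        res = compare_site_context(report, annot)
        table = res["ss_class"]["table"]
        # 3 adaptive vs (3 certified + 2 below-threshold) predicted non-adaptive
        assert table.loc["adaptive"].sum() == 3
        assert table.loc["non_adaptive"].sum() == 5

    def test_missing_group_error(self):
        report = _report_with_calls(["adaptive"] * 4)
        annot = [StructureAnnotation(i, "helix", "exposed", 0.0) for i in range(1, 5)]
        with pytest.raises(ValueError, match="non-adaptive"):
            compare_site_context(report, annot)
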