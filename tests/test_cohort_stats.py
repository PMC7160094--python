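"""Size stratification, per-subject medians, rank statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bronchotaper.cohort_stats import (
    SizeThresholds,
    assign_size_groups,
    compare_groups,
    correlate_with_visual,
    derive_size_thresholds,
    holm_adjust,
    per_subject_medians,
)


def branch_table(artery_diameters, subject_id="s", biomarker_values=None):
    n = len(artery_diameters)
    return pd.DataFrame(
        {
            "subject_id": [subject_id] * n,
            "branch_id": [f"b{i}" for i in range(n)],
            "artery_mm": artery_diameters,
            "intraBT_inner": biomarker_values
            if biomarker_values is not None else np.ones(n),
            "size_group": ["unassigned"] * n,
        }
    )


def exact_mwu_p(a, b):
    """Exhaustive permutation enumeration of the two-sided Mann-Whitney
    null: P(U <= min(U_obs, U'_obs)) * 2 over all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n_a):
        ga = pooled[list(idx)]
        gb = pooled[[i for i in range(n) if i not in idx]]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    # two-sided: double the smaller tail of the symmetric U distribution
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestSizeThresholds:
    def test_tertiles_of_1_to_9(self):
        thr = derive_size_thresholds(branch_table(np.arange(1.0, 10.0)))
        assert thr.low == pytest.approx(3.667, abs=1e-3)
        assert thr.high == pytest.approx(6.333, abs=1e-3)

    def test_equal_diameters_degenerate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            thr = derive_size_thresholds(branch_table([3.0] * 6))
        table = assign_size_groups(branch_table([3.0] * 6), thr)
        assert (table.size_group == "medium").all()

    @pytest.mark.parametrize("n", [4, 7, 30])
    def test_3n_distinct_values_split_evenly(self, n):
        rng = np.random.default_rng(n)
        d = rng.permutation(np.linspace(1, 12, 3 * n))
        table = branch_table(d)
        thr = derive_size_thresholds(table)
        groups = assign_size_groups(table, thr)["size_group"].value_counts()
        assert sorted(groups.values) in ([n, n, n], [n - 1, n, n + 1])

    def test_too_few_branches_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            derive_size_thresholds(branch_table([2.0, np.nan, np.nan]))

    def test_classification_is_pure_function_of_diameter(self):
        thr = SizeThresholds(3.08, 4.23)
        assert thr.classify(3.0) == "small"
        assert thr.classify(3.08) == "medium"
        assert thr.classify(4.23) == "medium"
        assert thr.classify(4.24) == "large"
        assert thr.classify(np.nan) == "unassigned"
        # thresholds transfer: a second cohort's branch with the same
        # diameter lands in the same group, unconditionally
        assert thr.classify(3.5) == SizeThresholds(3.08, 4.23, "other").classify(3.5)


class TestPerSubjectMedians:
    def test_median_is_outlier_robust(self):
        table = branch_table([3, 3, 3], biomarker_values=[1.0, 2.0, 100.0])
        assert per_subject_medians(table, "intraBT_inner")["s"] == 2.0

    def test_all_missing_subject_omitted(self):
        t1 = branch_table([3, 3], "s1", [np.nan, np.nan])
        t2 = branch_table([3, 3], "s2", [1.0, 3.0])
        med = per_subject_medians(pd.concat([t1, t2]), "intraBT_inner")
        assert med == {"s2": 2.0}

    def test_stratified_medians_match_hand_calculation(self):
        table = pd.DataFrame(
            {
                "subject_id": ["s"] * 5,
                "branch_id": list("abcde"),
                "artery_mm": [2.0, 2.5, 3.5, 5.0, 6.0],
                "intraBT_inner": [1.0, 3.0, 2.0, 7.0, 5.0],
                "size_group": ["unassigned"] * 5,
            }
        )
        table = assign_size_groups(table, SizeThresholds(3.0, 4.5))
        assert per_subject_medians(table, "intraBT_inner", "small")["s"] == 2.0
        assert per_subject_medians(table, "intraBT_inner", "medium")["s"] == 2.0
        assert per_subject_medians(table, "intraBT_inner", "large")["s"] == 6.0
        assert per_subject_medians(table, "intraBT_inner", "all")["s"] == 3.0


class TestCompareGroups:
    def test_separated_triples_exact(self):
        cs = compare_groups({"a1": 1, "a2": 2, "a3": 3},
                            {"b1": 4, "b2": 5, "b3": 6})
        assert cs.method == "exact"
        assert cs.u_statistic == 0.0
        assert cs.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        cs = compare_groups({"a1": 1.0, "a2": 2.0}, {"b1": 1.5, "b2": 1.7})
        assert cs.p_value > 0.6

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for n_a in (2, 3, 4, 5, 6):
            for n_b in (2, 4, 6):
                a = rng.normal(size=n_a)
                b = rng.normal(0.5, 1.0, size=n_b)
                cs = compare_groups(
                    {f"a{i}": v for i, v in enumerate(a)},
                    {f"b{i}": v for i, v in enumerate(b)},
                )
                assert cs.p_value == pytest.approx(
                    exact_mwu_p(a, b), abs=1e-12
                ), (n_a, n_b)

    def test_approximation_close_to_exact_for_small_groups(self):
        rng = np.random.default_rng(1)
        from scipy import stats

        for trial in range(20):
            a = rng.normal(size=6)
            b = rng.normal(0.8, 1.0, size=6)
            p_approx = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_approx - exact_mwu_p(a, b)) < 0.02

    def test_medians_and_iqrs_reported(self):
        cs = compare_groups(
            {f"a{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])},
            {f"b{i}": float(v) for i, v in enumerate([10, 20, 30])},
        )
        assert cs.median_a == 3.0
        assert cs.iqr_a == (2.0, 4.0)
        assert cs.median_b == 20.0
        assert cs.n_a == 5 and cs.n_b == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({}, {"b": 1.0})


class TestSpearman:
    def test_perfect_monotone_decrease(self):
        med = {f"s{i}": float(10 - i) for i in range(6)}
        score = {f"s{i}": float(i * 3) for i in range(6)}
        rho, p = correlate_with_visual(med, score)
        assert rho == pytest.approx(-1.0, abs=1e-12)
        assert p < 0.01

    def test_constant_scores_flagged_missing(self):
        med = {f"s{i}": float(i) for i in range(5)}
        rho, p = correlate_with_visual(med, {k: 1.0 for k in med})
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_rank_formula_on_hand_fixture(self):
        # tie-free: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        med = {"s1": 2.1, "s2": 0.7, "s3": 1.4, "s4": 3.3, "s5": 0.2, "s6": 2.8}
        score = {"s1": 5.0, "s2": 30.0, "s3": 12.0, "s4": 2.0, "s5": 44.0, "s6": 11.0}
        keys = sorted(med)
        rx = pd.Series([med[k] for k in keys]).rank().to_numpy()
        ry = pd.Series([score[k] for k in keys]).rank().to_numpy()
        expected = 1 - 6 * np.sum((rx - ry) ** 2) / (6 * 35)
        rho, _ = correlate_with_visual(med, score)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_visual({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestHolm:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.5]
        expected = multipletests(p, method="holm")[1]
        assert np.allclose(holm_adjust(p), expected, atol=1e-12)
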