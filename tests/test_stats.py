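"""Assumption tests, decision tree routing and the star map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from dermaquant.errors import ParameterError, StatsError
from dermaquant.stats import (
    GroupedSample,
    annotate_significance,
    compare_groups,
    dunn_test,
    pairwise_test,
)
from dermaquant.stats import test_normality as check_normality
from dermaquant.stats import test_variance_homogeneity as check_variance_homogeneity


class TestNormality:
    def test_null_acceptance_rate_over_seeded_repeats(self):
        ok = 0
        for i in range(100):
            x = np.random.default_rng(i).normal(0, 1, 100)
            ok += check_normality([("g", x)])[0].normal
        assert ok >= 90

    def test_constant_group_refused_and_routed_non_normal(self):
        res = check_normality([("g", np.full(20, 3.0))])[0]
        assert res.code == "ZERO_VARIANCE" and not res.normal

    def test_tiny_group_refused(self):
        res = check_normality([("g", np.array([1.0, 2.0]))])[0]
        assert res.code == "TOO_FEW" and not res.normal

    def test_bimodal_two_point_sample_rejected(self):
        x = np.array([0.0] * 25 + [10.0] * 25)
        res = check_normality([("g", x)])[0]
        assert res.p is not None and res.p < 0.05


class TestVarianceHomogeneity:
    def test_identical_groups_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = check_variance_homogeneity([("a", x), ("b", x.copy())])
        assert p == pytest.approx(1.0)

    def test_unequal_variances_detected(self):
        hits = 0
        for i in range(40):
            rng = np.random.default_rng(i)
            groups = [("a", rng.normal(0, 1, 50)), ("b", rng.normal(0, 5, 50))]
            _, p = check_variance_homogeneity(groups)
            hits += p < 0.05
        assert hits >= 38  # >= 95% detection

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        reps = 500
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            groups = [(f"g{j}", rng.normal(0, 1, 30)) for j in range(3)]
            _, p = check_variance_homogeneity(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            check_variance_homogeneity([("a", np.array([1.0])), ("b", np.arange(5.0))])


class TestDecisionTree:
    def test_identical_groups_null_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cmp = compare_groups(GroupedSample("m", [("a", x), ("b", x.copy()), ("c", x.copy())]))
        assert cmp.omnibus_p > 0.05
        assert (cmp.pairwise["stars"] == "ns").all()

    def test_all_constant_degenerate_path(self):
        x = np.full(10, 5.0)
        cmp = compare_groups(GroupedSample("m", [("a", x), ("b", x), ("c", x)]))
        assert cmp.omnibus_p == 1.0 and cmp.omnibus_test == "degenerate"

    def test_normal_homogeneous_routes_anova_tukey_and_stars_shifted_pair(self):
        rng = np.random.default_rng(5)
        groups = [
            ("a", rng.normal(0, 1, 30)),
            ("b", rng.normal(0, 1, 30)),
            ("c", rng.normal(3, 1, 30)),
        ]
        cmp = compare_groups(GroupedSample("m", groups))
        assert cmp.omnibus_test == "ANOVA" and cmp.posthoc_test == "Tukey"
        pair = cmp.pairwise.set_index(["A", "B"])
        assert pair.loc[("a", "c"), "stars"] in ("*", "**", "***")
        assert pair.loc[("b", "c"), "stars"] in ("*", "**", "***")
        assert pair.loc[("a", "b"), "stars"] == "ns"
        # cross-check the omnibus against the classical F test
        f, p = sps.f_oneway(*[v for _, v in groups])
        assert cmp.omnibus_p == pytest.approx(p)

    def test_normal_inhomogeneous_routes_welch_games_howell(self):
        rng = np.random.default_rng(8)
        groups = [
            ("a", rng.normal(0, 0.5, 40)),
            ("b", rng.normal(0, 0.5, 40)),
            ("c", rng.normal(1.5, 4.0, 40)),
        ]
        cmp = compare_groups(GroupedSample("m", groups))
        assert cmp.omnibus_test == "Welch-ANOVA"
        assert cmp.posthoc_test == "Games-Howell"
        assert cmp.levene_p is not None and cmp.levene_p < 0.05

    def test_heavy_tailed_routes_kruskal_dunn_with_trace(self):
        rng = np.random.default_rng(2)
        groups = [
            ("a", rng.standard_cauchy(40)),
            ("b", rng.normal(0, 1, 40)),
            ("c", rng.normal(0, 1, 40)),
        ]
        cmp = compare_groups(GroupedSample("m", groups))
        assert cmp.omnibus_test == "Kruskal-Wallis"
        assert cmp.posthoc_test.startswith("Dunn")
        assert any("non-parametric" in line for line in cmp.trace)
        assert len(cmp.trace) >= 4

    def test_every_path_produces_one_pairing_and_nonempty_trace(self):
        rng = np.random.default_rng(9)
        samples = [
            [("a", rng.normal(0, 1, 20)), ("b", rng.normal(0, 1, 20))],
            [("a", rng.exponential(1, 20)), ("b", rng.normal(0, 1, 20))],
            [("a", rng.normal(0, 1, 20)), ("b", rng.normal(0, 6, 20))],
        ]
        valid = {"ANOVA": "Tukey", "Welch-ANOVA": "Games-Howell", "Kruskal-Wallis": "Dunn"}
        for groups in samples:
            cmp = compare_groups(GroupedSample("m", groups))
            assert cmp.posthoc_test.split(" ")[0] == valid[cmp.omnibus_test]
            assert cmp.trace


class TestDunn:
    def test_two_group_z_squared_equals_kruskal_h_with_ties(self, rng):
        # exact identity between Dunn's z and the tie-corrected KW statistic
        for _ in range(5):
            a = np.round(rng.normal(0, 1, 12), 1)
            b = np.round(rng.normal(0.7, 1, 15), 1)
            h = sps.kruskal(a, b).statistic
            z = float(dunn_test([("a", a), ("b", b)], adjust="none")["statistic"].iloc[0])
            assert z**2 == pytest.approx(h, abs=1e-10)

    def test_holm_adjustment_matches_statsmodels(self, rng):
        groups = [(l, rng.normal(m, 1, 15)) for l, m in (("a", 0), ("b", 0.5), ("c", 2))]
        table = dunn_test(groups, adjust="holm")
        expected = multipletests(table["p_unadj"], method="holm")[1]
        assert np.allclose(table["p_adj"], expected)

    def test_unknown_adjustment_rejected(self, rng):
        with pytest.raises(ParameterError):
            dunn_test([("a", rng.normal(0, 1, 5)), ("b", rng.normal(0, 1, 5))], adjust="fdr")


class TestPairwise:
    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        res = pairwise_test(x, x.copy())
        assert res["p"] > 0.9 and res["stars"] == "ns"

    def test_large_shift_highly_significant_t_test(self):
        rng = np.random.default_rng(4)
        res = pairwise_test(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
        assert res["test"] in ("t", "Welch t")
        assert res["p"] < 0.001 and res["stars"] == "***"

    def test_ordinal_ties_route_mann_whitney_and_match_scipy(self):
        a = np.repeat([1.0, 5.0], 15)  # two-point sample: clearly non-normal
        b = np.array([2, 3, 3, 3, 4, 4, 5, 5, 5, 5] * 3, dtype=float)
        res = pairwise_test(a, b)
        assert res["test"] == "Mann-Whitney"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert res["p"] == pytest.approx(float(ref.pvalue))

    def test_tiny_groups_rejected(self):
        with pytest.raises(StatsError):
            pairwise_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.0005, "***"),
            (0.005, "**"),
            (0.03, "*"),
            (0.05, "ns"),   # strict boundary
            (0.01, "*"),    # strict boundary
            (0.001, "**"),  # strict boundary
            (1.0, "ns"),
            (0.0, "***"),
        ],
    )
    def test_star_map(self, p, stars):
        assert annotate_significance(p) == stars

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ParameterError):
            annotate_significance(bad)

    @given(st.floats(0, 1, allow_nan=False))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_step_function_consistency(self, p):
        stars = annotate_significance(p)
        thresholds = {"***": p < 0.001, "**": 0.001 <= p < 0.01, "*": 0.01 <= p < 0.05, "ns": p >= 0.05}
        assert thresholds[stars]
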