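"""Conductivity, the statistical decision tree, and report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from texelec.report import (
    AssumptionCheck,
    SheetSample,
    assumption_check,
    build_report,
    compare,
    conductivity,
    holm_adjust,
    select_test,
)


class TestConductivity:
    def test_worked_unit_example(self):
        """100 ohm/sq at 100 um: rho = 0.01 ohm m, sigma = 1 S/cm."""
        assert conductivity(SheetSample(100.0, 100e-6)) == pytest.approx(1.0)

    def test_doubling_thickness_halves_sigma(self):
        base = conductivity(SheetSample(50.0, 2e-4))
        assert conductivity(SheetSample(50.0, 4e-4)) == pytest.approx(base / 2.0)

    def test_strictly_decreasing_in_each_input(self):
        s0 = conductivity(SheetSample(10.0, 1e-4))
        assert conductivity(SheetSample(11.0, 1e-4)) < s0
        assert conductivity(SheetSample(10.0, 1.1e-4)) < s0

    def test_algebraic_roundtrip(self):
        """sigma -> R_s (given t) -> sigma recovers the input."""
        sigma, t = 3.7, 1.3e-4
        r_s = 1.0 / (sigma * 100.0 * t)
        assert conductivity(SheetSample(r_s, t)) == pytest.approx(sigma, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            SheetSample(-1.0, 1e-4)
        with pytest.raises(ValueError):
            SheetSample(1.0, 0.0)


class TestAssumptionCheck:
    def test_seeded_normal_groups_pass(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        res = assumption_check(groups)
        assert res.normal and res.homoscedastic and res.parametric_ok

    def test_scaled_group_fails_levene(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(0, 1, 30), 100.0 * rng.normal(0, 1, 30)]
        res = assumption_check(groups)
        assert not res.homoscedastic

    def test_cauchy_groups_fail_normality(self):
        rng = np.random.default_rng(7)
        groups = [rng.standard_cauchy(40) for _ in range(2)]
        assert not assumption_check(groups).normal

    def test_small_n_uses_shapiro_large_uses_ks(self):
        rng = np.random.default_rng(0)
        small = assumption_check([rng.normal(0, 1, 10) for _ in range(2)])
        large = assumption_check([rng.normal(0, 1, 60) for _ in range(2)])
        assert small.normality_test == "shapiro"
        assert large.normality_test == "ks"

    def test_constant_group_flags_degenerate(self):
        res = assumption_check([np.full(5, 2.0), np.array([1.0, 2.0, 3.0])])
        assert res.degenerate and not res.parametric_ok

    def test_too_few_groups_or_observations_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            assumption_check([np.arange(5.0)])
        with pytest.raises(ValueError, match="3 observations"):
            assumption_check([np.arange(5.0), np.array([1.0, 2.0])])


class TestSelectTest:
    @pytest.mark.parametrize(
        "ok,n,design,expected",
        [
            (True, 2, "independent", "anova"),
            (True, 2, "paired", "t_paired"),
            (True, 3, "independent", "anova"),
            (True, 2, "repeated", "anova_rm"),
            (True, 3, "repeated", "anova_rm"),
            (False, 2, "independent", "wilcoxon_ranksum"),
            (False, 2, "paired", "wilcoxon_signedrank"),
            (False, 2, "repeated", "wilcoxon_signedrank"),
            (False, 3, "independent", "kruskal"),
            (False, 3, "paired", "kruskal"),
            (False, 3, "repeated", "kruskal"),
        ],
    )
    def test_decision_table(self, ok, n, design, expected):
        assert select_test(ok, n, design) == expected

    def test_pure_function_total_over_domain(self):
        for ok, n, design in itertools.product(
            (True, False), (2, 3, 5), ("independent", "paired", "repeated")
        ):
            assert isinstance(select_test(ok, n, design), str)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            select_test(True, 2, "crossover")


class TestCompare:
    def test_same_distribution_groups_not_significant(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(5.0, 1.0, 25) for _ in range(3)]
        res = compare(groups)
        assert res.test == "anova"
        assert res.pvalue > 0.05

    def test_ten_sd_shift_highly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 24)
        b = rng.normal(10.0, 1.0, 24)
        res = compare([a, b])
        assert res.pvalue < 1e-6

    def test_nonnormal_two_groups_dispatches_ranksum(self):
        rng = np.random.default_rng(5)
        groups = [rng.standard_cauchy(40), rng.standard_cauchy(40)]
        res = compare(groups)
        assert res.test == "wilcoxon_ranksum"

    def test_forced_branches_match_scipy_oracles(self):
        """Each dispatched statistic equals the scipy call it should wrap."""
        rng = np.random.default_rng(9)
        a, b, c = rng.normal(0, 1, (3, 20))
        ok = AssumptionCheck(True, 0.5, "shapiro", True, 0.5)
        bad = AssumptionCheck(False, 0.01, "shapiro", True, 0.5)
        assert compare([a, b, c], checks=ok).statistic == pytest.approx(
            stats.f_oneway(a, b, c).statistic
        )
        assert compare([a, b], design="paired", checks=ok).statistic == pytest.approx(
            stats.ttest_rel(a, b).statistic
        )
        assert compare([a, b], checks=bad).statistic == pytest.approx(
            stats.ranksums(a, b).statistic
        )
        assert compare([a, b], design="paired", checks=bad).statistic == pytest.approx(
            stats.wilcoxon(a, b).statistic
        )
        assert compare([a, b, c], checks=bad).statistic == pytest.approx(
            stats.kruskal(a, b, c).statistic
        )

    def test_repeated_measures_anova_null_not_significant(self):
        rng = np.random.default_rng(21)
        subject_effect = rng.normal(0, 1, 12)
        groups = [subject_effect + rng.normal(0, 0.5, 12) for _ in range(3)]
        ok = AssumptionCheck(True, 0.5, "shapiro", True, 0.5)
        res = compare(groups, design="repeated", checks=ok)
        assert res.test == "anova_rm"
        assert res.pvalue > 0.05

    def test_paired_design_requires_equal_sizes(self):
        with pytest.raises(ValueError, match="equal group sizes"):
            compare([np.arange(5.0), np.arange(6.0)], design="paired")


class TestHolmAdjust:
    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.20])
        _, expected, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), expected)

    def test_monotone_and_bounded(self):
        adj = holm_adjust([0.5, 0.9, 0.001])
        assert np.all(adj <= 1.0)
        assert np.all(adj >= [0.5, 0.9, 0.001])


class TestBuildReport:
    def test_full_study_all_sections(self):
        rng = np.random.default_rng(1)
        imp = pd.DataFrame({"material": ["a", "b"], "auc": rng.uniform(1, 2, 2)})
        res = compare([rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
        rep = build_report(
            impedance=imp,
            polarization={"grand_mean_mv": 15.4},
            noise={"power_mv2": 0.02},
            longterm=pd.DataFrame({"hours": [0.0], "median_error": [0.0]}),
            comparisons={"material effect": res},
        )
        md = rep.to_markdown()
        for section in (
            "Contact impedance",
            "Polarization",
            "Noise and fidelity",
            "Long-term performance",
            "Statistical comparisons",
        ):
            assert section in md
        assert "absent" not in md

    def test_impedance_only_marks_others_absent(self):
        rep = build_report(impedance={"auc": 1.0})
        d = rep.to_dict()
        assert d["Polarization"] == "absent"
        assert d["Contact impedance"] == {"auc": 1.0}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no stage outputs"):
            build_report()

    def test_deterministic_assembly(self):
        kwargs = dict(polarization={"grand_mean_mv": 2.54})
        assert build_report(**kwargs).to_markdown() == build_report(**kwargs).to_markdown()
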