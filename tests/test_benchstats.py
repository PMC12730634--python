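"""Statistics pathway vs hand-computed oracles and independent libraries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from capetwin.benchstats import (
    DegenerateDataError,
    analyse_plate,
    dunn_holm,
    fold_change_table,
    games_howell,
    generate_plate,
    holm_adjust,
    kruskal_wallis,
    load_fixture_means,
    significance_tier,
    welch_anova,
)

G3 = [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]]


class TestWelchAnova:
    def test_hand_computed_example(self):
        """Three shifted groups with equal spread: the Welch weights are
        w_i = 4/(5/3) = 2.4, grand mean 6.5, giving F = 34.56 on
        (2, 6.0) df -- checked by hand through the standard formulas."""
        report = welch_anova(G3)
        assert report.statistic == pytest.approx(34.56, rel=1e-9)
        assert report.df[0] == 2
        assert report.df[1] == pytest.approx(6.0, rel=1e-9)
        assert report.p_value == pytest.approx(
            float(stats.f.sf(34.56, 2, 6.0)), rel=1e-9
        )

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = pd.DataFrame(
            {
                "value": np.concatenate([np.asarray(g, float) for g in G3]),
                "group": np.repeat(["a", "b", "c"], 4),
            }
        )
        ref = pingouin.welch_anova(data=data, dv="value", between="group")
        report = welch_anova(G3)
        assert report.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert report.p_value == pytest.approx(
            float(ref["p_unc"][0]), rel=1e-9
        )

    def test_identical_groups_give_f_zero_p_one(self):
        report = welch_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert report.statistic == 0.0
        assert report.p_value == 1.0

    def test_constant_group_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_reduces_to_classical_anova_under_homoscedasticity(self):
        """For two groups of equal size and equal sample variance the Welch
        statistic and degrees of freedom coincide exactly with the
        classical one-way ANOVA."""
        g = [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]]
        report = welch_anova(g)
        classical = stats.f_oneway(*g)
        assert abs(report.p_value - classical.pvalue) < 1e-6
        assert report.statistic == pytest.approx(classical.statistic,
                                                 rel=1e-12)


class TestGamesHowell:
    def test_identical_pair_is_null(self):
        pairs = games_howell([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pairs[0].difference == 0.0
        assert pairs[0].p_adjusted == 1.0

    def test_two_group_reduction_to_welch_t(self):
        """With k = 2 the studentized-range route (q = |t| sqrt(2)) must
        reproduce the two-sided Welch t-test p value."""
        a = [1.2, 3.4, 2.2, 4.8, 2.9]
        b = [5.1, 6.3, 8.0, 7.2]
        (pair,) = games_howell([a, b])
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert pair.p_adjusted == pytest.approx(ref.pvalue, rel=1e-6)

    def test_well_separated_groups_are_all_significant(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(mean, 1.0, 8) for mean in (0.0, 10.0, 20.0)]
        for pair in games_howell(groups):
            assert pair.p_adjusted < 0.001

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, s, 8)
                  for m, s in ((0, 1.0), (1.0, 2.0), (2.5, 0.5))]
        data = pd.DataFrame(
            {
                "value": np.concatenate(groups),
                "group": np.repeat(["a", "b", "c"], 8),
            }
        )
        ref = pingouin.pairwise_gameshowell(data=data, dv="value",
                                            between="group")
        ours = games_howell(groups)
        for pr, (_, row) in zip(ours, ref.iterrows()):
            assert pr.p_adjusted == pytest.approx(float(row["pval"]),
                                                  abs=1e-9)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..4, R1 = 3, R2 = 7: H = 12/20 (9/2 + 49/2) - 15 = 2.4
        report = kruskal_wallis([[1, 2], [3, 4]])
        assert report.statistic == pytest.approx(2.4, rel=1e-12)
        assert report.p_value == pytest.approx(
            float(stats.chi2.sf(2.4, 1)), rel=1e-12
        )

    def test_identical_groups_give_h_zero(self):
        report = kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert report.statistic == 0.0
        assert report.p_value == 1.0

    def test_agrees_with_scipy_under_ties(self):
        groups = [[1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 4.0], [5.0, 6.0, 2.0]]
        report = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert report.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert report.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    @given(
        shift=st.floats(min_value=-5, max_value=5),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, shift, scale):
        groups = [[1.0, 4.0, 2.5], [3.0, 8.0, 0.5], [6.0, 7.0, 9.0]]
        transformed = [
            [np.expm1(scale * x) + shift for x in g] for g in groups
        ]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(transformed).statistic, rel=1e-12
        )


class TestDunnHolm:
    def test_holm_hand_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_holm_is_monotone_and_bounded(self):
        raw = [0.04, 0.001, 0.2, 0.012, 0.9]
        adjusted = holm_adjust(raw)
        assert all(0.0 <= p <= 1.0 for p in adjusted)
        assert all(a >= r for a, r in zip(adjusted, raw))
        order = np.argsort(raw)
        assert np.all(np.diff(np.asarray(adjusted)[order]) >= 0)

    @given(
        raw=st.lists(st.floats(min_value=0.0, max_value=1.0),
                     min_size=1, max_size=8)
    )
    @settings(max_examples=100, deadline=None)
    def test_holm_properties_hold_for_any_input(self, raw):
        adjusted = holm_adjust(raw)
        assert all(0.0 <= p <= 1.0 for p in adjusted)
        assert all(a >= r - 1e-15 for a, r in zip(adjusted, raw))

    def test_identical_groups_all_p_one(self):
        pairs = dunn_holm([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                           [1.0, 2.0, 3.0]])
        for pr in pairs:
            assert pr.p_adjusted == 1.0

    def test_separated_groups_ordered_sensibly(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, 8) for m in (0.0, 5.0, 10.0)]
        pairs = {pr.pair: pr for pr in dunn_holm(groups)}
        # the extreme pair is at least as significant as the adjacent ones
        assert pairs[(0, 2)].p_adjusted <= pairs[(0, 1)].p_adjusted


class TestPlateGeneration:
    def test_zero_cv_reproduces_the_fixture_means(self):
        plate = generate_plate("decorin", 48, cv=0.0, n=4, seed=0)
        means = load_fixture_means("decorin", 48)
        for dose, values in plate.groups.items():
            assert np.allclose(values, means[dose])
        table = fold_change_table(plate)
        for dose, (ratio, sd) in table.items():
            assert ratio == pytest.approx(means[dose])
            assert sd == pytest.approx(0.0, abs=1e-15)

    def test_same_seed_is_reproducible(self):
        a = generate_plate("ca72_4", 48, cv=0.1, n=8, seed=5)
        b = generate_plate("ca72_4", 48, cv=0.1, n=8, seed=5)
        for dose in a.groups:
            assert np.array_equal(a.groups[dose], b.groups[dose])

    def test_group_means_within_sampling_error(self):
        cv, n = 0.1, 8
        plate = generate_plate("decorin", 48, cv=cv, n=n, seed=123)
        means = load_fixture_means("decorin", 48)
        for dose, values in plate.groups.items():
            # 3-sigma CLT bound on the group mean around its target
            bound = 3.0 * cv * means[dose] / np.sqrt(n)
            assert abs(values.mean() - means[dose]) < bound

    def test_printed_anchor_values_in_fixture(self):
        assert load_fixture_means("ca72_4", 48)[100.0] == 2.8
        assert load_fixture_means("decorin", 24)[50.0] == 1.8
        assert load_fixture_means("decorin", 48)[100.0] == 3.5

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            generate_plate("decorin", 48, n=1, seed=0)

    def test_control_only_table(self):
        plate = generate_plate("decorin", 48, dose_means={0.0: 1.0},
                               cv=0.0, n=2, seed=0)
        assert fold_change_table(plate) == {0.0: (1.0, 0.0)}


def test_significance_tiers():
    assert significance_tier(0.0005) == "***"
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.02) == "*"
    assert significance_tier(0.5) == "ns"


def test_full_plate_pathway_reports_dose_dependence():
    plate = generate_plate("decorin", 48, cv=0.1, n=8, seed=2)
    report = analyse_plate(plate)
    welch = report["welch_games_howell"]
    assert welch["p_value"] < 0.001  # 3.5-fold spread dwarfs 10% noise
    kw = report["kruskal_dunn_holm"]
    assert kw["p_value"] < 0.001
    extreme = [p for p in welch["pairwise"]
               if set(p["pair"]) == {0.0, 100.0}][0]
    assert extreme["tier"] in ("**", "***")
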