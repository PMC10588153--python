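"""Pooled t-tests, the comparison table, threshold scan and rater statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from isletmorph import (
    DegenerateDataError,
    GroupSummary,
    InsufficientDataError,
    RaterSheet,
    combine_group_summaries,
    compare_groups,
    pooled_ttest_from_summary,
    pooled_ttest_from_values,
    rater_accuracy,
    rater_group_stats,
    summarize_specimen,
    threshold_scan,
)
from isletmorph.errors import IncompleteSheetError
from isletmorph.synthetic import planted_threshold, simulate_cohort
from conftest import make_specimen


class TestPooledTTest:
    def test_reproduces_published_low_circularity_p(self):
        res = pooled_ttest_from_summary(
            GroupSummary(82.0, 19.0, 4), GroupSummary(30.0, 5.71, 5)
        )
        assert res.df == 7
        assert res.p == pytest.approx(0.023, abs=5e-4)

    def test_reproduces_published_islet_count_p(self):
        res = pooled_ttest_from_summary(
            GroupSummary(417.0, 67.8, 4), GroupSummary(501.0, 90.0, 5)
        )
        assert res.p == pytest.approx(0.50, abs=5e-3)

    def test_identical_summaries_give_null(self):
        g = GroupSummary(10.0, 2.0, 5)
        res = pooled_ttest_from_summary(g, g)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_equal_means_is_p_one(self):
        res = pooled_ttest_from_summary(GroupSummary(5.0, 0.0, 3), GroupSummary(5.0, 0.0, 4))
        assert res.p == 1.0

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pooled_ttest_from_values([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_identical_value_groups(self):
        res = pooled_ttest_from_values([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_short_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            pooled_ttest_from_values([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_scipy_equal_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1.3, 5)
        mine = pooled_ttest_from_values(x, y)
        oracle = sps.ttest_ind(x, y, equal_var=True)
        assert mine.t == pytest.approx(oracle.statistic, rel=1e-12)
        assert mine.p == pytest.approx(oracle.pvalue, rel=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_summary_and_raw_routes_agree(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(5, 2, 6), rng.normal(4, 2, 9)
        from isletmorph import summarize_values

        a = pooled_ttest_from_values(x, y)
        b = pooled_ttest_from_summary(summarize_values(x), summarize_values(y))
        assert a.t == pytest.approx(b.t, rel=1e-11)
        assert a.p == pytest.approx(b.p, rel=1e-11)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.tuples(
        st.floats(-50, 50), st.floats(0.01, 20), st.integers(2, 12),
        st.floats(-50, 50), st.floats(0.01, 20), st.integers(2, 12),
    )
)
def test_group_swap_symmetry(params):
    """Swapping the groups negates t and preserves p exactly."""
    m1, se1, n1, m2, se2, n2 = params
    g1, g2 = GroupSummary(m1, se1, n1), GroupSummary(m2, se2, n2)
    a = pooled_ttest_from_summary(g1, g2)
    b = pooled_ttest_from_summary(g2, g1)
    assert a.t == pytest.approx(-b.t, rel=1e-12, abs=1e-12)
    assert a.p == b.p


class TestCompareGroups:
    def _cohort(self):
        rng = np.random.default_rng(3)
        specimens = []
        for group, n in (("ANHH", 4), ("control", 5)):
            for i in range(n):
                circs = rng.uniform(0.5, 1.0, 50)
                specimens.append(
                    make_specimen(
                        circs, parenchyma_cm2=2.0, group=group,
                        specimen_id=f"{group}{i}",
                    )
                )
        return [summarize_specimen(s) for s in specimens]

    def test_duplicated_group_gives_p_one(self):
        rng = np.random.default_rng(5)
        half = [
            make_specimen(rng.uniform(0.4, 1.0, 30), group="ANHH", specimen_id=f"a{i}")
            for i in range(4)
        ]
        mirrored = [
            make_specimen(s.circularities(), group="control", specimen_id=f"c{i}")
            for i, s in enumerate(half)
        ]
        table = compare_groups([summarize_specimen(s) for s in half + mirrored])
        assert np.allclose(table["p"].dropna(), 1.0)

    def test_table_has_expected_rows(self):
        table = compare_groups(self._cohort())
        assert list(table["measurement"]) == [
            "n_islets",
            "n_islets_per_cm2",
            "total_islet_area_cm2",
            "islet_area_fraction_pct",
            "mean_max_diameter_um",
            "n_low_circularity",
            "n_low_circularity_per_cm2",
        ]
        assert ((table["p"].dropna() > 0) & (table["p"].dropna() <= 1)).all()

    def test_single_specimen_group_rejected(self):
        bad = [
            summarize_specimen(make_specimen([0.9], group="ANHH")),
            summarize_specimen(make_specimen([0.9], group="control", specimen_id="c1")),
            summarize_specimen(make_specimen([0.9], group="control", specimen_id="c2")),
        ]
        with pytest.raises(InsufficientDataError):
            compare_groups(bad)


class TestThresholdScan:
    def _separated_cohort(self):
        rng = np.random.default_rng(11)
        specimens = []
        for i in range(4):  # every ANHH islet at circularity 0.55
            n = rng.integers(20, 40)
            specimens.append(
                make_specimen([0.55] * n, parenchyma_cm2=rng.uniform(1.5, 2.5),
                              group="ANHH", specimen_id=f"a{i}")
            )
        for i in range(5):  # every control islet at 0.85
            n = rng.integers(20, 40)
            specimens.append(
                make_specimen([0.85] * n, parenchyma_cm2=rng.uniform(1.5, 2.5),
                              group="control", specimen_id=f"c{i}")
            )
        return specimens

    def test_perfect_separation_selects_plateau_start(self):
        res = threshold_scan(self._separated_cohort())
        # thresholds <= 0.55 are degenerate (all-zero counts) and skipped;
        # every threshold in (0.55, 0.85] fully separates with identical
        # counts, so the tie resolves to the smallest such grid point
        assert res.selected_threshold == pytest.approx(0.56)
        plateau = res.p_values[(res.grid > 0.56) & (res.grid <= 0.85)]
        assert np.allclose(plateau, res.selected_p)
        skipped = res.p_values[res.grid <= 0.55]
        assert np.isnan(skipped).all()

    def test_single_point_grid(self):
        res = threshold_scan(self._separated_cohort(), grid=np.array([0.7]))
        assert res.selected_threshold == 0.7

    def test_null_scan_shows_selection_bias(self):
        """Under the null, min-p selection over ~46 dependent candidates
        drags the selected p below the uniform median."""
        selected = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            specimens = []
            for group, n in (("ANHH", 4), ("control", 5)):
                for i in range(n):
                    circs = rng.uniform(0.4, 1.0, rng.integers(30, 60))
                    specimens.append(
                        make_specimen(
                            circs, parenchyma_cm2=rng.uniform(1.5, 2.5),
                            group=group, specimen_id=f"{group}{i}",
                        )
                    )
            selected.append(threshold_scan(specimens).selected_p)
        assert np.median(selected) < 0.5

    def test_planted_threshold_recovered_single_run(self):
        cohort = simulate_cohort(planted_threshold(seed=42))
        res = threshold_scan(cohort.records)
        assert abs(res.selected_threshold - 0.71) <= 0.05


class TestRaterStatistics:
    TRUTH = {f"s{i}": ("ANHH" if i < 4 else "control") for i in range(8)}

    def test_all_same_answer_is_chance(self):
        sheet = RaterSheet("r1", "experienced", {f"s{i}": "ANHH" for i in range(8)})
        assert rater_accuracy(sheet, self.TRUTH) == 50.0

    def test_perfect_answers(self):
        sheet = RaterSheet("r2", "experienced", dict(self.TRUTH))
        assert rater_accuracy(sheet, self.TRUTH) == 100.0

    def test_three_of_eight(self):
        answers = {
            sid: (lab if i < 3 else ("control" if lab == "ANHH" else "ANHH"))
            for i, (sid, lab) in enumerate(self.TRUTH.items())
        }
        assert rater_accuracy(RaterSheet("r3", "x", answers), self.TRUTH) == 37.5

    def test_missing_answer_raises(self):
        sheet = RaterSheet("r4", "x", {f"s{i}": "ANHH" for i in range(7)})
        with pytest.raises(IncompleteSheetError):
            rater_accuracy(sheet, self.TRUTH)

    def test_reproduces_published_interobserver_summary(self):
        experienced = GroupSummary(47.5, 6.12, 5)
        less = GroupSummary(50.0, 8.63, 7)
        combined, res = rater_group_stats(experienced, less)
        assert combined.mean == pytest.approx(49.0, abs=0.05)
        assert combined.se == pytest.approx(5.43, abs=0.01)
        assert res.p == pytest.approx(0.83, abs=5e-3)

    def test_identical_groups_combine_transparently(self):
        g = GroupSummary(50.0, 5.0, 4)
        combined, res = rater_group_stats(g, g)
        assert res.p == 1.0
        assert combined.mean == 50.0

    def test_between_group_variance_dominates_combination(self):
        g1, g2 = GroupSummary(0.0, 0.0, 2), GroupSummary(100.0, 0.0, 2)
        combined = combine_group_summaries(g1, g2)
        assert combined.mean == 50.0
        # total SS is purely between-group: 4 * 50² / 3 variance
        assert combined.se == pytest.approx(np.sqrt((4 * 50**2 / 3) / 4))
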