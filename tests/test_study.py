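"""Observer-study analytics tests, anchored on the published count table."""

import numpy as np
import pandas as pd
import pytest

from dvaseg import (
    best_of_dvas,
    bonferroni,
    chi_squared_grades,
    cohens_kappa,
    count_grade4_scans,
    count_rank_le,
    grade_distribution,
    load_observer_study_counts,
    observer_preference_kappas,
    preference_labels,
    records_from_counts,
    region_split,
    relative_area_by_region,
)
from dvaseg.metrics import BinaryMask
from dvaseg.study import IncompletePairError


@pytest.fixture(scope="module")
def counts():
    return load_observer_study_counts()


@pytest.fixture(scope="module")
def scan_ranks(counts):
    return best_of_dvas(records_from_counts(counts, "scan", "rank"))


@pytest.fixture(scope="module")
def scan_grades(counts):
    return best_of_dvas(records_from_counts(counts, "scan", "grade"))


def pearson_chi2(table):
    """From-scratch Pearson chi-squared oracle."""
    table = np.asarray(table, dtype=float)
    rs, cs, n = table.sum(1), table.sum(0), table.sum()
    expect = np.outer(rs, cs) / n
    return ((table - expect) ** 2 / expect).sum()


class TestBestOfDvas:
    def test_grade_merge_is_max_and_rank_merge_is_min(self):
        rec = pd.DataFrame({
            "observer": [1, 1], "scan": [1, 1], "slice": [pd.NA] * 2,
            "source": ["dvas_1", "dvas_2"], "grade": [3, 4]})
        merged = best_of_dvas(rec)
        assert merged[merged.source == "dvas_best"].grade.item() == 4
        rnk = pd.DataFrame({
            "observer": [1, 1], "scan": [1, 1],
            "source": ["dvas_1", "dvas_2"], "rank": [2, 1]})
        assert best_of_dvas(rnk).query("source == 'dvas_best'")["rank"].item() == 1

    def test_missing_counterpart_raises(self):
        rec = pd.DataFrame({
            "observer": [1], "scan": [1], "source": ["dvas_1"], "rank": [2]})
        with pytest.raises(IncompletePairError):
            best_of_dvas(rec)

    def test_merge_never_worse_than_either_source(self, scan_grades):
        a = scan_grades[scan_grades.source == "dvas_1"].grade.to_numpy()
        b = scan_grades[scan_grades.source == "dvas_2"].grade.to_numpy()
        m = scan_grades[scan_grades.source == "dvas_best"].grade.to_numpy()
        assert (m >= a).all() and (m >= b).all()
        assert (m[a == b] == a[a == b]).all()

    def test_observer1_merged_rank_counts(self, scan_ranks):
        got = grade_distribution(scan_ranks, 1, "dvas_best")
        np.testing.assert_array_equal(got, [6, 6, 1, 0])


class TestCountTable:
    def test_observer2_reference_scan_grades(self, scan_grades):
        got = grade_distribution(scan_grades, 2, "reference")
        np.testing.assert_array_equal(got, [1, 2, 4, 6])

    def test_per_scan_totals_are_thirteen(self, scan_grades):
        for obs in (1, 2, 3):
            for source in ("reference", "classical", "dvas_best"):
                assert grade_distribution(scan_grades, obs, source).sum() == 13

    def test_empty_selection_gives_zero_counts(self, scan_grades):
        np.testing.assert_array_equal(
            grade_distribution(scan_grades, 99, "reference"), [0, 0, 0, 0])

    def test_grade4_reference_scans_per_observer(self, scan_grades):
        assert [count_grade4_scans(scan_grades, o, "reference")
                for o in (1, 2, 3)] == [3, 6, 1]

    def test_rank_top2_margins_over_reference(self, scan_ranks):
        margins = [count_rank_le(scan_ranks, o, "dvas_best", 2)
                   - count_rank_le(scan_ranks, o, "reference", 2)
                   for o in (1, 2, 3)]
        assert margins == [3, 1, 1]
        assert count_rank_le(scan_ranks, 1, "dvas_best", 2) == 12
        assert count_rank_le(scan_ranks, 1, "reference", 2) == 9

    def test_threshold_at_max_rank_counts_all_scans(self, scan_ranks):
        assert count_rank_le(scan_ranks, 1, "reference", 4) == 13
        with pytest.raises(ValueError):
            count_rank_le(scan_ranks, 1, "reference", 0)


class TestChiSquared:
    def test_identical_distributions_give_zero(self):
        stat, df, p = chi_squared_grades([5, 6, 7, 8], [5, 6, 7, 8])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_grade4_vs_rest_worked_example(self):
        # observer 2 per-slice: classical 57 grade-4 of 192; merged
        # variants 79 of 192
        stat, df, p = chi_squared_grades([57, 135], [79, 113])
        assert df == 1
        assert stat == pytest.approx(5.5104, abs=1e-3)
        assert p < 0.05

    def test_doubling_counts_doubles_statistic(self):
        a, b = [10, 20, 5, 7], [8, 25, 2, 9]
        s1, _, _ = chi_squared_grades(a, b)
        s2, _, _ = chi_squared_grades([2 * x for x in a], [2 * x for x in b])
        assert s2 == pytest.approx(2 * s1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 60, 4)
        b = rng.integers(1, 60, 4)
        stat, df, _ = chi_squared_grades(a, b)
        assert df == 3
        assert stat == pytest.approx(pearson_chi2([a, b]), abs=1e-10)

    def test_zero_total_columns_dropped_with_df_reduced(self):
        stat, df, _ = chi_squared_grades([5, 0, 7, 8], [3, 0, 9, 1])
        assert df == 2
        assert stat == pytest.approx(pearson_chi2([[5, 7, 8], [3, 9, 1]]),
                                     abs=1e-10)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_grades([0, 0], [0, 0])


class TestBonferroni:
    def test_scaling_and_clamping(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.2, 1) == pytest.approx(0.2)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestCohensKappa:
    def test_perfect_agreement(self):
        labels = np.array(["a", "b", "a", "c"])
        assert cohens_kappa(labels, labels) == 1.0

    def test_confusion_matrix_worked_example(self):
        # 2x2 confusion counts [[20, 5], [10, 15]]: p_o=0.7, p_e=0.5
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        a = rng.choice(["p", "q", "r"], 60)
        b = rng.choice(["p", "q", "r"], 60)
        k = cohens_kappa(a, b)
        assert k == pytest.approx(cohens_kappa(b, a))
        assert -1.0 <= k <= 1.0

    def test_independent_labels_average_near_zero(self):
        rng = np.random.default_rng(12)
        kappas = []
        for _ in range(300):
            a = rng.choice(["v1", "v2", "tie"], 40, p=[0.4, 0.4, 0.2])
            b = rng.choice(["v1", "v2", "tie"], 40, p=[0.4, 0.4, 0.2])
            kappas.append(cohens_kappa(a, b))
        assert abs(np.mean(kappas)) < 0.03

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.choice(["u", "v", "w"], 50)
        b = rng.choice(["u", "v", "w"], 50)
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))


class TestPreferences:
    def test_grade_and_rank_preference_rules(self):
        rec = pd.DataFrame({
            "observer": [1, 1, 1, 1], "scan": [1, 1, 2, 2],
            "source": ["dvas_1", "dvas_2"] * 2, "grade": [4, 2, 3, 3]})
        prefs = preference_labels(rec)
        assert prefs.preference.tolist() == ["variant1", "tie"]
        rnk = pd.DataFrame({
            "observer": [1, 1], "scan": [1, 1],
            "source": ["dvas_1", "dvas_2"], "rank": [2, 1]})
        assert preference_labels(rnk).preference.item() == "variant2"

    def test_pairwise_observer_kappas(self):
        rows = []
        for obs in (1, 2, 3):
            for scan in range(1, 9):
                winner = scan % 2  # all observers agree perfectly
                rows.append({"observer": obs, "scan": scan,
                             "source": "dvas_1", "grade": 4 - winner})
                rows.append({"observer": obs, "scan": scan,
                             "source": "dvas_2", "grade": 3 + winner})
        kappas = observer_preference_kappas(pd.DataFrame(rows))
        assert set(kappas) == {(1, 2), (1, 3), (2, 3)}
        assert all(k == 1.0 for k in kappas.values())


class TestRegionSplit:
    @pytest.mark.parametrize("n,expected", [(9, (3, 3, 3)), (13, (5, 4, 4)),
                                            (10, (4, 3, 3)), (11, (4, 4, 3)),
                                            (3, (1, 1, 1))])
    def test_sizes_with_remainder_to_earliest(self, n, expected):
        split = region_split(0, n - 1)
        assert tuple(len(r) for r in split.regions) == expected
        covered = [z for r in split.regions for z in r]
        assert covered == list(range(n))

    def test_fewer_than_three_slices_rejected(self):
        with pytest.raises(ValueError):
            region_split(5, 6)


class TestRelativeArea:
    def test_identity_gives_unit_ratios(self):
        arr = np.zeros((9, 8, 8), np.uint8)
        arr[2:7, 2:6, 2:6] = 1
        m = BinaryMask(arr, (3.0, 0.59, 0.59))
        split = region_split(0, 8)
        assert relative_area_by_region(m, m, split) == (1.0, 1.0, 1.0)

    def test_outer_dilation_raises_outer_ratios_only(self):
        ref = np.zeros((9, 12, 12), np.uint8)
        ref[0:9, 4:8, 4:8] = 1
        var = ref.copy()
        var[0:3, 3:9, 3:9] = 1  # dilate base third
        var[6:9, 3:9, 3:9] = 1  # dilate apex third
        split = region_split(0, 8)
        ratios = relative_area_by_region(
            BinaryMask(var, (3.0, 1.0, 1.0)), BinaryMask(ref, (3.0, 1.0, 1.0)),
            split)
        assert ratios[0] > 1 and ratios[2] > 1
        assert ratios[1] == pytest.approx(1.0)

    def test_empty_reference_region_is_nan(self):
        ref = np.zeros((9, 8, 8), np.uint8)
        ref[0:3, 2:6, 2:6] = 1  # only the first third
        var = ref.copy()
        split = region_split(0, 8)
        ratios = relative_area_by_region(
            BinaryMask(var, (1, 1, 1)), BinaryMask(ref, (1, 1, 1)), split)
        assert ratios[0] == 1.0
        assert np.isnan(ratios[1]) and np.isnan(ratios[2])
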