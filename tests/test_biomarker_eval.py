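"""Survival, association, IHC and ROC statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats
from sklearn.metrics import roc_auc_score

from _oracles import (
    auc_oracle,
    fisher_oracle,
    km_oracle,
    logrank_oracle,
    youden_scan_oracle,
)
from stromamark import biomarker_eval as bm


class TestKmCurve:
    def test_all_censored_curve_stays_at_one(self):
        curve = bm.km_curve([3, 5, 8], [0, 0, 0])
        assert curve.empty
        assert bm.km_survival_at(curve, 100) == 1.0

    def test_three_events_closed_form(self):
        curve = bm.km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve["survival"], [2 / 3, 1 / 3, 0.0])

    def test_record_order_invariance(self, random_survival_factory):
        t, e = random_survival_factory(15)
        perm = np.random.default_rng(0).permutation(len(t))
        pd.testing.assert_frame_equal(bm.km_curve(t, e), bm.km_curve(t[perm], e[perm]))

    def test_non_increasing_and_no_censoring_equals_empirical(self, rng):
        t = rng.integers(1, 10, size=20).astype(float)
        curve = bm.km_curve(t, np.ones(20))
        assert (np.diff(curve["survival"]) <= 1e-12).all()
        for tt in np.unique(t):
            assert bm.km_survival_at(curve, tt) == pytest.approx(np.mean(t > tt))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_product_limit_oracle(self, trial, random_survival_factory):
        t, e = random_survival_factory(np.random.default_rng(trial).integers(5, 25))
        curve = bm.km_curve(t, e)
        for time, s in km_oracle(t, e).items():
            assert bm.km_survival_at(curve, time) == pytest.approx(s)

    def test_matches_lifelines(self, random_survival_factory):
        t, e = random_survival_factory(30)
        kmf = KaplanMeierFitter().fit(t, e)
        curve = bm.km_curve(t, e)
        for time in np.unique(t):
            assert bm.km_survival_at(curve, time) == pytest.approx(
                float(kmf.predict(time))
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bm.km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 1]
        chi2, p, df = bm.logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_statistic_grows_with_separation(self):
        base = np.arange(1.0, 11.0)
        e = np.ones(10)
        chis = [
            bm.logrank_test((base, e), (base + shift, e))[0]
            for shift in (0.0, 5.0, 20.0)
        ]
        assert chis[0] < chis[1] < chis[2]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_event_table_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        t1 = np.round(rng.exponential(10, 12), 1) + 0.1
        t2 = np.round(rng.exponential(6, 10), 1) + 0.1
        e1 = rng.random(12) > 0.3
        e2 = rng.random(10) > 0.3
        if not (e1.any() or e2.any()):
            e1[0] = True
        chi2, _, _ = bm.logrank_test((t1, e1), (t2, e2))
        assert chi2 == pytest.approx(logrank_oracle(t1, e1, t2, e2))

    def test_matches_lifelines(self, random_survival_factory):
        t1, e1 = random_survival_factory(20)
        t2, e2 = random_survival_factory(18)
        chi2, p, _ = bm.logrank_test((t1, e1), (t2, e2))
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)

    def test_group_swap_symmetry(self, random_survival_factory):
        g1 = random_survival_factory(15)
        g2 = random_survival_factory(15)
        assert bm.logrank_test(g1, g2)[0] == pytest.approx(
            bm.logrank_test(g2, g1)[0]
        )

    def test_four_group_statistic_has_three_df(self, random_survival_factory):
        groups = [random_survival_factory(12) for _ in range(4)]
        chi2, p, df = bm.logrank_test(*groups)
        assert df == 3 and chi2 >= 0 and 0 <= p <= 1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            bm.logrank_test(([1.0, 2.0], [0, 0]), ([3.0], [0]))


class TestDichotomize:
    def test_even_split(self):
        labels = bm.dichotomize_by_median([1, 2, 3, 4])
        assert list(labels) == [bm.LOWER, bm.LOWER, bm.HIGHER, bm.HIGHER]

    def test_all_equal_warns_and_goes_lower(self):
        with pytest.warns(UserWarning, match="median"):
            labels = bm.dichotomize_by_median([5, 5, 5])
        assert set(labels) == {bm.LOWER}

    def test_group_size_gap_bounded_by_ties(self, rng):
        # with ties sent to the lower group, |low| - |high| = 2b + 2k - n for
        # b values below the median and k ties, so the gap is at most
        # 2k - 1 (and at most 1 when the median falls between two values)
        for _ in range(20):
            v = rng.integers(0, 6, size=int(rng.integers(4, 30))).astype(float)
            labels = bm.dichotomize_by_median(v)
            ties = int(np.sum(v == np.median(v)))
            gap = abs(int(np.sum(labels == bm.HIGHER)) - int(np.sum(labels == bm.LOWER)))
            assert gap <= max(1, 2 * ties - 1)


class TestIhcScore:
    def test_single_image_rule(self):
        sc = bm.ihc_score([5.0], [100.0])
        assert sc.intensity == pytest.approx(0.05)
        assert sc.positive

    def test_cutoff_is_strict(self):
        sc = bm.ihc_score([4.3], [100.0])
        assert sc.intensity == pytest.approx(0.043)
        assert not sc.positive

    def test_mean_of_per_image_ratios(self, rng):
        iod = rng.uniform(1, 100, 5)
        area = rng.uniform(10, 1000, 5)
        sc = bm.ihc_score(iod, area)
        assert sc.intensity == pytest.approx(np.mean(iod / area))

    def test_scale_consistency(self, rng):
        iod = rng.uniform(1, 100, 4)
        area = rng.uniform(10, 1000, 4)
        assert bm.ihc_score(iod, area).intensity == pytest.approx(
            bm.ihc_score(2 * iod, 2 * area).intensity
        )

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            bm.ihc_score([1.0], [0.0])


class TestFisher:
    def test_perfect_diagonal_table(self):
        assert bm.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_identical_rows_give_p1(self):
        assert bm.fisher_exact_2x2([[4, 6], [4, 6]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(900 + trial)
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum() == 0:
            table[0, 0] = 1
        p = bm.fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_oracle(table.tolist()))
        assert p == pytest.approx(stats.fisher_exact(table)[1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bm.fisher_exact_2x2([[0, 0], [0, 0]])


class TestAssociationRouting:
    def test_small_expected_counts_use_fisher(self):
        res = bm.association_test([[2, 1], [1, 3]])
        assert res["method"] == "fisher"

    def test_large_tables_use_chi2(self):
        res = bm.association_test([[30, 20], [25, 35]])
        assert res["method"] == "chi2"
        assert 0 <= res["p"] <= 1


class TestRoc:
    def test_perfect_separation(self):
        conc = [1, 2, 3, 10, 11, 12]
        case = [0, 0, 0, 1, 1, 1]
        curve = bm.roc_points(conc, case)
        assert ((curve["fpr"] == 0) & (curve["tpr"] == 1)).any()
        assert bm.auc(curve) == 1.0
        best = bm.optimal_cutoff(curve)
        assert best["cutoff"] == 10  # lowest case value
        assert best["sensitivity"] == 1.0 and best["specificity"] == 1.0

    def test_uninformative_labels_near_diagonal(self, rng):
        conc = rng.normal(50, 10, 2000)
        case = rng.random(2000) < 0.5
        assert bm.auc(bm.roc_points(conc, case)) == pytest.approx(0.5, abs=0.05)

    def test_flipped_orientation_warns(self):
        with pytest.warns(UserWarning, match="AUC < 0.5"):
            bm.roc_points([10, 9, 1, 2], [0, 0, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bm.roc_points([1, 2], [1, 1])

    @pytest.mark.parametrize("trial", range(20))
    def test_auc_matches_pairwise_oracle_and_sklearn(self, trial):
        rng = np.random.default_rng(700 + trial)
        n = int(rng.integers(6, 30))
        conc = np.round(rng.normal(50, 10, n), 1)  # rounding forces ties
        case = rng.random(n) < 0.5
        if case.all() or not case.any():
            case[0] = ~case[0]
        a = bm.auc(bm.roc_points(conc, case))
        assert a == pytest.approx(auc_oracle(conc, case))
        assert a == pytest.approx(roc_auc_score(case, conc))

    def test_auc_invariant_under_monotone_transform(self, rng):
        conc = rng.lognormal(3, 0.5, 60)
        case = rng.random(60) < 0.4
        if case.all() or not case.any():
            case[0] = ~case[0]
        a1 = bm.auc(bm.roc_points(conc, case))
        a2 = bm.auc(bm.roc_points(np.log(conc) ** 3 + 7, case))
        assert a1 == pytest.approx(a2)

    def test_label_flip_complements_auc(self, rng):
        conc = rng.normal(0, 1, 40)
        case = rng.random(40) < 0.5
        if case.all() or not case.any():
            case[0] = ~case[0]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a1 = bm.auc(bm.roc_points(conc, case))
            a2 = bm.auc(bm.roc_points(conc, ~case))
        assert a1 + a2 == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_cutoff_matches_exhaustive_scan(self, trial):
        rng = np.random.default_rng(800 + trial)
        conc = np.round(rng.normal(50, 12, 30), 0)
        case = rng.normal(0, 1, 30) + (conc - 50) / 12 > 0  # overlapping groups
        if case.all() or not case.any():
            case[0] = ~case[0]
        best = bm.optimal_cutoff(bm.roc_points(conc, case))
        ref = youden_scan_oracle(conc, case)
        assert best["cutoff"] == pytest.approx(ref["cutoff"])
        assert best["sensitivity"] == pytest.approx(ref["sensitivity"])
        assert best["specificity"] == pytest.approx(ref["specificity"])
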