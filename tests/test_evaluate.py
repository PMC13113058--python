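"""Statistics harness tests, including exact reproduction of the printed
cohort-table p-values and the published CI arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvlkit.evaluate import (CalibrationResult, aggregate_folds,
                             brier_and_calibration, chi2_yates_p,
                             cohort_table_tests, confusion_metrics,
                             decision_curve, delong_test, per_fold_metrics,
                             roc_auc, summarize_prediction_set)
from pvlkit.training import PredictionSet


def make_pred(y, p, fold=None, tag="X"):
    n = len(y)
    fold = np.zeros(n, dtype=int) if fold is None else np.asarray(fold)
    return PredictionSet([f"p{i}" for i in range(n)], np.asarray(y),
                         np.asarray(p, dtype=float), fold, tag)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_independent_scores_near_half(self, rng):
        y = (rng.uniform(size=20000) < 0.3).astype(int)
        s = rng.normal(size=20000)
        assert roc_auc(y, s) == pytest.approx(0.5, abs=0.02)

    def test_matches_pairwise_loop_oracle(self, rng):
        for _ in range(100):
            n = 30
            y = np.zeros(n, dtype=int)
            y[:int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            s = np.round(rng.uniform(size=n), 1)  # induce ties
            num, den = 0.0, 0
            for i in np.where(y == 1)[0]:
                for j in np.where(y == 0)[0]:
                    den += 1
                    if s[i] > s[j]:
                        num += 1.0
                    elif s[i] == s[j]:
                        num += 0.5
            assert roc_auc(y, s) == pytest.approx(num / den, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_all_negative_closed_form(self):
        y = np.array([1] * 2 + [0] * 8)
        m = confusion_metrics(y, np.zeros(10, dtype=int))
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["npv"] == pytest.approx(0.8)
        assert math.isnan(m["ppv"])  # undefined, never reported as 0

    def test_matches_hand_count(self, rng):
        y = (rng.uniform(size=50) < 0.4).astype(int)
        yhat = (rng.uniform(size=50) < 0.5).astype(int)
        tp = sum(1 for a, b in zip(y, yhat) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(y, yhat) if a == 0 and b == 1)
        tn = sum(1 for a, b in zip(y, yhat) if a == 0 and b == 0)
        fn = sum(1 for a, b in zip(y, yhat) if a == 1 and b == 0)
        m = confusion_metrics(y, yhat)
        assert m["accuracy"] == pytest.approx((tp + tn) / 50)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["ppv"] == pytest.approx(tp / (tp + fp))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0, 1, 1])


class TestAggregateFolds:
    def five_values(self, mean, sd):
        """Five numbers with exactly the requested mean and sample SD."""
        base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        base = base / base.std(ddof=1)
        return list(mean + sd * base)

    def test_t_convention_reproduces_published_row(self):
        # AUC 0.822 +/- 0.114 -> 95% CI 0.680-0.964 under t(4)*SD/sqrt(5)
        s = aggregate_folds(self.five_values(0.822, 0.114),
                            convention="t_sem")
        assert round(s.ci_low, 3) == 0.680
        assert round(s.ci_high, 3) == 0.964

    def test_normal_convention_reproduces_published_row(self):
        # AUC 0.694 +/- 0.050 -> 95% CI 0.596-0.792 under mean +/- 1.96*SD
        s = aggregate_folds(self.five_values(0.694, 0.050),
                            convention="normal_sd")
        assert round(s.ci_low, 3) == 0.596
        assert round(s.ci_high, 3) == 0.792

    def test_zero_sd_ci_is_point(self):
        s = aggregate_folds([0.7] * 5)
        assert s.ci_low == s.ci_high == pytest.approx(0.7)

    def test_truncation_to_unit_interval(self):
        s = aggregate_folds(self.five_values(0.97, 0.05),
                            convention="normal_sd")
        assert s.ci_high == 1.0

    def test_nan_folds_dropped(self):
        s = aggregate_folds([0.8, float("nan"), 0.9, 0.7, 0.8])
        assert s.mean == pytest.approx(0.8)

    def test_too_few_folds(self):
        with pytest.raises(ValueError):
            aggregate_folds([0.5])


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        y = np.array([0, 1] * 10)
        s = rng.uniform(size=20)
        res = delong_test(s, s, y)
        assert res["p_value"] == 1.0
        assert res["delta"] == 0.0

    def test_variance_matches_structural_loop(self, rng):
        """Direct O(n^2) recomputation of the DeLong variance, n=20."""
        y = np.array([1] * 8 + [0] * 12)
        a = rng.uniform(size=20)
        b = rng.uniform(size=20)
        res = delong_test(a, b, y)

        def components(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = np.array([np.mean([1.0 if x > yv else 0.5 if x == yv
                                     else 0.0 for yv in neg]) for x in pos])
            v01 = np.array([np.mean([1.0 if x > yv else 0.5 if x == yv
                                     else 0.0 for x in pos]) for yv in neg])
            return v10, v01

        va10, va01 = components(a)
        vb10, vb01 = components(b)
        m, n = 8, 12

        def cov(u, v):
            return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

        var = (cov(va10, va10) + cov(vb10, vb10) - 2 * cov(va10, vb10)) / m \
            + (cov(va01, va01) + cov(vb01, vb01) - 2 * cov(va01, vb01)) / n
        assert res["variance"] == pytest.approx(var, rel=1e-9)

    def test_agrees_with_paired_bootstrap(self, rng):
        n = 40
        y = np.array([1] * 15 + [0] * 25)
        signal = y + rng.normal(0, 1.2, size=n)
        a = signal + rng.normal(0, 0.7, size=n)
        b = rng.normal(size=n)
        res = delong_test(a, b, y)
        # paired bootstrap over patients, 20000 reps
        reps = 20000
        idx = rng.integers(0, n, size=(reps, n))
        deltas = []
        for r in range(reps):
            ii = idx[r]
            if len(np.unique(y[ii])) < 2:
                continue
            deltas.append(roc_auc(y[ii], a[ii]) - roc_auc(y[ii], b[ii]))
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1)
        z = res["delta"] / se
        p_boot = 2 * stats.norm.sf(abs(z))
        assert res["p_value"] == pytest.approx(p_boot, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])


class TestBrierCalibration:
    def test_prevalence_constant_predictor(self):
        # pi = 35/210 -> Brier pi(1-pi) = 0.1389 ~ 0.139
        y = np.array([1] * 35 + [0] * 175)
        pi = 35 / 210
        pred = make_pred(y, np.full(210, pi))
        cal = brier_and_calibration(pred)
        assert cal.brier == pytest.approx(pi * (1 - pi), abs=1e-12)
        assert round(cal.brier, 3) == 0.139

    def test_perfect_probabilities(self):
        y = np.array([0, 1, 0, 1])
        cal = brier_and_calibration(make_pred(y, y.astype(float)))
        assert cal.brier == 0.0

    def test_matches_loop_oracle(self, rng):
        y = (rng.uniform(size=100) < 0.3).astype(int)
        p = rng.uniform(size=100)
        cal = brier_and_calibration(make_pred(y, p))
        ref = sum((pi - yi) ** 2 for pi, yi in zip(p, y)) / 100
        assert cal.brier == pytest.approx(ref, abs=1e-12)

    def test_bins_partition_and_counts_sum(self, rng):
        y = (rng.uniform(size=57) < 0.3).astype(int)
        p = rng.uniform(size=57)
        cal = brier_and_calibration(make_pred(y, p), n_bins=10)
        assert cal.bin_counts.sum() == 57
        assert len(cal.bin_edges) == 11
        # empty bins reported with count 0 and NaN curve values
        for b in range(10):
            if cal.bin_counts[b] == 0:
                assert math.isnan(cal.bin_mean_predicted[b])


class TestDecisionCurve:
    def test_treat_all_closed_form(self, rng):
        y = (rng.uniform(size=200) < 0.2).astype(int)
        dc = decision_curve(make_pred(y, rng.uniform(size=200)))
        pi = y.mean()
        expected = pi - (1 - pi) * dc.thresholds / (1 - dc.thresholds)
        np.testing.assert_allclose(dc.net_benefit_all, expected, atol=1e-12)
        np.testing.assert_array_equal(dc.net_benefit_none, 0.0)

    def test_perfect_model_net_benefit_equals_prevalence(self):
        y = np.array([1] * 20 + [0] * 80)
        dc = decision_curve(make_pred(y, y.astype(float)))
        np.testing.assert_allclose(dc.net_benefit_model, 0.2, atol=1e-12)

    def test_hand_count_at_quarter_threshold(self, rng):
        y = (rng.uniform(size=60) < 0.3).astype(int)
        p = rng.uniform(size=60)
        dc = decision_curve(make_pred(y, p), thresholds=np.array([0.25]))
        tp = int(np.sum((p >= 0.25) & (y == 1)))
        fp = int(np.sum((p >= 0.25) & (y == 0)))
        assert dc.net_benefit_model[0] == pytest.approx(
            tp / 60 - fp / (3 * 60), abs=1e-12)

    def test_grid_contract(self):
        y = np.array([0, 1])
        with pytest.raises(ValueError):
            decision_curve(make_pred(y, [0.2, 0.8]),
                           thresholds=np.array([1.0]))


class TestCohortTableTests:
    def test_sex_row_reproduces_printed_p(self):
        # 27/36 male among events vs 201/366 among non-events -> p = 0.032
        assert round(chi2_yates_p([[27, 9], [201, 165]]), 3) == 0.032

    def test_hypertension_row(self):
        assert round(chi2_yates_p([[9, 27], [114, 252]]), 3) == 0.566

    def test_cad_row(self):
        assert round(chi2_yates_p([[6, 30], [89, 277]]), 3) == 0.409

    def test_fisher_balanced_table_p_one(self):
        df = pd.DataFrame({
            "y": [1] * 8 + [0] * 8,
            "trait": [1, 0] * 8,
        })
        res = cohort_table_tests(df, "y", [], ["trait"])
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert res.loc[0, "test"] == "fisher"  # expected counts 4 < 5

    def test_fisher_selected_for_small_expected_counts(self):
        df = pd.DataFrame({"y": [1] * 5 + [0] * 200,
                           "trait": [1, 0, 0, 0, 0] + [1] * 20 + [0] * 180})
        res = cohort_table_tests(df, "y", [], ["trait"])
        assert res.loc[0, "test"] == "fisher"

    def test_continuous_uses_ranksum(self, rng):
        df = pd.DataFrame({"y": [1] * 30 + [0] * 30,
                           "v": np.r_[rng.normal(2, 1, 30),
                                      rng.normal(0, 1, 30)]})
        res = cohort_table_tests(df, "y", ["v"], [])
        assert res.loc[0, "test"] == "wilcoxon_rank_sum"
        assert res.loc[0, "p_value"] < 1e-6

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"y": [0, 0], "v": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cohort_table_tests(df, "y", ["v"], [])


class TestSummarize:
    def test_per_fold_and_summary_shapes(self, rng):
        y = np.array(([1] * 3 + [0] * 17) * 5)
        fold = np.repeat(np.arange(5), 20)
        p = np.clip(y * 0.6 + rng.uniform(0, 0.4, size=100), 0, 1)
        pred = make_pred(y, p, fold)
        folds = per_fold_metrics(pred)
        assert len(folds["auc"]) == 5
        summary = summarize_prediction_set(pred)
        assert set(summary) == {"auc", "accuracy", "sensitivity",
                                "specificity", "ppv", "npv"}
        for s in summary.values():
            assert s.ci_low <= s.mean <= s.ci_high
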