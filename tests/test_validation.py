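"""Validation statistics against brute-force and hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wristmet.validation import (
    UndefinedMetricError,
    AucResult,
    binarize_by_category,
    bland_altman,
    compare_auc,
    confusion_metrics,
    error_metrics,
    evaluate,
    icc,
    roc_auc,
    spearman_corr,
)

# independent hand-computed ICC(2,1) fixture (6 paired measurements);
# value frozen from a direct mean-squares oracle computation
ICC_FIXTURE_TRUE = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
ICC_FIXTURE_EST = np.array([1.2, 1.9, 3.4, 3.9, 5.3, 5.9])
ICC_FIXTURE_VALUE = 0.9922630560928437


def brute_force_auc(truth, scores):
    """Pairwise concordance count with ties counted one half."""
    pos = scores[truth == 1][:, None]
    neg = scores[truth == 0][None, :]
    return ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size)


class TestBinarize:
    def test_threshold_definitions(self):
        mets = [1.0, 2.0, 4.0, 7.0]
        assert list(binarize_by_category(mets, "SED")) == [1, 0, 0, 0]
        assert list(binarize_by_category(mets, "MVPA")) == [0, 0, 1, 1]
        assert list(binarize_by_category(mets, "VPA")) == [0, 0, 0, 1]

    def test_unknown_category(self):
        with pytest.raises(ValueError):
            binarize_by_category([1.0], "LPA")


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        cm = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.sensitivity, cm.specificity, cm.youden) == (1.0, 1.0, 1.0)

    def test_counts_and_youden_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 2, 40)
            if len(np.unique(t)) < 2:
                continue
            p = rng.integers(0, 2, 40)
            cm = confusion_metrics(t, p)
            assert cm.youden == pytest.approx(cm.sensitivity + cm.specificity - 1)
            assert cm.tp + cm.fn + cm.tn + cm.fp == 40

    def test_wilson_ci_brackets_the_point_estimate(self):
        cm = confusion_metrics([1] * 30 + [0] * 30, [1] * 27 + [0] * 3 + [0] * 30)
        lo, hi = cm.sensitivity_ci
        assert lo < cm.sensitivity < hi and 0 <= lo and hi <= 1

    def test_single_class_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            confusion_metrics([1, 1, 1], [1, 0, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert res.auc == 1.0

    def test_all_ties_is_half(self):
        res = roc_auc([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert res.auc == 0.5

    def test_small_worked_example(self):
        # positives {3,1}, negatives {2,0}: 3 of 4 pairs concordant
        res = roc_auc([1, 1, 0, 0], [3.0, 1.0, 2.0, 0.0])
        assert res.auc == pytest.approx(0.75)

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(4, 200))
            truth = rng.integers(0, 2, n)
            if len(np.unique(truth)) < 2:
                continue
            scores = np.round(rng.normal(truth, 1.0), 1)  # induce ties
            res = roc_auc(truth, scores)
            assert res.auc == pytest.approx(brute_force_auc(truth, scores), abs=1e-12)
            assert res.ci[0] <= res.auc <= res.ci[1]

    def test_single_class_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0, 0], [1.0, 2.0])


class TestCompareAuc:
    def test_identical_results_give_p_one(self):
        a = AucResult(0.9, 0.001, (0.8, 1.0), 50, 50)
        z, p = compare_auc(a, a)
        assert (z, p) == (0.0, 1.0)

    def test_z_of_1_96_gives_p_05(self):
        a = AucResult(0.9, 0.5 * (0.1 / 1.959963984540054) ** 2, (0, 1), 50, 50)
        b = AucResult(0.8, a.variance, (0, 1), 50, 50)
        z, p = compare_auc(a, b)
        assert z == pytest.approx(1.959963984540054)
        assert p == pytest.approx(0.05, abs=1e-6)


class TestErrorMetrics:
    def test_exact_estimates_give_zero(self):
        em = error_metrics([1.0, 2.0], [1.0, 2.0])
        assert (em.mae, em.mape, em.rmse) == (0.0, 0.0, 0.0)

    def test_hand_computed_examples(self):
        em = error_metrics([2.0, 4.0], [3.0, 3.0])
        assert em.mae == pytest.approx(1.0)
        assert em.rmse == pytest.approx(1.0)
        assert em.mape == pytest.approx(37.5)
        em = error_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert em.mae == pytest.approx(2 / 3)
        assert em.rmse == pytest.approx(np.sqrt(2 / 3))

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.uniform(0.5, 10, 30)
            e = t + rng.normal(0, 1, 30)
            em = error_metrics(t, e)
            assert em.mae <= em.rmse + 1e-12

    def test_per_participant_summaries(self):
        em = error_metrics(
            [1.0, 1.0, 2.0, 2.0], [1.5, 1.5, 2.0, 2.0], ["a", "a", "b", "b"]
        )
        assert em.participant_mae_mean == pytest.approx(0.25)
        assert em.participant_mae_sd == pytest.approx(np.std([0.5, 0.0], ddof=1))

    def test_nonpositive_truth_is_domain_error(self):
        with pytest.raises(ValueError):
            error_metrics([0.0, 1.0], [1.0, 1.0])


class TestBlandAltman:
    def test_exact_agreement(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_computed_loa(self):
        # differences {-1, 0, 1}: bias 0, sample SD 1, LoA = ±1.96
        bias, lo, hi = bland_altman([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert bias == 0.0
        assert (lo, hi) == (pytest.approx(-1.96), pytest.approx(1.96))

    @given(
        st.lists(
            st.tuples(
                st.floats(0.5, 12, allow_nan=False), st.floats(0.5, 12, allow_nan=False)
            ),
            min_size=2,
            max_size=60,
        )
    )
    def test_midpoint_is_bias_and_width_identity(self, pairs):
        t = np.array([p[0] for p in pairs])
        e = np.array([p[1] for p in pairs])
        bias, lo, hi = bland_altman(t, e)
        assert (lo + hi) / 2 == pytest.approx(bias, abs=1e-9)
        assert hi - lo == pytest.approx(2 * 1.96 * np.std(e - t, ddof=1), abs=1e-9)


class TestIcc:
    def test_perfect_agreement(self):
        assert icc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_six_pair_fixture_matches_variance_components_oracle(self):
        assert icc(ICC_FIXTURE_TRUE, ICC_FIXTURE_EST) == pytest.approx(
            ICC_FIXTURE_VALUE, abs=1e-10
        )

    def test_matches_pingouin_two_way_absolute_single(self):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(
            {
                "targets": list(range(6)) * 2,
                "raters": ["t"] * 6 + ["e"] * 6,
                "scores": list(ICC_FIXTURE_TRUE) + list(ICC_FIXTURE_EST),
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "scores")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(ICC_FIXTURE_TRUE, ICC_FIXTURE_EST) == pytest.approx(ref_icc, abs=1e-9)

    def test_constant_shift_reduces_absolute_agreement(self):
        t = np.linspace(1, 8, 30)
        vals = [icc(t, t + c) for c in (0.0, 0.5, 1.5)]
        assert vals[0] == pytest.approx(1.0)
        assert vals[0] > vals[1] > vals[2]

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc([2.0, 2.0], [2.0, 2.0])


class TestSpearman:
    def test_monotone_directions(self):
        t = np.linspace(1, 5, 20)
        assert spearman_corr(t, np.exp(t))[0] == pytest.approx(1.0)
        assert spearman_corr(t, -(t**3))[0] == pytest.approx(-1.0)

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(1, 9, 50)
        e = t + rng.normal(0, 1, 50)
        rho_raw, _ = spearman_corr(t, e)
        rho_log, _ = spearman_corr(t, np.log(e - e.min() + 1.0))
        assert rho_raw == pytest.approx(rho_log, abs=1e-12)

    def test_constant_input_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEvaluate:
    def test_report_shape_and_minute_count(self, adult_study, trained_adult):
        report = evaluate(
            trained_adult, adult_study.test_minutes(), adult_study.participants
        )
        assert report.n_minutes == len(adult_study.test_minutes())
        assert set(report.classification) == {"SED", "MVPA", "VPA"}
        a = report.agreement
        assert (a.loa_low + a.loa_high) / 2 == pytest.approx(a.bias, abs=1e-9)
        assert a.mae <= a.rmse + 1e-12

    def test_leakage_is_an_error(self, adult_study, trained_adult):
        from wristmet.validation import LeakageError

        with pytest.raises(LeakageError):
            evaluate(
                trained_adult, adult_study.train_minutes(), adult_study.participants
            )

    def test_shuffled_estimates_give_chance_auc(self, adult_study, trained_adult):
        """Breaking the truth-estimate pairing must drive AUC to ~0.5."""
        from wristmet.met_model import build_design

        X, true_mets, _ = build_design(
            adult_study.test_minutes(), adult_study.participants
        )
        _, est = trained_adult.predict_batch(X)
        rng = np.random.default_rng(17)
        aucs = []
        for _ in range(30):
            shuffled = rng.permutation(est)
            truth = binarize_by_category(true_mets, "MVPA")
            aucs.append(roc_auc(truth, shuffled).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_report_json_round_trip_is_stable(self, adult_study, trained_adult):
        report = evaluate(
            trained_adult, adult_study.test_minutes(), adult_study.participants
        )
        assert report.to_json() == report.to_json()
        assert "Youden" in report.to_text()
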