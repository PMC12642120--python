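"""Nested-LOOCV machinery: leakage, CIs, metric identities, determinism."""

import numpy as np
import pandas as pd
import pytest

from povmark.datamodel import FEATURES, FeatureMatrix
from povmark.ml import (
    averaged_importance,
    fold_preprocess,
    hanley_mcneil_auc_ci,
    light_config,
    metrics_from_counts,
    nested_loocv,
    pooled_metrics,
    stratified_bootstrap_f1_ci,
    wilson_ci,
)


def noise_matrix(rng, n1=10, n2=10, d=0.0, feature="center_gaze_s"):
    data = {}
    for f in FEATURES:
        shift = d if f == feature else 0.0
        data[f] = np.concatenate([rng.normal(shift, 1, n1), rng.normal(0, 1, n2)])
    ids = [f"p{i}" for i in range(n1 + n2)]
    df = pd.DataFrame(data, index=ids)[list(FEATURES)]
    labels = pd.Series(["MDD"] * n1 + ["HC"] * n2, index=ids)
    return FeatureMatrix(data=df, labels=labels)


class TestWilsonCI:
    def test_printed_sensitivity_interval(self):
        lo, hi = wilson_ci(40 / 44, 85)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (82.9, 95.4)

    def test_printed_specificity_interval(self):
        lo, hi = wilson_ci(32 / 41, 85)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (68.1, 85.5)

    def test_zero_proportion_lower_bound(self):
        lo, _ = wilson_ci(0.0, 20)
        assert lo == 0.0

    def test_direct_formula_value(self):
        lo, hi = wilson_ci(0.5, 100)
        assert lo == pytest.approx(0.4038, abs=2e-4)
        assert hi == pytest.approx(0.5962, abs=2e-4)

    def test_matches_statsmodels_on_integer_counts(self):
        from statsmodels.stats.proportion import proportion_confint

        for count, n in [(40, 44), (32, 41), (72, 85), (1, 10), (9, 10)]:
            lo, hi = wilson_ci(count / n, n)
            ref_lo, ref_hi = proportion_confint(count, n, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_strict_interval_contains_point_and_shrinks(self):
        for p in (0.2, 0.5, 0.9):
            lo44, hi44 = wilson_ci(p, 44)
            lo440, hi440 = wilson_ci(p, 440)
            assert lo44 <= p <= hi44
            assert (hi440 - lo440) < (hi44 - lo44)


class TestHanleyMcNeil:
    def test_printed_auc_interval(self):
        lo, hi, se = hanley_mcneil_auc_ci(0.89, 44, 41)
        assert se == pytest.approx(0.0362, abs=2e-4)
        assert (round(lo, 2), round(hi, 2)) == (0.82, 0.96)

    def test_perfect_auc_degenerate(self):
        lo, hi, se = hanley_mcneil_auc_ci(1.0, 44, 41)
        assert se == 0.0 and (lo, hi) == (1.0, 1.0)

    def test_reflection_below_half(self):
        lo1, hi1, se1 = hanley_mcneil_auc_ci(0.89, 44, 41)
        _, _, se2 = hanley_mcneil_auc_ci(0.11, 44, 41)
        assert se2 == pytest.approx(se1)


class TestPooledMetrics:
    def _preds(self, tp=40, fn=4, tn=32, fp=9):
        y_true = [1] * (tp + fn) + [0] * (tn + fp)
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        rng = np.random.default_rng(0)
        proba = np.clip(
            np.array(y_pred) * 0.6 + 0.2 + rng.normal(0, 0.05, len(y_pred)), 0, 1
        )
        return pd.DataFrame(
            {
                "y_true": y_true,
                "y_pred": y_pred,
                "proba_mdd": proba,
            },
            index=[f"p{i}" for i in range(len(y_true))],
        )

    def test_printed_confusion_metrics(self):
        rep = pooled_metrics(self._preds(), bootstrap_B=200)
        assert rep["accuracy"]["value"] == pytest.approx(72 / 85)
        assert rep["precision"]["value"] == pytest.approx(40 / 49)
        assert rep["sensitivity"]["value"] == pytest.approx(40 / 44)
        assert rep["specificity"]["value"] == pytest.approx(32 / 41)
        assert rep["f1"]["value"] == pytest.approx(80 / 93)

    def test_metric_identities_two_routes(self):
        c = {"tp": 40, "fn": 4, "tn": 32, "fp": 9}
        m = metrics_from_counts(c)
        n = sum(c.values())
        assert m["accuracy"] == (c["tp"] + c["tn"]) / n
        assert m["f1"] == pytest.approx(2 * c["tp"] / (2 * c["tp"] + c["fp"] + c["fn"]))
        prec, rec = m["precision"], m["sensitivity"]
        assert m["f1"] == pytest.approx(2 * prec * rec / (prec + rec))

    def test_perfect_predictions_degenerate(self):
        preds = self._preds(tp=44, fn=0, tn=41, fp=0)
        preds["proba_mdd"] = preds["y_true"].astype(float)
        rep = pooled_metrics(preds, bootstrap_B=100)
        for metric in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
            assert rep[metric]["value"] == 1.0
        assert rep["f1"]["ci"] == (1.0, 1.0)
        assert rep["roc_auc"]["value"] == 1.0

    def test_strict_mode_uses_own_denominators(self):
        rep_r = pooled_metrics(self._preds(), bootstrap_B=50, wilson_mode="replicate")
        rep_s = pooled_metrics(self._preds(), bootstrap_B=50, wilson_mode="strict")
        # sensitivity at n=44 (strict) is wider than at n=85 (replicate)
        w_r = rep_r["sensitivity"]["ci"][1] - rep_r["sensitivity"]["ci"][0]
        w_s = rep_s["sensitivity"]["ci"][1] - rep_s["sensitivity"]["ci"][0]
        assert w_s > w_r

    def test_f1_bootstrap_brackets_point(self):
        preds = self._preds()
        lo, hi = stratified_bootstrap_f1_ci(
            preds["y_true"].to_numpy(), preds["y_pred"].to_numpy(), B=500, seed=1
        )
        assert lo <= 80 / 93 <= hi


class TestFoldPreprocess:
    def test_median_fill_applied_to_test_row(self):
        train = pd.DataFrame({"silence_ratio": [0.1, 0.21, 0.4], "x": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"silence_ratio": [np.nan], "x": [np.nan]})
        tr, te, medians, dropped = fold_preprocess(train, test)
        assert te.loc[0, "silence_ratio"] == pytest.approx(0.21)
        assert te.loc[0, "x"] == pytest.approx(2.0)
        assert medians["silence_ratio"] == pytest.approx(0.21)
        assert dropped == ()

    def test_no_missing_is_identity(self, rng):
        train = pd.DataFrame(rng.random((5, 3)), columns=list("abc"))
        test = pd.DataFrame(rng.random((1, 3)), columns=list("abc"))
        tr, te, _, _ = fold_preprocess(train, test)
        pd.testing.assert_frame_equal(tr, train)
        pd.testing.assert_frame_equal(te, test)

    def test_leakage_sentinel_detects_test_row_in_train(self):
        # duplicating an extreme test row into training shifts the fitted
        # median -> the audit can detect leakage
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        test = pd.DataFrame({"a": [100.0]})
        _, _, clean, _ = fold_preprocess(train, test)
        _, _, leaked, _ = fold_preprocess(
            pd.concat([train, test], ignore_index=True), test
        )
        assert leaked["a"] != clean["a"]

    def test_feature_all_missing_in_train_dropped(self):
        train = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        test = pd.DataFrame({"a": [5.0], "b": [np.nan]})
        tr, te, medians, dropped = fold_preprocess(train, test)
        assert dropped == ("a",)
        assert list(tr.columns) == ["b"]


class TestNestedLOOCV:
    def test_one_prediction_per_participant(self, rng):
        m = noise_matrix(rng, 6, 6)
        preds, artifacts = nested_loocv(m, config=light_config(), seed=3)
        assert len(preds) == 12
        assert list(preds.index) == list(m.data.index)
        assert preds["proba_mdd"].between(0, 1).all()
        assert len(artifacts) == 12

    def test_seed_determinism(self, rng):
        m = noise_matrix(rng, 6, 6)
        p1, _ = nested_loocv(m, config=light_config(), seed=9)
        p2, _ = nested_loocv(m, config=light_config(), seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_fold_artifacts_fitted_from_train_rows_only(self, rng):
        m = noise_matrix(rng, 5, 5)
        m.data.iloc[0, 2] = np.nan
        preds, artifacts = nested_loocv(m, config=light_config(), seed=4)
        for i, art in enumerate(artifacts):
            train = m.data.drop(index=m.data.index[i])
            test = m.data.iloc[[i]]
            _, _, medians, dropped = fold_preprocess(train, test)
            assert art.imputer_medians == medians
            assert art.dropped_features == dropped

    def test_strong_signal_recovered(self, rng):
        # d = 3 leaves an irreducible ~6.7% error per held-out draw, so a
        # small run can only support a loose accuracy bound; the tight
        # accuracy check lives in the acceptance suite at a larger n.
        from povmark.ml import CVConfig

        config = CVConfig(
            inner_folds=3,
            rfe_sizes=(3, 15),  # small subsets keep noise dims from diluting
            grids={"extra_trees": [{"n_estimators": 20, "max_depth": 5}]},
            calibration=("platt",),
            ranker_params={"n_estimators": 5, "max_depth": 3},
        )
        m = noise_matrix(rng, 15, 15, d=3.0)
        preds, artifacts = nested_loocv(m, config=config, seed=5)
        acc = (preds["y_true"] == preds["y_pred"]).mean()
        # at n=30 the pooled accuracy has SD ~ 0.09; assert clearly above
        # chance rather than a bound the Monte-Carlo noise could cross
        assert acc >= 0.65
        freq = np.mean(["center_gaze_s" in a.selected_features for a in artifacts])
        assert freq >= 0.9

    def test_too_small_class_raises(self, rng):
        m = noise_matrix(rng, 1, 10)
        with pytest.raises(ValueError, match="2 participants"):
            nested_loocv(m, config=light_config())


class TestAveragedImportance:
    def test_scores_sum_to_one(self, rng):
        m = noise_matrix(rng, 8, 8)
        imp = averaged_importance(m, seed=0, params={"n_estimators": 30})
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()

    def test_informative_feature_ranks_first(self, rng):
        m = noise_matrix(rng, 25, 25, d=3.0)
        imp = averaged_importance(m, seed=0, params={"n_estimators": 50})
        assert imp.idxmax() == "center_gaze_s"

    def test_duplicated_feature_splits_importance(self, rng):
        m = noise_matrix(rng, 30, 30, d=3.0)
        single = averaged_importance(
            m, learners=("extra_trees",), seed=0, params={"n_estimators": 200}
        )["center_gaze_s"]
        m2 = noise_matrix(rng, 30, 30, d=0.0)
        m2.data[:] = m.data.values
        m2.data["right_gaze_s"] = m.data["center_gaze_s"]  # identical copy
        dup = averaged_importance(
            m2, learners=("extra_trees",), seed=0, params={"n_estimators": 200}
        )
        # the informative mass is shared ~evenly between the copies, so each
        # copy scores clearly below the single-copy importance
        assert dup["center_gaze_s"] < single
        assert dup["right_gaze_s"] < single
        ratio = dup["center_gaze_s"] / dup["right_gaze_s"]
        assert 1 / 3 < ratio < 3

    def test_non_tree_registry_rejected(self, rng):
        m = noise_matrix(rng, 5, 5)
        with pytest.raises(ValueError, match="importances"):
            averaged_importance(m, learners=("knn", "svm"))
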