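"""Logistic wettedness classifier: training, prediction, grouped CV,
voltage generalization, subset search, and leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from porenoise.classify import (
    DEFAULT_HYPERPARAMS,
    ClassifierModel,
    cross_validate,
    evaluate_split,
    exhaustive_feature_search,
    leave_one_voltage_out,
    metrics_from_confusion,
    predict_wettedness,
    stratified_group_kfold,
    train_logistic,
)


def gaussian_features(rng, n_pos=40, n_neg=200, sep=6.0, n_groups=20, n_noise=0):
    """Separable two-class table with group structure and optional pure-noise
    feature columns."""
    n = n_pos + n_neg
    y = np.array(["unwetted"] * n_pos + ["wetted"] * n_neg)
    x1 = np.concatenate([rng.normal(sep, 1, n_pos), rng.normal(0, 1, n_neg)])
    x2 = np.concatenate([rng.normal(-sep, 1, n_pos), rng.normal(0, 1, n_neg)])
    frame = pd.DataFrame({"x1": x1, "x2": x2})
    for j in range(n_noise):
        frame[f"noise{j}"] = rng.normal(size=n)
    # groups assigned within class so each group is single-class, like pores
    frame["label"] = y
    groups = np.empty(n, dtype=object)
    groups[:n_pos] = [f"u{g % (n_groups // 4)}" for g in range(n_pos)]
    groups[n_pos:] = [f"w{g % (3 * n_groups // 4)}" for g in range(n_neg)]
    frame["group_id"] = groups
    frame["V"] = rng.choice([50.0, 100.0, 150.0, 200.0, 250.0, 300.0], size=n)
    return frame


class TestTrainAndPredict:
    def test_zero_weights_give_half_probability(self):
        model = ClassifierModel(
            feature_subset=("x",), scaling_mean=np.zeros(1), scaling_sd=np.ones(1),
            weights=np.zeros(1), intercept=0.0,
        )
        prob, calls = predict_wettedness(model, pd.DataFrame({"x": [-3.0, 0.0, 42.0]}))
        np.testing.assert_allclose(prob, 0.5)
        assert set(calls) == {"unwetted"}  # threshold is inclusive

    def test_separable_1d_training(self, rng):
        frame = gaussian_features(rng)
        model = train_logistic(frame, frame["label"], ("x1",))
        prob, calls = predict_wettedness(model, frame)
        assert np.mean(calls == frame["label"].to_numpy()) == 1.0
        order = np.argsort(frame["x1"].to_numpy())
        assert np.all(np.diff(prob[order]) >= 0)  # monotone in the feature
        assert np.all((prob > 0) & (prob < 1))

    def test_coefficients_match_brute_force_penalized_likelihood(self, rng):
        """sklearn's newton-cholesky solution equals direct numerical
        minimization of 0.5 ||w||^2 + C sum log(1+exp(-t eta)) within 1e-6."""
        frame = gaussian_features(rng, n_pos=30, n_neg=60, sep=1.5)
        subset = ("x1", "x2")
        model = train_logistic(frame, frame["label"], subset)
        X = frame.loc[:, list(subset)].to_numpy()
        z = (X - model.scaling_mean) / model.scaling_sd
        t = np.where(frame["label"].to_numpy() == "unwetted", 1.0, -1.0)
        C = DEFAULT_HYPERPARAMS["C"]

        def objective(params):
            w, b = params[:2], params[2]
            eta = z @ w + b
            return 0.5 * w @ w + C * np.sum(np.logaddexp(0.0, -t * eta))

        res = minimize(objective, np.zeros(3), method="BFGS", tol=1e-14)
        np.testing.assert_allclose(model.weights, res.x[:2], atol=1e-6)
        assert model.intercept == pytest.approx(res.x[2], abs=1e-6)

    def test_hand_computed_logit(self):
        model = ClassifierModel(
            feature_subset=("u", "v"), scaling_mean=np.array([1.0, -2.0]),
            scaling_sd=np.array([2.0, 4.0]), weights=np.array([0.5, -1.5]),
            intercept=0.25,
        )
        frame = pd.DataFrame({"u": [3.0], "v": [2.0]})
        prob, _ = predict_wettedness(model, frame)
        logit = 0.25 + 0.5 * (3 - 1) / 2 - 1.5 * (2 + 2) / 4
        assert prob[0] == pytest.approx(1 / (1 + np.exp(-logit)), rel=1e-12)

    def test_training_input_errors(self, rng):
        frame = gaussian_features(rng)
        with pytest.raises(ValueError, match="both classes"):
            train_logistic(frame, ["wetted"] * len(frame), ("x1",))
        frame.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_logistic(frame, frame["label"], ("x1",))

    def test_missing_feature_rejected_at_prediction(self, rng):
        frame = gaussian_features(rng)
        model = train_logistic(frame, frame["label"], ("x1", "x2"))
        with pytest.raises(ValueError, match="lacks"):
            predict_wettedness(model, frame[["x1"]])


class TestMetrics:
    def test_contingency_arithmetic(self):
        m = metrics_from_confusion(tp=9, fp=1, fn=0, tn=90)
        assert m["precision"] == pytest.approx(90.0)
        assert m["recall"] == pytest.approx(100.0)
        assert m["f1"] == pytest.approx(2 * 90 * 100 / 190)
        assert m["specificity"] == pytest.approx(100 * 90 / 91)
        assert m["accuracy"] == pytest.approx(99.0)

    def test_zero_denominators_are_nan_markers(self):
        m = metrics_from_confusion(tp=0, fp=0, fn=0, tn=10)
        assert np.isnan(m["precision"]) and np.isnan(m["recall"]) and np.isnan(m["f1"])
        assert m["specificity"] == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=200)
    @given(counts=st.tuples(*[st.integers(min_value=0, max_value=500)] * 4))
    def test_metric_ranges_and_f1_harmonic_mean(self, counts):
        """For any confusion table: defined metrics lie in [0, 100] and F1
        is the harmonic mean of precision and recall."""
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        m = metrics_from_confusion(tp, fp, fn, tn)
        for name in ("accuracy", "precision", "recall", "specificity", "f1"):
            v = m[name]
            assert np.isnan(v) or 0.0 <= v <= 100.0
        if np.isfinite(m["precision"]) and np.isfinite(m["recall"]) \
                and m["precision"] + m["recall"] > 0:
            expected = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(expected)


class TestStratifiedGroupKfold:
    def test_groups_never_straddle_folds(self, rng):
        frame = gaussian_features(rng)
        folds = stratified_group_kfold(frame["label"], frame["group_id"], k=5, seed=1)
        table = pd.DataFrame({"g": frame["group_id"], "f": folds})
        assert (table.groupby("g")["f"].nunique() == 1).all()
        assert set(folds) == set(range(5))

    def test_k_equal_to_group_count_is_leave_one_group_out(self, rng):
        frame = gaussian_features(rng)
        n_groups = frame["group_id"].nunique()
        folds = stratified_group_kfold(frame["label"], frame["group_id"], k=n_groups, seed=0)
        table = pd.DataFrame({"g": frame["group_id"], "f": folds})
        assert table.groupby("f")["g"].nunique().max() == 1

    def test_fold_class_balance_near_global(self, rng):
        frame = gaussian_features(rng, n_pos=60, n_neg=240, n_groups=40)
        y = (frame["label"] == "unwetted").to_numpy()
        folds = stratified_group_kfold(frame["label"], frame["group_id"], k=5, seed=3)
        global_frac = y.mean()
        for f in range(5):
            frac = y[folds == f].mean()
            assert abs(frac - global_frac) <= 0.5 * global_frac

    def test_determinism_and_too_few_groups(self, rng):
        frame = gaussian_features(rng)
        f1 = stratified_group_kfold(frame["label"], frame["group_id"], k=5, seed=7)
        f2 = stratified_group_kfold(frame["label"], frame["group_id"], k=5, seed=7)
        np.testing.assert_array_equal(f1, f2)
        with pytest.raises(ValueError, match="groups"):
            stratified_group_kfold(["wetted", "unwetted"], ["g1", "g1"], k=10)


class TestCrossValidate:
    def test_separable_archetypes_reach_perfect_median_f1(self, rng):
        frame = gaussian_features(rng)
        report = cross_validate(frame, frame["label"], frame["group_id"],
                                ("x1", "x2"), k=5, seed=0)
        agg = report.aggregate()
        assert agg.loc["f1", "median"] == pytest.approx(100.0)

    def test_label_permutation_destroys_performance(self, rng):
        """With labels shuffled at the group level the median F1 collapses
        toward the prevalence baseline."""
        frame = gaussian_features(rng, n_pos=80, n_neg=160, n_groups=48, sep=8.0)
        true_report = cross_validate(frame, frame["label"], frame["group_id"],
                                     ("x1", "x2"), k=6, seed=0)
        groups = frame["group_id"].unique()
        flip = dict(zip(groups, rng.permutation(
            [l for g, l in frame.groupby("group_id")["label"].first().items()])))
        shuffled = frame["group_id"].map(flip)
        null_report = cross_validate(frame, shuffled, frame["group_id"],
                                     ("x1", "x2"), k=6, seed=0)
        assert true_report.aggregate().loc["f1", "median"] == pytest.approx(100.0)
        null_f1 = null_report.aggregate().loc["f1", "median"]
        # an all-NaN median means no fold produced a defined F1 at all
        assert np.isnan(null_f1) or null_f1 < 70.0

    def test_imbalanced_separable_data_keeps_high_unwetted_recall(self, rng):
        """At 10:1 imbalance no rebalancing is needed: recall for the rare
        unwetted class stays above 95%."""
        frame = gaussian_features(rng, n_pos=30, n_neg=300, n_groups=40)
        report = cross_validate(frame, frame["label"], frame["group_id"],
                                ("x1", "x2"), k=5, seed=0)
        assert report.aggregate().loc["recall", "median"] > 95.0

    def test_determinism(self, rng):
        frame = gaussian_features(rng)
        r1 = cross_validate(frame, frame["label"], frame["group_id"], ("x1",), k=5, seed=4)
        r2 = cross_validate(frame, frame["label"], frame["group_id"], ("x1",), k=5, seed=4)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_scaling_fitted_on_training_folds_only(self, rng):
        """Corrupting test-fold feature values never changes the
        training-time standardization of that fold's model."""
        frame = gaussian_features(rng)
        folds = stratified_group_kfold(frame["label"], frame["group_id"], k=5, seed=2)
        base = cross_validate(frame, frame["label"], frame["group_id"], ("x1", "x2"),
                              folds=folds, keep_models=True)
        corrupted = frame.copy()
        corrupted.loc[folds == 0, ["x1", "x2"]] = 1e6  # poison fold 0's test rows
        poisoned = cross_validate(corrupted, corrupted["label"], corrupted["group_id"],
                                  ("x1", "x2"), folds=folds, keep_models=True)
        np.testing.assert_array_equal(base.models[0].scaling_mean,
                                      poisoned.models[0].scaling_mean)
        np.testing.assert_array_equal(base.models[0].scaling_sd,
                                      poisoned.models[0].scaling_sd)


class TestLeaveOneVoltageOut:
    def test_one_report_per_voltage(self, rng):
        frame = gaussian_features(rng)
        reports = leave_one_voltage_out(frame, frame["label"], frame["group_id"],
                                        ("x1", "x2"))
        assert set(reports) == {50.0, 100.0, 150.0, 200.0, 250.0, 300.0}

    def test_training_excludes_held_out_voltage(self, rng):
        """A poisoned held-out voltage cannot leak into training-time
        standardization."""
        frame = gaussian_features(rng)
        base = leave_one_voltage_out(frame, frame["label"], frame["group_id"], ("x1",))
        poisoned_frame = frame.copy()
        poisoned_frame.loc[poisoned_frame["V"] == 150.0, "x1"] = 1e6
        poisoned = leave_one_voltage_out(poisoned_frame, poisoned_frame["label"],
                                         poisoned_frame["group_id"], ("x1",))
        np.testing.assert_array_equal(base[150.0].models[0].scaling_mean,
                                      poisoned[150.0].models[0].scaling_mean)

    def test_single_class_voltage_yields_nan_markers(self, rng):
        frame = gaussian_features(rng)
        frame = frame[(frame["V"] != 50.0) | (frame["label"] == "wetted")].reset_index(drop=True)
        reports = leave_one_voltage_out(frame, frame["label"], frame["group_id"],
                                        ("x1", "x2"))
        row = reports[50.0].per_fold.iloc[0]
        assert np.isnan(row["recall"]) or row["tp"] + row["fn"] > 0


class TestExhaustiveSearch:
    def test_subset_count_is_two_to_n_minus_one(self, rng):
        frame = gaussian_features(rng, n_noise=1)
        table = exhaustive_feature_search(frame, frame["label"], frame["group_id"],
                                          ("x1", "x2"), k=5, seed=0)
        assert len(table) == 3
        table3 = exhaustive_feature_search(frame, frame["label"], frame["group_id"],
                                           ("x1", "x2", "noise0"), k=5, seed=0)
        assert len(table3) == 7

    def test_signal_features_rank_top_and_noise_does_not_help(self, rng):
        """Signal is carried jointly by (x1, x2): each marginal overlaps,
        their sum separates perfectly, and pure-noise features cannot
        improve the top subset."""
        n_pos, n_neg = 60, 120
        y = np.array([1] * n_pos + [0] * n_neg)
        shared = rng.normal(0, 2.0, y.size)
        delta = 3.0
        frame = pd.DataFrame(
            {
                "x1": shared + delta * y + rng.normal(0, 1, y.size),
                "x2": -shared + delta * y + rng.normal(0, 1, y.size),
                "noise0": rng.normal(size=y.size),
                "noise1": rng.normal(size=y.size),
                "label": np.where(y == 1, "unwetted", "wetted"),
                "group_id": [f"g{i % 36}_{c}" for i, c in enumerate(y)],
            }
        )
        table = exhaustive_feature_search(
            frame, frame["label"], frame["group_id"],
            ("x1", "x2", "noise0", "noise1"), k=6, seed=0,
        )
        top = table.iloc[0]
        assert {"x1", "x2"} <= set(top["subset"])
        assert not any(f.startswith("noise") for f in top["subset"])
        best_signal = table[table["subset"].map(lambda s: set(s) == {"x1", "x2"})]
        noisy = table[table["subset"].map(lambda s: any(f.startswith("noise") for f in s))]
        # NaN medians (no fold with a defined F1) trivially do not improve
        assert (noisy["median_f1"].dropna() <= best_signal["median_f1"].iloc[0] + 1e-9).all()

    def test_ties_break_toward_fewer_features(self, rng):
        frame = gaussian_features(rng, sep=10.0, n_noise=1)
        table = exhaustive_feature_search(frame, frame["label"], frame["group_id"],
                                          ("x1", "noise0"), k=5, seed=0)
        perfect = table[table["median_f1"] == table["median_f1"].max()]
        assert perfect.iloc[0]["n_features"] == perfect["n_features"].min()

    def test_missing_candidate_rejected(self, rng):
        frame = gaussian_features(rng)
        with pytest.raises(ValueError, match="absent"):
            exhaustive_feature_search(frame, frame["label"], frame["group_id"],
                                      ("x1", "ghost"), k=5, seed=0)
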