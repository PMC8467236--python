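"""Splits, SVM/RF training, cross-validation, and confusion-matrix metrics."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from apneabands import (
    FEATURE_COLUMNS,
    ConfusionCounts,
    Metrics,
    SplitSpec,
    compute_metrics,
    confusion_counts,
    cross_validate,
    evaluate,
    make_svm,
    split_dataset,
    train_rf,
    train_svm,
)


def cluster_table(n_per_class, shift, seed, noise=1.0):
    """Gaussian class clusters in feature space; ``shift`` controls separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mu in (("apnea", 0.0), ("normal", shift)):
        X = rng.normal(mu, noise, size=(n_per_class, len(FEATURE_COLUMNS)))
        for i, x in enumerate(X):
            rows.append({"subject_id": f"{label}_{i}", "label": label,
                         **dict(zip(FEATURE_COLUMNS, x))})
    return pd.DataFrame(rows)


def xor_table(seed, n=40):
    """Two interleaved XOR clusters embedded in the first two features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        x1, x2 = rng.choice([-1.0, 1.0], 2) + rng.normal(0, 0.1, 2)
        label = "apnea" if x1 * x2 > 0 else "normal"
        feats = dict.fromkeys(FEATURE_COLUMNS, 0.0)
        feats[FEATURE_COLUMNS[0]], feats[FEATURE_COLUMNS[1]] = x1, x2
        rows.append({"subject_id": f"s{i}", "label": label, **feats})
    return pd.DataFrame(rows)


class TestSplitDataset:
    def test_isruc_like_counts(self):
        """89 subjects (57/32) at 90% training split 79 train / 10 test."""
        df = cluster_table(57, 1.0, 0)[:57]
        df2 = cluster_table(32, 1.0, 1)
        df2 = df2[df2.label == "normal"].assign(
            subject_id=lambda d: "n_" + d.subject_id)
        table = pd.concat([df.assign(label="apnea"), df2], ignore_index=True)
        train, test = split_dataset(table, SplitSpec(train_fraction=0.9, seed=0))
        assert len(train) == 79 and len(test) == 10
        assert (test.label == "apnea").sum() == 6 and (test.label == "normal").sum() == 4

    def test_deterministic_for_fixed_seed(self):
        table = cluster_table(5, 1.0, 0)
        a = split_dataset(table, SplitSpec(train_fraction=0.5, seed=7))
        b = split_dataset(table, SplitSpec(train_fraction=0.5, seed=7))
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_stratified_proportions_within_one(self):
        table = cluster_table(50, 1.0, 3)
        train, test = split_dataset(table, SplitSpec(train_fraction=0.7, seed=1))
        assert abs((test.label == "apnea").sum() - 0.5 * len(test)) <= 1
        assert len(train) + len(test) == 100
        assert set(train.subject_id).isdisjoint(test.subject_id)

    def test_single_class_rejected(self):
        table = cluster_table(10, 1.0, 0).query("label == 'apnea'")
        with pytest.raises(ValueError):
            split_dataset(table, SplitSpec())


class TestSvm:
    def test_separable_clusters_linear_kernel(self):
        table = cluster_table(20, 8.0, 0)
        model = train_svm(table, kernel="linear")
        _, m = evaluate(model, table)
        assert m.accuracy == 1.0

    def test_poly2_beats_linear_on_xor(self):
        table = xor_table(0)
        acc = {}
        for kernel in ("linear", "poly2"):
            model = train_svm(table, kernel=kernel)
            _, m = evaluate(model, table)
            acc[kernel] = m.accuracy
        assert acc["poly2"] > acc["linear"]

    def test_label_permutation_null(self):
        """Uninformative features: test accuracy within the 95% binomial
        interval around chance."""
        table = cluster_table(50, 0.0, 11)
        train, test = split_dataset(table, SplitSpec(train_fraction=0.7, seed=2))
        _, m = evaluate(train_svm(train, kernel="poly2"), test)
        half_width = 1.96 * math.sqrt(0.25 / len(test))
        assert abs(m.accuracy - 0.5) <= half_width

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_svm(cluster_table(10, 1.0, 0).query("label == 'apnea'"))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            make_svm("sigmoid")

    def test_scaler_statistics_come_from_training_data_only(self):
        """Anti-leakage: extreme held-out values must not move the scaler."""
        train = cluster_table(20, 2.0, 5)
        model = train_svm(train, kernel="linear")
        X_train = train[list(FEATURE_COLUMNS)].to_numpy(float)
        scaler = model.named_steps["scale"]
        assert np.allclose(scaler.mean_, X_train.mean(axis=0))
        assert np.allclose(scaler.var_, X_train.var(axis=0))


class TestRandomForest:
    def test_separated_cohort_low_oob_error(self):
        table = cluster_table(30, 6.0, 0)
        _, oob = train_rf(table, n_trees=150, seed=0)
        assert oob < 0.1

    def test_ensemble_size_reduces_oob_error(self):
        """150 trees beat a single tree on a noisy cohort in >= 90% of replicates."""
        wins = 0
        for seed in range(20):
            table = cluster_table(30, 0.8, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, o1 = train_rf(table, n_trees=1, seed=seed)
                _, o150 = train_rf(table, n_trees=150, seed=seed)
            wins += o150 <= o1
        assert wins >= 18

    def test_duplicated_single_samples_reproduce_labels(self):
        base = cluster_table(1, 5.0, 0)
        table = pd.concat([base] * 5, ignore_index=True)
        model, _ = train_rf(table, n_trees=10, seed=0)
        _, m = evaluate(model, table)
        assert m.accuracy == 1.0

    def test_deterministic_for_fixed_seed(self):
        table = cluster_table(20, 1.0, 4)
        _, a = train_rf(table, seed=3)
        _, b = train_rf(table, seed=3)
        assert a == b


class TestCrossValidate:
    def test_separable_cohort_perfect_mean_accuracy(self):
        table = cluster_table(30, 8.0, 0)
        res = cross_validate(table, k=10, seed=0)
        assert res.mean.accuracy == 1.0
        assert len(res.per_fold) == 10

    def test_leave_one_out_boundary(self):
        table = cluster_table(5, 8.0, 0)
        res = cross_validate(table, k=5, seed=0)
        assert len(res.per_fold) == 5

    def test_k_above_class_count_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(cluster_table(4, 1.0, 0), k=10)

    def test_matches_manual_fold_loop(self):
        """Manual StratifiedKFold loop with the same seed reproduces the mean."""
        table = cluster_table(100, 1.5, 9)
        res = cross_validate(table, k=10, seed=21)
        X = table[list(FEATURE_COLUMNS)].to_numpy(float)
        y = table["label"].to_numpy()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=21)
        accs = []
        for tr, te in skf.split(X, y):
            model = make_svm().fit(X[tr], y[tr])
            accs.append(np.mean(model.predict(X[te]) == y[te]))
        assert abs(res.mean.accuracy - np.mean(accs)) < 0.05


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_clinical_style_example(self):
        """A 10-subject test set with one false alarm: 90% / 100% / 83%."""
        m = compute_metrics(ConfusionCounts(tp=4, fn=0, tn=5, fp=1))
        assert m.accuracy == pytest.approx(0.90)
        assert m.sensitivity == pytest.approx(1.00)
        assert m.specificity == pytest.approx(0.833, abs=5e-4)

    def test_undefined_sensitivity_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert math.isnan(m.sensitivity)
        assert m.specificity == pytest.approx(0.75)

    def test_exhaustive_small_confusion_tables(self):
        """Brute-force enumeration of every table with total <= 20."""
        for tp, tn, fp, fn in itertools.product(range(6), repeat=4):
            total = tp + tn + fp + fn
            if total == 0 or total > 20:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy == pytest.approx((tp + tn) / total)
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))

    def test_confusion_counts_from_labels(self):
        cc = confusion_counts(["apnea", "apnea", "normal", "normal"],
                              ["apnea", "normal", "normal", "apnea"])
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (1, 1, 1, 1)
        assert cc.total == 4
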