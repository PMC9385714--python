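"""Dataset encoding, training, threshold tuning and evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ribonet.activity_quant import NeutralityConfig
from ribonet.neutrality_classifier import (
    EncodedDataset,
    NeutralityClassifier,
    cross_validate,
    evaluate,
    evaluate_predictions,
    make_dataset,
    train,
    tune_threshold_roc,
)
from ribonet.sequence_core import one_hot_matrix, sample_k_mutants
from ribonet.synthetic_data import DEFAULT_WT


def _activity_table(rng, n=400, separable=True):
    """Synthetic table whose neutrality is a linear function of two positions."""
    seqs = list({s for s in sample_k_mutants(DEFAULT_WT, 3, n, rng)})
    ra = []
    for s in seqs:
        score = (s[0] == DEFAULT_WT[0]) + (s[5] == DEFAULT_WT[5])
        if separable:
            ra.append(0.9 if score == 2 else 0.05)
        else:
            ra.append(float(rng.uniform(0, 1)))
    return pd.DataFrame({"sequence": seqs, "RA_mean": ra})


class TestMakeDataset:
    def test_labels_and_split(self, rng):
        table = _activity_table(rng)
        data = make_dataset(table, NeutralityConfig(0.2), rng=0)
        assert data.X.shape == (len(table), 140)
        assert len(data.test_idx) == round(0.3 * len(table))
        assert not set(data.train_idx) & set(data.test_idx)

    def test_threshold_is_inclusive(self):
        table = pd.DataFrame(
            {"sequence": [DEFAULT_WT, DEFAULT_WT[::-1]], "RA_mean": [0.2, 0.1999]}
        )
        data = make_dataset(table, NeutralityConfig(0.2), rng=0, test_fraction=0.0)
        labels = dict(zip(table["RA_mean"], data.y))
        assert labels[0.2] == 1 and labels[0.1999] == 0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            make_dataset(pd.DataFrame(columns=["sequence", "RA_mean"]))


class TestTraining:
    def test_logistic_regression_separates_linear_data(self, rng):
        table = _activity_table(rng)
        data = make_dataset(table, rng=0)
        clf = train("logistic_regression", data, rng_seed=0, tune_threshold=False)
        assert (clf.predict(data.X_train) == data.y_train).mean() == 1.0

    def test_mlp_close_to_linear_baseline_on_linear_data(self, rng):
        table = _activity_table(rng, n=1000)
        data = make_dataset(table, rng=0)
        lr = train("logistic_regression", data, rng_seed=0, tune_threshold=False)
        mlp = train(
            "multilayer_perceptron", data, rng_seed=0, tune_threshold=False,
            hyperparameters={"max_iter": 200, "batch_size": 256},
        )
        acc_lr = (lr.predict(data.X_test) == data.y_test).mean()
        acc_mlp = (mlp.predict(data.X_test) == data.y_test).mean()
        assert acc_mlp >= acc_lr - 0.05

    def test_deterministic_families_reproducible(self, rng):
        table = _activity_table(rng)
        data = make_dataset(table, rng=0)
        for family in ("logistic_regression", "linear_svm", "k_nearest_neighbors"):
            a = train(family, data, rng_seed=1)
            b = train(family, data, rng_seed=1)
            assert np.array_equal(a.predict(data.X_test), b.predict(data.X_test))

    def test_single_class_raises(self, rng):
        X = one_hot_matrix([DEFAULT_WT] * 10)
        with pytest.raises(ValueError):
            NeutralityClassifier("logistic_regression").fit(X, np.ones(10))

    def test_sklearn_compatibility(self):
        clf = NeutralityClassifier(family="linear_svm", random_state=3)
        params = clf.get_params()
        assert params["family"] == "linear_svm"
        cloned = clone(clf)
        assert cloned.get_params() == params


class TestEpistasisLearnability:
    def test_nonlinear_family_beats_linear_on_epistatic_landscape(self):
        """On landscapes dominated by pairwise interactions, a tree
        ensemble should beat logistic regression (directional check)."""
        from ribonet.synthetic_data import SpectrumSpec, simulate_landscape_from_spectrum

        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            spec = SpectrumSpec(
                n_loci=8, terms_per_order={2: 20}, scale_per_order=1.5, order0=-1.2
            )
            land, _ = simulate_landscape_from_spectrum(
                spec, np.random.default_rng(seed)
            )
            table = pd.DataFrame(
                {"sequence": land.sequences(),
                 "RA_mean": [land.ra(s) for s in land.sequences()]}
            )
            data = make_dataset(table, NeutralityConfig(0.2), rng=seed)
            lr = train("logistic_regression", data, rng_seed=seed, tune_threshold=False)
            gb = train("gradient_boosted_trees", data, rng_seed=seed, tune_threshold=False)
            acc_lr = (lr.predict(data.X_test) == data.y_test).mean()
            acc_gb = (gb.predict(data.X_test) == data.y_test).mean()
            wins += acc_gb > acc_lr
        assert wins > n_seeds / 2


class TestThresholdTuning:
    def test_perfect_scorer(self):
        y = np.array([0, 0, 1, 1])
        proba = np.array([0.1, 0.2, 0.8, 0.9])
        t = tune_threshold_roc(y, proba)
        pred = (proba >= t).astype(int)
        assert np.array_equal(pred, y)

    def test_random_scorer_gmean_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=10000)
        proba = rng.uniform(size=10000)
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, proba)
        gmean = np.sqrt(tpr * (1 - fpr))
        assert gmean.max() == pytest.approx(0.5, abs=0.03)

    def test_degenerate_validation_raises(self):
        with pytest.raises(ValueError):
            tune_threshold_roc(np.ones(5), np.linspace(0, 1, 5))

    def test_threshold_reproduces_reported_max(self, rng):
        y = rng.integers(0, 2, size=200)
        proba = np.clip(y * 0.4 + rng.uniform(0, 0.6, size=200), 0, 1)
        t = tune_threshold_roc(y, proba)
        pred = (proba >= t).astype(int)
        tpr = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
        fpr = ((pred == 1) & (y == 0)).sum() / (y == 0).sum()
        from sklearn.metrics import roc_curve

        f, tp, th = roc_curve(y, proba)
        assert np.sqrt(tpr * (1 - fpr)) == pytest.approx(
            np.sqrt(tp * (1 - f)).max(), abs=1e-9
        )


class TestEvaluation:
    def test_hand_computed_confusion(self):
        y = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 9 + [0] + [1] * 3 + [0] * 7)
        rep = evaluate_predictions(y, pred)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (9, 3, 1, 7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(0.8)

    def test_majority_prediction_hits_null_accuracy(self):
        y = np.array([1] * 7 + [0] * 3)
        rep = evaluate_predictions(y, np.ones(10))
        assert rep.accuracy == rep.null_accuracy == pytest.approx(0.7)

    def test_no_positive_predictions_flagged(self):
        rep = evaluate_predictions(np.array([1, 0, 1]), np.zeros(3))
        assert rep.degenerate and np.isnan(rep.precision)

    def test_row_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        pred = rng.integers(0, 2, size=50)
        rep1 = evaluate_predictions(y, pred)
        p = rng.permutation(50)
        rep2 = evaluate_predictions(y[p], pred[p])
        assert rep1 == rep2


class TestCrossValidation:
    def test_folds_partition_and_beat_null(self, rng):
        table = _activity_table(rng, n=300)
        data = make_dataset(table, rng=0, test_fraction=0.0)
        reports = cross_validate(
            "logistic_regression", data, folds=5, rng_seed=0, tune_threshold=False
        )
        assert len(reports) == 5
        accs = [r.accuracy for r in reports]
        nulls = [r.null_accuracy for r in reports]
        assert np.mean(accs) > np.mean(nulls)

    def test_too_few_examples_raises(self, rng):
        table = _activity_table(rng, n=30)
        data = make_dataset(table, rng=0, test_fraction=0.0)
        with pytest.raises(ValueError):
            cross_validate("logistic_regression", data, folds=50)
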