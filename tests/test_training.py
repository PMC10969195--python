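"""Fold assignment, loss arithmetic and the cross-validation contract."""

import math

import numpy as np
import pytest

from sttcnn.autodiff import Tensor
from sttcnn.model import ModelConfig
from sttcnn.synthetic import SyntheticSpec, generate_dataset
from sttcnn.training import (TrainConfig, cross_validate, loss, make_folds,
                             train_fold)


class TestMakeFolds:
    def test_partition_exhaustive_and_disjoint(self, reduced_dataset):
        folds = make_folds(reduced_dataset, k=10, seed=0)
        assert folds.shape == (len(reduced_dataset),)
        assert set(folds.tolist()) == set(range(10))
        # every segment belongs to exactly one fold by construction
        assert np.all(folds >= 0)

    def test_equal_sizes_for_balanced_data(self, reduced_dataset):
        folds = make_folds(reduced_dataset, k=10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_stratification_within_one(self, reduced_dataset):
        _, y = reduced_dataset.arrays()
        folds = make_folds(reduced_dataset, k=10, seed=0)
        per_class = len(reduced_dataset) / reduced_dataset.n_classes / 10
        for f in range(10):
            counts = np.bincount(y[folds == f], minlength=3)
            assert np.all(np.abs(counts - per_class) <= 1)

    def test_deterministic_given_seed(self, reduced_dataset):
        a = make_folds(reduced_dataset, 10, seed=4)
        b = make_folds(reduced_dataset, 10, seed=4)
        c = make_folds(reduced_dataset, 10, seed=5)
        np.testing.assert_array_equal(a, b)
        assert np.any(a != c)

    def test_trial_grouped_mode_keeps_trials_together(self, reduced_dataset):
        folds = make_folds(reduced_dataset, k=3, seed=0, group_by_trial=True)
        trial_of = [s.trial_id for s in reduced_dataset.segments]
        fold_of_trial = {}
        for t, f in zip(trial_of, folds):
            fold_of_trial.setdefault(t, set()).add(int(f))
        assert all(len(fs) == 1 for fs in fold_of_trial.values())

    def test_too_small_dataset_rejected(self, reduced_dataset):
        with pytest.raises(ValueError):
            make_folds(reduced_dataset, k=len(reduced_dataset) + 1)


class TestLoss:
    def test_uniform_logits_give_log_n_classes(self):
        logits = np.zeros((7, 4))
        labels = np.array([0, 1, 2, 3, 0, 1, 2])
        assert loss(logits, labels).data == pytest.approx(math.log(4), abs=1e-12)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        labels = np.array([0, 1])
        logits = np.array([[50.0, 0.0], [0.0, 50.0]])
        assert loss(logits, labels).data == pytest.approx(0.0, abs=1e-12)

    def test_l2_term_hand_value(self):
        # single weight w=2 with lambda=0.5 adds 0.5 * 2^2 = 2.0
        params = {"head.fc.W": Tensor(np.array([[2.0]]), requires_grad=True),
                  "head.fc.b": Tensor(np.array([5.0]), requires_grad=True)}
        base = loss(np.zeros((1, 1)), np.array([0]))
        full = loss(np.zeros((1, 1)), np.array([0]), params, l2_lambda=0.5)
        assert full.data - base.data == pytest.approx(2.0, abs=1e-12)

    def test_bias_exempt_from_penalty(self):
        params = {"head.fc.b": Tensor(np.array([3.0]), requires_grad=True)}
        a = loss(np.zeros((1, 2)), np.array([1]), params, l2_lambda=1.0)
        b = loss(np.zeros((1, 2)), np.array([1]))
        assert a.data == pytest.approx(b.data)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            loss(np.zeros((2, 3)), np.array([0, 3]))


@pytest.fixture(scope="module")
def tiny_cv_report():
    """One cheap 10-fold CV run shared across contract tests."""
    spec = SyntheticSpec(n_channels=4, sampling_rate=64, trial_seconds=10.0,
                         n_classes=3, spatial_snr=2.0, temporal_snr=2.0, seed=21)
    ds = generate_dataset(spec, n_trials_per_class=2, task="pnn", window_seconds=1.0)
    mc = ModelConfig(n_channels=4, window_samples=64, n_classes=3, variant="st-t",
                     d_model=8, n_heads=2, dropout=0.0)
    tc = TrainConfig(k_folds=10, learning_rate=1e-3, batch_size=32, max_epochs=2,
                     l2_lambda=0.0, seed=1)
    return ds, cross_validate(ds, mc, tc)


class TestCrossValidate:
    def test_ten_fold_results_and_mean(self, tiny_cv_report):
        _, report = tiny_cv_report
        assert len(report.fold_accuracies) == 10
        assert report.mean_accuracy == pytest.approx(
            np.mean(report.fold_accuracies), abs=1e-12)

    def test_variance_is_population_variance_of_folds(self, tiny_cv_report):
        _, report = tiny_cv_report
        accs = report.fold_accuracies
        hand = sum((a - sum(accs) / 10) ** 2 for a in accs) / 10
        assert report.variance == pytest.approx(hand, abs=1e-12)

    def test_pooled_confusion_total_is_dataset_size(self, tiny_cv_report):
        ds, report = tiny_cv_report
        assert report.confusion.sum() == len(ds)

    def test_fold_confusion_totals_match_fold_sizes(self, tiny_cv_report):
        ds, report = tiny_cv_report
        sizes = sorted(r.confusion.sum() for r in report.fold_results)
        assert sum(sizes) == len(ds)

    def test_run_to_run_reproducibility(self, tiny_cv_report):
        ds, report = tiny_cv_report
        mc = ModelConfig(n_channels=4, window_samples=64, n_classes=3, variant="st-t",
                         d_model=8, n_heads=2, dropout=0.0)
        tc = TrainConfig(k_folds=10, learning_rate=1e-3, batch_size=32, max_epochs=2,
                         l2_lambda=0.0, seed=1)
        again = cross_validate(ds, mc, tc)
        assert again.fold_accuracies == report.fold_accuracies


def test_divergence_reported_with_diagnostic(reduced_dataset):
    mc = ModelConfig(n_channels=8, window_samples=64, n_classes=3, variant="s-t",
                     d_model=8, n_heads=2, conv_channels=4, dropout=0.0)
    tc = TrainConfig(k_folds=3, learning_rate=1e12, batch_size=64, max_epochs=3,
                     seed=0)
    folds = make_folds(reduced_dataset, 3, 0)
    with pytest.raises(RuntimeError, match="diverged"):
        train_fold(reduced_dataset, folds, 0, mc, tc)


def test_invalid_train_config():
    with pytest.raises(ValueError):
        TrainConfig(k_folds=1)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
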