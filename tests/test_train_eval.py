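"""Fold planning, SGD training contracts, metrics, ROC/AUC and CV plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvcnn3d import (
    ConfusionCounts,
    TrainConfig,
    evaluate,
    make_patient_folds,
    roc_auc,
    run_cv,
    train_model,
    weighted_average,
)
from mvcnn3d.dataprep import VolumeSample
from mvcnn3d.layers import Conv3D, Dense, Flatten, MaxPool3D, ReLU, Sequential
from mvcnn3d.train_eval import confusion_metrics


def mann_whitney_auc(scores, labels):
    """Pairwise-win oracle: P(score_pos > score_neg), ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFoldPlanner:
    def test_96_patients_split_6x10_4x9(self):
        plan = make_patient_folds([f"P{i}" for i in range(96)], k=10, seed=0)
        assert sorted(plan.fold_sizes()) == [9, 9, 9, 9, 10, 10, 10, 10, 10, 10]

    def test_seeded_determinism_and_independence(self):
        pats = [f"P{i}" for i in range(30)]
        a = make_patient_folds(pats, k=5, seed=11)
        b = make_patient_folds(pats, k=5, seed=11)
        c = make_patient_folds(pats, k=5, seed=12)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_partition_is_patient_disjoint_and_total(self):
        pats = [f"P{i}" for i in range(23)]
        plan = make_patient_folds(pats, k=4, seed=3)
        assert set(plan.assignment) == set(pats)
        assert set(plan.assignment.values()) == set(range(4))
        sizes = plan.fold_sizes()
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_patient_folds(["a", "b"], k=3)


def _toy_net(rng, n_classes=2):
    return Sequential(
        [
            Conv3D((2, 3, 3), 1, 4, padding="same", rng=rng),
            ReLU(),
            MaxPool3D((2, 2, 2)),
            Flatten(),
            Dense(2 * 4 * 4 * 4, n_classes, rng=rng, is_softmax=True),
        ]
    )


def _toy_data(rng, n=48):
    """Binary volumes separable by mean intensity."""
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, 4, 8, 8, 1)).astype(np.float32) * 0.2
    x[y == 1] += 1.0
    return x, y


class TestTrainModel:
    def test_zero_epochs_leaves_network_unchanged(self, rng):
        net = _toy_net(rng)
        before = net.get_weights()
        x, y = _toy_data(rng)
        assert train_model(net, x, y, TrainConfig(epochs=0)) == []
        for b, a in zip(before, net.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_training_reduces_error_on_separable_data(self, rng):
        x, y = _toy_data(rng, n=64)
        net = _toy_net(np.random.default_rng(0))
        history = train_model(net, x, y, TrainConfig(epochs=8, seed=0))
        assert len(history) == 8
        assert history[-1]["error_rate"] < history[0]["error_rate"]

    def test_same_seed_gives_identical_weights(self, rng):
        x, y = _toy_data(rng)
        runs = []
        for _ in range(2):
            net = _toy_net(np.random.default_rng(42))
            train_model(net, x, y, TrainConfig(epochs=3, seed=9))
            runs.append(net.get_weights())
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)


class TestMetrics:
    def test_sensitivity_example(self):
        err, sens, spec = confusion_metrics(ConfusionCounts(tp=9, tn=0, fp=0, fn=1))
        assert sens == pytest.approx(0.9)

    def test_error_rate_example(self):
        err, _, _ = confusion_metrics(ConfusionCounts(tp=95, tn=90, fp=10, fn=5))
        assert err == pytest.approx(0.075)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_error_is_one_minus_accuracy(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        err, sens, spec = confusion_metrics(c)
        assert err == pytest.approx(1.0 - (tp + tn) / c.total)
        for v in (sens, spec):
            assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_perfect_predictions(self, rng):
        class Perfect:
            def predict_proba(self, x):
                mean = x.mean(axis=(1, 2, 3, 4))
                return np.stack([1.0 - (mean > 0.5), (mean > 0.5).astype(float)], axis=1)

        x, y = _toy_data(rng)
        rep = evaluate(Perfect(), x, y, task="binary")
        assert rep.error_rate == 0.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_ternary_reports_error_rate_only(self, rng):
        class Uniform:
            def predict_proba(self, x):
                return np.full((x.shape[0], 3), 1 / 3)

        x = rng.normal(size=(9, 2, 4, 4, 1))
        y = np.array([0, 1, 2] * 3)
        rep = evaluate(Uniform(), x, y, task="ternary")
        assert rep.sensitivity is None and rep.specificity is None
        assert 0.0 <= rep.error_rate <= 1.0

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(None, np.zeros((0, 2, 2, 2, 1)), np.zeros(0))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_worked_example(self):
        # pairs: (.35,.1)+ (.35,.4)- (.8,.1)+ (.8,.4)+ -> 3/4
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("case", range(20))
    def test_matches_mann_whitney_oracle(self, case):
        rng = np.random.default_rng(3000 + case)
        n = int(rng.integers(6, 40))
        scores = np.round(rng.random(n), 2)  # rounding forces some ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels))
        fprs, tprs = zip(*points)
        assert all(np.diff(fprs) >= 0) and all(np.diff(tprs) >= 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=12)
        labels = np.array([0, 1] * 6)
        _, auc = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(2.0 * scores), labels)
        assert auc2 == pytest.approx(auc)


class TestWeightedAverage:
    def test_identical_values(self):
        assert weighted_average([0.3, 0.3, 0.3], [1, 5, 2]) == pytest.approx(0.3)

    def test_worked_example(self):
        assert weighted_average([0.10, 0.20], [0.6, 0.4]) == pytest.approx(0.14)

    def test_uniform_weights_are_the_mean(self, rng):
        v = rng.random(7)
        assert weighted_average(v, np.ones(7)) == pytest.approx(v.mean())

    def test_bounded_by_inputs(self, rng):
        v, w = rng.random(9), rng.random(9) + 0.01
        out = weighted_average(v, w)
        assert v.min() <= out <= v.max()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([1.0], [0.5, 0.5])


class _MajorityStub:
    """Deterministic stub: always predicts class 0."""

    def predict_proba(self, x):
        out = np.zeros((x.shape[0], 2))
        out[:, 0] = 1.0
        return out

    def parameters(self):
        return []


class TestRunCV:
    @staticmethod
    def _samples():
        # 4 patients x 3 samples; patients P0,P1 all-benign, P2,P3 all-malignant
        samples = []
        for p in range(4):
            label = int(p >= 2)
            for i in range(3):
                data = np.full((2, 4, 4, 1), float(label), dtype=np.float32)
                samples.append(VolumeSample(data, label, f"P{p}", f"P{p}-N{i}"))
        return samples

    def test_stub_model_error_is_positive_fraction(self):
        report = run_cv(
            lambda s: _MajorityStub(),
            self._samples(),
            TrainConfig(epochs=0),
            task="binary",
            k=2,
            n_repeats=1,
            seed=0,
        )
        # the stub calls everything benign; weighted error = malignant share
        assert report.error_rate == pytest.approx(0.5)

    def test_identical_repeats_average_to_same_value(self):
        report = run_cv(
            lambda s: _MajorityStub(),
            self._samples(),
            TrainConfig(epochs=0),
            task="binary",
            k=2,
            n_repeats=3,
            seed=1,
        )
        per_repeat = [r["aggregate"]["error_rate"] for r in report.per_repeat]
        assert report.error_rate == pytest.approx(np.mean(per_repeat))

    def test_no_patient_straddles_folds(self):
        samples = self._samples()
        from mvcnn3d.dataprep import samples_to_arrays

        _, _, pids = samples_to_arrays(samples)
        plan = make_patient_folds(pids, k=2, seed=5)
        fold_of = plan.sample_folds(pids)
        for p in set(pids):
            assert len(set(fold_of[pids == p])) == 1
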