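"""Grad-CAM attribution and ROC/AUC evaluation."""

import numpy as np
import pytest

from eegtriage.evaluate import evaluate_model, roc_micro_average, roc_one_vs_all
from eegtriage.interpret import grad_cam_temporal, moving_average
from eegtriage.nn import Model, NetworkSpec, build_feature_network
from eegtriage.nn.layers import Conv1D, Dense, GlobalAvgPool, ReLU, Softmax


def _toy_conv_model(T=18000, fs=100.0):
    """One conv filter matched to a 10 Hz burst, class 1 reads its output."""
    spec = NetworkSpec(input_shape=(1, T))
    spec.add("conv", Conv1D(1, 25, 1))
    spec.add("relu", ReLU())
    spec.add("gap", GlobalAvgPool())
    spec.add("fc", Dense(3))
    spec.add("sm", Softmax())
    m = Model(spec, seed=0)
    t = np.arange(25) / fs
    m.params["conv"]["W"][0, 0, :] = np.sin(2 * np.pi * 10 * t)
    m.params["conv"]["b"][:] = 0
    m.params["fc"]["W"][:] = 0
    m.params["fc"]["W"][0, 1] = 1.0
    m.params["fc"]["b"][:] = 0
    return m


class TestGradCAM:
    def test_trace_aligned_to_input_samples(self):
        m = _toy_conv_model()
        x = np.random.default_rng(0).standard_normal((1, 18000)) * 0.1
        trace = grad_cam_temporal(m, x, target_class=1, fs=100.0)
        assert trace.importance.shape == (18000,)
        assert trace.importance.min() >= 0.0

    def test_planted_burst_localized_within_one_second(self):
        fs, T = 100.0, 18000
        m = _toy_conv_model(T, fs)
        rng = np.random.default_rng(1)
        t = np.arange(T) / fs
        x = 0.05 * rng.standard_normal((1, T))
        burst = (t >= 60) & (t < 70)
        x[0, burst] += 3.0 * np.sin(2 * np.pi * 10 * t[burst])
        trace = grad_cam_temporal(m, x, target_class=1, fs=fs, smooth_s=1.0)
        peak_s = np.argmax(trace.importance) / fs
        assert 59.0 <= peak_s <= 71.0

    def test_zero_gradient_gives_zero_trace(self):
        m = _toy_conv_model()
        m.params["fc"]["W"][:] = 0.0  # class scores blind to the feature map
        x = np.random.default_rng(2).standard_normal((1, 18000))
        trace = grad_cam_temporal(m, x, target_class=1, fs=100.0)
        assert np.allclose(trace.importance, 0.0)

    def test_architecture_without_convolutions_rejected(self):
        m = Model(build_feature_network(30), seed=0)
        with pytest.raises(ValueError, match="convolutional"):
            grad_cam_temporal(m, np.zeros(30), target_class=0)

    def test_normalized_trace_peaks_at_one(self):
        m = _toy_conv_model()
        x = np.random.default_rng(3).standard_normal((1, 18000))
        trace = grad_cam_temporal(m, x, target_class=1, fs=100.0)
        if trace.importance.max() > 0:
            assert trace.normalized().max() == pytest.approx(1.0)


class TestMovingAverage:
    def test_preserves_mean_and_nonnegativity(self):
        rng = np.random.default_rng(4)
        x = np.abs(rng.standard_normal(5000))
        y = moving_average(x, 100)
        assert y.min() >= 0.0
        assert abs(y.mean() - x.mean()) < 0.01 * x.mean()
        assert y.shape == x.shape

    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.0)
        assert np.allclose(moving_average(x, 50), 3.0)


def concordance_auc(scores, y):
    """Brute-force rank-statistic AUC: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def _scores(self, n, informative, seed=0, classes=("Normal", "TBI", "Stroke")):
        rng = np.random.default_rng(seed)
        labels = rng.choice(classes, n)
        raw = rng.standard_normal((n, 3))
        if informative:
            for i, c in enumerate(classes):
                raw[labels == c, i] += 2.0
        e = np.exp(raw)
        return e / e.sum(axis=1, keepdims=True), labels

    def test_hand_example_four_points(self):
        scores = np.array(
            [[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.4, 0.3, 0.3],
             [0.1, 0.45, 0.45]]
        )
        labels = np.array(["Normal", "Normal", "TBI", "Stroke"])
        roc = roc_one_vs_all(scores, labels, "Normal")
        assert roc.auc == pytest.approx(1.0)

    def test_curve_endpoints_and_monotonicity(self):
        scores, labels = self._scores(200, informative=True, seed=1)
        roc = roc_one_vs_all(scores, labels, "TBI")
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_uninformative_scores_near_half(self):
        scores, labels = self._scores(4000, informative=False, seed=2)
        roc = roc_micro_average(scores, labels)
        assert abs(roc.auc - 0.5) < 0.03

    def test_auc_equals_concordance_statistic(self):
        """Trapezoid AUC matches brute-force pair counting to 1e-12."""
        rng = np.random.default_rng(3)
        for n in (20, 200, 1000):
            scores = rng.random((n, 3))
            scores[:, 0] = np.round(scores[:, 0], 2)  # force score ties
            labels = rng.choice(["Normal", "TBI", "Stroke"], n)
            roc = roc_one_vs_all(scores, labels, "Normal")
            y = (labels == "Normal").astype(int)
            assert roc.auc == pytest.approx(
                concordance_auc(scores[:, 0], y), abs=1e-12
            )

    def test_perfect_per_class_gives_perfect_micro(self):
        scores = np.eye(3)[np.array([0, 1, 2, 0, 1, 2])] * 0.9 + 0.05
        labels = np.array(["Normal", "TBI", "Stroke"] * 2)
        assert roc_micro_average(scores, labels).auc == pytest.approx(1.0)

    def test_micro_between_min_and_max_per_class_on_balanced_data(self):
        scores, labels = self._scores(600, informative=True, seed=4)
        res = evaluate_model(scores, labels)
        per_class = [res["Normal"], res["TBI"], res["Stroke"]]
        assert min(per_class) - 1e-9 <= res["micro"] <= max(per_class) + 1e-9

    def test_micro_invariant_to_class_relabeling(self):
        scores, labels = self._scores(300, informative=True, seed=5)
        base = roc_micro_average(scores, labels).auc
        perm = {"Normal": "TBI", "TBI": "Stroke", "Stroke": "Normal"}
        relabeled = np.array([perm[c] for c in labels])
        rescored = scores[:, [2, 0, 1]]  # columns follow the relabeling
        assert roc_micro_average(rescored, relabeled).auc == pytest.approx(base)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_one_vs_all(np.random.rand(5, 3), np.array(["TBI"] * 5), "TBI")
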