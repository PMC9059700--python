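"""Parameter accounting, the multi-label loss, metrics, and smoke fitting."""

import math

import numpy as np
import pytest

from fundoprep import (LabelVector, ModelSpec, SynthSpec, TinyFundusClassifier,
                       binarize, build_classifier, challenge_decision_score,
                       compute_metrics, count_parameters, fit,
                       generate_fundus, multilabel_loss)
from fundoprep.model_zoo import (ARCH_NAMES, IMAGENET_PARAM_COUNTS,
                                 PENULTIMATE_WIDTH, head_swap_count)

# Published parameter totals (in millions) of each backbone once its
# 1000-way ImageNet classifier is replaced by the 8-way disease head.
EXPECTED_8CLASS_COUNTS = {
    "SqueezeNet": 726_600,
    "MobileNetv2": 2_234_120,
    "Inceptionv1": 5_608_104,
    "DenseNet121": 6_962_056,
    "EfficientNet-B3": 10_708_528,
    "ResNeXt50": 22_996_296,
    "ResNet50": 23_524_424,
    "Inceptionv3": 25_128_656,
    "EfficientNet-B7": 63_807_448,
    "WideResNet50": 66_850_632,
    "VGG16": 134_293_320,
}


class TestParameterAccounting:
    @pytest.mark.parametrize("arch", ARCH_NAMES)
    def test_head_swap_identity(self, arch):
        """Structural count equals published_1000 - old head + new head."""
        model = build_classifier(ModelSpec(arch, n_classes=8))
        assert count_parameters(model) == head_swap_count(arch, 8)

    @pytest.mark.parametrize("arch", ARCH_NAMES)
    def test_structural_count_matches_published_1000_class_total(self, arch):
        model = build_classifier(ModelSpec(arch, n_classes=1000))
        assert count_parameters(model) == IMAGENET_PARAM_COUNTS[arch]

    def test_resnet50_head_maps_2048_to_8(self):
        model = build_classifier(ModelSpec("ResNet50"))
        assert model.head_shape == (2048, 8)
        assert model.head_weights.shape == (2048, 8)

    def test_same_head_seed_gives_identical_head_weights(self):
        a = build_classifier(ModelSpec("VGG16", head_seed=3))
        b = build_classifier(ModelSpec("VGG16", head_seed=3))
        c = build_classifier(ModelSpec("VGG16", head_seed=4))
        assert np.array_equal(a.head_weights, b.head_weights)
        assert not np.array_equal(a.head_weights, c.head_weights)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            build_classifier(ModelSpec("AlexNet"))

    def test_toy_head_count_is_d_times_8_plus_8(self):
        for arch in ("ResNet50", "VGG16"):
            d = PENULTIMATE_WIDTH[arch]
            with_head = count_parameters(build_classifier(ModelSpec(arch)))
            without = sum(p for _, p in
                          build_classifier(ModelSpec(arch)).layers)
            assert with_head - without == d * 8 + 8


def _loss_oracle(y_hat, y):
    """Element-wise scalar evaluation of the one-versus-all loss."""
    n, c = y_hat.shape
    total = 0.0
    for i in range(n):
        s = 0.0
        for j in range(c):
            sig = 1.0 / (1.0 + math.exp(-y_hat[i, j]))
            s += y[i, j] * math.log(sig) + (1 - y[i, j]) * math.log(1 - sig)
        total += -s / c
    return total / n


class TestMultilabelLoss:
    def test_zero_scores_give_ln2(self, rng):
        y = rng.integers(0, 2, (5, 8))
        assert multilabel_loss(np.zeros((5, 8)), y) == pytest.approx(
            math.log(2), abs=1e-12)

    def test_limit_to_zero_for_confident_correct(self):
        y = np.ones((1, 8))
        assert multilabel_loss(np.full((1, 8), 50.0), y) < 1e-15

    def test_matches_scalar_oracle_on_random_batches(self, rng):
        y_hat = rng.normal(0, 3, (4, 8))
        y = rng.integers(0, 2, (4, 8)).astype(float)
        assert multilabel_loss(y_hat, y) == pytest.approx(
            _loss_oracle(y_hat, y), rel=1e-12)

    def test_stable_for_large_scores(self):
        y = np.array([[1, 0, 1, 0, 1, 0, 1, 0]], dtype=float)
        val = multilabel_loss(np.full((1, 8), 100.0), y)
        assert np.isfinite(val) and val > 0

    def test_decreases_as_correct_score_grows(self):
        y = np.zeros((1, 8))
        y[0, 0] = 1
        losses = [multilabel_loss(np.eye(1, 8) * s, y) for s in (0, 1, 5, 20)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError):
            multilabel_loss(np.zeros((1, 8)), np.full((1, 8), 0.5))


class TestBinarize:
    def test_threshold_is_inclusive(self):
        out = binarize(np.array([0.5, 0.499, 0.0, 1.0]))
        assert out.tolist() == [1, 0, 0, 1]


def _metrics_oracle(yt, yp):
    """Scalar-wise evaluation of macro precision/recall, F1, mean kappa."""
    C = yt.shape[1]
    precs, recs, kappas = [], [], []
    for c in range(C):
        tp = fp = fn = tn = 0
        for i in range(yt.shape[0]):
            t, p = yt[i, c], yp[i, c]
            tp += t == 1 and p == 1
            fp += t == 0 and p == 1
            fn += t == 1 and p == 0
            tn += t == 0 and p == 0
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
        n = tp + fp + fn + tn
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        kappas.append((po - pe) / (1 - pe) if abs(1 - pe) > 1e-12
                      else (1.0 if po > 1 - 1e-12 else 0.0))
    precision = sum(precs) / C
    recall = sum(recs) / C
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1, sum(kappas) / C


class TestComputeMetrics:
    def test_perfect_agreement(self, rng):
        y = rng.integers(0, 2, (60, 8))
        while (y.sum(axis=0) == 0).any() or (y.sum(axis=0) == 60).any():
            y = rng.integers(0, 2, (60, 8))
        rep = compute_metrics(y, y, y.astype(float))
        assert rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.kappa == pytest.approx(1.0)
        assert rep.auc == pytest.approx(1.0)

    def test_complement_prediction_gives_kappa_minus_one(self):
        # balanced single label, prediction is the exact complement
        y = np.zeros((40, 8), int)
        y[:20, 0] = 1
        pred = y.copy()
        pred[:, 0] = 1 - y[:, 0]
        rep = compute_metrics(y, pred)
        assert rep.per_label_kappa[0] == pytest.approx(-1.0)

    def test_matches_scalar_oracle_on_random_matrices(self, rng):
        yt = rng.integers(0, 2, (200, 8))
        yp = rng.integers(0, 2, (200, 8))
        rep = compute_metrics(yt, yp)
        precision, recall, f1, kappa = _metrics_oracle(yt, yp)
        assert rep.precision == pytest.approx(precision)
        assert rep.recall == pytest.approx(recall)
        assert rep.f1 == pytest.approx(f1)
        assert rep.kappa == pytest.approx(kappa)

    def test_kappa_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        yt = rng.integers(0, 2, (150, 8))
        yp = (yt ^ (rng.uniform(size=yt.shape) < 0.25)).astype(int)
        rep = compute_metrics(yt, yp)
        expected = np.mean([cohen_kappa_score(yt[:, c], yp[:, c])
                            for c in range(8)])
        assert rep.kappa == pytest.approx(expected)

    def test_kappa_symmetric_under_swap(self, rng):
        yt = rng.integers(0, 2, (80, 8))
        yp = rng.integers(0, 2, (80, 8))
        assert compute_metrics(yt, yp).kappa == pytest.approx(
            compute_metrics(yp, yt).kappa)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((4, 8), int), np.zeros((5, 8), int))


class TestChallengeScore:
    def test_single_correct_decision_among_4000(self):
        y_true = np.zeros((500, 8), int)
        y_pred = 1 - y_true
        y_pred[0, 0] = 0  # the single correct decision
        assert challenge_decision_score(y_true, y_pred) == 0.00025

    def test_all_correct_scores_one(self, rng):
        y = rng.integers(0, 2, (50, 8))
        assert challenge_decision_score(y, y) == 1.0


@pytest.fixture(scope="module")
def small_dataset():
    data = []
    for i in range(64):
        tag = ("C" if i % 2 else "N")
        counts = {"C": 1} if tag == "C" else {}
        img, gt = generate_fundus(
            SynthSpec(seed=300 + i, disc_radius=60,
                      image_size=(128, 128), lesion_counts=counts))
        data.append((img.pixels, gt.label))
    return data


class TestFit:
    def test_loss_decreases_over_epochs(self, small_dataset):
        model = TinyFundusClassifier(head_seed=0)
        _, trace = fit(model, small_dataset, epochs=2, seed=1)
        assert trace[1] < trace[0]

    def test_zero_learning_rate_freezes_loss(self, small_dataset):
        model = TinyFundusClassifier(head_seed=0)
        _, trace = fit(model, small_dataset, epochs=3, seed=1, lr=0.0)
        assert trace[0] == pytest.approx(trace[1]) == pytest.approx(trace[2])

    def test_same_seed_same_trace(self, small_dataset):
        _, t1 = fit(TinyFundusClassifier(head_seed=2), small_dataset,
                    epochs=2, seed=5)
        _, t2 = fit(TinyFundusClassifier(head_seed=2), small_dataset,
                    epochs=2, seed=5)
        assert t1 == t2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit(TinyFundusClassifier(), [], epochs=1, seed=0)

    def test_scores_in_unit_interval(self, small_dataset):
        model, _ = fit(TinyFundusClassifier(head_seed=0), small_dataset,
                       epochs=1, seed=1)
        scores = model.predict_scores([small_dataset[0][0]])
        assert scores.shape == (1, 8)
        assert ((scores >= 0) & (scores <= 1)).all()
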