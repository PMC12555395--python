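"""Metrics, schedules, perturbations, and the training loop."""

import numpy as np
import pytest

from gcassn.autodiff import Tensor
from gcassn.io import LabeledCloud
from gcassn.nn import cross_entropy
from gcassn.train import (TrainConfig, confusion_matrix, drop_points, evaluate,
                          fit, gaussian_perturb, lr_schedule,
                          segmentation_metrics, shapenet_mciou)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected",
                             [(0, 0.1), (20, 0.05), (40, 0.025), (45, 0.025),
                              (60, 0.0125)])
    def test_step_decay_values(self, epoch, expected):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(expected)

    def test_non_increasing_piecewise_constant(self):
        cfg = TrainConfig()
        values = [lr_schedule(e, cfg) for e in range(100)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        for start in range(0, 100, 20):
            assert len(set(values[start:start + 20])) == 1

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(cm, np.diag([1, 2, 1]))

    def test_hand_tally(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])

    def test_total_conserved_and_matches_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix as sk_cm
        for _ in range(20):
            t = rng.integers(0, 4, 50)
            p = rng.integers(0, 4, 50)
            cm = confusion_matrix(t, p, 4)
            assert cm.sum() == 50
            np.testing.assert_array_equal(cm, sk_cm(t, p, labels=range(4)))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)


def tally_oracle(truth, pred, n_classes):
    """Direct per-point counting loops, independent of the implementation."""
    tp = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    for t, p in zip(truth, pred):
        if t == p:
            tp[t] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    iou = {}
    for c in range(n_classes):
        union = tp[c] + fp[c] + fn[c]
        if union:
            iou[c] = tp[c] / union
    acc = sum(tp) / len(truth)
    return iou, acc


class TestSegmentationMetrics:
    def test_worked_iou_value(self):
        # one class with TP=3, FP=1, FN=1 -> IoU 0.6
        cm = np.array([[3, 1], [1, 5]])
        m = segmentation_metrics(cm)
        assert m.iou_per_class[0] == pytest.approx(3 / 5)

    def test_perfect_diagonal(self):
        m = segmentation_metrics(np.diag([4, 5, 6]))
        np.testing.assert_allclose(m.iou_per_class, 1.0)
        assert m.miou == 1.0 and m.acc_overall == 1.0

    def test_miou_is_unweighted_mean_of_defined_ious(self, rng):
        # the worked pair: averaging class IoUs 1.0 and 0.5 gives 0.75
        assert np.mean([1.0, 0.5]) == pytest.approx(0.75)
        # and the implementation averages exactly the defined per-class IoUs
        for _ in range(10):
            cm = rng.integers(0, 6, (3, 3))
            cm[2] = 0
            cm[:, 2] = 0          # class 2 absent from truth and prediction
            if cm.sum() == 0:
                continue
            m = segmentation_metrics(cm)
            assert np.isnan(m.iou_per_class[2])
            assert m.miou == pytest.approx(np.nanmean(m.iou_per_class))

    def test_agrees_with_tally_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 3, 40)
            p = rng.integers(0, 3, 40)
            m = segmentation_metrics(confusion_matrix(t, p, 3))
            iou, acc = tally_oracle(t, p, 3)
            assert m.acc_overall == pytest.approx(acc)
            for c, v in iou.items():
                assert m.iou_per_class[c] == pytest.approx(v)

    def test_absent_class_excluded_from_mean(self):
        cm = np.array([[4, 0, 0], [0, 4, 0], [0, 0, 0]])
        m = segmentation_metrics(cm)
        assert m.miou == 1.0
        assert np.isnan(m.iou_per_class[2])
        m1 = segmentation_metrics(cm, absent_class="score_one")
        assert m1.miou == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(np.zeros((3, 3)))


class TestShapenetMciou:
    def test_worked_example(self):
        miou, mciou = shapenet_mciou([("A", 0.8), ("A", 0.6), ("B", 1.0)])
        assert miou == pytest.approx(0.8)
        assert mciou == pytest.approx(0.85)

    def test_single_category_equal(self):
        miou, mciou = shapenet_mciou([("A", 0.7), ("A", 0.9)])
        assert miou == mciou == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shapenet_mciou([])


class TestPerturbations:
    def test_drop_zero_is_identity(self, random_cloud):
        out = drop_points(random_cloud, 0, seed=0)
        np.testing.assert_array_equal(out.coords, random_cloud.coords)

    def test_drop_counts(self, rng):
        cloud = LabeledCloud(rng.normal(size=(2048, 3)),
                             rng.integers(0, 3, 2048))
        assert drop_points(cloud, 512, seed=0).n_points == 1536

    def test_survivors_are_subset(self, random_cloud):
        out = drop_points(random_cloud, 10, seed=2)
        orig = {tuple(r) for r in random_cloud.coords}
        assert all(tuple(r) in orig for r in out.coords)

    def test_drop_all_rejected(self, random_cloud):
        with pytest.raises(ValueError):
            drop_points(random_cloud, random_cloud.n_points, seed=0)

    def test_noise_zero_is_identity(self, random_cloud):
        out = gaussian_perturb(random_cloud, 0.0, seed=0)
        np.testing.assert_array_equal(out.coords, random_cloud.coords)

    def test_noise_empirical_std(self):
        cloud = LabeledCloud(np.zeros((40000, 3)))
        out = gaussian_perturb(cloud, 0.02, seed=1)
        assert np.std(out.coords - cloud.coords) == pytest.approx(0.02,
                                                                  rel=0.05)

    def test_noise_preserves_labels_bitwise(self, random_cloud):
        out = gaussian_perturb(random_cloud, 0.05, seed=3)
        np.testing.assert_array_equal(out.labels, random_cloud.labels)

    def test_negative_sigma_rejected(self, random_cloud):
        with pytest.raises(ValueError):
            gaussian_perturb(random_cloud, -0.1, seed=0)


class TestLoss:
    def test_uniform_logits_give_log_p(self):
        for P in (2, 3, 5):
            logits = Tensor(np.zeros((4, 10, P)))
            labels = np.random.default_rng(0).integers(0, P, (4, 10))
            loss = cross_entropy(logits, labels)
            assert float(loss.data) == pytest.approx(np.log(P), abs=1e-6)


class _OracleModel:
    """Stub that predicts the true labels (stored per cloud by coords hash)."""

    def __init__(self, clouds, n_classes):
        from gcassn.model import ModelConfig
        self.config = ModelConfig(n_classes=n_classes, n_gcasm_layers=1,
                                  channels=(4,), k=1, global_dim=4,
                                  head_dims=(4, 4))
        self._lookup = {c.coords.tobytes(): c.labels for c in clouds}

    def predict(self, coords):
        from gcassn.model import SegmentationResult
        labels = self._lookup[np.asarray(coords).tobytes()]
        logits = np.zeros((len(labels), self.config.n_classes))
        logits[np.arange(len(labels)), labels] = 1.0
        return SegmentationResult.from_logits(logits)


class TestFitAndEvaluate:
    def test_perfect_oracle_scores_miou_one(self, small_plants):
        model = _OracleModel(small_plants, 3)
        m = evaluate(model, small_plants)
        assert m.miou == 1.0 and m.acc_overall == 1.0

    def test_evaluate_is_deterministic(self, two_class_plants, tiny_config):
        from dataclasses import replace
        from gcassn.model import GCASSN
        cfg = replace(tiny_config, n_classes=2)
        model = GCASSN(cfg, seed=0).eval()
        a = evaluate(model, two_class_plants)
        b = evaluate(model, two_class_plants)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_drop_sweep_returns_records_in_order(self, two_class_plants,
                                                 tiny_config):
        from dataclasses import replace
        from gcassn.experiments import drop_fraction_sweep
        from gcassn.model import GCASSN
        cfg = replace(tiny_config, n_classes=2)
        model = GCASSN(cfg, seed=0).eval()
        records = drop_fraction_sweep(model, two_class_plants, seed=0)
        assert [r["fraction"] for r in records] == [0.0, 0.25, 0.5, 0.75]
        assert all(np.isfinite(r["acc"]) for r in records)

    def test_first_batch_loss_finite_positive(self, two_class_plants):
        from gcassn.model import ModelConfig, GCASSN
        cfg = ModelConfig(n_classes=2, n_gcasm_layers=1, channels=(8,), k=4,
                          global_dim=16, head_dims=(16, 8),
                          use_transnet=False)
        model = GCASSN(cfg, seed=0)
        model.train()
        X = np.stack([c.coords for c in two_class_plants])
        y = np.stack([c.labels for c in two_class_plants])
        loss = float(cross_entropy(model(Tensor(X)), y).data)
        assert np.isfinite(loss) and loss > 0

    def test_fit_is_seed_reproducible(self, two_class_plants):
        from gcassn.model import ModelConfig
        cfg = ModelConfig(n_classes=2, n_gcasm_layers=1, channels=(8,), k=4,
                          global_dim=16, head_dims=(16, 8),
                          use_transnet=False)
        tc = TrainConfig(batch_size=4, epochs=1, seed=5)
        _, h1 = fit(cfg, two_class_plants[:4], two_class_plants[4:], tc)
        _, h2 = fit(cfg, two_class_plants[:4], two_class_plants[4:], tc)
        assert h1.loss == h2.loss
        assert h1.test_miou == h2.test_miou

    def test_shuffled_labels_stay_near_chance(self, two_class_plants):
        """Label-shuffled training must not beat chance on held-out clouds
        (guards against information leakage in the harness)."""
        from dataclasses import replace
        from gcassn.model import ModelConfig
        rng = np.random.default_rng(0)
        shuffled = [LabeledCloud(c.coords, rng.permutation(c.labels))
                    for c in two_class_plants]
        cfg = ModelConfig(n_classes=2, n_gcasm_layers=1, channels=(8,), k=4,
                          global_dim=16, head_dims=(16, 8),
                          use_transnet=False)
        tc = TrainConfig(batch_size=4, epochs=5, seed=0)
        model, hist = fit(cfg, shuffled[:4], shuffled[4:], tc)
        test_labels = np.concatenate([c.labels for c in shuffled[4:]])
        chance = max(np.bincount(test_labels)) / len(test_labels)
        assert max(hist.test_acc) <= chance + 0.1

    def test_empty_sets_rejected(self, two_class_plants, tiny_config):
        with pytest.raises(ValueError):
            fit(tiny_config, [], two_class_plants, TrainConfig(epochs=1))
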