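"""Training recipe, segmentation metrics, and robustness perturbations.

The optimizer recipe is SGD with momentum 0.9, weight decay 1e-4, batch
size 8, initial learning rate 0.1 halved every 20 epochs, trained with
per-point cross-entropy; the reported parameters are those of the epoch
with the best test-set mIoU.

Metrics follow the point-cloud segmentation convention: a pooled (micro)
confusion matrix over the whole test set, per-class IoU = TP/(TP+FP+FN),
mIoU as the unweighted mean over classes present in truth or prediction,
overall point accuracy, and per-class accuracy (TP+TN)/total.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .io import LabeledCloud
from .model import GCASSN, ModelConfig
from .nn import SGD, cross_entropy

__all__ = [
    "TrainConfig", "SegMetrics", "TrainHistory", "lr_schedule",
    "confusion_matrix", "segmentation_metrics", "shapenet_mciou",
    "drop_points", "gaussian_perturb", "fit", "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr0: float = 0.1
    decay_factor: float = 0.5
    decay_every: int = 20
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.decay_every, self.epochs) < 1 or \
                self.lr0 <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must be in (0, 1)")


@dataclass
class SegMetrics:
    confusion: np.ndarray
    iou_per_class: np.ndarray
    miou: float
    acc_overall: float
    acc_per_class: np.ndarray
    acc_mean_class: float
    n_points: int


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    test_miou: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.test_miou))


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: lr0 * factor^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """P x P counts; rows are true classes, columns predicted classes."""
    t = np.asarray(true_labels, dtype=np.int64).ravel()
    p = np.asarray(predicted_labels, dtype=np.int64).ravel()
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size and (t.min() < 0 or p.min() < 0 or
                   t.max() >= n_classes or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    return np.bincount(t * n_classes + p,
                       minlength=n_classes * n_classes).reshape(n_classes,
                                                                n_classes)


def segmentation_metrics(confusion: np.ndarray,
                         absent_class: str = "exclude") -> SegMetrics:
    """Derive IoU/accuracy metrics from a pooled confusion matrix.

    Classes absent from both truth and prediction (zero union) are excluded
    from the mIoU mean by default (``absent_class='score_one'`` scores them
    as 1 instead).
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.min() < 0:
        raise ValueError("confusion matrix entries must be non-negative")
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    union = tp + fp + fn
    present = union > 0
    iou = np.full(confusion.shape[0], np.nan)
    iou[present] = tp[present] / union[present]
    if absent_class == "exclude":
        miou = float(np.mean(iou[present]))
    elif absent_class == "score_one":
        miou = float(np.mean(np.where(present, iou, 1.0)))
    else:
        raise ValueError(f"unknown absent_class policy {absent_class!r}")
    tn = total - tp - fp - fn
    acc_per_class = (tp + tn) / total
    return SegMetrics(confusion=confusion,
                      iou_per_class=iou,
                      miou=miou,
                      acc_overall=float(tp.sum() / total),
                      acc_per_class=acc_per_class,
                      acc_mean_class=float(acc_per_class[present].mean()),
                      n_points=int(total))


def shapenet_mciou(per_instance: list[tuple[str, float]]) -> tuple[float, float]:
    """Instance-mean mIoU and category-mean mcIoU from (category, mIoU) pairs."""
    if not per_instance:
        raise ValueError("need at least one instance")
    values = np.array([v for _, v in per_instance], dtype=float)
    miou = float(values.mean())
    cats: dict[str, list[float]] = {}
    for c, v in per_instance:
        cats.setdefault(c, []).append(v)
    mciou = float(np.mean([np.mean(v) for v in cats.values()]))
    return miou, mciou


# ---------------------------------------------------------------------------
# robustness perturbations
# ---------------------------------------------------------------------------

def drop_points(cloud: LabeledCloud, n_drop: int, seed: int) -> LabeledCloud:
    """Remove ``n_drop`` uniformly chosen points (labels follow survivors)."""
    if not 0 <= n_drop < cloud.n_points:
        raise ValueError("n_drop must be in [0, N)")
    if n_drop == 0:
        return LabeledCloud(cloud.coords.copy(),
                            None if cloud.labels is None else cloud.labels.copy(),
                            source_id=cloud.source_id)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(cloud.n_points, cloud.n_points - n_drop,
                              replace=False))
    return LabeledCloud(cloud.coords[keep],
                        None if cloud.labels is None else cloud.labels[keep],
                        source_id=cloud.source_id)


def gaussian_perturb(cloud: LabeledCloud, sigma: float, seed: int) -> LabeledCloud:
    """Add iid zero-mean Gaussian noise (std ``sigma``, normalized units)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    coords = cloud.coords.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, sigma, coords.shape)
    return LabeledCloud(coords,
                        None if cloud.labels is None else cloud.labels.copy(),
                        source_id=cloud.source_id)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _stack(clouds: list[LabeledCloud]) -> tuple[np.ndarray, np.ndarray]:
    sizes = {c.n_points for c in clouds}
    if len(sizes) != 1:
        raise ValueError("all clouds must be sampled to a common size first")
    if any(c.labels is None for c in clouds):
        raise ValueError("training requires labeled clouds")
    coords = np.stack([c.coords for c in clouds])
    labels = np.stack([c.labels for c in clouds])
    return coords, labels


def fit(model_cfg: ModelConfig, train_set: list[LabeledCloud],
        test_set: list[LabeledCloud], train_cfg: TrainConfig,
        verbose: bool = False) -> tuple[GCASSN, TrainHistory]:
    """Train a segmentation network; return the best-mIoU-epoch parameters.

    Fully seed-reproducible: the seed fixes the weight initialization, the
    batch shuffling and the dropout masks.
    """
    if not train_set or not test_set:
        raise ValueError("train and test sets must be non-empty")
    X, y = _stack(train_set)
    model = GCASSN(model_cfg, seed=train_cfg.seed)
    model.reseed_dropout(train_cfg.seed + 1)
    opt = SGD(model.parameters(), lr=train_cfg.lr0,
              momentum=train_cfg.momentum,
              weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed + 2)
    history = TrainHistory()
    best = (-1.0, None)
    for epoch in range(train_cfg.epochs):
        opt.lr = lr_schedule(epoch, train_cfg)
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            logits = model(Tensor(X[batch]))
            loss = cross_entropy(logits, y[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        metrics = evaluate(model, test_set)
        history.loss.append(float(np.mean(losses)))
        history.lr.append(opt.lr)
        history.test_miou.append(metrics.miou)
        history.test_acc.append(metrics.acc_overall)
        if metrics.miou > best[0]:
            best = (metrics.miou, copy.deepcopy(model.state_dict()))
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.4f}  "
                  f"loss {history.loss[-1]:.4f}  "
                  f"test mIoU {metrics.miou:.4f}  "
                  f"test acc {metrics.acc_overall:.4f}")
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


def evaluate(model: GCASSN, test_set: list[LabeledCloud],
             perturbation: tuple[str, float] | None = None,
             seed: int = 0,
             absent_class: str = "exclude") -> SegMetrics:
    """Pooled test-set metrics, optionally after a perturbation.

    ``perturbation`` is ``('drop', n_points)`` or ``('noise', sigma)``
    applied per cloud before the forward pass (seed-deterministic).
    """
    if not test_set:
        raise ValueError("test set must be non-empty")
    n_classes = model.config.n_classes
    pooled = np.zeros((n_classes, n_classes), dtype=np.int64)
    for i, cloud in enumerate(test_set):
        if cloud.labels is None:
            raise ValueError("evaluation requires labeled clouds")
        c = cloud
        if perturbation is not None:
            kind, value = perturbation
            if kind == "drop":
                c = drop_points(c, int(value), seed + i)
            elif kind == "noise":
                c = gaussian_perturb(c, float(value), seed + i)
            else:
                raise ValueError(f"unknown perturbation {kind!r}")
        result = model.predict(c.coords)
        pooled += confusion_matrix(c.labels, result.predicted, n_classes)
    return segmentation_metrics(pooled, absent_class=absent_class)
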