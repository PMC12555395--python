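"""Design-space sweep harness.

Enumerates the architecture and robustness variants the model exposes —
GCASM depth 1..4, neighborhood size k, the five neighborhood metrics
(squared Euclidean / Pearson / cosine / two weighted blends), attention
variants (shared-QK, general, 4/8-head), Trans-net on/off, point dropping
and Gaussian noise levels — and runs each one, either as a single
forward/backward smoke step or as a short training.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .autodiff import Tensor
from .io import LabeledCloud
from .model import GCASSN, ModelConfig
from .nn import SGD, cross_entropy
from .train import TrainConfig, evaluate, fit, segmentation_metrics, \
    confusion_matrix

__all__ = ["variant_configs", "noise_levels", "run_one_step", "run_sweep"]

#: the robustness noise standard deviations, in normalized-coordinate units
NOISE_SIGMAS = (0.0, 0.01, 0.02, 0.04, 0.08)
DROP_FRACTIONS = (0.0, 0.25, 0.5, 0.75)


def variant_configs(sweep: str, base: ModelConfig | None = None
                    ) -> list[tuple[str, ModelConfig]]:
    """Named model configurations for one design-space axis."""
    base = base or ModelConfig()
    if sweep == "layers":
        return [(f"layers={n}",
                 replace(base, n_gcasm_layers=n,
                         channels=base.channels[:1] * n))
                for n in (1, 2, 3, 4)]
    if sweep == "k":
        return [(f"k={k}", replace(base, k=k)) for k in (10, 20, 30, 40)]
    if sweep == "metric":
        variants = [("sq_euclidean", "sq_euclidean", 1.0),
                    ("pearson", "pearson", 1.0),
                    ("cosine", "cosine", 1.0),
                    ("weighted_0.5", "weighted", 0.5),
                    ("weighted_0.7", "weighted", 0.7)]
        return [(name, replace(base, graph_metric=metric,
                               weight_sq_euclid=w))
                for name, metric, w in variants]
    if sweep == "attention":
        return [(v, replace(base, attn_variant=v))
                for v in ("gcasm", "general", "multihead4", "multihead8")]
    if sweep == "transnet":
        return [("transnet=on", replace(base, use_transnet=True)),
                ("transnet=off", replace(base, use_transnet=False))]
    raise ValueError(f"unknown sweep {sweep!r}")


def run_one_step(config: ModelConfig, clouds: list[LabeledCloud],
                 seed: int = 0) -> dict:
    """One forward/backward/optimizer step plus metrics on the same batch.

    The structural smoke test for a variant: verifies the configuration
    builds, differentiates, and produces a finite loss and valid metrics.
    """
    X = np.stack([c.coords for c in clouds])
    y = np.stack([c.labels for c in clouds])
    model = GCASSN(config, seed=seed)
    model.train()
    opt = SGD(model.parameters(), lr=0.1, momentum=0.9, weight_decay=1e-4)
    logits = model(Tensor(X))
    loss = cross_entropy(logits, y)
    opt.zero_grad()
    loss.backward()
    grad_norms = {name: float(np.linalg.norm(p.grad))
                  for name, p in model.named_parameters()}
    opt.step()
    model.eval()
    pred = np.argmax(model(Tensor(X)).data, axis=-1)
    metrics = segmentation_metrics(
        confusion_matrix(y.ravel(), pred.ravel(), config.n_classes))
    return {"loss": float(loss.data),
            "miou": metrics.miou,
            "acc": metrics.acc_overall,
            "n_parameters": model.n_parameters(),
            "all_grads_finite": all(np.isfinite(v) for v in grad_norms.values()),
            "n_zero_grad_params": sum(v == 0.0 for v in grad_norms.values())}


def run_sweep(sweep: str, clouds: list[LabeledCloud], epochs: int = 10,
              seed: int = 0, base: ModelConfig | None = None) -> dict:
    """Short training per variant of one axis; returns metrics per variant.

    ``sweep`` may also be ``noise`` or ``drop``, which train the base
    configuration once and evaluate it across perturbation levels.
    """
    n_train = max(2, int(round(0.8 * len(clouds))))
    train_set, test_set = clouds[:n_train], clouds[n_train:] or clouds[-1:]
    cfg = TrainConfig(epochs=epochs, seed=seed)
    results: dict[str, dict] = {}
    if sweep in ("noise", "drop"):
        base = base or ModelConfig()
        model, _ = fit(base, train_set, test_set, cfg)
        if sweep == "noise":
            levels = [("noise", s) for s in NOISE_SIGMAS]
        else:
            n = test_set[0].n_points
            levels = [("drop", int(f * n)) for f in DROP_FRACTIONS]
        for kind, value in levels:
            m = evaluate(model, test_set,
                         None if value == 0 else (kind, value), seed=seed)
            results[f"{kind}={value}"] = {"miou": m.miou,
                                          "acc": m.acc_overall}
        return results
    for name, config in variant_configs(sweep, base):
        model, history = fit(config, train_set, test_set, cfg)
        results[name] = {"best_miou": float(max(history.test_miou)),
                         "best_acc": float(max(history.test_acc)),
                         "n_parameters": model.n_parameters()}
    return results
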