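"""Mini-batch training and evaluation loops shared by all settings.

One function trains a model in place for a number of epochs (Adam,
cross-entropy, shuffled mini-batches drawn from a caller-supplied random
generator); another evaluates class scores in eval mode.  The federated
simulation, the sklearn-style estimator and the LL/CL harness all run
through these two entry points, which is what makes the single-client
federated run reproducible against plain sequential training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Tensor
from .models import CephNet
from .transforms import TransformConfig

__all__ = ["OptimizerConfig", "train_model", "predict_scores"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam hyperparameters (defaults: lr 0.001, batch 64)."""

    lr: float = 1e-3
    batch_size: int = 64
    betas: tuple[float, float] = (0.9, 0.999)


def _apply_train_transform(
    xb: np.ndarray, transform: TransformConfig | None, rng: np.random.Generator
) -> np.ndarray:
    if transform is None:
        return xb
    return np.stack([transform.train(img, rng) for img in xb])


def train_model(
    model: CephNet,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    opt_cfg: OptimizerConfig,
    rng: np.random.Generator,
    transform: TransformConfig | None = None,
    optimizer: Adam | None = None,
) -> list[float]:
    """Train ``model`` in place; returns the mean loss per epoch.

    ``x``: images (N, C, H, W) in [0, 1]; ``y``: integer class targets.
    A fresh Adam state is created unless ``optimizer`` is passed in.
    """
    n = len(x)
    if n == 0:
        raise ValueError("cannot train on an empty dataset")
    y = np.asarray(y, dtype=np.intp)
    opt = optimizer or Adam(model.parameters(), lr=opt_cfg.lr, betas=opt_cfg.betas)
    model.train()
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, opt_cfg.batch_size):
            idx = order[start : start + opt_cfg.batch_size]
            xb = _apply_train_transform(x[idx], transform, rng)
            opt.zero_grad()
            logits = model(Tensor(xb))
            loss = logits.cross_entropy(y[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return losses


def predict_scores(
    model: CephNet,
    x: np.ndarray,
    batch_size: int = 64,
    transform: TransformConfig | None = None,
) -> np.ndarray:
    """Class probabilities (softmax of logits) in eval mode, shape (N, K)."""
    model.eval()
    outs = []
    for start in range(0, len(x), batch_size):
        xb = x[start : start + batch_size]
        if transform is not None:
            xb = np.stack([transform.test(img) for img in xb])
        logits = model(Tensor(xb)).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        outs.append(e / e.sum(axis=1, keepdims=True))
    model.train()
    return np.concatenate(outs) if outs else np.zeros((0, model.spec.n_classes))
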