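"""A scikit-learn-compatible estimator around the convolutional classifiers.

``CephCNNClassifier`` wraps model construction, the Adam training loop and
softmax prediction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` surface, so the classifier composes with sklearn model
selection and pipelines.  The local-learning and centralized settings of the
experiment harness train through this class.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import BackboneConfig, ModelSpec, build_model, get_parameters, set_parameters
from .training import OptimizerConfig, predict_scores, train_model
from .transforms import TransformConfig

__all__ = ["CephCNNClassifier"]


class CephCNNClassifier(ClassifierMixin, BaseEstimator):
    """Dense convolutional classifier for cephalogram-style image arrays.

    Parameters
    ----------
    head : one of "plain", "ca", "sa", "se", "sa_se", "spp"
        Augmentation block appended to the backbone.
    backbone : "tiny" or "densenet121"
        Tiny ([2, 2] blocks, growth 8, 64x64, grayscale) is the desk-scale
        preset; densenet121 is the full 121-layer configuration.
    epochs, lr, batch_size : training-loop hyperparameters.
    transform : TransformConfig or None
        Data augmentation/normalization; ``None`` feeds images through as-is.
    seed : controls weight initialization and batch shuffling.

    Attributes
    ----------
    model_ : the trained network.
    classes_ : class labels seen in ``fit`` (target indices 0/1/2).
    history_ : mean training loss per epoch.
    """

    def __init__(
        self,
        head: str = "plain",
        backbone: str = "tiny",
        input_size: int = 64,
        epochs: int = 20,
        lr: float = 1e-3,
        batch_size: int = 64,
        reduction: int = 16,
        spp_sizes: tuple[int, ...] = (4, 8, 16),
        transform: TransformConfig | None = None,
        seed: int = 0,
    ):
        self.head = head
        self.backbone = backbone
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.reduction = reduction
        self.spp_sizes = spp_sizes
        self.transform = transform
        self.seed = seed

    def _make_spec(self, in_channels: int) -> ModelSpec:
        if self.backbone == "tiny":
            bb = BackboneConfig.tiny(in_channels=in_channels)
        elif self.backbone == "densenet121":
            bb = BackboneConfig.densenet121(in_channels=in_channels)
        else:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        return ModelSpec(
            backbone=bb,
            head=self.head,
            input_size=self.input_size,
            spp_sizes=tuple(self.spp_sizes),
            reduction=self.reduction,
        )

    @staticmethod
    def _check_images(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:  # (N, H, W) grayscale
            x = x[:, None, :, :]
        if x.ndim != 4:
            raise ValueError(f"expected images of shape (N, C, H, W), got {x.shape}")
        return x

    def fit(self, X, y):
        X = self._check_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.spec_ = self._make_spec(in_channels=X.shape[1])
        self.model_ = build_model(self.spec_, seed=self.seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7A31]))
        self.history_ = train_model(
            self.model_,
            X,
            y_idx,
            epochs=self.epochs,
            opt_cfg=OptimizerConfig(lr=self.lr, batch_size=self.batch_size),
            rng=rng,
            transform=self.transform,
        ) if self.epochs > 0 else []
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._check_images(X)
        return predict_scores(self.model_, X, self.batch_size, self.transform)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # federated plumbing: expose the full model state as a parameter vector
    def get_weights(self):
        check_is_fitted(self, "model_")
        return get_parameters(self.model_)

    def set_weights(self, vec) -> None:
        check_is_fitted(self, "model_")
        set_parameters(self.model_, vec)
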