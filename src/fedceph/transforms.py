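"""Image transform pipelines for training and evaluation.

Operates on float arrays of shape (C, H, W) scaled to [0, 1].  The default
full-scale pipeline mirrors common radiograph-classification practice:
random resized crop to the input size plus random horizontal flip during
training; resize to 256 then center crop during testing; channel
normalization in both.  Horizontal flip mirrors a lateral cephalogram's
facing direction, so the synthetic-data pipelines disable it by default
(`TransformConfig.minimal`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["TransformConfig", "IMAGENET_MEAN", "IMAGENET_STD"]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def _resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    if img.shape[1] == h and img.shape[2] == w:
        return img
    return np.stack(
        [_sk_resize(ch, (h, w), anti_aliasing=True, preserve_range=True) for ch in img]
    )


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    _, h, w = img.shape
    if h < size or w < size:
        img = _resize(img, max(h, size), max(w, size))
        _, h, w = img.shape
    top, left = (h - size) // 2, (w - size) // 2
    return img[:, top : top + size, left : left + size]


@dataclass(frozen=True)
class TransformConfig:
    """Configurable train/test transform pair.

    ``crop_scale`` is the area fraction range sampled by the random resized
    crop; ``resize_test`` is the shorter-side resize applied before the
    center crop at test time.
    """

    input_size: int = 224
    random_resized_crop: bool = True
    crop_scale: tuple[float, float] = (0.6, 1.0)
    horizontal_flip: bool = True
    resize_test: int = 256
    mean: tuple[float, ...] = (0.5,)
    std: tuple[float, ...] = (0.25,)

    @classmethod
    def paper_default(cls, input_size: int = 224) -> "TransformConfig":
        return cls(input_size=input_size, mean=IMAGENET_MEAN, std=IMAGENET_STD)

    @classmethod
    def minimal(cls, input_size: int = 64) -> "TransformConfig":
        """Normalize-only pipeline (no crop, no flip), for synthetic runs."""
        return cls(
            input_size=input_size,
            random_resized_crop=False,
            horizontal_flip=False,
            resize_test=input_size,
        )

    def _normalize(self, img: np.ndarray) -> np.ndarray:
        c = img.shape[0]
        mean = np.resize(np.asarray(self.mean), c)[:, None, None]
        std = np.resize(np.asarray(self.std), c)[:, None, None]
        return (img - mean) / std

    def train(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        size = self.input_size
        if self.random_resized_crop:
            _, h, w = img.shape
            for _ in range(10):
                area = h * w * rng.uniform(*self.crop_scale)
                aspect = np.exp(rng.uniform(np.log(3 / 4), np.log(4 / 3)))
                ch = int(round(np.sqrt(area / aspect)))
                cw = int(round(np.sqrt(area * aspect)))
                if 0 < ch <= h and 0 < cw <= w:
                    top = rng.integers(0, h - ch + 1)
                    left = rng.integers(0, w - cw + 1)
                    img = img[:, top : top + ch, left : left + cw]
                    break
            img = _resize(img, size, size)
        elif img.shape[1] != size or img.shape[2] != size:
            img = _resize(img, size, size)
        if self.horizontal_flip and rng.random() < 0.5:
            img = img[:, :, ::-1]
        return self._normalize(np.ascontiguousarray(img))

    def test(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        size = self.input_size
        if self.resize_test != size or img.shape[1] != size or img.shape[2] != size:
            _, h, w = img.shape
            scale = self.resize_test / min(h, w)
            img = _resize(img, int(round(h * scale)), int(round(w * scale)))
            img = _center_crop(img, size)
        return self._normalize(img)
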