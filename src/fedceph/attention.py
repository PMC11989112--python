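"""Attention and pyramid-pooling transforms on single feature maps.

These are the four augmentation blocks appended to the convolutional
backbone, expressed as pure numpy functions on a rank-3 feature map
``F`` of shape (C, H, W):

* channel attention — per-channel gates from spatially avg- and max-pooled
  descriptors passed through a shared one-hidden-layer MLP and summed before
  the sigmoid;
* spatial attention — an H x W gate from the channel-wise mean and max maps
  stacked and convolved with a single 7 x 7 kernel (stride 1, zero-padding 3);
* squeeze-and-excitation — global-average squeeze to a channel descriptor,
  then an FC -> ReLU -> FC -> sigmoid excitation producing per-channel scales;
* spatial pyramid pooling — adaptive average pooling to each grid size in the
  configuration, flattened and concatenated into a fixed-length vector.

The trainable model heads in :mod:`fedceph.models` implement the same math on
the autodiff engine; tests pin the two routes together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "SEParams",
    "SPPConfig",
    "channel_attention",
    "spatial_attention",
    "se_squeeze",
    "se_excite",
    "apply_block",
    "spp_pool",
    "adaptive_avg_pool",
    "hidden_width",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"feature map must be rank 3 (C,H,W), got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite entries")
    return f


def hidden_width(channels: int, reduction: int) -> int:
    """Bottleneck width C/r, clamped to at least one unit."""
    return max(1, channels // reduction)


@dataclass
class ChannelAttentionParams:
    """Shared-MLP weights for channel attention (hidden ReLU layer).

    ``w1``: (C/r, C), ``w2``: (C, C/r); the same MLP is applied to both the
    average- and max-pooled channel descriptors.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        hidden, c = self.w1.shape
        if self.w2.shape != (c, hidden) or self.b1.shape != (hidden,) or self.b2.shape != (c,):
            raise ValueError("inconsistent channel-attention parameter shapes")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def random(cls, channels: int, reduction: int = 16,
               rng: np.random.Generator | None = None) -> "ChannelAttentionParams":
        rng = rng or np.random.default_rng(0)
        h = hidden_width(channels, reduction)
        return cls(
            w1=rng.normal(0, 0.1, (h, channels)),
            b1=np.zeros(h),
            w2=rng.normal(0, 0.1, (channels, h)),
            b2=np.zeros(channels),
        )

    @classmethod
    def zeros(cls, channels: int, reduction: int = 16) -> "ChannelAttentionParams":
        h = hidden_width(channels, reduction)
        return cls(np.zeros((h, channels)), np.zeros(h), np.zeros((channels, h)), np.zeros(channels))


@dataclass
class SpatialAttentionParams:
    """7x7 convolution over the stacked [mean; max] channel descriptor."""

    kernel: np.ndarray  # (2, 7, 7)
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel.shape != (2, 7, 7):
            raise ValueError(
                f"spatial-attention kernel must be (2, 7, 7), got {self.kernel.shape}"
            )

    @classmethod
    def random(cls, rng: np.random.Generator | None = None) -> "SpatialAttentionParams":
        rng = rng or np.random.default_rng(0)
        return cls(kernel=rng.normal(0, 0.1, (2, 7, 7)), bias=0.0)

    @classmethod
    def zeros(cls) -> "SpatialAttentionParams":
        return cls(kernel=np.zeros((2, 7, 7)), bias=0.0)


@dataclass
class SEParams:
    """Squeeze-and-excitation weights: FC -> ReLU -> FC -> sigmoid."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        hidden, c = self.w1.shape
        if self.w2.shape != (c, hidden) or self.b1.shape != (hidden,) or self.b2.shape != (c,):
            raise ValueError("inconsistent squeeze-excitation parameter shapes")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def random(cls, channels: int, reduction: int = 16,
               rng: np.random.Generator | None = None) -> "SEParams":
        rng = rng or np.random.default_rng(0)
        h = hidden_width(channels, reduction)
        return cls(
            w1=rng.normal(0, 0.1, (h, channels)),
            b1=np.zeros(h),
            w2=rng.normal(0, 0.1, (channels, h)),
            b2=np.zeros(channels),
        )

    @classmethod
    def zeros(cls, channels: int, reduction: int = 16) -> "SEParams":
        h = hidden_width(channels, reduction)
        return cls(np.zeros((h, channels)), np.zeros(h), np.zeros((channels, h)), np.zeros(channels))


@dataclass(frozen=True)
class SPPConfig:
    """Pyramid grid sizes; strictly increasing, default [4, 8, 16]."""

    pooling_sizes: tuple[int, ...] = (4, 8, 16)

    def __post_init__(self) -> None:
        sizes = self.pooling_sizes
        if len(sizes) == 0:
            raise ValueError("pooling_sizes must be nonempty")
        if any(s < 1 for s in sizes) or any(
            b <= a for a, b in zip(sizes, sizes[1:])
        ):
            raise ValueError(f"pooling sizes must be strictly increasing positive, got {sizes}")

    @property
    def bins_per_channel(self) -> int:
        return int(sum(s * s for s in self.pooling_sizes))


def channel_attention(f: np.ndarray, p: ChannelAttentionParams) -> np.ndarray:
    """Per-channel attention weights in (0, 1), length C."""
    f = _check_feature_map(f)
    if f.shape[0] != p.channels:
        raise ValueError(f"feature map has {f.shape[0]} channels, params expect {p.channels}")
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))

    def mlp(v: np.ndarray) -> np.ndarray:
        return p.w2 @ np.maximum(p.w1 @ v + p.b1, 0.0) + p.b2

    return _sigmoid(mlp(avg) + mlp(mx))


def spatial_attention(f: np.ndarray, p: SpatialAttentionParams) -> np.ndarray:
    """Spatial attention map in (0, 1), shape (H, W) preserved by padding 3."""
    f = _check_feature_map(f)
    desc = np.stack([f.mean(axis=0), f.max(axis=0)])  # (2, H, W)
    padded = np.pad(desc, ((0, 0), (3, 3), (3, 3)))
    win = sliding_window_view(padded, (7, 7), axis=(1, 2))  # (2, H, W, 7, 7)
    conv = np.einsum("chwij,cij->hw", win, p.kernel)
    return _sigmoid(conv + p.bias)


def se_squeeze(f: np.ndarray) -> np.ndarray:
    """Global-average squeeze: per-channel spatial mean, length C."""
    f = _check_feature_map(f)
    return f.mean(axis=(1, 2))


def se_excite(z: np.ndarray, p: SEParams) -> np.ndarray:
    """Excitation scales in (0, 1): sigmoid(fc2(relu(fc1(z))))."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (p.channels,):
        raise ValueError(f"descriptor length {z.shape} does not match {p.channels} channels")
    return _sigmoid(p.w2 @ np.maximum(p.w1 @ z + p.b1, 0.0) + p.b2)


def apply_block(
    f: np.ndarray,
    block: str,
    ca: ChannelAttentionParams | None = None,
    sa: SpatialAttentionParams | None = None,
    se: SEParams | None = None,
) -> np.ndarray:
    """Rescale ``f`` by a block's attention values (same output shape).

    ``block`` is one of ``"ca"``, ``"sa"``, ``"se"``, ``"sa_se"``.  Channel
    gates broadcast over H x W; the spatial gate broadcasts over channels.
    ``"sa_se"`` applies spatial attention first, then squeeze-excitation on
    the rescaled map.
    """
    f = _check_feature_map(f)
    block = block.lower()
    if block == "ca":
        if ca is None:
            raise ValueError("channel-attention parameters not initialized")
        return f * channel_attention(f, ca)[:, None, None]
    if block == "sa":
        if sa is None:
            raise ValueError("spatial-attention parameters not initialized")
        return f * spatial_attention(f, sa)[None, :, :]
    if block == "se":
        if se is None:
            raise ValueError("squeeze-excitation parameters not initialized")
        return f * se_excite(se_squeeze(f), se)[:, None, None]
    if block == "sa_se":
        return apply_block(apply_block(f, "sa", sa=sa), "se", se=se)
    raise ValueError(f"unknown block {block!r}")


def adaptive_avg_pool(f: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Adaptive average pooling of (C,H,W) to (C,out_h,out_w).

    Bin ``b`` spans rows ``floor(b*H/out_h)`` to ``ceil((b+1)*H/out_h)``
    (half-open), likewise for columns; when the input is smaller than the
    grid, bins overlap/repeat rows.
    """
    f = _check_feature_map(f)
    c, h, w = f.shape
    out = np.empty((c, out_h, out_w))
    for bi in range(out_h):
        r0, r1 = int(np.floor(bi * h / out_h)), int(np.ceil((bi + 1) * h / out_h))
        for bj in range(out_w):
            c0, c1 = int(np.floor(bj * w / out_w)), int(np.ceil((bj + 1) * w / out_w))
            out[:, bi, bj] = f[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return out


def spp_pool(f: np.ndarray, cfg: SPPConfig = SPPConfig()) -> np.ndarray:
    """Fixed-length pyramid descriptor: length C * sum(s_i^2) for any H, W."""
    f = _check_feature_map(f)
    parts = [adaptive_avg_pool(f, s, s).ravel() for s in cfg.pooling_sizes]
    return np.concatenate(parts)
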