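"""Classifier architectures: densely connected backbone plus augmented heads.

The backbone is a DenseNet-style network: a 7x7/stride-2 stem with 3x3
max pooling, dense blocks whose layers each concatenate their ``growth_rate``
new channels onto everything before them (bottleneck 1x1 at four times the
growth rate), and transition layers (1x1 convolution at compression 0.5 plus
2x2 average pooling) between blocks.  The standard preset uses block layout
[6, 12, 24, 16] with growth 32 — the 121-layer configuration ending in a
1024-channel feature map — and a "tiny" preset ([2, 2], growth 8, 64x64
grayscale input) supports CPU-scale experiments.

Six head variants attach to the final feature map: ``plain`` (global average
pooling + FC), ``ca``/``sa``/``se``/``sa_se`` (the attention block rescales
the feature map, then global average pooling + FC), and ``spp`` (spatial
pyramid pooling straight into an FC sized by :func:`fc_input_size`).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import SPPConfig, hidden_width
from .nn import Tensor

__all__ = [
    "BackboneConfig",
    "ModelSpec",
    "HEADS",
    "CephNet",
    "build_model",
    "fc_input_size",
    "get_parameters",
    "set_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "ParameterVector",
]

HEADS = ("plain", "ca", "sa", "se", "sa_se", "spp")

#: A model's full trainable state: ordered (name, array) pairs covering every
#: weight and every batch-norm running statistic.  Ordering is deterministic
#: and identical across models built from the same spec — the contract the
#: federated averaging relies on.
ParameterVector = list[tuple[str, np.ndarray]]


@dataclass(frozen=True)
class BackboneConfig:
    block_layout: tuple[int, ...] = (6, 12, 24, 16)
    growth_rate: int = 32
    compression: float = 0.5
    in_channels: int = 3

    @classmethod
    def densenet121(cls, in_channels: int = 3) -> "BackboneConfig":
        return cls((6, 12, 24, 16), 32, 0.5, in_channels)

    @classmethod
    def tiny(cls, in_channels: int = 1) -> "BackboneConfig":
        """Desk-scale preset for 64x64 grayscale inputs."""
        return cls((2, 2), 8, 0.5, in_channels)

    def channel_trace(self) -> tuple[list[int], int]:
        """Per-dense-block output channel counts and the final channel count."""
        c = 2 * self.growth_rate  # stem output
        per_block = []
        for i, n_layers in enumerate(self.block_layout):
            c = c + n_layers * self.growth_rate
            per_block.append(c)
            if i < len(self.block_layout) - 1:
                c = int(c * self.compression)
        return per_block, c


@dataclass(frozen=True)
class ModelSpec:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    head: str = "plain"
    n_classes: int = 3
    input_size: int = 224
    spp_sizes: tuple[int, ...] = (4, 8, 16)
    reduction: int = 16
    sa_se_order: tuple[str, ...] = ("sa", "se")

    def __post_init__(self) -> None:
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}, got {self.head!r}")
        SPPConfig(tuple(self.spp_sizes))  # validates
        n_down = 2 + (len(self.backbone.block_layout) - 1)  # stem+pool, transitions
        if self.input_size // (2**n_down) < 1:
            raise ValueError(
                f"input size {self.input_size} too small for "
                f"{len(self.backbone.block_layout)} dense blocks"
            )

    @classmethod
    def tiny(cls, head: str = "plain", **kw) -> "ModelSpec":
        return cls(backbone=BackboneConfig.tiny(), head=head, input_size=64, **kw)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["backbone"] = BackboneConfig(
            block_layout=tuple(d["backbone"]["block_layout"]),
            growth_rate=d["backbone"]["growth_rate"],
            compression=d["backbone"]["compression"],
            in_channels=d["backbone"]["in_channels"],
        )
        d["spp_sizes"] = tuple(d["spp_sizes"])
        d["sa_se_order"] = tuple(d["sa_se_order"])
        return cls(**d)


def fc_input_size(final_channels: int, spp_sizes) -> int:
    """Width of the FC layer fed by the pyramid pooling: C * sum(s_i^2)."""
    sizes = tuple(spp_sizes)
    if len(sizes) == 0:
        raise ValueError("spp_sizes must be nonempty")
    if final_channels < 1 or any(s < 1 for s in sizes):
        raise ValueError("channel count and pooling sizes must be positive")
    return final_channels * sum(s * s for s in sizes)


# ---------------------------------------------------------------------------
# backbone blocks
# ---------------------------------------------------------------------------


class _DenseLayer(nn.Module):
    def __init__(self, in_channels: int, growth: int, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_channels)
        self.conv1 = nn.Conv2d(in_channels, 4 * growth, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(4 * growth)
        self.conv2 = nn.Conv2d(4 * growth, growth, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(self.bn1(x).relu())
        y = self.conv2(self.bn2(y).relu())
        return Tensor.concat([x, y], axis=1)


class _DenseBlock(nn.Module):
    def __init__(self, in_channels: int, n_layers: int, growth: int, rng):
        super().__init__()
        layers = []
        c = in_channels
        for i in range(n_layers):
            layer = _DenseLayer(c, growth, rng)
            setattr(self, f"layer{i}", layer)
            layers.append(layer)
            c += growth
        self._layers = layers
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        for layer in self._layers:
            x = layer(x)
        return x


class _Transition(nn.Module):
    def __init__(self, in_channels: int, compression: float, rng):
        super().__init__()
        self.out_channels = int(in_channels * compression)
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, self.out_channels, 1, rng=rng)
        self.pool = nn.AvgPool2d(2, 2)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.conv(self.bn(x).relu()))


class _Backbone(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng):
        super().__init__()
        g = cfg.growth_rate
        self.stem_conv = nn.Conv2d(cfg.in_channels, 2 * g, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(2 * g)
        self.stem_pool = nn.MaxPool2d(3, 2, padding=1)
        c = 2 * g
        self.block_channels: list[int] = []
        blocks = []
        for i, n_layers in enumerate(cfg.block_layout):
            block = _DenseBlock(c, n_layers, g, rng)
            setattr(self, f"block{i}", block)
            blocks.append(block)
            c = block.out_channels
            self.block_channels.append(c)
            if i < len(cfg.block_layout) - 1:
                trans = _Transition(c, cfg.compression, rng)
                setattr(self, f"transition{i}", trans)
                blocks.append(trans)
                c = trans.out_channels
        self._sequence = blocks
        self.final_bn = nn.BatchNorm2d(c)
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_pool(self.stem_bn(self.stem_conv(x)).relu())
        for block in self._sequence:
            x = block(x)
        return self.final_bn(x).relu()


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


class ChannelAttentionHead(nn.Module):
    """Shared-MLP channel gate from spatial average- and max-pooling."""

    def __init__(self, channels: int, reduction: int, rng):
        super().__init__()
        h = hidden_width(channels, reduction)
        self.fc1 = nn.Linear(channels, h, rng=rng)
        self.fc2 = nn.Linear(h, channels, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        gate = (self._mlp(x.mean((2, 3))) + self._mlp(x.amax((2, 3)))).sigmoid()
        return x * gate.reshape(n, c, 1, 1)


class SpatialAttentionHead(nn.Module):
    """7x7 convolutional gate over the stacked channel mean/max maps."""

    def __init__(self, rng):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 7, padding=3, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        desc = Tensor.concat([x.mean(1, keepdims=True), x.amax(1, keepdims=True)], axis=1)
        gate = self.conv(desc).sigmoid()  # (N, 1, H, W) broadcasts over channels
        return x * gate


class SEHead(nn.Module):
    """Squeeze-and-excitation channel recalibration."""

    def __init__(self, channels: int, reduction: int, rng):
        super().__init__()
        h = hidden_width(channels, reduction)
        self.fc1 = nn.Linear(channels, h, rng=rng)
        self.fc2 = nn.Linear(h, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        z = x.mean((2, 3))
        s = self.fc2(self.fc1(z).relu()).sigmoid()
        return x * s.reshape(n, c, 1, 1)


class SPPPool(nn.Module):
    """Batched spatial pyramid pooling to a fixed-length vector."""

    def __init__(self, sizes: tuple[int, ...]):
        super().__init__()
        self.sizes = tuple(sizes)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        parts = [
            x.adaptive_avg_pool2d(s, s).reshape(n, c * s * s) for s in self.sizes
        ]
        return Tensor.concat(parts, axis=1)


class CephNet(nn.Module):
    """Backbone + head: batch of images (N,C,H,W) -> class logits (N,K)."""

    def __init__(self, spec: ModelSpec, seed: int):
        super().__init__()
        self.spec = spec
        ss = np.random.SeedSequence([int(seed), 0x5EED])
        rng_backbone, rng_head, rng_fc = (np.random.default_rng(c) for c in ss.spawn(3))
        self.backbone = _Backbone(spec.backbone, rng_backbone)
        c = self.backbone.out_channels
        self.attn_modules: list[nn.Module] = []
        if spec.head in ("ca",):
            self.attn_ca = ChannelAttentionHead(c, spec.reduction, rng_head)
            self.attn_modules = [self.attn_ca]
        elif spec.head == "sa":
            self.attn_sa = SpatialAttentionHead(rng_head)
            self.attn_modules = [self.attn_sa]
        elif spec.head == "se":
            self.attn_se = SEHead(c, spec.reduction, rng_head)
            self.attn_modules = [self.attn_se]
        elif spec.head == "sa_se":
            self.attn_sa = SpatialAttentionHead(rng_head)
            self.attn_se = SEHead(c, spec.reduction, rng_head)
            order = {"sa": self.attn_sa, "se": self.attn_se}
            self.attn_modules = [order[k] for k in spec.sa_se_order]
        if spec.head == "spp":
            self.spp = SPPPool(spec.spp_sizes)
            fc_in = fc_input_size(c, spec.spp_sizes)
        else:
            self.gap = nn.AdaptiveAvgPool2d(1)
            fc_in = c
        self.fc = nn.Linear(fc_in, spec.n_classes, rng=rng_fc)
        self.final_channels = c

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        f = self.backbone(x)
        for attn in self.attn_modules:
            f = attn(f)
        if self.spec.head == "spp":
            v = self.spp(f)
        else:
            n = f.shape[0]
            v = self.gap(f).reshape(n, self.final_channels)
        return self.fc(v)


def build_model(spec: ModelSpec, seed: int = 0) -> CephNet:
    """Build a classifier; identical spec + seed give bit-identical weights."""
    return CephNet(spec, seed)


# ---------------------------------------------------------------------------
# parameter vectors and checkpoints
# ---------------------------------------------------------------------------


def get_parameters(model: CephNet) -> ParameterVector:
    """Copy the full model state (weights + batch-norm buffers), ordered."""
    vec: ParameterVector = [
        (f"param:{name}", p.data.copy()) for name, p in model.named_parameters()
    ]
    vec += [(f"buffer:{name}", b.copy()) for name, b in model.named_buffers()]
    return vec


def set_parameters(model: CephNet, vec: ParameterVector) -> None:
    """Load a parameter vector; errors name the first mismatching array."""
    params = dict(model.named_parameters())
    buffers = dict(model.named_buffers())
    expected = [f"param:{n}" for n in params] + [f"buffer:{n}" for n in buffers]
    got = [name for name, _ in vec]
    if got != expected:
        for e, g in zip(expected, got):
            if e != g:
                raise ValueError(f"parameter vector mismatch: expected {e!r}, got {g!r}")
        raise ValueError(
            f"parameter vector length mismatch: expected {len(expected)}, got {len(got)}"
        )
    for name, arr in vec:
        kind, key = name.split(":", 1)
        target = params[key].data if kind == "param" else buffers[key]
        if target.shape != arr.shape:
            raise ValueError(
                f"shape mismatch for {name}: model {target.shape}, vector {arr.shape}"
            )
        target[...] = arr


def save_checkpoint(model: CephNet, seed: int, path: str | Path) -> None:
    """Single-archive checkpoint: spec JSON + every named array."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vec = get_parameters(model)
    buf = io.BytesIO()
    np.savez(buf, **{name: arr for name, arr in vec})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("spec.json", json.dumps({"spec": json.loads(model.spec.to_json()), "seed": seed, "order": [n for n, _ in vec]}))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> CephNet:
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("spec.json"))
        with np.load(io.BytesIO(zf.read("arrays.npz"))) as arrs:
            vec = [(name, arrs[name]) for name in meta["order"]]
    spec = ModelSpec.from_json(json.dumps(meta["spec"]))
    model = build_model(spec, seed=meta["seed"])
    set_parameters(model, vec)
    return model
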