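"""The modified 3D ResNet-50 difficulty classifier.

Backbone changes relative to a plain residual network, all motivated by the
task being a *positional* one (the classifier must read distances between
bone structures out of a binary mask):

* a Convolutional Block Attention Module (CBAM) — channel attention followed
  by spatial attention — refines the output of every residual block;
* every pooling layer is replaced by a convolution; all stride-2 convolutions
  use an even kernel so downsampling introduces no half-voxel position offset;
* the global-average-pooling head is replaced by a 1x1x1 "shrink" convolution
  plus stride-2 even-kernel convolutions down to spatial size 1, preserving
  positional information into the feature vector;
* normalized clinical covariates (BMI, sex, neoadjuvant therapy) pass through
  a linear layer whose output re-weights the image feature vector elementwise
  before the dropout + linear classifier produces a single logit, mapped to a
  score in (0,1) by a sigmoid.

Two presets are provided: ``full`` mirrors ResNet-50 (block counts 3,4,6,3)
for realistic volume sizes, and ``desk`` is a small configuration with the
same operator set for laptop-scale experiments on 32^3 phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import (
    BatchNorm3d,
    Conv3d,
    DownsampleConv3d,
    Dropout,
    Linear,
    Module,
    Tensor,
    concat,
    max_axes,
    mean_axes,
    relu,
    reshape,
    sigmoid,
)

__all__ = [
    "NetworkConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "Bottleneck",
    "ShrinkHead",
    "DifficultyNet",
    "ForwardResult",
    "desk_config",
    "full_config",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the modified 3D residual classifier."""

    input_shape: tuple[int, int, int] = (32, 32, 32)
    stem_width: int = 8
    stem_kernel: int = 4
    stage_block_counts: tuple[int, int, int, int] = (1, 1, 1, 1)
    stage_channel_widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    bottleneck_divisor: int = 2
    channel_attention_reduction: int = 4
    spatial_attention_kernel: int = 3
    dropout_rate: float = 0.5
    clinical_dim: int = 3
    downsample_kernel: int = 2
    shrink_width: int = 32

    def validate(self) -> None:
        if self.downsample_kernel % 2 != 0 or self.stem_kernel % 2 != 0:
            raise ConfigurationError("stride-2 kernels must be even")
        if self.spatial_attention_kernel % 2 != 1:
            raise ConfigurationError("spatial-attention kernel must be odd")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        for w in self.stage_channel_widths:
            if w % self.channel_attention_reduction != 0:
                raise ConfigurationError(
                    f"stage width {w} not divisible by attention reduction {self.channel_attention_reduction}"
                )
        if len(self.stage_block_counts) != 4 or len(self.stage_channel_widths) != 4:
            raise ConfigurationError("exactly four stages are expected")
        final = self.final_spatial()
        if final < 1 or 2 ** int(math.log2(final)) != final:
            raise ConfigurationError(
                f"input shape {self.input_shape} leaves non-power-of-two spatial size {final} for the head"
            )

    def final_spatial(self) -> int:
        n = min(self.input_shape)
        if max(self.input_shape) != n:
            raise ConfigurationError("cubic input volumes are expected")
        # stem halves once; stages 2-4 halve once each
        if n % 16 != 0:
            raise ConfigurationError("input side must be divisible by 16")
        return n // 16


def desk_config() -> NetworkConfig:
    """Small preset exercising every operator on 32^3 inputs."""
    return NetworkConfig()


def full_config(input_side: int = 128) -> NetworkConfig:
    """ResNet-50-scale preset for realistic volume sizes."""
    return NetworkConfig(
        input_shape=(input_side, input_side, input_side),
        stem_width=64,
        stem_kernel=8,
        stage_block_counts=(3, 4, 6, 3),
        stage_channel_widths=(256, 512, 1024, 2048),
        bottleneck_divisor=4,
        channel_attention_reduction=16,
        spatial_attention_kernel=7,
        dropout_rate=0.5,
        shrink_width=256,
    )


class ChannelAttention(Module):
    """Per-channel gate from global max- and average-pooled descriptors.

    Both descriptors pass through a shared two-layer bottleneck and are summed
    before the sigmoid, so each channel receives one weight in (0,1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ConfigurationError(f"channels {channels} not divisible by reduction {reduction}")
        self.fc1 = Linear(channels, channels // reduction, rng=rng)
        self.fc2 = Linear(channels // reduction, channels, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        avg = mean_axes(x, (2, 3, 4))
        mx = max_axes(x, (2, 3, 4))
        gate = sigmoid(self.fc2(relu(self.fc1(avg))) + self.fc2(relu(self.fc1(mx))))
        n, c = gate.data.shape
        return reshape(gate, (n, c, 1, 1, 1))


class SpatialAttention(Module):
    """Per-voxel gate from the channelwise max and mean maps, one odd-kernel conv."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ConfigurationError("spatial-attention kernel must be odd")
        self.conv = Conv3d(2, 1, kernel, padding=(kernel - 1) // 2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        avg = mean_axes(x, (1,), keepdims=True)
        mx = max_axes(x, (1,), keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))


class CBAM(Module):
    """Convolutional Block Attention Module: channel gate first, then spatial gate."""

    def __init__(self, channels: int, reduction: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        refined = x * self.channel(x)
        return refined * self.spatial(refined)


class Bottleneck(Module):
    """1-3-1 bottleneck residual block with CBAM before the residual addition."""

    def __init__(self, cin: int, cout: int, mid: int, downsample: bool,
                 reduction: int, sa_kernel: int, ds_kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(cin, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm3d(mid)
        if downsample:
            self.conv2 = DownsampleConv3d(mid, mid, kernel=ds_kernel, rng=rng)
        else:
            self.conv2 = Conv3d(mid, mid, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm3d(mid)
        self.conv3 = Conv3d(mid, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm3d(cout)
        self.cbam = CBAM(cout, reduction, sa_kernel, rng)
        self.has_shortcut_conv = downsample or cin != cout
        if self.has_shortcut_conv:
            if downsample:
                self.shortcut = DownsampleConv3d(cin, cout, kernel=ds_kernel, rng=rng)
            else:
                self.shortcut = Conv3d(cin, cout, 1, bias=False, rng=rng)
            self.bn_sc = BatchNorm3d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.bn1(self.conv1(x)))
        h = relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        h = self.cbam(h)
        sc = self.bn_sc(self.shortcut(x)) if self.has_shortcut_conv else x
        return relu(h + sc)


class ShrinkHead(Module):
    """1x1x1 channel-shrink conv, then stride-2 even-kernel convs to spatial size 1.

    Replaces global average pooling so the feature vector keeps positional
    information; requires a power-of-two final spatial size.
    """

    def __init__(self, cin: int, shrink: int, spatial: int, ds_kernel: int, rng: np.random.Generator):
        super().__init__()
        if spatial < 1 or 2 ** int(math.log2(spatial)) != spatial:
            raise ShapeError(f"head requires a power-of-two spatial size, got {spatial}")
        self.shrink = Conv3d(cin, shrink, 1, bias=False, rng=rng)
        self.bn = BatchNorm3d(shrink)
        self.n_down = int(math.log2(spatial))
        for i in range(self.n_down):
            setattr(self, f"down{i}", DownsampleConv3d(shrink, shrink, kernel=ds_kernel, rng=rng))
        self.out_dim = shrink

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.bn(self.shrink(x)))
        for i in range(self.n_down):
            h = relu(getattr(self, f"down{i}")(h))
        n = h.data.shape[0]
        if h.data.shape[2:] != (1, 1, 1):
            raise ShapeError(f"head did not reach spatial size 1: {h.data.shape}")
        return reshape(h, (n, self.out_dim))


@dataclass
class ForwardResult:
    score: Tensor
    logit: Tensor
    stages: dict[str, Tensor]
    features: Tensor


class DifficultyNet(Module):
    """Image + clinical difficulty classifier; ``forward`` returns a score in (0,1)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ds = config.downsample_kernel
        self.stem = DownsampleConv3d(1, config.stem_width, kernel=config.stem_kernel, rng=rng)
        self.stem_bn = BatchNorm3d(config.stem_width)
        cin = config.stem_width
        for s, (blocks, width) in enumerate(zip(config.stage_block_counts, config.stage_channel_widths), start=1):
            mid = max(1, width // config.bottleneck_divisor)
            for b in range(blocks):
                block = Bottleneck(
                    cin=cin,
                    cout=width,
                    mid=mid,
                    downsample=(b == 0 and s > 1),
                    reduction=config.channel_attention_reduction,
                    sa_kernel=config.spatial_attention_kernel,
                    ds_kernel=ds,
                    rng=rng,
                )
                setattr(self, f"layer{s}_{b}", block)
                cin = width
        self.head = ShrinkHead(cin, config.shrink_width, config.final_spatial(), ds, rng=rng)
        self.reweight = Linear(config.clinical_dim, config.shrink_width, rng=rng)
        self.dropout = Dropout(config.dropout_rate)
        self.dropout.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        self.classifier = Linear(config.shrink_width, 1, rng=rng)

    # ------------------------------------------------------------------
    def forward(self, volume: np.ndarray, clinical: np.ndarray) -> ForwardResult:
        """Full forward pass.

        ``volume``: (N, 1, D, H, W) float array (a binary mask cast to float);
        ``clinical``: (N, 3) normalized covariates.  Stage outputs are kept in
        the result so attention maps can read features and gradients.
        """
        x = np.asarray(volume, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.config.input_shape):
            raise ShapeError(f"expected input shape {self.config.input_shape}, got {x.shape[2:]}")
        clin = np.asarray(clinical, dtype=np.float32).reshape(x.shape[0], self.config.clinical_dim)

        h = relu(self.stem_bn(self.stem(Tensor(x))))
        stages: dict[str, Tensor] = {}
        for s, blocks in enumerate(self.config.stage_block_counts, start=1):
            for b in range(blocks):
                h = getattr(self, f"layer{s}_{b}")(h)
            stages[f"layer{s}"] = h
        feats = self.head(h)
        fused = feats * self.reweight(Tensor(clin))
        logit = self.classifier(self.dropout(fused))
        return ForwardResult(score=sigmoid(logit), logit=logit, stages=stages, features=feats)

    def predict_scores(self, volumes: np.ndarray, clinical: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Deterministic evaluation-mode scores for a stack of cases."""
        was_training = self.training
        self.eval()
        out = []
        volumes = np.asarray(volumes, dtype=np.float32)
        for i in range(0, len(volumes), batch_size):
            res = self.forward(volumes[i : i + batch_size], clinical[i : i + batch_size])
            out.append(res.score.data.reshape(-1))
        if was_training:
            self.train()
        return np.concatenate(out)

    def cbam_count(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, CBAM))

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def contains_pooling(model: Module) -> bool:
    """Graph inspection: True if any instantiated module is a pooling layer."""
    return any("pool" in type(m).__name__.lower() for m in model.modules())
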