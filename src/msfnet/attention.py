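"""Channel and spatial attention gating (CBAM).

The convolutional block attention module recalibrates a feature map in two
sequential multiplicative steps:

* **channel attention** — global max- and average-pooled channel descriptors
  are passed through one *shared* two-layer bottleneck MLP (ReLU in the
  middle, no biases), summed, and squashed by a sigmoid into per-channel
  weights in (0, 1);
* **spatial attention** — the channel-wise max and mean maps are stacked
  into a 2-channel image, reduced to one channel by a single odd-sized
  convolution, and sigmoid-squashed into per-pixel weights.

Channel gating is applied first, spatial gating second; both broadcast over
the axes they do not index, so the output shape always equals the input
shape and never exceeds it in absolute value.

Two call surfaces are provided: the module classes operate on batched
autograd tensors (N, C, H, W) inside networks, while :meth:`attend` /
:meth:`gate` accept a single plain (C, H, W) array for analysis use.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .nn import Tensor, cat


def validate_feature_map(f: np.ndarray) -> np.ndarray:
    """Check a (C, H, W) feature map: rank 3, positive extents, finite."""
    f = np.asarray(f, dtype=np.float32)
    if f.ndim != 3:
        raise ValidationError(f"feature map must have shape (C, H, W); got rank {f.ndim}")
    if min(f.shape) < 1:
        raise ValidationError(f"feature map extents must be >= 1; got {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValidationError("feature map contains non-finite values")
    return f


class ChannelAttention(nn.Module):
    """Per-channel gate: sigmoid(MLP(maxpool) + MLP(avgpool)), shared MLP.

    The bottleneck width is ``max(1, channels // reduction_ratio)``; channel
    counts need not be divisible by the ratio.
    """

    def __init__(
        self,
        channels: int,
        reduction_ratio: int = 16,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if reduction_ratio < 1:
            raise ConfigurationError(f"reduction_ratio must be >= 1, got {reduction_ratio}")
        self.channels = channels
        self.reduction_ratio = reduction_ratio
        hidden = max(1, channels // reduction_ratio)
        self.fc1 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> channel weights (N, C, 1, 1), entries in (0, 1)."""
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        z = self._mlp(avg) + self._mlp(mx)
        return z.sigmoid().reshape(n, c, 1, 1)

    def attend(self, f: np.ndarray) -> np.ndarray:
        """Weights for a single (C, H, W) map, returned as a length-C vector."""
        f = validate_feature_map(f)
        if f.shape[0] != self.channels:
            raise ValidationError(f"expected {self.channels} channels, got {f.shape[0]}")
        w = self.forward(Tensor(f[None]))
        return w.data.reshape(-1)


class SpatialAttention(nn.Module):
    """Per-pixel gate from channel-wise max/mean maps through one convolution."""

    def __init__(self, kernel_size: int = 7, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ConfigurationError(f"kernel_size must be odd and positive, got {kernel_size}")
        self.kernel_size = kernel_size
        self.conv = nn.Conv2d(2, 1, kernel_size, padding=kernel_size // 2, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> spatial weights (N, 1, H, W), entries in (0, 1)."""
        mx = x.max(axis=1, keepdims=True)
        avg = x.mean(axis=1, keepdims=True)
        stacked = cat([mx, avg], axis=1)
        return self.conv(stacked).sigmoid()

    def attend(self, f: np.ndarray) -> np.ndarray:
        """Weights for a single (C, H, W) map, returned as an (H, W) array."""
        f = validate_feature_map(f)
        w = self.forward(Tensor(f[None]))
        return w.data.reshape(f.shape[1], f.shape[2])


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention gating; shape preserving."""

    def __init__(
        self,
        channels: int,
        reduction_ratio: int = 16,
        spatial_kernel: int = 7,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction_ratio, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel(x)
        return x * self.spatial(x)

    def gate(self, f: np.ndarray) -> np.ndarray:
        """Gate a single (C, H, W) map; returns an array of identical shape."""
        f = validate_feature_map(f)
        out = self.forward(Tensor(f[None]))
        return out.data[0]


def channel_attention(
    f: np.ndarray,
    reduction_ratio: int = 16,
    module: Optional[ChannelAttention] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Convenience wrapper: channel-attention weights for one feature map.

    If ``module`` is given its (trained) parameters are used and
    ``reduction_ratio`` is ignored; otherwise a freshly initialized gate is
    built from ``rng``.
    """
    f = validate_feature_map(f)
    if module is None:
        module = ChannelAttention(f.shape[0], reduction_ratio, rng=rng)
    return module.attend(f)


def spatial_attention(
    f: np.ndarray,
    kernel_size: int = 7,
    module: Optional[SpatialAttention] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Convenience wrapper: spatial-attention weights for one feature map."""
    f = validate_feature_map(f)
    if module is None:
        module = SpatialAttention(kernel_size, rng=rng)
    return module.attend(f)


def cbam(
    f: np.ndarray,
    reduction_ratio: int = 16,
    spatial_kernel: int = 7,
    module: Optional[CBAM] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Convenience wrapper: CBAM-gated copy of one (C, H, W) feature map."""
    f = validate_feature_map(f)
    if module is None:
        module = CBAM(f.shape[0], reduction_ratio, spatial_kernel, rng=rng)
    return module.gate(f)
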