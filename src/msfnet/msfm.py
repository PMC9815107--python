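"""Multi-scale fusion module (MSFM).

The block recalibrates a feature map with CBAM, then extracts context at
several scales with parallel 3×3 *dilated* convolutions (rates 1, 2 and 4 by
default).  A dilated kernel spaces its taps ``r`` pixels apart, so a 3×3
kernel at rate 2 covers the same 5×5 neighbourhood as an ordinary 5×5 kernel
while keeping just 9 weights per channel pair.  The branch outputs are fused
by channel concatenation followed by a 1×1 dimensionality-reducing
convolution (an elementwise-sum fusion mode is available behind a flag).

Each branch pads by its dilation rate so every branch preserves the spatial
extent and the fused maps align pixel-for-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .attention import CBAM, validate_feature_map
from .errors import ConfigurationError, ValidationError
from .nn import Tensor, cat


def dilated_kernel_size(k: int, r: int) -> int:
    """Side length of the bounding box of a k×k kernel's taps at dilation r.

    ``k_d = k + (k-1)(r-1)``.  For k=3, r=2 this gives 5: the dilated 3×3
    kernel spans the same 5×5 window as a dense 5×5 kernel.
    """
    if k < 1 or k % 2 == 0:
        raise ValidationError(f"kernel size must be odd and >= 1, got {k}")
    if r < 1:
        raise ValidationError(f"dilation rate must be >= 1, got {r}")
    return k + (k - 1) * (r - 1)


def receptive_field_side(k: int, r: int) -> int:
    """Alternative receptive-field formula ``(k+1)(r-1) + k``.

    Retained for reference only: for k=3, r=2 it yields 7, which disagrees
    with the tap bounding box (5) that a single dilated convolution actually
    covers.  Nothing in this package derives padding or footprints from it;
    use :func:`dilated_kernel_size` instead.
    """
    if k < 1 or r < 1:
        raise ValidationError("k and r must be >= 1")
    return (k + 1) * (r - 1) + k


@dataclass(frozen=True)
class DilationSpec:
    """A kernel/dilation pair with its derived geometric quantities."""

    k: int
    r: int
    k_d: int = field(init=False)
    r_f: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "k_d", dilated_kernel_size(self.k, self.r))
        object.__setattr__(self, "r_f", receptive_field_side(self.k, self.r))


class DilatedBranch(nn.Module):
    """One 3×3 convolution branch at dilation ``rate``, 'same' padded.

    The tap count per input/output channel pair is 9 regardless of the rate;
    only the spacing of the taps changes.  Optionally followed by batch norm
    and swish, matching the backbone's conv blocks.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rate: int,
        kernel_size: int = 3,
        norm_act: bool = True,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if rate < 1:
            raise ValidationError(f"dilation rate must be >= 1, got {rate}")
        self.rate = rate
        pad = (dilated_kernel_size(kernel_size, rate) - 1) // 2
        self.conv = nn.Conv2d(
            in_channels, out_channels, kernel_size,
            padding=pad, dilation=rate, bias=bias, rng=rng,
        )
        self.norm = nn.BatchNorm2d(out_channels) if norm_act else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x).swish()
        return x


class MultiScaleFusion(nn.Module):
    """CBAM recalibration + parallel dilated branches + fusion.

    Parameters
    ----------
    in_channels:
        Channels of the incoming feature map.
    branch_channels, out_channels:
        Width of each dilated branch and of the fused output; both default
        to ``in_channels`` so the module is drop-in shape preserving.
    rates:
        Dilation rates of the parallel branches (default ``(1, 2, 4)``).
    fusion:
        ``"concat"`` — channel concatenation then a 1×1 reduction to
        ``out_channels``; ``"sum"`` — elementwise sum of equal-width branches
        (requires ``branch_channels == out_channels``).
    """

    def __init__(
        self,
        in_channels: int,
        branch_channels: Optional[int] = None,
        out_channels: Optional[int] = None,
        rates: Sequence[int] = (1, 2, 4),
        fusion: str = "concat",
        reduction_ratio: int = 16,
        spatial_kernel: int = 7,
        norm_act: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        branch_channels = in_channels if branch_channels is None else branch_channels
        out_channels = in_channels if out_channels is None else out_channels
        if fusion not in ("concat", "sum"):
            raise ConfigurationError(f"unknown fusion mode: {fusion!r}")
        if fusion == "sum" and branch_channels != out_channels:
            raise ConfigurationError("sum fusion requires branch_channels == out_channels")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.rates = tuple(int(r) for r in rates)
        self.fusion = fusion
        self.cbam = CBAM(in_channels, reduction_ratio, spatial_kernel, rng=rng)
        self.branches = nn.ModuleList(
            DilatedBranch(in_channels, branch_channels, r, norm_act=norm_act, rng=rng)
            for r in self.rates
        )
        if fusion == "concat":
            self.reduce = nn.Conv2d(
                branch_channels * len(self.rates), out_channels, 1, bias=False, rng=rng
            )
            self.reduce_norm = nn.BatchNorm2d(out_channels) if norm_act else None
        else:
            self.reduce = None
            self.reduce_norm = None

    def forward(self, x: Tensor) -> Tensor:
        g = self.cbam(x)
        outs = [branch(g) for branch in self.branches]
        if self.fusion == "sum":
            fused = outs[0]
            for o in outs[1:]:
                fused = fused + o
            return fused
        fused = self.reduce(cat(outs, axis=1))
        if self.reduce_norm is not None:
            fused = self.reduce_norm(fused).swish()
        return fused

    def apply_to(self, f: np.ndarray) -> np.ndarray:
        """Run the module on a single plain (C, H, W) array."""
        f = validate_feature_map(f)
        if f.shape[0] != self.in_channels:
            raise ValidationError(f"expected {self.in_channels} channels, got {f.shape[0]}")
        return self.forward(Tensor(f[None])).data[0]


def dilated_branch(
    f: np.ndarray,
    out_channels: int,
    rate: int,
    module: Optional[DilatedBranch] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply one dilated 3×3 branch to a single (C, H, W) map."""
    f = validate_feature_map(f)
    if module is None:
        module = DilatedBranch(f.shape[0], out_channels, rate, norm_act=False, rng=rng)
    return module(Tensor(f[None])).data[0]


def msfm_forward(
    f: np.ndarray,
    module: MultiScaleFusion,
) -> np.ndarray:
    """Apply a multi-scale fusion module to a single (C, H, W) map."""
    return module.apply_to(f)


def gradient_footprint_side(rate: int, kernel_size: int = 3, image_size: Optional[int] = None) -> int:
    """Measure the effective kernel side empirically.

    Applies a single dilated convolution (all-ones kernel, no bias) to a
    delta image and returns the side of the bounding box of the nonzero
    output support — an independent check of :func:`dilated_kernel_size`.
    """
    k_d = dilated_kernel_size(kernel_size, rate)
    size = image_size or (2 * k_d + 3)
    img = np.zeros((1, 1, size, size), dtype=np.float32)
    img[0, 0, size // 2, size // 2] = 1.0
    conv = nn.Conv2d(1, 1, kernel_size, padding=rate * (kernel_size // 2),
                     dilation=rate, bias=False)
    conv.weight.data = np.ones_like(conv.weight.data)
    out = conv(Tensor(img)).data[0, 0]
    ys, xs = np.nonzero(np.abs(out) > 0)
    return int(max(ys.max() - ys.min(), xs.max() - xs.min()) + 1)
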