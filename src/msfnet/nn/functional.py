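"""2-D convolution for the autograd core, via im2col/col2im.

Supports stride, symmetric zero padding, dilation and channel groups
(``groups == in_channels`` gives a depthwise convolution).  Dilation spaces
the kernel taps ``dilation`` pixels apart without adding parameters, which
is exactly what the multi-scale branches rely on.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .tensor import Tensor


def conv_output_size(size: int, kernel: int, stride: int, padding: int, dilation: int) -> int:
    eff = dilation * (kernel - 1) + 1
    out = (size + 2 * padding - eff) // stride + 1
    if out < 1:
        raise ValueError(
            f"convolution output collapsed: size={size} kernel={kernel} "
            f"stride={stride} padding={padding} dilation={dilation}"
        )
    return out


def _patch_indices(
    h: int, w: int, kh: int, kw: int, stride: int, padding: int, dilation: int
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    out_h = conv_output_size(h, kh, stride, padding, dilation)
    out_w = conv_output_size(w, kw, stride, padding, dilation)
    i0 = np.repeat(np.arange(kh) * dilation, kw)
    j0 = np.tile(np.arange(kw) * dilation, kh)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    rows = i0[:, None] + i1[None, :]  # (kh*kw, out_h*out_w)
    cols = j0[:, None] + j1[None, :]
    return rows, cols, out_h, out_w


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with ``weight`` (Cout,Cin/g,kh,kw)."""
    n, c, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c != c_in_g * groups:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {c_in_g * groups}")
    if c_out % groups:
        raise ValueError("out_channels must be divisible by groups")

    rows, cols, out_h, out_w = _patch_indices(h, w, kh, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches = xp[:, :, rows, cols]  # (N, C, kh*kw, L)
    L = out_h * out_w
    patches_g = patches.reshape(n, groups, c_in_g * kh * kw, L)
    w_g = weight.data.reshape(groups, c_out // groups, c_in_g * kh * kw)
    out = np.einsum("gok,ngkl->ngol", w_g, patches_g, optimize=True)
    out = np.ascontiguousarray(out.reshape(n, c_out, out_h, out_w))
    if bias is not None:
        out += bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g: np.ndarray) -> None:
        g_flat = g.reshape(n, groups, c_out // groups, L)
        if weight.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", g_flat, patches_g, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g_patches = np.einsum("gok,ngol->ngkl", w_g, g_flat, optimize=True)
            g_patches = g_patches.reshape(n, c, kh * kw, L)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), slice(None), rows, cols), g_patches)
            if padding:
                gxp = gxp[:, :, padding : padding + h, padding : padding + w]
            x._accumulate(gxp)

    return Tensor(out, _parents=parents, _backward=bwd)
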