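"""Gradient-weighted class-activation heatmaps (Grad-CAM) and overlays.

For a chosen spatial layer, the gradient of the target-class logit with
respect to that layer's activations is averaged over space to give one
weight per channel; the weighted channel sum is rectified, bilinearly
upsampled to the input image size and min-max normalized to [0, 1].  The
default layer is the multi-scale fusion output, where lesion detail is still
spatially resolved.

A constant raw map (e.g. a dead layer) normalizes to all zeros and sets the
``constant`` flag instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .model import preprocess_images
from .nn import Tensor


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray          # (H, W) floats in [0, 1]
    target_class: int
    layer: str
    constant: bool = False      # raw map had zero range; values are all 0


def grad_cam(
    model,
    image: np.ndarray,
    target_class: int,
    layer: str = "msfm",
) -> Heatmap:
    """Compute a Grad-CAM heatmap for ``image`` at ``layer``.

    ``image`` may be an uint8 H×W×3 photo (preprocessed through the model's
    config) or an already-normalized (1, 3, R, R) float batch.  ``model``
    must expose ``forward(x, capture=name)`` returning (logits, activation);
    the captured activation must be spatial (N, C, h, w).
    """
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 3:
        out_size = image.shape[:2]
        x = preprocess_images([image], model.config)
    elif image.ndim == 4 and image.shape[0] == 1:
        out_size = image.shape[2:]
        x = image.astype(np.float32)
    else:
        raise ValidationError(f"expected H×W×3 image or (1,3,R,R) batch, got {image.shape}")

    if hasattr(model, "eval"):
        model.eval()
    xt = Tensor(x)
    logits, act = model.forward(xt, capture=layer)
    if act.ndim != 4:
        raise ConfigurationError(f"layer {layer!r} is not spatial: shape {act.shape}")
    k = logits.shape[1]
    if not (0 <= target_class < k):
        raise ValidationError(f"target_class {target_class} out of range [0, {k})")
    score = logits.gather(np.array([target_class]), axis=1).sum()
    score.backward()
    grads = act.grad[0]                      # (C, h, w)
    weights = grads.mean(axis=(1, 2))        # one weight per channel
    raw = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)

    zoom = (out_size[0] / raw.shape[0], out_size[1] / raw.shape[1])
    up = ndimage.zoom(raw, zoom, order=1)
    up = up[: out_size[0], : out_size[1]]
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        return Heatmap(np.zeros(out_size, dtype=np.float64), target_class, layer, constant=True)
    return Heatmap((up - lo) / (hi - lo), target_class, layer)


def overlay(
    image: np.ndarray,
    heatmap: Heatmap,
    opacity: float = 0.5,
    colormap: str = "jet",
) -> np.ndarray:
    """Alpha-blend the colormapped heatmap onto the image.

    ``opacity`` 0 returns the original image, 1 the pure colormap; the
    output is uint8 with the input's shape.
    """
    import matplotlib
    matplotlib.use("Agg")

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected H×W×3 image, got shape {image.shape}")
    if heatmap.values.shape != image.shape[:2]:
        raise ValidationError(
            f"heatmap shape {heatmap.values.shape} does not match image {image.shape[:2]}"
        )
    if not (0.0 <= opacity <= 1.0):
        raise ValidationError(f"opacity must be in [0, 1], got {opacity}")
    cmap = matplotlib.colormaps[colormap]
    colored = cmap(heatmap.values)[:, :, :3] * 255.0
    blended = (1.0 - opacity) * image.astype(np.float64) + opacity * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def comparison_grid(
    image: np.ndarray,
    heatmaps: Tuple[Heatmap, ...],
    titles: Tuple[str, ...],
    path: Optional[str] = None,
    opacity: float = 0.5,
):
    """Side-by-side panel: original image followed by one overlay per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [image] + [overlay(image, h, opacity) for h in heatmaps]
    names = ["original"] + list(titles)
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3))
    for ax, panel, name in zip(np.atleast_1d(axes), panels, names):
        ax.imshow(panel)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
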