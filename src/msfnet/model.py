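"""Classifier assembly: EfficientNet-B6-shaped backbone with multi-scale fusion.

The network is: stem conv → mobile inverted-bottleneck (MBConv) stages laid
out with B6's widths/depths/strides → a multi-scale fusion module (MSFM)
inserted after a shallow stage (default: stage 2, where maps are still
high-resolution and carry lesion colour/texture detail) → CBAM recalibration
of the later stages → 1×1 head conv → global average pooling → K-way linear
head.

CBAM placement: in each selected stage, the *last* block applies CBAM to its
projected features immediately before the projection batch norm.  The MSFM
output replaces the shallow feature stream (single path).

No pretrained weights are used anywhere; initialization is a pure function
of the seed.  ``width_multiplier``/``depth_multiplier`` scale the network
down to CPU-friendly sizes for experimentation and testing.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from . import nn
from .attention import CBAM
from .errors import ConfigurationError, DataError, ValidationError
from .msfm import MultiScaleFusion
from .nn import Tensor, softmax


@dataclass(frozen=True)
class StageSpec:
    expand_ratio: int
    channels: int
    repeats: int
    stride: int
    kernel: int


# B6-shaped stage table: widths/depths follow the standard compound-scaled
# layout (width x1.8, depth x2.6 over the base seven-stage design).
B6_STAGES: Tuple[StageSpec, ...] = (
    StageSpec(1, 32, 3, 1, 3),
    StageSpec(6, 40, 6, 2, 3),
    StageSpec(6, 72, 6, 2, 5),
    StageSpec(6, 144, 8, 2, 3),
    StageSpec(6, 200, 8, 1, 5),
    StageSpec(6, 344, 11, 2, 5),
    StageSpec(6, 576, 3, 1, 3),
)
B6_STEM_CHANNELS = 56
B6_HEAD_CHANNELS = 2304


def _scale_width(c: int, m: float) -> int:
    return max(1, int(round(c * m)))


def _scale_depth(d: int, m: float) -> int:
    return max(1, int(math.ceil(d * m)))


@dataclass
class BackboneConfig:
    """Everything needed to rebuild the architecture (JSON-serializable)."""

    stages: Tuple[StageSpec, ...] = B6_STAGES
    stem_channels: int = B6_STEM_CHANNELS
    head_channels: int = B6_HEAD_CHANNELS
    resolution: int = 224
    width_multiplier: float = 1.0
    depth_multiplier: float = 1.0
    num_classes: int = 5
    msfm_stage: Optional[int] = 2        # MSFM inserted after this 1-based stage; None = off
    cbam_stages: Optional[Tuple[int, ...]] = None  # default: all stages after msfm_stage
    msfm_rates: Tuple[int, ...] = (1, 2, 4)
    msfm_fusion: str = "concat"
    reduction_ratio: int = 16
    spatial_kernel: int = 7
    normalize_mean: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    normalize_std: Tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        if self.resolution < 32:
            raise ConfigurationError(f"resolution must be >= 32, got {self.resolution}")
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        n = len(self.stages)
        if self.msfm_stage is not None and not (1 <= self.msfm_stage <= n):
            raise ConfigurationError(
                f"msfm_stage must be in 1..{n}, got {self.msfm_stage}"
            )
        if self.cbam_stages is not None:
            bad = [s for s in self.cbam_stages if not (1 <= s <= n)]
            if bad:
                raise ConfigurationError(f"cbam_stages out of range: {bad}")

    def effective_cbam_stages(self) -> Tuple[int, ...]:
        if self.cbam_stages is not None:
            return tuple(self.cbam_stages)
        if self.msfm_stage is None:
            return ()
        return tuple(range(self.msfm_stage + 1, len(self.stages) + 1))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [asdict(s) for s in self.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["stages"] = tuple(StageSpec(**s) for s in d["stages"])
        for key in ("cbam_stages", "msfm_rates", "normalize_mean", "normalize_std"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def tiny_config(**overrides) -> BackboneConfig:
    """A CPU-scale preset: width x0.1, one block per stage, 64 px input."""
    base = dict(width_multiplier=0.1, depth_multiplier=0.12, resolution=64)
    base.update(overrides)
    return BackboneConfig(**base)


class MBConv(nn.Module):
    """Mobile inverted bottleneck: expand 1×1 → depthwise k×k → project 1×1.

    A residual connection is used when stride is 1 and widths match.  When
    ``attach_cbam`` is set, CBAM gates the projected features right before
    the projection batch norm.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        expand_ratio: int,
        attach_cbam: bool = False,
        reduction_ratio: int = 16,
        spatial_kernel: int = 7,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        mid = in_channels * expand_ratio
        self.use_skip = stride == 1 and in_channels == out_channels
        if expand_ratio != 1:
            self.expand = nn.Conv2d(in_channels, mid, 1, bias=False, rng=rng)
            self.expand_bn = nn.BatchNorm2d(mid)
        else:
            self.expand = None
        self.dw = nn.Conv2d(
            mid, mid, kernel, stride=stride, padding=kernel // 2,
            groups=mid, bias=False, rng=rng,
        )
        self.dw_bn = nn.BatchNorm2d(mid)
        self.project = nn.Conv2d(mid, out_channels, 1, bias=False, rng=rng)
        self.cbam = (
            CBAM(out_channels, reduction_ratio, spatial_kernel, rng=rng)
            if attach_cbam else None
        )
        self.project_bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        out = x
        if self.expand is not None:
            out = self.expand_bn(self.expand(out)).swish()
        out = self.dw_bn(self.dw(out)).swish()
        out = self.project(out)
        if self.cbam is not None:
            out = self.cbam(out)
        out = self.project_bn(out)
        if self.use_skip:
            out = out + x
        return out


class MSFNet(nn.Module):
    """The assembled classifier. ``forward`` optionally captures a named layer."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        wm, dm = config.width_multiplier, config.depth_multiplier
        stem_c = _scale_width(config.stem_channels, wm)
        self.stem = nn.Conv2d(3, stem_c, 3, stride=2, padding=1, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)

        cbam_stages = set(config.effective_cbam_stages())
        self.stages = nn.ModuleList()
        self.msfm: Optional[MultiScaleFusion] = None
        c_in = stem_c
        for idx, spec in enumerate(config.stages, start=1):
            c_out = _scale_width(spec.channels, wm)
            repeats = _scale_depth(spec.repeats, dm)
            blocks = []
            for b in range(repeats):
                blocks.append(
                    MBConv(
                        c_in if b == 0 else c_out,
                        c_out,
                        spec.kernel,
                        spec.stride if b == 0 else 1,
                        spec.expand_ratio,
                        attach_cbam=(idx in cbam_stages and b == repeats - 1),
                        reduction_ratio=config.reduction_ratio,
                        spatial_kernel=config.spatial_kernel,
                        rng=rng,
                    )
                )
            self.stages.append(nn.Sequential(*blocks))
            c_in = c_out
            if config.msfm_stage == idx:
                self.msfm = MultiScaleFusion(
                    c_out,
                    rates=config.msfm_rates,
                    fusion=config.msfm_fusion,
                    reduction_ratio=config.reduction_ratio,
                    spatial_kernel=config.spatial_kernel,
                    rng=rng,
                )

        head_c = _scale_width(config.head_channels, wm)
        self.head_conv = nn.Conv2d(c_in, head_c, 1, bias=False, rng=rng)
        self.head_bn = nn.BatchNorm2d(head_c)
        self.fc = nn.Linear(head_c, config.num_classes, rng=rng)

    def layer_names(self) -> List[str]:
        names = ["stem"] + [f"stage{i}" for i in range(1, len(self.stages) + 1)]
        if self.msfm is not None:
            names.insert(1 + self.config.msfm_stage, "msfm")
        names.append("features")
        return names

    def forward(self, x: Tensor, capture: Optional[str] = None):
        """Return logits (N, K); with ``capture`` also the named activation."""
        captured = None

        def keep(name: str, t: Tensor) -> Tensor:
            nonlocal captured
            if capture == name:
                captured = t
            return t

        out = keep("stem", self.stem_bn(self.stem(x)).swish())
        for idx, stage in enumerate(self.stages, start=1):
            out = keep(f"stage{idx}", stage(out))
            if self.msfm is not None and self.config.msfm_stage == idx:
                out = keep("msfm", self.msfm(out))
        out = keep("features", self.head_bn(self.head_conv(out)).swish())
        pooled = out.mean(axis=(2, 3))
        logits = self.fc(pooled)
        if capture is not None:
            if captured is None:
                raise ConfigurationError(
                    f"unknown capture layer {capture!r}; valid: {self.layer_names()}"
                )
            return logits, captured
        return logits


def build_model(config: BackboneConfig, seed: int = 0) -> MSFNet:
    """Construct a network with initialization determined entirely by ``seed``."""
    rng = np.random.default_rng(seed)
    return MSFNet(config, rng)


def preprocess_images(
    images: Sequence[np.ndarray],
    config: BackboneConfig,
) -> np.ndarray:
    """uint8 H×W×3 images → normalized float32 batch (N, 3, R, R).

    Images are bilinearly resized to the configured resolution, scaled to
    [0, 1], then standardized per channel with the config's mean/std.
    """
    r = config.resolution
    mean = np.asarray(config.normalize_mean, dtype=np.float32).reshape(3, 1, 1)
    std = np.asarray(config.normalize_std, dtype=np.float32).reshape(3, 1, 1)
    out = np.empty((len(images), 3, r, r), dtype=np.float32)
    for i, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValidationError(f"expected H×W×3 RGB image, got shape {img.shape}")
        if img.shape[:2] != (r, r):
            img = np.asarray(
                Image.fromarray(img.astype(np.uint8)).resize((r, r), Image.BILINEAR)
            )
        x = img.astype(np.float32).transpose(2, 0, 1) / 255.0
        out[i] = (x - mean) / std
    return out


def predict(model: MSFNet, images: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for a preprocessed (N, 3, R, R) batch."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValidationError(f"expected (N, 3, R, R) batch, got {images.shape}")
    r = model.config.resolution
    if images.shape[2] != r or images.shape[3] != r:
        raise ValidationError(
            f"batch spatial size {images.shape[2:]} does not match model resolution {r}"
        )
    model.eval()
    logits = model(Tensor(images))
    return softmax(logits, axis=1).data


def save_checkpoint(model: MSFNet, path: str) -> None:
    """Write weights (.npz) plus a JSON config sidecar (<path>.json)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    np.savez(path, **model.state_dict())
    with open(_sidecar_path(path), "w") as fh:
        json.dump(model.config.to_dict(), fh, indent=2)


def load_checkpoint(path: str) -> MSFNet:
    """Rebuild the architecture from the sidecar and load the weights."""
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise DataError(f"missing config sidecar: {sidecar}")
    with open(sidecar) as fh:
        config = BackboneConfig.from_dict(json.load(fh))
    model = build_model(config, seed=0)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    if not os.path.exists(npz_path) and os.path.exists(path):
        npz_path = path
    try:
        with np.load(npz_path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
    except (OSError, ValueError, KeyError) as exc:
        raise DataError(f"unreadable checkpoint {path}: {exc}") from exc
    return model


def _sidecar_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"
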