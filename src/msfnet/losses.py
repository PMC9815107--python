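"""Classification losses: weighted cross-entropy and focal loss.

For a true-class probability ``p_t`` and class weight ``a_t``:

* cross-entropy:  ``CE(p_t) = -a_t * ln(p_t)``
* focal loss:     ``FL(p_t) = -a_t * (1 - p_t)**gamma * ln(p_t)``

Focal loss down-weights well-classified examples (``p_t`` near 1) so that
hard, typically minority-class, examples dominate the gradient; at
``gamma = 0`` and unit weights it coincides exactly with cross-entropy.
The multiclass batch form sums/averages the true-class terms.

``p_t`` is clamped to ``[eps, 1]`` (default eps 1e-7) before the logarithm,
so the loss is always finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, ValidationError
from .nn import Tensor, softmax

EPS_DEFAULT = 1e-7

ArrayOrFloat = Union[float, np.ndarray]


def _clamp_probs(p_t: ArrayOrFloat, eps: float) -> np.ndarray:
    p = np.asarray(p_t, dtype=np.float64)
    if np.any(~np.isfinite(p)) or np.any(p > 1.0 + 1e-12):
        raise ValidationError("probabilities must be finite and <= 1")
    if np.any(p <= 0.0):
        warnings.warn(
            f"non-positive probability clamped to eps={eps}", RuntimeWarning, stacklevel=3
        )
    return np.clip(p, eps, 1.0)


def cross_entropy(
    p_t: ArrayOrFloat, a_t: ArrayOrFloat = 1.0, eps: float = EPS_DEFAULT
) -> np.ndarray:
    """Elementwise weighted cross-entropy ``-a_t * ln(p_t)``."""
    a = np.asarray(a_t, dtype=np.float64)
    if np.any(a <= 0):
        raise ValidationError("class weights a_t must be positive")
    return np.asarray(-a * np.log(_clamp_probs(p_t, eps)))


def focal_loss(
    p_t: ArrayOrFloat,
    a_t: ArrayOrFloat = 1.0,
    gamma: float = 2.0,
    eps: float = EPS_DEFAULT,
) -> np.ndarray:
    """Elementwise focal loss ``-a_t * (1 - p_t)**gamma * ln(p_t)``."""
    if gamma < 0:
        raise ValidationError(f"gamma must be >= 0, got {gamma}")
    p = _clamp_probs(p_t, eps)
    a = np.asarray(a_t, dtype=np.float64)
    if np.any(a <= 0):
        raise ValidationError("class weights a_t must be positive")
    return np.asarray(-a * (1.0 - p) ** gamma * np.log(p))


def inverse_frequency_weights(labels: Sequence[int], num_classes: int) -> np.ndarray:
    """Balanced per-class weights ``a_c = N / (K * n_c)`` from training labels.

    A class absent from ``labels`` receives the weight of a singleton class.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=num_classes).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    return labels.size / (num_classes * counts)


@dataclass
class LossConfig:
    """Run-level loss selection.

    ``alpha`` may be a scalar, a length-K vector, or None — None means
    inverse-frequency weights computed from the training split.  ``gamma``
    is the focusing exponent (0 recovers cross-entropy).
    """

    kind: str = "focal"
    gamma: float = 2.0
    alpha: Optional[Union[float, Sequence[float]]] = None
    reduction: str = "mean"
    eps: float = EPS_DEFAULT

    def __post_init__(self):
        if self.kind not in ("cross_entropy", "focal"):
            raise ConfigurationError(f"unknown loss kind: {self.kind!r}")
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")
        if self.reduction not in ("mean", "sum", "none"):
            raise ConfigurationError(f"unknown reduction: {self.reduction!r}")

    def effective_gamma(self) -> float:
        return 0.0 if self.kind == "cross_entropy" else self.gamma

    def alpha_vector(self, num_classes: int, train_labels=None) -> np.ndarray:
        if self.alpha is None:
            if train_labels is None:
                return np.ones(num_classes)
            return inverse_frequency_weights(train_labels, num_classes)
        a = np.asarray(self.alpha, dtype=np.float64)
        if a.ndim == 0:
            a = np.full(num_classes, float(a))
        if a.shape != (num_classes,):
            raise ConfigurationError(
                f"alpha must be scalar or length-{num_classes}, got shape {a.shape}"
            )
        if np.any(a <= 0):
            raise ConfigurationError("alpha entries must be positive")
        return a


class BatchLoss:
    """Differentiable batch loss on logits, for the training loop."""

    def __init__(self, config: LossConfig, alpha_vector: np.ndarray):
        self.config = config
        self.alpha = np.asarray(alpha_vector, dtype=np.float32)

    def __call__(self, logits: Tensor, labels: np.ndarray) -> Tensor:
        labels = np.asarray(labels, dtype=int)
        probs = softmax(logits, axis=1)
        # clamp keeps log and the gamma-power finite at the extremes
        p_t = probs.gather(labels, axis=1).clip(self.config.eps, 1.0 - self.config.eps)
        a_t = self.alpha[labels]
        gamma = self.config.effective_gamma()
        nll = -(p_t.log())
        if gamma > 0:
            nll = ((1.0 - p_t) ** gamma) * nll
        loss = Tensor(a_t) * nll
        if self.config.reduction == "mean":
            return loss.mean()
        if self.config.reduction == "sum":
            return loss.sum()
        return loss
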