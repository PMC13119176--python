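"""Closed-form model utilities: saliency response maps and a FLOPs estimate.

These operate on user-supplied arrays only — the package deliberately has
no deep-learning dependency and never computes network gradients itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class FeatureStack:
    """K feature planes A_k (K×H×W) with their gradients ∂y/∂A_k."""

    maps: np.ndarray
    grads: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.grads = np.asarray(self.grads, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be a K×H×W array with K >= 1")
        if self.maps.shape != self.grads.shape:
            raise ValueError(
                f"maps {self.maps.shape} and grads {self.grads.shape} differ in shape"
            )


@dataclass
class ConvSpec:
    """Input size C×H×W and the parallel kernel sizes of a multi-scale block."""

    channels: int
    height: int
    width: int
    kernel_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if min(self.channels, self.height, self.width) < 1:
            raise ValueError("channels/height/width must be positive")
        if not self.kernel_sizes or min(self.kernel_sizes) < 1:
            raise ValueError("kernel sizes must be positive")


def hirescam(fs: FeatureStack) -> np.ndarray:
    """HiResCAM response map: ReLU of the channel sum of grad ⊙ map.

    Unlike Grad-CAM's pooled channel weights, the element-wise product
    preserves full spatial resolution. Output is non-negative and
    invariant to channel permutation.
    """
    return np.maximum(0.0, np.einsum("khw,khw->hw", fs.grads, fs.maps))


def gradcam_baseline(fs: FeatureStack) -> np.ndarray:
    """Grad-CAM response: ReLU of maps weighted by spatially averaged gradients.

    Coincides with :func:`hirescam` exactly when every gradient plane is
    spatially constant.
    """
    weights = fs.grads.mean(axis=(1, 2))
    return np.maximum(0.0, np.einsum("k,khw->hw", weights, fs.maps))


def emscp_flops(spec: ConvSpec) -> int:
    """Added cost of parallel multi-scale convolution branches: Σ_i C²·k_i²·H·W.

    Multiply-count convention (no ×2 for multiply–add); additive over the
    kernel list, linear in H·W, quadratic in C.
    """
    c2hw = spec.channels**2 * spec.height * spec.width
    return int(sum(c2hw * k**2 for k in spec.kernel_sizes))
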