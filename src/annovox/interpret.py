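"""Voxel-wise model-attention maps: saliency, CAM, Grad-CAM, SAM.

These visualizations answer "which pixels drove this class score?" for a
section fed through a differentiable model:

* **saliency** — ``|d score_c / d input|``, reduced over input channels by
  max.  Large where an infinitesimal intensity change moves the score.
* **Grad-CAM** — at a chosen spatial layer with feature maps ``A^k``,
  channel weights ``alpha_k = spatial_mean(d score_c / d A^k)`` combine
  into ``ReLU(sum_k alpha_k A^k)``, upsampled bilinearly to the input grid.
* **CAM** — for architectures ending in global average pooling followed by
  one linear classifier, the classifier weights themselves combine the
  final feature maps: ``sum_k w_k^c A^k`` (negatives clipped for display).
  On such models CAM and final-layer Grad-CAM agree up to a positive
  scale (Grad-CAM's alpha is ``w_k^c`` divided by the pooled area), so the
  two coincide exactly after min-max normalization.
* **SAM** — combined saliency/activation view: the elementwise product of
  the min-max-normalized saliency and Grad-CAM maps, renormalized to
  [0, 1].  This is a documented stand-in definition behind a pluggable
  function; the exact published formulation can be substituted.

All maps are nonnegative.  Display thresholding hides activations below a
fraction of the map maximum (default 0.2); originals are preserved so the
threshold can be re-adjusted losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ArchitectureError, UnsupportedLayerError, ValidationError
from .nets import Dense, Flatten, GlobalAvgPool, Network

__all__ = [
    "ActivationMap",
    "saliency",
    "grad_cam",
    "cam",
    "sam",
    "auto_threshold",
]

DEFAULT_THRESHOLD_FRACTION = 0.2


@dataclass
class ActivationMap:
    """Nonnegative per-pixel attention map at input resolution."""

    values: np.ndarray
    source: str  # saliency | cam | grad_cam | sam
    layer: Optional[int] = None
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("activation values must be nonnegative")
        if not (0 <= self.threshold_fraction < 1):
            raise ValidationError("threshold_fraction must be in [0, 1)")

    @property
    def visible(self) -> np.ndarray:
        """Mask of pixels at or above fraction x max; low background hidden."""
        peak = self.values.max()
        if peak == 0:
            return np.zeros(self.values.shape, dtype=bool)
        return self.values >= self.threshold_fraction * peak

    def thresholded(self) -> np.ndarray:
        """Values with hidden pixels zeroed; originals remain in .values."""
        return np.where(self.visible, self.values, 0.0)

    def normalized(self) -> np.ndarray:
        """Min-max normalization to [0, 1]; all-zero maps stay zero."""
        return _minmax(self.values)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _upsample(coarse: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    if coarse.shape == tuple(target_shape):
        return coarse
    factors = [t / s for t, s in zip(target_shape, coarse.shape)]
    out = ndimage.zoom(coarse, factors, order=1)
    # zoom can over/undershoot the target by a pixel on tiny grids
    return out[: target_shape[0], : target_shape[1]]


def _forward(model: Network, section: np.ndarray, class_index: int):
    out = model.forward(section)
    if not (0 <= class_index < out.shape[-1]):
        raise ValidationError(f"class index {class_index} out of range for output {out.shape}")
    return out


def saliency(model: Network, section: np.ndarray, class_index: int) -> ActivationMap:
    """Absolute input gradient of the class score, max-reduced over channels."""
    _forward(model, section, class_index)
    grad_in, _ = model.backward(class_index)
    values = np.abs(grad_in).max(axis=-1)
    return ActivationMap(values=values, source="saliency")


def _spatial_layer(model: Network, layer: int) -> np.ndarray:
    if not (0 <= layer < len(model.layers)):
        raise ValidationError(f"layer index {layer} out of range")
    act = model.activations[layer]
    if act.ndim != 3:
        raise UnsupportedLayerError(
            f"layer {layer} ({model.layers[layer].name}) has no spatial feature maps"
        )
    return act


def grad_cam(model: Network, section: np.ndarray, class_index: int, layer: int) -> ActivationMap:
    """Gradient-weighted class activation map at a spatial layer."""
    section = model._coerce(section)
    _forward(model, section, class_index)
    acts = _spatial_layer(model, layer)
    _, layer_grads = model.backward(class_index)
    grads = layer_grads[layer]
    alpha = grads.mean(axis=(0, 1))  # (C,)
    combined = np.tensordot(acts, alpha, axes=([2], [0]))
    values = np.maximum(combined, 0.0)
    values = _upsample(values, section.shape[:2])
    return ActivationMap(values=values, source="grad_cam", layer=layer)


def _cam_structure(model: Network) -> tuple[int, Dense]:
    """Locate the GAP -> linear tail; raise ArchitectureError otherwise."""
    layers = model.layers
    gap_idx = None
    for idx, layer in enumerate(layers):
        if isinstance(layer, GlobalAvgPool):
            gap_idx = idx
    if gap_idx is None:
        raise ArchitectureError("CAM requires a global-average-pooling layer")
    tail = [l for l in layers[gap_idx + 1 :] if not isinstance(l, Flatten)]
    if len(tail) != 1 or not isinstance(tail[0], Dense):
        raise ArchitectureError(
            "CAM requires global average pooling followed by a single linear layer"
        )
    if gap_idx == 0:
        raise ArchitectureError("CAM requires spatial feature maps before pooling")
    return gap_idx, tail[0]


def cam(model: Network, section: np.ndarray, class_index: int) -> ActivationMap:
    """Class activation map for GAP-linear architectures.

    ``map = sum_k w_k^c A^k`` over the feature maps entering the pooling
    layer, with negatives clipped to zero for display.
    """
    section = model._coerce(section)
    gap_idx, dense = _cam_structure(model)
    out = _forward(model, section, class_index)
    acts = model.activations[gap_idx - 1]
    if acts.ndim != 3:
        raise ArchitectureError("layer before pooling must have spatial feature maps")
    w_c = dense.weights[:, class_index]
    combined = np.tensordot(acts, w_c, axes=([2], [0]))
    values = np.maximum(combined, 0.0)
    values = _upsample(values, section.shape[:2])
    return ActivationMap(values=values, source="cam", layer=gap_idx - 1)


def sam(model: Network, section: np.ndarray, class_index: int, layer: int) -> ActivationMap:
    """Saliency activation map: normalized saliency x normalized Grad-CAM.

    Either component being identically zero yields an all-zero map with a
    warning (degenerate case).
    """
    s = saliency(model, section, class_index).normalized()
    g = grad_cam(model, section, class_index, layer).normalized()
    if s.max() == 0 or g.max() == 0:
        warnings.warn("degenerate SAM: a component map is identically zero")
        return ActivationMap(np.zeros(s.shape), source="sam", layer=layer)
    values = _minmax(s * g)
    return ActivationMap(values=values, source="sam", layer=layer)


def auto_threshold(amap: ActivationMap, fraction: Optional[float] = None) -> ActivationMap:
    """Set the display threshold; values below fraction x max are hidden.

    Returns a new map sharing the original values, so re-thresholding at a
    different fraction is lossless.  ``fraction=0`` hides nothing.
    """
    if fraction is None:
        fraction = DEFAULT_THRESHOLD_FRACTION
    if not (0 <= fraction < 1):
        raise ValidationError("threshold fraction must be in [0, 1)")
    return ActivationMap(
        values=amap.values, source=amap.source, layer=amap.layer, threshold_fraction=fraction
    )
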