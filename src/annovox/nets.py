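"""Minimal differentiable array-network engine.

A tiny feed-forward network implementation (2-D convolution, ReLU, global
average pooling, flatten, dense) with exact forward and reverse-mode
gradient computation in numpy.  It exists so the model-plugin harness and
the interpretability maps can be exercised and tested end-to-end with
deterministic, HDF5-serializable models whose gradients have closed forms.
The plugin harness itself only requires the predict-function contract, so
any backend exposing ``predict(array) -> array`` (and, for gradient-based
visualizations, ``forward``/``backward``) can be substituted.

Array conventions: network input is a single section ``(H, W, C)``;
spatial layers produce ``(H, W, C')``; GAP/dense produce vectors.  The
scalar "class score" differentiated everywhere is ``output[..., c]``
summed over any spatial axes.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy import signal

from .errors import ValidationError

__all__ = [
    "Conv2D",
    "ReLU",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Network",
    "save_network",
    "load_network",
]


class Layer:
    name: str = "layer"

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 2-D convolution (cross-correlation), odd kernels."""

    name = "conv2d"

    def __init__(self, weights: np.ndarray, bias: Optional[np.ndarray] = None):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 4:
            raise ValidationError("Conv2D weights must be (kh, kw, c_in, c_out)")
        kh, kw, _, c_out = weights.shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValidationError("Conv2D kernels must have odd spatial size")
        self.weights = weights
        self.bias = np.zeros(c_out) if bias is None else np.asarray(bias, dtype=float)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.weights.shape[2]:
            raise ValidationError(
                f"Conv2D expects (H, W, {self.weights.shape[2]}), got {x.shape}"
            )
        self._x = x
        kh, kw, c_in, c_out = self.weights.shape
        out = np.empty((x.shape[0], x.shape[1], c_out))
        for o in range(c_out):
            acc = np.zeros(x.shape[:2])
            for i in range(c_in):
                acc += signal.correlate2d(x[:, :, i], self.weights[:, :, i, o], mode="same")
            out[:, :, o] = acc + self.bias[o]
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        kh, kw, c_in, c_out = self.weights.shape
        grad_x = np.zeros(self._x.shape)
        for i in range(c_in):
            for o in range(c_out):
                grad_x[:, :, i] += signal.convolve2d(
                    grad_out[:, :, o], self.weights[:, :, i, o], mode="same"
                )
        return grad_x


class ReLU(Layer):
    name = "relu"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class GlobalAvgPool(Layer):
    """(H, W, C) -> (C,) spatial mean."""

    name = "gap"

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3:
            raise ValidationError(f"GlobalAvgPool expects (H, W, C), got {x.shape}")
        self._shape = x.shape
        return x.mean(axis=(0, 1))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        H, W, C = self._shape
        return np.broadcast_to(grad_out / (H * W), self._shape).copy()


class Flatten(Layer):
    name = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Dense(Layer):
    name = "dense"

    def __init__(self, weights: np.ndarray, bias: Optional[np.ndarray] = None):
        self.weights = np.asarray(weights, dtype=float)  # (c_in, c_out)
        if self.weights.ndim != 2:
            raise ValidationError("Dense weights must be (c_in, c_out)")
        self.bias = np.zeros(self.weights.shape[1]) if bias is None else np.asarray(bias, dtype=float)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 1:
            raise ValidationError(f"Dense expects a vector, got shape {x.shape}")
        self._x = x
        return x @ self.weights + self.bias

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.weights @ grad_out


class Network:
    """A feed-forward stack of layers with cached forward/backward passes."""

    def __init__(self, layers: Sequence[Layer], input_shape: Optional[tuple] = None, name: str = "net"):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape) if input_shape is not None else None
        self.name = name
        self.activations: list[np.ndarray] = []  # output of each layer, last forward

    def _coerce(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._coerce(x)
        self._input = x
        self.activations = []
        for layer in self.layers:
            x = layer.forward(x)
            self.activations.append(x)
        return x

    # the harness predict contract
    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, class_index: int) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradient of the class score w.r.t. the input and every layer output.

        Must follow a :meth:`forward` call.  The score is
        ``output[..., class_index]`` summed over spatial axes, so the seed
        gradient is an indicator on the class channel.
        """
        if not self.activations:
            raise ValidationError("backward requires a prior forward pass")
        out = self.activations[-1]
        if not (0 <= class_index < out.shape[-1]):
            raise ValidationError(f"class index {class_index} out of range for output {out.shape}")
        grad = np.zeros_like(out)
        grad[..., class_index] = 1.0
        layer_grads: list[Optional[np.ndarray]] = [None] * len(self.layers)
        layer_grads[-1] = grad
        for k in range(len(self.layers) - 1, -1, -1):
            grad = self.layers[k].backward(grad)
            if k > 0:
                layer_grads[k - 1] = grad
        return grad, layer_grads  # grad is now d(score)/d(input)


# ---------------------------------------------------------------------------
# deterministic toy-model builders (fixtures for the harness and tests)
# ---------------------------------------------------------------------------

def make_threshold_segmenter(threshold: float = 0.5, name: str = "threshold_seg") -> Network:
    """Fixed-weight per-pixel segmenter: class 1 wins exactly where x > theta.

    A 1x1 convolution emits two channels, (theta, x); argmax over channels
    implements thresholding of the (already normalized) input.
    """
    w = np.zeros((1, 1, 1, 2))
    w[0, 0, 0, 1] = 1.0
    return Network([Conv2D(w, bias=np.array([threshold, 0.0]))], name=name)


def make_sum_scorer(coef: float = 3.0, name: str = "sum_scorer") -> Network:
    """Linear scorer y = coef * sum(x); its saliency is |coef| everywhere.

    The 1x1 convolution emits coef*x, and the class score differentiated by
    the backward pass is the channel summed over space, i.e. coef * sum(x).
    """
    w = np.full((1, 1, 1, 1), coef)
    return Network([Conv2D(w)], name=name)


def make_gap_classifier(
    seed: int = 0,
    in_channels: int = 1,
    features: int = 4,
    classes: int = 3,
    kernel: int = 3,
    input_shape: Optional[tuple] = None,
    name: str = "gap_classifier",
) -> Network:
    """Random GAP-linear classifier: conv -> ReLU -> GAP -> dense.

    The canonical architecture for class-activation mapping; biases are
    offset positive so activations sit away from the ReLU kink (gradients
    then agree with finite differences).
    """
    rng = np.random.default_rng(seed)
    conv_w = rng.normal(0, 0.4, size=(kernel, kernel, in_channels, features))
    conv_b = rng.uniform(0.5, 1.0, size=features)
    dense_w = rng.normal(0, 0.7, size=(features, classes))
    dense_b = rng.normal(0, 0.1, size=classes)
    return Network(
        [Conv2D(conv_w, conv_b), ReLU(), GlobalAvgPool(), Dense(dense_w, dense_b)],
        input_shape=input_shape,
        name=name,
    )


def make_dense_classifier(seed: int = 0, n_inputs: int = 16, classes: int = 2,
                          name: str = "dense_classifier") -> Network:
    """Flatten -> dense classifier: no spatial layers, not CAM-capable."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.3, size=(n_inputs, classes))
    return Network([Flatten(), Dense(w, rng.normal(0, 0.1, size=classes))], name=name)


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def save_network(net: Network, path: str) -> str:
    """Serialize a network's architecture and weights to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "annovox-net-v1"
        f.attrs["name"] = net.name
        if net.input_shape is not None:
            f.attrs["input_shape"] = json.dumps(list(net.input_shape))
        grp = f.create_group("layers")
        for idx, layer in enumerate(net.layers):
            g = grp.create_group(f"{idx:03d}")
            g.attrs["type"] = layer.name
            if isinstance(layer, (Conv2D, Dense)):
                g.create_dataset("weights", data=layer.weights)
                g.create_dataset("bias", data=layer.bias)
    return path


def load_network(path: str) -> Network:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "annovox-net-v1":
            raise ValidationError(f"{path!r} is not an annovox network file")
        layers: list[Layer] = []
        for key in sorted(f["layers"].keys()):
            g = f["layers"][key]
            kind = g.attrs["type"]
            if kind == "conv2d":
                layers.append(Conv2D(g["weights"][...], g["bias"][...]))
            elif kind == "dense":
                layers.append(Dense(g["weights"][...], g["bias"][...]))
            elif kind == "relu":
                layers.append(ReLU())
            elif kind == "gap":
                layers.append(GlobalAvgPool())
            elif kind == "flatten":
                layers.append(Flatten())
            else:
                raise ValidationError(f"unknown layer type {kind!r} in {path!r}")
        input_shape = None
        if "input_shape" in f.attrs:
            input_shape = tuple(json.loads(f.attrs["input_shape"]))
        return Network(layers, input_shape=input_shape, name=str(f.attrs.get("name", "net")))
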