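"""NumPy forward pass of the AlexNet architecture, exposing fc6/fc7.

This is the canonical 227x227 variant (Krizhevsky et al. layout): five
convolutional layers (conv2/4/5 grouped in two halves), local response
normalization after conv1 and conv2, 3x3 stride-2 max pooling, and the two
4096-unit fully connected layers fc6 and fc7 whose activations form the
8192-dimensional feature vector used downstream. Weights are frozen: either
seeded He-normal random initialization (the default, sufficient for every
architectural contract — layer shapes, feature lengths, determinism) or a
user-supplied ``.npz`` of pretrained tensors. Grayscale inputs in [0, 1]
are bilinearly resized to the input side, replicated to three channels and
normalized with the ImageNet channel statistics before the forward pass.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ConfigurationError, NumericalError
from .patching import _resize_array

__all__ = ["AlexNetFeatureExtractor"]

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

# (name, out_channels, in_channels_per_group, kernel, stride, pad, groups)
_CONV_SPECS = [
    ("conv1", 96, 3, 11, 4, 0, 1),
    ("conv2", 256, 48, 5, 1, 2, 2),
    ("conv3", 384, 256, 3, 1, 1, 1),
    ("conv4", 384, 192, 3, 1, 1, 2),
    ("conv5", 256, 192, 3, 1, 1, 2),
]
_FC_SPECS = [("fc6", 4096, 9216), ("fc7", 4096, 4096)]


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int,
            pad: int, groups: int) -> np.ndarray:
    """Grouped 2-D convolution of a CHW tensor via im2col + GEMM."""
    c_in, h, w_in = x.shape
    c_out, cpg, k, _ = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h_out = (x.shape[1] - k) // stride + 1
    w_out = (x.shape[2] - k) // stride + 1
    out = np.empty((c_out, h_out, w_out), dtype=np.float32)
    opg = c_out // groups
    for g in range(groups):
        xg = x[g * cpg : (g + 1) * cpg]
        # im2col: (h_out*w_out, cpg*k*k)
        windows = np.lib.stride_tricks.sliding_window_view(xg, (k, k), axis=(1, 2))
        windows = windows[:, ::stride, ::stride]  # (cpg, h_out, w_out, k, k)
        col = windows.transpose(1, 2, 0, 3, 4).reshape(h_out * w_out, cpg * k * k)
        wg = w[g * opg : (g + 1) * opg].reshape(opg, cpg * k * k)
        res = col @ wg.T + b[g * opg : (g + 1) * opg]
        out[g * opg : (g + 1) * opg] = res.T.reshape(opg, h_out, w_out)
    return out


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    c, h, w = x.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return windows[:, ::stride, ::stride].max(axis=(3, 4))


def _lrn(x: np.ndarray, n: int = 5, k: float = 2.0, alpha: float = 1e-4,
         beta: float = 0.75) -> np.ndarray:
    """Local response normalization across channels."""
    sq = x.astype(np.float64) ** 2
    c = x.shape[0]
    half = n // 2
    pad = np.pad(sq, ((half, half), (0, 0), (0, 0)))
    csum = np.cumsum(pad, axis=0)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    acc = csum[n:] - csum[:-n]  # running channel sums, length c
    denom = (k + (alpha / n) * acc[:c]) ** beta
    return (x / denom).astype(np.float32)


class AlexNetFeatureExtractor:
    """Frozen AlexNet-architecture backbone emitting fc6 || fc7 (8192 values).

    Parameters
    ----------
    weights : mapping or None
        Tensors keyed ``conv1.weight``, ``conv1.bias``, ..., ``fc7.bias``.
        None (default) draws seeded He-normal weights.
    seed : int
        Seed for the random initialization; ignored when weights are given.
    pre_activation : bool
        Return fc6/fc7 values before their rectifier instead of after.
    """

    name = "alexnet-fc6fc7"
    input_side = 227
    output_dim = 8192
    deterministic = True
    layer_blocks = (("fc6", 4096), ("fc7", 4096))

    def __init__(self, weights: dict | None = None, seed: int = 0,
                 pre_activation: bool = False):
        self.pre_activation = pre_activation
        self.seed = seed
        if weights is None:
            weights = self._random_init(seed)
            self.weights_origin = f"random-he-init(seed={seed})"
        else:
            self.weights_origin = "user-supplied"
        self._check_and_store(weights)

    @classmethod
    def from_npz(cls, path: str | Path, **kwargs) -> "AlexNetFeatureExtractor":
        data = np.load(path)
        return cls(weights={k: data[k] for k in data.files}, **kwargs)

    @staticmethod
    def _random_init(seed: int) -> dict:
        rng = np.random.default_rng([seed, 227])
        w: dict[str, np.ndarray] = {}
        for name, c_out, cpg, k, _, _, _ in _CONV_SPECS:
            fan_in = cpg * k * k
            w[f"{name}.weight"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, cpg, k, k)
            ).astype(np.float32)
            w[f"{name}.bias"] = np.zeros(c_out, dtype=np.float32)
        for name, d_out, d_in in _FC_SPECS:
            w[f"{name}.weight"] = rng.normal(
                0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)
            ).astype(np.float32)
            w[f"{name}.bias"] = np.zeros(d_out, dtype=np.float32)
        return w

    def _check_and_store(self, weights: dict) -> None:
        expected = {f"{n}.weight": (c, g, k, k) for n, c, g, k, _, _, _ in _CONV_SPECS}
        expected.update({f"{n}.bias": (c,) for n, c, _, _, _, _, _ in _CONV_SPECS})
        expected.update({f"{n}.weight": (o, i) for n, o, i in _FC_SPECS})
        expected.update({f"{n}.bias": (o,) for n, o, _ in _FC_SPECS})
        for key, shape in expected.items():
            if key not in weights:
                raise ConfigurationError(f"weights: missing tensor {key}")
            got = tuple(weights[key].shape)
            if got != shape:
                raise ConfigurationError(
                    f"weights: tensor {key} has shape {got}, expected {shape}"
                )
        self._w = {k: np.asarray(weights[k], dtype=np.float32) for k in expected}

    def _preprocess(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=np.float64)
        if grid.ndim != 2 or grid.size == 0:
            raise ConfigurationError("extractor input must be a non-empty 2-D grid")
        x = _resize_array(grid, self.input_side, self.input_side).astype(np.float32)
        x3 = np.repeat(x[None, :, :], 3, axis=0)
        return (x3 - _IMAGENET_MEAN[:, None, None]) / _IMAGENET_STD[:, None, None]

    def _checked(self, x: np.ndarray, layer: str) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise NumericalError(f"non-finite activation in layer {layer}")
        return x

    def extract(self, grid: np.ndarray) -> np.ndarray:
        """Return the 8192-vector (fc6 then fc7) for one grayscale grid."""
        x = self._preprocess(grid)
        w = self._w
        for spec in _CONV_SPECS:
            name, _, _, _, stride, pad, groups = spec
            x = _conv2d(x, w[f"{name}.weight"], w[f"{name}.bias"], stride, pad, groups)
            x = np.maximum(x, 0.0)
            x = self._checked(x, name)
            if name in ("conv1", "conv2"):
                x = _lrn(x)
                x = _maxpool(x)
            elif name == "conv5":
                x = _maxpool(x)
        flat = x.reshape(-1)
        fc6 = w["fc6.weight"] @ flat + w["fc6.bias"]
        fc6 = self._checked(fc6, "fc6")
        fc7_in = np.maximum(fc6, 0.0)
        fc7 = w["fc7.weight"] @ fc7_in + w["fc7.bias"]
        fc7 = self._checked(fc7, "fc7")
        if self.pre_activation:
            return np.concatenate([fc6, fc7]).astype(np.float32)
        return np.concatenate(
            [np.maximum(fc6, 0.0), np.maximum(fc7, 0.0)]
        ).astype(np.float32)

    def extract_many(self, grids: list[np.ndarray]) -> np.ndarray:
        return np.stack([self.extract(g) for g in grids])
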