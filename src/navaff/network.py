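"""A small feedforward convolutional network as an activation provider.

The network implements the four linear-nonlinear operations of the classic
convolutional scene-classification architecture family — convolution,
rectified linear activation, local max pooling, and local (cross-channel)
response normalization — plus dense layers, with seeded random weights (no
training).  It exists to provide a hierarchical, image-computable activation
source for the in-silico experiments: stimulus filtering, slice occlusion,
occlusion-based receptive-field mapping, and unit-subset classification.

Any object with a ``forward(images) -> {layer_name: (n, units) array}``
method and an ``input_size`` attribute satisfies the activation-provider
contract, so activations from an external pre-trained model can be plugged
into every analysis in place of this network.

Local normalization: b = a / (k + alpha * sum a^2)^beta over a cross-channel
neighborhood of n channels at the same spatial position, with the standard
constants k=2, alpha=1e-4, beta=0.75, n=5.

Weights are stored as a JSON manifest (layer names, shapes, dtype, byte
offsets) plus a little-endian float32 binary blob.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from ._utils import rng_from

__all__ = [
    "ActivationProvider",
    "LayerSpec",
    "Network",
    "NetworkConfig",
    "build_network",
    "default_network_config",
    "load_weights",
    "save_weights",
]


@runtime_checkable
class ActivationProvider(Protocol):
    input_size: tuple[int, int]

    def forward(self, images) -> dict[str, np.ndarray]: ...


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # convolution | rectification | max_pool | local_norm | dense
    kernel_size: int = 3
    stride: int = 1
    n_filters: int = 8
    pool_size: int = 2
    pool_stride: int = 2
    norm_k: float = 2.0
    norm_alpha: float = 1e-4
    norm_beta: float = 0.75
    norm_n: int = 5
    n_units: int = 64

    def __post_init__(self) -> None:
        kinds = {"convolution", "rectification", "max_pool", "local_norm", "dense"}
        if self.kind not in kinds:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "convolution" and (self.kernel_size < 1 or self.stride < 1):
            raise ValueError("kernel size and stride must be >= 1")
        if self.kind == "max_pool" and (self.pool_size < 1 or self.pool_stride < 1):
            raise ValueError("pool size and stride must be >= 1")
        if self.kind == "dense" and self.n_units < 1:
            raise ValueError("dense layer needs at least one unit")


@dataclass(frozen=True)
class NetworkConfig:
    input_size: tuple[int, int] = (64, 64)
    channels: int = 1
    layers: tuple[LayerSpec, ...] = ()
    seed: int = 0

    def layer_names(self) -> list[str]:
        names, counts = [], {}
        for spec in self.layers:
            short = {
                "convolution": "conv",
                "rectification": "relu",
                "max_pool": "pool",
                "local_norm": "norm",
                "dense": "dense",
            }[spec.kind]
            counts[short] = counts.get(short, 0) + 1
            names.append(f"{short}{counts[short]}")
        return names


def default_network_config(input_size: tuple[int, int] = (64, 64),
                           seed: int = 0) -> NetworkConfig:
    """Desk-scale default: three conv+relu stages (max-pool and local norm
    after the first two) and a dense readout, on grayscale input."""
    layers = (
        LayerSpec("convolution", kernel_size=7, stride=2, n_filters=8),
        LayerSpec("rectification"),
        LayerSpec("max_pool", pool_size=3, pool_stride=2),
        LayerSpec("local_norm"),
        LayerSpec("convolution", kernel_size=5, stride=1, n_filters=16),
        LayerSpec("rectification"),
        LayerSpec("max_pool", pool_size=3, pool_stride=2),
        LayerSpec("local_norm"),
        LayerSpec("convolution", kernel_size=3, stride=1, n_filters=32),
        LayerSpec("rectification"),
        LayerSpec("dense", n_units=64),
    )
    return NetworkConfig(input_size=input_size, channels=1, layers=layers, seed=seed)


def _conv_out(size: int, kernel: int, stride: int) -> int:
    return (size - kernel) // stride + 1


class Network:
    """Feedforward evaluation of a validated NetworkConfig."""

    def __init__(self, config: NetworkConfig, weights: list[np.ndarray | None]):
        self.config = config
        self.weights = weights
        self.input_size = config.input_size

    # -- evaluation ---------------------------------------------------------

    def forward(self, images, spatial: bool = False) -> dict[str, np.ndarray]:
        """Activations after every named operation.

        ``images``: array (H, W), (B, H, W) or (B, C, H, W), or a list of 2-D
        arrays / SceneImage objects.  Inputs whose spatial size differs from
        the configured input size are rescaled with bilinear interpolation.
        Returns flattened (B, units) activations per layer name; with
        ``spatial=True``, convolutional-stage outputs are returned in their
        (B, C, H, W) spatial view instead.
        """
        x = self._prepare(images)
        out: dict[str, np.ndarray] = {}
        for name, spec, w in zip(self.config.layer_names(), self.config.layers,
                                 self.weights):
            if spec.kind == "convolution":
                x = _conv2d(x, w, spec.stride)
            elif spec.kind == "rectification":
                x = np.maximum(x, 0.0)
            elif spec.kind == "max_pool":
                x = _max_pool(x, spec.pool_size, spec.pool_stride)
            elif spec.kind == "local_norm":
                x = _local_norm(x, spec)
            elif spec.kind == "dense":
                x = x.reshape(x.shape[0], -1) @ w
            out[name] = x if (spatial and x.ndim == 4) else x.reshape(x.shape[0], -1)
        return out

    def _prepare(self, images) -> np.ndarray:
        if isinstance(images, (list, tuple)):
            arrs = [getattr(im, "pixels", im) for im in images]
            images = np.stack([np.asarray(a, dtype=float) for a in arrs])
        else:
            images = np.asarray(getattr(images, "pixels", images), dtype=float)
        if images.ndim == 2:
            images = images[None]
        if images.ndim == 3:
            images = images[:, None]
        if images.ndim != 4:
            raise ValueError("images must be 2-D, 3-D or 4-D")
        if images.shape[1] != self.config.channels:
            raise ValueError(
                f"expected {self.config.channels} channel(s), got {images.shape[1]}"
            )
        h, w = self.config.input_size
        if images.shape[2:] != (h, w):
            images = np.stack([
                np.stack([
                    resize(ch, (h, w), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
                    for ch in img
                ])
                for img in images
            ])
        return images

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        save_weights(self, path)


def build_network(config: NetworkConfig) -> Network:
    """Validate shapes, initialize weights from the seed, return a Network.

    Convolution and dense weights are Gaussian scaled by 1/sqrt(fan-in)
    (biases are zero), which keeps untrained activations in a stable range.
    A layer that would collapse the spatial dimensions below 1x1 is reported
    by name at build time.
    """
    rng = rng_from(config.seed)
    h, w = config.input_size
    c = config.channels
    if h < 1 or w < 1 or c not in (1, 3):
        raise ValueError("input size must be positive; channels must be 1 or 3")
    names = config.layer_names()
    has_dense = any(s.kind == "dense" for s in config.layers)
    weights: list[np.ndarray | None] = []
    flattened = False
    for name, spec in zip(names, config.layers):
        if spec.kind == "convolution":
            if flattened:
                raise ValueError(f"{name}: convolution after dense is unsupported")
            oh, ow = _conv_out(h, spec.kernel_size, spec.stride), _conv_out(
                w, spec.kernel_size, spec.stride)
            if oh < 1 or ow < 1:
                raise ValueError(
                    f"{name}: spatial dimensions collapse to {oh}x{ow}"
                )
            fan_in = c * spec.kernel_size**2
            w_init = rng.standard_normal(
                (spec.n_filters, c, spec.kernel_size, spec.kernel_size)
            ) / np.sqrt(fan_in)
            # float32 storage so a save/load roundtrip is bit-exact
            weights.append(w_init.astype(np.float32))
            h, w, c = oh, ow, spec.n_filters
        elif spec.kind == "max_pool":
            if flattened:
                raise ValueError(f"{name}: pooling after dense is unsupported")
            oh, ow = _conv_out(h, spec.pool_size, spec.pool_stride), _conv_out(
                w, spec.pool_size, spec.pool_stride)
            if oh < 1 or ow < 1:
                raise ValueError(
                    f"{name}: spatial dimensions collapse to {oh}x{ow}"
                )
            weights.append(None)
            h, w = oh, ow
        elif spec.kind == "dense":
            fan_in = h * w * c if not flattened else c
            w_init = rng.standard_normal((fan_in, spec.n_units)) / np.sqrt(fan_in)
            weights.append(w_init.astype(np.float32))
            flattened, c = True, spec.n_units
        else:
            weights.append(None)
    if has_dense and (not config.layers or config.layers[-1].kind not in
                      ("dense", "rectification")):
        raise ValueError("classification heads require a trailing dense layer")
    return Network(config, weights)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided cross-correlation, (B,C,H,W) x (F,C,k,k) -> (B,F,.,.)."""
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B, C, Ho, Wo, k, k); contract C, k, k against w
    return np.einsum("bchwij,fcij->bfhw", win, w, optimize=True)


def _max_pool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (size, size), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.max(axis=(-2, -1))


def _local_norm(x: np.ndarray, spec: LayerSpec) -> np.ndarray:
    """Cross-channel response normalization at each spatial position."""
    c = x.shape[1]
    sq = x**2
    half = spec.norm_n // 2
    denom = np.empty_like(x)
    for ch in range(c):
        lo, hi = max(0, ch - half), min(c, ch + half + 1)
        denom[:, ch] = sq[:, lo:hi].sum(axis=1)
    return x / (spec.norm_k + spec.norm_alpha * denom) ** spec.norm_beta


# ---------------------------------------------------------------------------
# weight store: JSON manifest + float32 little-endian blob
# ---------------------------------------------------------------------------

def save_weights(network: Network, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    blob = path.with_suffix(".bin")
    entries, offset = [], 0
    with open(blob, "wb") as fh:
        for name, w in zip(network.config.layer_names(), network.weights):
            if w is None:
                continue
            data = np.ascontiguousarray(w, dtype="<f4")
            fh.write(data.tobytes())
            entries.append({
                "layer": name,
                "shape": list(w.shape),
                "dtype": "<f4",
                "offset": offset,
            })
            offset += data.nbytes
    manifest = {"blob": blob.name, "total_bytes": offset, "layers": entries}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_weights(config: NetworkConfig, path) -> Network:
    """Rebuild a network and replace its weights from a manifest + blob.

    Layer names and weight shapes must match the config exactly; mismatches
    are reported with the expected and found shapes.
    """
    path = Path(path)
    try:
        manifest = json.loads(path.read_text())
        entries = {e["layer"]: e for e in manifest["layers"]}
        raw = (path.parent / manifest["blob"]).read_bytes()
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted weight manifest: {exc}") from exc
    network = build_network(config)
    expected = [
        (name, w.shape)
        for name, w in zip(config.layer_names(), network.weights)
        if w is not None
    ]
    found = [(e["layer"], tuple(e["shape"])) for e in manifest["layers"]]
    if [n for n, _ in expected] != [n for n, _ in found]:
        raise ValueError(
            f"layer mismatch: config has {[n for n, _ in expected]}, "
            f"manifest has {[n for n, _ in found]}"
        )
    new_weights = []
    for name, w in zip(config.layer_names(), network.weights):
        if w is None:
            new_weights.append(None)
            continue
        e = entries[name]
        shape = tuple(e["shape"])
        if shape != w.shape:
            raise ValueError(
                f"{name}: expected shape {w.shape}, manifest has {shape}"
            )
        count = int(np.prod(shape))
        arr = np.frombuffer(
            raw, dtype=e["dtype"], count=count, offset=e["offset"]
        ).reshape(shape)
        new_weights.append(arr.astype(np.float32))
    network.weights = new_weights
    return network
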