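"""In-silico stimulus-input experiments.

Two families of manipulated stimulus sets probe which image inputs carry the
representational similarity between a network and a target RDM (an affordance
model or a neural RDM):

* **feature filters** — grayscale conversion, Fourier-domain Gaussian
  high-pass (sigma 0.1 cycles/pixel) and low-pass (sigma 0.0075 cycles/pixel)
  filters, and oriented edge-energy maps from 3x3 zero-sum line-detection
  kernels at cardinal (0/90 degree) or oblique (45/135 degree) orientations;
* **slice occlusion** — everything outside a small horizontal slice
  (41 px high, advanced with a 5 px stride by default) is masked with
  mid-gray.

For each manipulated set, layer RDMs are rebuilt and a two-predictor
regression (original-stimulus layer RDM + manipulated-stimulus layer RDM,
target = affordance or neural RDM) is decomposed by commonality analysis; the
reported score is the shared-variance percentage SV: how much of the original
representation's explained variance survives in the manipulated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import check_finite
from .inference import commonality
from .rdm import RDM, compute_rdm, reduce_pca

__all__ = [
    "CARDINAL_KERNELS",
    "OBLIQUE_KERNELS",
    "FilterSpec",
    "SharedVarianceProfile",
    "SliceOcclusionConfig",
    "apply_filter",
    "fourier_gaussian_filter",
    "layer_rdms",
    "make_slice_stimuli",
    "orientation_energy",
    "run_feature_experiment",
    "run_slice_experiment",
    "slice_positions",
    "to_grayscale",
]

# classical 3x3 line-detection kernels; each sums to zero
_H = np.array([[-1.0, -1.0, -1.0], [2.0, 2.0, 2.0], [-1.0, -1.0, -1.0]])
_D1 = np.array([[2.0, -1.0, -1.0], [-1.0, 2.0, -1.0], [-1.0, -1.0, 2.0]])
CARDINAL_KERNELS = (_H, _H.T.copy())          # 0 and 90 degrees
OBLIQUE_KERNELS = (_D1, np.fliplr(_D1).copy())  # 45 and 135 degrees

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FilterSpec:
    """One stimulus manipulation.

    ``kind`` is one of grayscale / highpass / lowpass / cardinal / oblique;
    ``sigma_cpp`` (cycles per pixel) applies to the frequency filters.
    """

    kind: str
    sigma_cpp: float | None = None

    def __post_init__(self) -> None:
        kinds = {"grayscale", "highpass", "lowpass", "cardinal", "oblique"}
        if self.kind not in kinds:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind in ("highpass", "lowpass"):
            sigma = self.resolved_sigma()
            if sigma <= 0:
                raise ValueError("sigma_cpp must be positive")

    def resolved_sigma(self) -> float:
        if self.sigma_cpp is not None:
            return self.sigma_cpp
        return {"highpass": 0.1, "lowpass": 0.0075}.get(self.kind, 0.0)


DEFAULT_FILTERS = (
    FilterSpec("grayscale"),
    FilterSpec("highpass"),
    FilterSpec("lowpass"),
    FilterSpec("cardinal"),
    FilterSpec("oblique"),
)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale conversion; idempotent on 2-D input."""
    img = check_finite(getattr(image, "pixels", image), "image")
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] == 3:
        return img @ _LUMA
    if img.ndim == 3 and img.shape[0] == 3:
        return np.tensordot(_LUMA, img, axes=1)
    raise ValueError("expected (H, W) or RGB image")


def fourier_gaussian_filter(image: np.ndarray, sigma_cpp: float,
                            mode: str) -> np.ndarray:
    """Gaussian frequency filtering of a grayscale image.

    The spectrum is multiplied by G(f) = exp(-f^2 / (2 sigma^2)) with f the
    radial frequency in cycles/pixel on the discrete Fourier grid ("lowpass"),
    or by its complement 1 - G ("highpass", which removes low frequencies
    including DC).  The imaginary residue of the inverse transform is
    discarded (it is at rounding level for real input).
    """
    img = check_finite(image, "image")
    if img.ndim != 2:
        raise ValueError("frequency filters need a 2-D grayscale image")
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f2 = fy**2 + fx**2
    g = np.exp(-f2 / (2.0 * sigma_cpp**2))
    transfer = g if mode == "lowpass" else 1.0 - g
    out = np.fft.ifft2(np.fft.fft2(img) * transfer)
    return np.real(out)


def orientation_energy(image: np.ndarray, kernel_set: str) -> np.ndarray:
    """Edge-energy map for one orientation set.

    Convolves the grayscale image with both zero-sum kernels of the set
    (cardinal: 0/90 degrees; oblique: 45/135), squares, sums, and takes the
    square root.
    """
    from scipy.ndimage import convolve

    img = to_grayscale(image)
    kernels = {"cardinal": CARDINAL_KERNELS, "oblique": OBLIQUE_KERNELS}[kernel_set]
    total = np.zeros_like(img, dtype=float)
    for k in kernels:
        total += convolve(img, k, mode="reflect") ** 2
    return np.sqrt(total)


def apply_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply one stimulus manipulation; grayscale conversion happens first."""
    gray = to_grayscale(image)
    if spec.kind == "grayscale":
        return gray
    if spec.kind in ("highpass", "lowpass"):
        return fourier_gaussian_filter(gray, spec.resolved_sigma(), spec.kind)
    return orientation_energy(gray, spec.kind)


# ---------------------------------------------------------------------------
# slice occlusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceOcclusionConfig:
    slice_height: int = 41
    stride: int = 5
    fill: float = 0.5
    append_flush_bottom: bool = True


def slice_positions(image_height: int, config: SliceOcclusionConfig) -> list[int]:
    """Top rows of the exposed slice, covering the whole vertical axis.

    Regular positions advance by ``stride``; if the last regular position does
    not reach the bottom of the image, one flush-bottom position is appended
    (so the union of slices always covers every row).
    """
    h, sh = image_height, config.slice_height
    if sh > h:
        raise ValueError(f"slice height {sh} exceeds image height {h}")
    if config.stride < 1:
        raise ValueError("stride must be >= 1")
    n_regular = (h - sh) // config.stride + 1
    positions = [i * config.stride for i in range(n_regular)]
    if config.append_flush_bottom and positions[-1] != h - sh:
        positions.append(h - sh)
    return positions


def make_slice_stimuli(images, config: SliceOcclusionConfig
                       ) -> tuple[list[np.ndarray], list[int]]:
    """Occluded stimulus sets: one per slice position.

    Returns (sets, positions) where sets[i] is an (n_images, H, W) array in
    which everything outside rows [positions[i], positions[i]+slice_height)
    is replaced by the occluder fill value.
    """
    arrs = np.stack([to_grayscale(im) for im in images])
    h = arrs.shape[1]
    positions = slice_positions(h, config)
    sets = []
    for top in positions:
        occluded = np.full_like(arrs, config.fill)
        occluded[:, top: top + config.slice_height, :] = (
            arrs[:, top: top + config.slice_height, :]
        )
        sets.append(occluded)
    return sets, positions


# ---------------------------------------------------------------------------
# shared-variance experiments
# ---------------------------------------------------------------------------

def layer_rdms(network, images, labels, pca_k: int | None = 45,
               layer_names: list[str] | None = None) -> dict[str, RDM]:
    """Forward a stimulus set and build one RDM per layer.

    Each layer's (image x unit) activations are reduced to at most ``pca_k``
    principal components (capped at the available rank), z-scored across
    components per image, and converted to a squared-Euclidean RDM.  A layer
    whose activations are identical for every image (e.g. fully occluded,
    featureless stimuli) yields the all-zero RDM.
    """
    acts = network.forward(images)
    if layer_names is not None:
        acts = {k: acts[k] for k in layer_names}
    out = {}
    n = len(labels)
    for name, a in acts.items():
        a = a.reshape(n, -1)
        if np.allclose(a.std(axis=0), 0.0):
            out[name] = RDM(np.zeros((n, n)), labels, source=name)
            continue
        if pca_k is not None:
            k = min(pca_k, n - 1, a.shape[1])
            a = reduce_pca(a, k)
        out[name] = compute_rdm(a, labels, source=name)
    return out


def _sv_or_nan(target: RDM, x1: RDM, x2: RDM) -> float:
    res = commonality(target, x1, x2)
    return res.shared_variance_pct if res.sv_defined else float("nan")


def run_feature_experiment(
    images,
    network,
    target_rdms: dict[str, RDM],
    specs=DEFAULT_FILTERS,
    pca_k: int | None = 45,
    layer_names: list[str] | None = None,
    labels=None,
) -> pd.DataFrame:
    """Shared-variance table over feature filters, layers, and targets.

    For each layer and filter, X1 = the layer RDM of the original stimuli and
    X2 = the layer RDM of the filtered stimuli; the target is each RDM in
    ``target_rdms``.  SV says how much of X1's explained variance in the
    target the filtered inputs retain.  Returns a tidy frame with columns
    (feature, layer, target, shared_variance_pct) plus per-feature mean and
    SEM across layers.
    """
    if labels is None:
        labels = next(iter(target_rdms.values())).labels
    gray = [to_grayscale(im) for im in images]
    orig = layer_rdms(network, gray, labels, pca_k, layer_names)
    rows = []
    for spec in specs:
        filtered = [apply_filter(im, spec) for im in images]
        filt = layer_rdms(network, filtered, labels, pca_k, layer_names)
        for layer in orig:
            if layer not in filt:
                continue
            for tname, target in target_rdms.items():
                rows.append({
                    "feature": spec.kind,
                    "layer": layer,
                    "target": tname,
                    "shared_variance_pct": _sv_or_nan(
                        target, orig[layer], filt[layer]),
                })
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["feature", "target"])["shared_variance_pct"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    df.attrs["summary"] = summary
    return df


@dataclass
class SharedVarianceProfile:
    per_slice: pd.DataFrame  # columns: position, layer, target, shared_variance_pct
    pixel_heatmap: dict[str, np.ndarray]  # per target, (H,) mean SV covering each row
    lower_minus_upper: dict[str, float]
    positions: list[int]
    slice_height: int


def run_slice_experiment(
    images,
    network,
    target_rdms: dict[str, RDM],
    config: SliceOcclusionConfig = SliceOcclusionConfig(),
    pca_k: int | None = 45,
    layer_names: list[str] | None = None,
    labels=None,
) -> SharedVarianceProfile:
    """Shared variance of slice-occluded stimuli along the vertical axis.

    Per slice position and layer, SV of the occluded-stimulus layer RDM with
    respect to the original layer RDM for each target.  The pixel heat map
    assigns each image row the mean SV (across layers and covering slices) of
    the slices that expose it; ``lower_minus_upper`` is the mean SV over
    slices whose centers fall in the lower image half minus the upper-half
    mean — positive values indicate a lower-visual-field bias.
    """
    if labels is None:
        labels = next(iter(target_rdms.values())).labels
    gray = [to_grayscale(im) for im in images]
    h = gray[0].shape[0]
    orig = layer_rdms(network, gray, labels, pca_k, layer_names)
    sets, positions = make_slice_stimuli(gray, config)
    rows = []
    for top, occluded in zip(positions, sets):
        occ = layer_rdms(network, list(occluded), labels, pca_k, layer_names)
        for layer in orig:
            if layer not in occ:
                for tname in target_rdms:
                    rows.append({"position": top, "layer": layer,
                                 "target": tname,
                                 "shared_variance_pct": float("nan")})
                continue
            for tname, target in target_rdms.items():
                rows.append({
                    "position": top,
                    "layer": layer,
                    "target": tname,
                    "shared_variance_pct": _sv_or_nan(
                        target, orig[layer], occ[layer]),
                })
    df = pd.DataFrame(rows)
    heatmaps, lmu = {}, {}
    centers = {top: top + (config.slice_height - 1) / 2.0 for top in positions}
    for tname in target_rdms:
        sub = df[df["target"] == tname]
        per_pos = sub.groupby("position")["shared_variance_pct"].mean()
        acc = np.zeros(h)
        cnt = np.zeros(h)
        for top, sv in per_pos.items():
            if np.isnan(sv):
                continue
            acc[top: top + config.slice_height] += sv
            cnt[top: top + config.slice_height] += 1
        with np.errstate(invalid="ignore"):
            heatmaps[tname] = acc / np.where(cnt > 0, cnt, np.nan)
        lower = [sv for top, sv in per_pos.items() if centers[top] >= h / 2.0]
        upper = [sv for top, sv in per_pos.items() if centers[top] < h / 2.0]
        lmu[tname] = float(np.nanmean(lower) - np.nanmean(upper))
    return SharedVarianceProfile(
        per_slice=df, pixel_heatmap=heatmaps, lower_minus_upper=lmu,
        positions=positions, slice_height=config.slice_height,
    )
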