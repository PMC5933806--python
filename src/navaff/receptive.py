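"""Occlusion-based receptive-field characterization of network units.

A unit's sensitivity to each image location is mapped by sliding a small
occluder (11x11 px of random pixel values, stride 3 by default) over the
image and logging the absolute change in the unit's activation; assigning
each occluder's discrepancy to the pixels it covers (averaging overlaps)
yields a pixel-resolution discrepancy map whose peak localizes the unit's
receptive field.  Downstream: units are ranked by their unit-wise RSA
correlations to the affordance and neural RDMs; discrepancy maps are smoothed
with a 20x20 box filter and segmented at 10% of the peak; and units are
embedded in 2-D (t-SNE over their responses to 81x81 patches cut around the
peaks of their top-3 images) and grouped by silhouette-selected k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, uniform_filter
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from ._utils import rng_from, zscore
from .rdm import RDM, compute_rdm
from .inference import spearman_rsa

__all__ = [
    "DiscrepancyMap",
    "SegmentationMask",
    "UnitClustering",
    "UnitSelection",
    "embed_and_cluster_units",
    "map_discrepancy",
    "segment_receptive_field",
    "select_units",
]


@dataclass
class DiscrepancyMap:
    values: np.ndarray  # (H, W), >= 0
    unit_id: int
    image_id: int | str = 0
    grid: np.ndarray | None = None  # occluder top-left positions

    def smoothed(self, size: int = 20) -> np.ndarray:
        return uniform_filter(self.values, size=size, mode="reflect")

    def peak(self, smooth: int = 20) -> tuple[int, int]:
        """Peak of the smoothed map; ties break to lowest row, then column."""
        sm = self.smoothed(smooth)
        idx = int(np.argmax(sm))  # argmax is row-major: lowest row/col first
        return np.unravel_index(idx, sm.shape)


@dataclass
class SegmentationMask:
    mask: np.ndarray  # boolean (H, W)
    threshold_value: float
    outline: np.ndarray  # boolean boundary pixels
    empty: bool = False


@dataclass
class UnitSelection:
    unit_ids: np.ndarray
    scores: np.ndarray  # aligned with unit_ids
    layer: str


@dataclass
class UnitClustering:
    embedding: np.ndarray  # (n_units, 2)
    labels: np.ndarray
    k: int
    silhouette: float | None
    degenerate: bool = False


def map_discrepancy(
    network,
    image,
    layer: str,
    units=None,
    patch_size: int = 11,
    stride: int = 3,
    seed: int = 0,
) -> dict[int, DiscrepancyMap]:
    """Occlusion discrepancy maps for the requested units of one layer.

    For every occluder position on the stride grid the occluded image (patch
    replaced by seeded uniform-random values over [0, 1]) is forwarded and the
    per-unit |activation difference| from the intact image is logged; the
    pixel map averages the discrepancies of all occluders covering each pixel.
    """
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    h, w = img.shape
    if patch_size > min(h, w):
        raise ValueError("occluder does not fit in the image")
    base = network.forward(img[None])[layer][0]
    n_units_total = base.size
    if units is None:
        units = np.arange(n_units_total)
    units = np.asarray(units, dtype=int)
    if np.any(units < 0) or np.any(units >= n_units_total):
        bad = units[(units < 0) | (units >= n_units_total)]
        raise ValueError(f"unit id(s) {bad.tolist()} not in layer {layer!r}")

    tops = np.arange(0, h - patch_size + 1, stride)
    lefts = np.arange(0, w - patch_size + 1, stride)
    rng = rng_from(seed)
    batch, grid = [], []
    for t in tops:
        for l in lefts:
            occ = img.copy()
            occ[t: t + patch_size, l: l + patch_size] = rng.uniform(
                0.0, 1.0, size=(patch_size, patch_size))
            batch.append(occ)
            grid.append((t, l))
    acts = network.forward(np.stack(batch))[layer]  # (positions, units)
    disc = np.abs(acts[:, units] - base[units])  # (positions, n_sel)

    acc = np.zeros((len(units), h, w))
    cnt = np.zeros((h, w))
    for i, (t, l) in enumerate(grid):
        acc[:, t: t + patch_size, l: l + patch_size] += disc[i][:, None, None]
        cnt[t: t + patch_size, l: l + patch_size] += 1
    covered = cnt > 0
    maps = {}
    grid_arr = np.asarray(grid)
    for j, u in enumerate(units):
        vals = np.zeros((h, w))
        vals[covered] = acc[j][covered] / cnt[covered]
        maps[int(u)] = DiscrepancyMap(values=vals, unit_id=int(u), grid=grid_arr)
    return maps


def select_units(
    layer_activations: np.ndarray,
    affordance_rdm: RDM,
    neural_rdm: RDM,
    n: int = 50,
) -> UnitSelection:
    """Top-n units by mean unit-wise RSA correlation to the two target RDMs.

    A unit's RDM is the matrix of squared differences of its z-scored
    activations across images; its score is the mean of the Spearman
    correlations to the affordance RDM and the neural RDM.  Constant
    (zero-variance) units cannot be scored and rank last.
    """
    acts = np.asarray(layer_activations, dtype=float)
    n_images, n_units = acts.shape
    if n > n_units:
        raise ValueError(f"requested {n} units but layer has {n_units}")
    labels = affordance_rdm.labels
    scores = np.full(n_units, -np.inf)
    sd = acts.std(axis=0, ddof=1)
    for u in range(n_units):
        if sd[u] == 0:
            continue
        z = (acts[:, u] - acts[:, u].mean()) / sd[u]
        unit_rdm = compute_rdm(z[:, None], labels, source=f"unit{u}")
        r1 = spearman_rsa(unit_rdm, affordance_rdm)
        r2 = spearman_rsa(unit_rdm, neural_rdm)
        score = np.nanmean([r1, r2])
        if not np.isnan(score):
            scores[u] = score
    order = np.argsort(-scores, kind="stable")
    chosen = order[:n]
    return UnitSelection(unit_ids=chosen, scores=scores[chosen], layer="")


def segment_receptive_field(
    disc_map: DiscrepancyMap,
    image: np.ndarray | None = None,
    smooth: int = 20,
    threshold_frac: float = 0.10,
    darken: float = 0.3,
) -> tuple[SegmentationMask, np.ndarray | None]:
    """Threshold the smoothed discrepancy map at a fraction of its peak.

    Pixels whose smoothed discrepancy is at least ``threshold_frac`` times the
    peak (inclusive) form the mask, so the mask is invariant to positive
    rescaling of the map.  When an image is supplied, a composite is returned
    with out-of-mask pixels darkened and the mask boundary highlighted.
    An all-zero map yields an empty, flagged mask.
    """
    sm = disc_map.smoothed(smooth)
    peak = float(sm.max())
    if peak <= 0:
        mask = np.zeros_like(sm, dtype=bool)
        seg = SegmentationMask(mask=mask, threshold_value=0.0,
                               outline=mask.copy(), empty=True)
        return seg, None
    thr = threshold_frac * peak
    mask = sm >= thr
    outline = mask & ~binary_erosion(mask)
    seg = SegmentationMask(mask=mask, threshold_value=thr, outline=outline)
    if image is None:
        return seg, None
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    composite = np.stack([img, img, img], axis=-1)
    composite[~mask] *= darken
    composite[outline] = (1.0, 0.0, 0.0)
    return seg, composite


def embed_and_cluster_units(
    unit_maps: dict[int, list[DiscrepancyMap]],
    images: list[np.ndarray],
    network,
    layer: str,
    patch: int = 81,
    top_k: int = 3,
    k_range: range = range(2, 11),
    min_silhouette: float = 0.25,
    seed: int = 0,
) -> UnitClustering:
    """2-D embedding and clustering of units by their preferred image content.

    For each unit, the ``top_k`` images with the largest discrepancy are
    identified; ``patch`` x ``patch`` windows centered on the smoothed-map
    peaks are cut out (clipped at image borders), forwarded through the
    network, and the requested layer's responses are averaged over the top
    images.  The unit x response matrix is embedded in 2-D with t-SNE
    (perplexity min(15, (n_units - 1)/3)) and partitioned by k-means with the
    silhouette criterion over ``k_range``; when the best silhouette falls
    below ``min_silhouette`` a single cluster is reported.  An all-identical
    response matrix is flagged degenerate.
    """
    unit_ids = sorted(unit_maps)
    if len(unit_ids) < 3:
        raise ValueError("need at least three units to embed")
    if any(len(unit_maps[u]) < top_k for u in unit_ids):
        raise ValueError(f"each unit needs at least {top_k} discrepancy maps")
    responses = []
    for u in unit_ids:
        maps = sorted(unit_maps[u], key=lambda m: -float(m.values.max()))[:top_k]
        patches = []
        for m in maps:
            img = np.asarray(
                getattr(images[_image_index(m)], "pixels", images[_image_index(m)]),
                dtype=float)
            pr, pc = m.peak()
            half = patch // 2
            h, w = img.shape
            r0 = int(np.clip(pr - half, 0, max(0, h - patch)))
            c0 = int(np.clip(pc - half, 0, max(0, w - patch)))
            patches.append(img[r0: r0 + patch, c0: c0 + patch])
        acts = network.forward(patches)[layer]
        responses.append(acts.mean(axis=0))
    x = np.asarray(responses)
    if np.allclose(x, x[0], atol=1e-12):
        return UnitClustering(
            embedding=np.zeros((len(unit_ids), 2)),
            labels=np.zeros(len(unit_ids), dtype=int),
            k=1, silhouette=None, degenerate=True,
        )
    n_units = len(unit_ids)
    perplexity = min(15.0, (n_units - 1) / 3.0)
    emb = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        random_state=seed, max_iter=500,
    ).fit_transform(x)
    best = (None, -np.inf, None)
    for k in k_range:
        if k >= n_units or k < 2:
            continue
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(emb)
        sil = silhouette_score(emb, km.labels_)
        if sil > best[1]:
            best = (k, sil, km.labels_)
    if best[0] is None or best[1] < min_silhouette:
        return UnitClustering(embedding=emb,
                              labels=np.zeros(n_units, dtype=int),
                              k=1, silhouette=None if best[0] is None else float(best[1]))
    return UnitClustering(embedding=emb, labels=best[2], k=int(best[0]),
                          silhouette=float(best[1]))


def _image_index(m: DiscrepancyMap) -> int:
    try:
        return int(m.image_id)
    except (TypeError, ValueError):
        raise ValueError(
            "DiscrepancyMap.image_id must index into the images list"
        ) from None
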