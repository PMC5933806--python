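"""Navigational-affordance histograms from behavioral path heat maps.

A path heat map (nonnegative pixel mass of walking trajectories drawn from the
bottom center of a scene image) is converted into a 180-bin angular histogram
of navigability: each pixel's mass is assigned to the one-degree bin of its
angle from the origin at the bottom center.  Angular convention: angle =
atan2(rows above origin, columns right of origin), so 0 degrees is the
rightward horizontal, 90 degrees is straight ahead (up the image), and 180
(folded into bin 179) is the leftward horizontal; bin k covers [k, k+1)
degrees.  The synthetic scene generator uses the same convention for its
opening azimuths.

The raw histogram is then smoothed with a discrete-cosine-transform penalized
least-squares smoother whose penalty is chosen by generalized cross-validation
(an automated smoother of the Whittaker/Garcia family), and finally z-scored
across bins.  The z-scored histograms are the representational patterns from
which the affordance RDM is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import dct, idct

from ._utils import check_finite
from .rdm import RDM, compute_rdm

N_BINS = 180

__all__ = [
    "AffordanceHistogram",
    "N_BINS",
    "affordance_rdm",
    "bin_paths",
    "dct_pls_smooth",
    "histogram_from_map",
    "smooth_and_normalize",
]


@dataclass
class AffordanceHistogram:
    """Raw, smoothed and normalized 180-bin angular navigability profile."""

    raw: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray
    degenerate: bool = False

    def argmax_deg(self) -> int:
        """Center bin (degrees) of the smoothed histogram's peak."""
        return int(np.argmax(self.smoothed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_deg": np.arange(N_BINS),
                "raw": self.raw,
                "smoothed": self.smoothed,
                "normalized": self.normalized,
            }
        )


def bin_paths(heat_map: np.ndarray, origin: tuple[int, int] | None = None) -> np.ndarray:
    """Sum heat-map mass along one-degree angular bins radiating from origin.

    Pixels above the origin row contribute to the bin of their angle from the
    origin; pixels exactly on the origin row go to bin 0 (right of origin) or
    bin 179 (left); the origin pixel itself is excluded.  Total histogram mass
    therefore equals the map mass over the upper half-plane.
    """
    m = check_finite(heat_map, "heat map")
    if m.ndim != 2:
        raise ValueError("heat map must be 2-D")
    if np.any(m < 0):
        raise ValueError("heat map must be nonnegative")
    h, w = m.shape
    if origin is None:
        origin = (h - 1, w // 2)
    r0, c0 = origin
    if m.sum() <= 0:
        raise ValueError("heat map has zero mass")
    rows, cols = np.mgrid[0:h, 0:w]
    dy = r0 - rows  # rows above origin (positive = upward)
    dx = cols - c0  # columns right of origin
    ang = np.degrees(np.arctan2(dy, dx))  # in [0, 180] for dy >= 0
    bins = np.floor(ang).astype(int)
    # on-origin-row pixels: angle is exactly 0 or 180; fold 180 into bin 179
    bins = np.clip(bins, 0, N_BINS - 1)
    valid = (dy >= 0) & ~((dy == 0) & (dx == 0))
    hist = np.bincount(bins[valid], weights=m[valid], minlength=N_BINS)
    return hist[:N_BINS]


def dct_pls_smooth(y: np.ndarray, penalty: float | None = None,
                   grid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Penalized least-squares smoothing in the DCT domain.

    The smoothed signal is z = IDCT(G * DCT(y)) with per-frequency gains
    G_i = 1 / (1 + s * lam_i^2), lam_i = 2 - 2 cos(pi i / n): the eigenvalues
    of a second-difference penalty with reflective boundaries.  The penalty s
    is selected by generalized cross-validation over a 61-point log grid
    spanning 1e-6 ... 1e6 unless given explicitly.

    Returns (smoothed, selected_penalty).
    """
    y = check_finite(np.asarray(y, dtype=float), "signal")
    n = y.size
    lam = 2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n)
    yd = dct(y, type=2, norm="ortho")
    if penalty is not None:
        gains = 1.0 / (1.0 + penalty * lam**2)
        return idct(gains * yd, type=2, norm="ortho"), float(penalty)
    if grid is None:
        grid = np.logspace(-6, 6, 61)
    best = (np.inf, grid[0])
    for s in grid:
        gains = 1.0 / (1.0 + s * lam**2)
        resid = (gains - 1.0) * yd  # Parseval: residual norm in DCT domain
        trace_h = gains.sum()
        denom = (1.0 - trace_h / n) ** 2
        if denom <= 0:
            continue
        gcv = (np.sum(resid**2) / n) / denom
        if gcv < best[0]:
            best = (gcv, s)
    s = best[1]
    gains = 1.0 / (1.0 + s * lam**2)
    return idct(gains * yd, type=2, norm="ortho"), float(s)


def smooth_and_normalize(raw: np.ndarray) -> AffordanceHistogram:
    """Smooth a raw angular histogram and z-score it across bins.

    A constant raw histogram has no angular structure to normalize; it is
    returned with an all-zero normalized profile and ``degenerate=True``
    instead of NaNs, which keeps downstream RDM construction total.
    """
    raw = check_finite(np.asarray(raw, dtype=float), "raw histogram")
    if raw.size != N_BINS:
        raise ValueError(f"expected {N_BINS} bins, got {raw.size}")
    smoothed, _ = dct_pls_smooth(raw)
    sd = smoothed.std(ddof=1)
    if sd == 0:
        return AffordanceHistogram(raw, smoothed, np.zeros(N_BINS), degenerate=True)
    normalized = (smoothed - smoothed.mean()) / sd
    return AffordanceHistogram(raw, smoothed, normalized)


def histogram_from_map(heat_map: np.ndarray) -> AffordanceHistogram:
    """Convenience: bin a path heat map and smooth + normalize the result."""
    return smooth_and_normalize(bin_paths(heat_map))


def affordance_rdm(histograms: list[AffordanceHistogram], labels,
                   source: str = "affordance") -> RDM:
    """Squared Euclidean RDM over the z-scored affordance histograms."""
    patterns = np.stack([h.normalized for h in histograms])
    return compute_rdm(patterns, labels, source=source)
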