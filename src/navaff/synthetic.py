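"""Synthetic inputs with known ground truth.

This module generates every input the downstream analyses need — indoor scene
images with parametric doorway openings, rater path heat maps, cohorts of
run-level voxel patterns planted from a target RDM, and labeled unit
activation sets — so the full pipeline is testable end to end without any
external recordings or pre-trained weights.

Scenes are simple parametric renderings: a textured floor plane, wall planes,
a dark floor-wall junction row, bright door-like rectangles at the opening
azimuths, and bright path stripes on the floor leading to each opening.
Azimuths use the same convention as the affordance histograms: 0 degrees is
the rightward horizontal from the bottom-center origin, 90 is straight ahead.

Voxel-pattern cohorts are planted by classically (Torgerson) embedding a
target RDM and mapping the embedding into voxel space with an orthonormal
map, so the squared-Euclidean RDM of a noiseless subject's averaged patterns
reproduces the target exactly.  Two maps are available: a QR map (random
orthonormal directions) and a Hadamard map whose flat +-1/sqrt(m) entries
additionally give every voxel identical variance, which makes the voxel-wise
z-scoring stage of the fMRI normalization an exact rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.ndimage import gaussian_filter

from ._utils import check_finite, rng_from
from .rdm import RDM

__all__ = [
    "LabeledActivationSet",
    "PathHeatMap",
    "SceneImage",
    "SceneSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_labeled_activations",
    "render_scene",
    "simulate_rater_paths",
]


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic indoor scene.

    ``opening_azimuths`` are degrees in (0, 180) (exclusive endpoints: an
    opening must lie ahead of the viewer); ``opening_widths`` is the angular
    width of each doorway, scalar or per-opening.  ``junction_frac`` places
    the floor-wall junction row as a fraction of image height from the top.
    """

    image_size: tuple[int, int] = (227, 227)
    opening_azimuths: tuple[float, ...] = (90.0,)
    opening_widths: float | tuple[float, ...] = 14.0
    wall_luminance: float = 0.45
    floor_luminance: float = 0.25
    texture_frequency: float = 0.06
    junction_frac: float = 0.55
    door_luminance: float = 0.95
    path_luminance: float = 0.75
    draw_floor_paths: bool = True
    seed: int = 0

    def widths(self) -> tuple[float, ...]:
        if np.isscalar(self.opening_widths):
            return tuple(float(self.opening_widths) for _ in self.opening_azimuths)
        w = tuple(float(x) for x in self.opening_widths)
        if len(w) != len(self.opening_azimuths):
            raise ValueError("one width per opening required")
        return w

    def mirrored(self) -> "SceneSpec":
        """The left-right mirrored scene (azimuth -> 180 - azimuth)."""
        return SceneSpec(
            image_size=self.image_size,
            opening_azimuths=tuple(180.0 - a for a in self.opening_azimuths),
            opening_widths=self.opening_widths,
            wall_luminance=self.wall_luminance,
            floor_luminance=self.floor_luminance,
            texture_frequency=self.texture_frequency,
            junction_frac=self.junction_frac,
            door_luminance=self.door_luminance,
            path_luminance=self.path_luminance,
            draw_floor_paths=self.draw_floor_paths,
            seed=self.seed,
        )


@dataclass
class SceneImage:
    pixels: np.ndarray  # (H, W) grayscale in [0, 1]
    azimuths: tuple[float, ...] = ()
    spec: SceneSpec | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.pixels * 255.0), 0, 255).astype(np.uint8)

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.to_uint8(), mode="L").save(path)


def _door_column_interval(az: float, half_width: float, rise: float,
                          cx: float) -> tuple[float, float]:
    """Horizontal pixel interval of a doorway at the junction row.

    Columns of the rays at az +- half_width where they cross ``rise`` rows
    above the origin.  cot is decreasing on (0, 180), so the + edge is the
    left one.
    """
    lo_ang = min(179.5, az + half_width)
    hi_ang = max(0.5, az - half_width)
    c_left = cx + rise / math.tan(math.radians(lo_ang))
    c_right = cx + rise / math.tan(math.radians(hi_ang))
    return c_left, c_right


def render_scene(spec: SceneSpec) -> SceneImage:
    """Render a synthetic indoor scene; deterministic for a fixed spec.

    The rendering commutes with left-right mirroring: textures are cosine
    patterns symmetric about the center column, and all door/path extents are
    computed as float column intervals tested symmetrically, so mirroring the
    spec mirrors the image bit-exactly (odd image widths mirror about the
    origin column).
    """
    h, w = spec.image_size
    if h < 8 or w < 8:
        raise ValueError("image too small")
    azs = tuple(float(a) for a in spec.opening_azimuths)
    if any(not (0.0 < a < 180.0) for a in azs):
        raise ValueError("opening azimuths must lie strictly within (0, 180)")
    widths = spec.widths()
    if any(wd <= 0 for wd in widths):
        raise ValueError("opening widths must be positive")

    junction_row = int(round(spec.junction_frac * (h - 1)))
    origin_row, cx = h - 1, w // 2
    rise = origin_row - junction_row
    if rise < 1:
        raise ValueError("junction_frac leaves no floor")

    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    img = np.empty((h, w), dtype=float)

    # wall: vertical cosine texture, even about the center column
    wall_tex = 0.05 * np.cos(2 * np.pi * spec.texture_frequency * (cols - cx))
    img[: junction_row + 1, :] = spec.wall_luminance + wall_tex
    # floor: horizontal cosine texture (rows only), mirror-invariant
    floor_tex = 0.05 * np.cos(2 * np.pi * spec.texture_frequency * (rows - junction_row))
    img[junction_row + 1:, :] = (spec.floor_luminance + floor_tex)[junction_row + 1:, :]

    # doorways: bright rectangles rising from the junction row
    door_height = max(2, int(round(0.22 * h)))
    intervals = []
    for az, wd in zip(azs, widths):
        c_lo, c_hi = _door_column_interval(az, wd / 2.0, rise, cx)
        intervals.append((c_lo, c_hi, az))
    intervals.sort()
    for (a_lo, a_hi, az_a), (b_lo, b_hi, az_b) in zip(intervals, intervals[1:]):
        if b_lo <= a_hi:
            raise ValueError(
                f"openings at azimuths {az_a:g} and {az_b:g} degrees overlap "
                "after rendering"
            )
    col_grid = cols[0]
    for c_lo, c_hi, _az in intervals:
        mask = (col_grid >= c_lo) & (col_grid <= c_hi)
        top = max(0, junction_row - door_height)
        img[top: junction_row + 1, mask] = spec.door_luminance

    # floor-wall junction: a dark row
    img[junction_row, :] = 0.05

    # floor paths toward each opening
    if spec.draw_floor_paths:
        half_px = max(1.5, 0.015 * w)
        for az in azs:
            cot = 1.0 / math.tan(math.radians(az))
            for r in range(junction_row + 1, h):
                center = cx + (origin_row - r) * cot
                mask = np.abs(col_grid - center) <= half_px
                img[r, mask] = spec.path_luminance

    return SceneImage(pixels=np.clip(img, 0.0, 1.0), azimuths=azs, spec=spec)


# ---------------------------------------------------------------------------
# rater paths
# ---------------------------------------------------------------------------

@dataclass
class PathHeatMap:
    values: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        v = check_finite(self.values, "path heat map")
        if np.any(v < 0):
            raise ValueError("heat map entries must be nonnegative")
        self.values = v


def _splat_ray(acc: np.ndarray, origin: tuple[int, int], angle_deg: float,
               step: float = 0.25) -> float:
    """Bilinearly splat a unit-mass straight ray from origin to the boundary.

    Samples the ray every ``step`` pixels and deposits equal weights with
    bilinear interpolation, then scales the deposit to total mass 1.  A ray at
    exactly 90 degrees lands entirely on the origin column.  Returns the mass
    deposited (1.0).
    """
    h, w = acc.shape
    r0, c0 = origin
    theta = math.radians(angle_deg)
    dy, dx = math.sin(theta), math.cos(theta)  # dy: rows upward
    # distance to image boundary
    ts = [(h - 1) / dy if dy > 0 else math.inf]
    if dx > 1e-12:
        ts.append((w - 1 - c0) / dx)
    elif dx < -1e-12:
        ts.append(-c0 / dx)
    t_max = min(ts)
    n_samples = max(2, int(t_max / step) + 1)
    t = np.linspace(0.0, t_max, n_samples)
    rr = r0 - t * dy
    cc = c0 + t * dx
    w_each = 1.0 / n_samples
    r_lo = np.floor(rr).astype(int)
    c_lo = np.floor(cc).astype(int)
    fr = rr - r_lo
    fc = cc - c_lo
    for drow, dcol, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        r_i = np.clip(r_lo + drow, 0, h - 1)
        c_i = np.clip(c_lo + dcol, 0, w - 1)
        np.add.at(acc, (r_i, c_i), w_each * wt)
    return 1.0


def simulate_rater_paths(
    truth_azimuths,
    n_raters: int,
    angular_noise_sd: float,
    image_size: tuple[int, int] = (227, 227),
    seed: int = 0,
    blur_sigma: float = 2.0,
) -> PathHeatMap:
    """Superpose rasterized rater paths toward noisy draws of true azimuths.

    Each rater walks one straight path from the bottom-center origin toward a
    Gaussian perturbation (sd ``angular_noise_sd`` degrees) of a ground-truth
    azimuth; raters cycle deterministically through the azimuth list, so an
    even rater count splits mass exactly across two openings at zero noise.
    Every path deposits unit mass.  A final Gaussian blur (default sigma 2 px,
    disable with ``blur_sigma=0``) mimics the spatial spread of real mouse
    trajectories.
    """
    truth = [float(a) for a in truth_azimuths]
    if not truth:
        raise ValueError("truth_azimuths must not be empty")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    h, w = image_size
    rng = rng_from(seed)
    acc = np.zeros((h, w), dtype=float)
    origin = (h - 1, w // 2)
    for i in range(n_raters):
        az = truth[i % len(truth)]
        if angular_noise_sd > 0:
            az = az + rng.normal(0.0, angular_noise_sd)
        az = float(np.clip(az, 0.5, 179.5))
        _splat_ray(acc, origin, az)
    if blur_sigma > 0:
        acc = gaussian_filter(acc, sigma=blur_sigma, mode="constant")
    if acc.sum() <= 0:
        raise ValueError("simulated heat map has zero mass")
    return PathHeatMap(values=acc, origin=origin)


# ---------------------------------------------------------------------------
# voxel-pattern cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    patterns: np.ndarray  # (n_subjects, n_runs, n_conditions, n_voxels)
    target_rdm: RDM
    noise_sd: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[1]

    def subject_runs(self, s: int) -> list[np.ndarray]:
        return [self.patterns[s, r] for r in range(self.n_runs)]


def _mds_embedding(target: RDM, tol: float = 1e-10) -> np.ndarray:
    """Classical (Torgerson) MDS scores of a squared-distance RDM.

    Eigenvalues below ``tol`` times the largest are truncated (numerical
    rank); a meaningfully negative eigenvalue means the RDM is not Euclidean-
    embeddable and is reported as an error.
    """
    d = target.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d @ j
    evals, evecs = np.linalg.eigh(b)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    top = evals[0]
    if top <= 0:
        raise ValueError("target RDM has no positive structure to embed")
    if evals[-1] < -1e-6 * top:
        raise ValueError(
            "target RDM is not Euclidean-embeddable: most negative eigenvalue "
            f"of the double-centered matrix is {evals[-1]:.6g}"
        )
    keep = evals > tol * top
    return evecs[:, keep] * np.sqrt(evals[keep])


def _voxel_map(k: int, n_voxels: int, rng: np.random.Generator,
               kind: str) -> np.ndarray:
    """(n_voxels, k) matrix with orthonormal columns, each orthogonal to 1.

    ``qr``: QR decomposition of a seeded Gaussian matrix after projecting out
    the constant direction.  ``hadamard``: non-DC columns of a normalized
    Hadamard block, randomly permuted over voxels and sign-flipped; its flat
    +-1/sqrt(m) entries give every voxel the same planted variance.  Voxels
    beyond the Hadamard block carry no signal (they receive only noise).
    """
    if kind == "qr":
        g = rng.standard_normal((n_voxels, k))
        g -= g.mean(axis=0, keepdims=True)
        q, r = np.linalg.qr(g)
        return q * np.sign(np.diag(r))
    if kind == "hadamard":
        m = 1
        while m < k + 1:
            m *= 2
        if n_voxels < m:
            raise ValueError(
                f"hadamard map needs at least {m} voxels for rank {k}"
            )
        block = hadamard(m).astype(float) / np.sqrt(m)  # columns orthonormal
        cols = block[:, 1: k + 1]  # skip the DC column
        full = np.zeros((n_voxels, k))
        full[:m, :] = cols
        perm = rng.permutation(n_voxels)
        signs = rng.choice([-1.0, 1.0], size=n_voxels)
        return full[perm] * signs[:, None]
    raise ValueError(f"unknown voxel map kind: {kind}")


def generate_cohort(
    target_rdm: RDM,
    n_subjects: int = 8,
    n_runs: int = 2,
    n_voxels: int = 64,
    noise_sd: float = 0.5,
    seed: int = 0,
    voxel_map: str = "hadamard",
) -> SyntheticCohort:
    """Plant a target RDM into a multi-subject, multi-run voxel cohort.

    Noiseless base patterns are the classical MDS embedding of the target RDM
    mapped into voxel space by an orthonormal map (shared across subjects);
    each run adds i.i.d. Gaussian noise of sd ``noise_sd``.  At zero noise the
    squared-Euclidean RDM of any subject's run-averaged patterns equals the
    target exactly.  The default Hadamard map additionally equalizes planted
    voxel variances so the voxel-wise z-scoring step of ``normalize_fmri`` is
    distance-preserving.
    """
    y = _mds_embedding(target_rdm)
    k = y.shape[1]
    if n_voxels < k:
        raise ValueError(f"n_voxels={n_voxels} below embedding rank {k}")
    rng = rng_from(seed)
    m = _voxel_map(k, n_voxels, rng, voxel_map)
    base = y @ m.T  # (n_conditions, n_voxels)
    n_cond = base.shape[0]
    patterns = np.empty((n_subjects, n_runs, n_cond, n_voxels))
    for s in range(n_subjects):
        for r in range(n_runs):
            noise = rng.standard_normal((n_cond, n_voxels)) * noise_sd
            patterns[s, r] = base + noise
    return SyntheticCohort(patterns=patterns, target_rdm=target_rdm,
                           noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# labeled activation sets
# ---------------------------------------------------------------------------

@dataclass
class LabeledActivationSet:
    activations: np.ndarray  # (n_images, n_units)
    labels: pd.DataFrame  # one column per property, values "low"/"high"
    informative_units: np.ndarray
    effect_size: float

    @property
    def focal_property(self) -> str:
        return str(self.labels.columns[0])


def generate_labeled_activations(
    n_images: int = 100,
    n_units: int = 2000,
    n_informative: int = 50,
    effect_size: float = 2.0,
    n_properties: int = 1,
    seed: int = 0,
) -> LabeledActivationSet:
    """Unit activations with a planted informative subset for one property.

    Images are split into balanced "low"/"high" classes per property.  For the
    focal (first) property, each informative unit responds N(+e/2, 1) to one
    class pole and N(-e/2, 1) to the other (which pole it prefers is drawn at
    random per unit, as real units prefer either low or high navigability);
    all other units are N(0, 1) noise, so class separation is ``effect_size``
    in units of the noise sd.  Balanced unit preferences matter: a subset of
    units that all preferred the same pole would lose its signal to the
    across-unit z-scoring step of the minimum-distance classifier.
    """
    if n_images % 2 != 0:
        raise ValueError("n_images must be even for balanced classes")
    if not 0 <= n_informative <= n_units:
        raise ValueError("n_informative must be at most n_units")
    if n_properties < 1:
        raise ValueError("need at least one property")
    rng = rng_from(seed)
    acts = rng.standard_normal((n_images, n_units))
    half = n_images // 2
    cols = {}
    for p in range(n_properties):
        assign = np.array(["low"] * half + ["high"] * half)
        rng.shuffle(assign)
        cols[f"property_{p}" if p else "navigability"] = assign
    labels = pd.DataFrame(cols)
    informative = rng.choice(n_units, size=n_informative, replace=False)
    focal = labels.iloc[:, 0].to_numpy()
    shift = np.where(focal == "high", effect_size / 2.0, -effect_size / 2.0)
    unit_sign = rng.choice([-1.0, 1.0], size=n_informative)
    acts[:, informative] += shift[:, None] * unit_sign[None, :]
    return LabeledActivationSet(
        activations=acts,
        labels=labels,
        informative_units=np.sort(informative),
        effect_size=float(effect_size),
    )
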