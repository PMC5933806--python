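"""Representational dissimilarity matrices (RDMs) and pattern normalization.

An RDM summarizes a set of condition-evoked response patterns (voxels, network
units, or affordance-histogram bins) as the matrix of squared Euclidean
distances between all pairs of conditions.  Squared Euclidean distances are
used because they sum linearly over features, which is what multiple-regression
RSA requires; on z-scored patterns they are linearly proportional to Pearson
correlation distances, d_ij = 2(n_features - 1)(1 - r_ij) with the sample-sd
convention used throughout this package.

The voxel-pattern normalization pipeline mirrors the standard two-stage
procedure for run-wise fMRI estimates: each voxel is z-scored across conditions
within each run, runs are averaged, and each condition's pattern is then
z-scored across voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._utils import check_finite, zscore

__all__ = [
    "RDM",
    "compute_rdm",
    "group_rdm",
    "normalize_fmri",
    "reduce_pca",
    "vectorize_rdm",
]


@dataclass
class RDM:
    """Symmetric condition x condition matrix of squared Euclidean distances."""

    values: np.ndarray
    labels: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        v = check_finite(np.asarray(self.values, dtype=float), "RDM values")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM must be square, got shape {v.shape}")
        n = v.shape[0]
        self.labels = tuple(str(l) for l in self.labels)
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} conditions")
        if len(set(self.labels)) != n:
            raise ValueError("RDM labels must be unique")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        v = (v + v.T) / 2.0
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        np.fill_diagonal(v, 0.0)
        if np.any(v < -1e-10):
            raise ValueError("RDM entries must be nonnegative")
        self.values = np.clip(v, 0.0, None)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize_rdm(self.values)

    def subset(self, idx: np.ndarray) -> "RDM":
        """Restrict to a condition subset (used by bootstrap resampling)."""
        idx = np.asarray(idx)
        return RDM(
            self.values[np.ix_(idx, idx)],
            tuple(self.labels[i] for i in idx),
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, source: str = "") -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.columns), source=source)


def vectorize_rdm(values: np.ndarray) -> np.ndarray:
    """Upper-triangle (row-major, diagonal excluded) vector of length n(n-1)/2.

    This is the single vector representation used by every inference
    operation; RDM diagonals are never used.
    """
    values = np.asarray(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def compute_rdm(patterns: np.ndarray, labels, source: str = "") -> RDM:
    """Squared Euclidean RDM: d(i, j) = sum_f (x_if - x_jf)^2."""
    x = check_finite(patterns, "patterns")
    if x.ndim != 2:
        raise ValueError("patterns must be condition x feature")
    sq = np.sum(x**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return RDM(d, tuple(labels), source=source)


def group_rdm(subject_rdms: list[RDM], source: str = "group") -> RDM:
    """Element-wise mean of subject-level RDMs (labels must match in order)."""
    if not subject_rdms:
        raise ValueError("need at least one subject RDM")
    labels = subject_rdms[0].labels
    for r in subject_rdms[1:]:
        if r.labels != labels:
            raise ValueError("subject RDM labels differ or are reordered")
    mean = np.mean([r.values for r in subject_rdms], axis=0)
    return RDM(mean, labels, source=source)


def normalize_fmri(runs: list[np.ndarray]) -> np.ndarray:
    """Two-stage normalization of run-level voxel patterns.

    Per voxel: z-score across conditions within each run; average across runs;
    then per condition: z-score across voxels.  Voxels with zero variance in
    any run are dropped with a warning (dead voxels cannot be normalized and
    would otherwise poison the distances).

    Parameters
    ----------
    runs : list of (n_conditions, n_voxels) arrays, identical condition order.

    Returns
    -------
    (n_conditions, n_kept_voxels) array of doubly normalized patterns.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    arrs = [check_finite(r, "run patterns") for r in runs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all runs must share condition and voxel counts")
    if shape[0] < 2:
        raise ValueError("need at least two conditions")
    stacked = np.stack(arrs)  # (runs, cond, vox)
    sd = stacked.std(axis=1, ddof=1)  # (runs, vox)
    dead = np.any(sd == 0, axis=0)
    if np.any(dead):
        warnings.warn(
            f"excluding {int(dead.sum())} zero-variance voxel(s)", stacklevel=2
        )
        stacked = stacked[:, :, ~dead]
        sd = sd[:, ~dead]
        if stacked.shape[2] < 2:
            raise ValueError("fewer than two voxels left after exclusion")
    mu = stacked.mean(axis=1, keepdims=True)
    z = (stacked - mu) / sd[:, None, :]
    avg = z.mean(axis=0)  # (cond, vox)
    return zscore(avg, axis=1)


def reduce_pca(activations: np.ndarray, k: int) -> np.ndarray:
    """Project condition x feature activations onto the top-k PCs, then
    z-score each condition's score vector across components.

    PCA uses mean-centering only (no feature standardization): raw activations
    enter the decomposition, and the z-scoring happens after projection.
    """
    x = check_finite(activations, "activations")
    n, p = x.shape
    max_k = min(n - 1, p)
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} out of range; available rank is {max_k}")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(x)
    if k == 1:
        # a single component cannot be z-scored across components
        return scores
    return zscore(scores, axis=1)
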