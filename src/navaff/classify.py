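"""Binary classification of scene properties from unit activations.

Two classifiers mirror the two analysis regimes:

* a **minimum-distance classifier** for the full unit population (no fitted
  parameters): activations are z-scored across images and then across units,
  and each image is assigned to the class ("low"/"high") with the smaller
  mean pairwise Euclidean distance, excluding the image's own self-comparison;
* a **leave-one-out linear discriminant** for small unit subsets: for each
  held-out image a two-class linear discriminant with a shrinkage-regularized
  pooled covariance is fit on the remaining images and used to predict the
  held-out label.

The informativeness of a designated unit subset is assessed against a
resampling null: the same leave-one-out classification is repeated for many
random same-size unit subsets (the designated units are not excluded from the
draws) and the focal accuracy's strictly-less percentile within that null
distribution is reported.  Accuracies of different properties are compared
with 2x2 chi-squared tests for equality of proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import rng_from

__all__ = [
    "ClassificationResult",
    "ResamplingNull",
    "compare_accuracies",
    "loo_lda_classify",
    "min_distance_classify",
    "resampling_null",
]


@dataclass
class ClassificationResult:
    property: str
    accuracy: float  # percent correct over leave-one-out folds
    n_images: int
    classifier: str
    n_correct: int
    predictions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage")


@dataclass
class ResamplingNull:
    focal_accuracy: float
    null_accuracies: np.ndarray
    percentile: float  # strictly-less rank of focal among null, in [0, 100]

    def density(self, grid_size: int = 200) -> tuple[np.ndarray, np.ndarray]:
        """Kernel-density summary of the null accuracies (for plotting)."""
        vals = self.null_accuracies
        lo, hi = vals.min() - 5.0, vals.max() + 5.0
        grid = np.linspace(lo, hi, grid_size)
        if np.ptp(vals) == 0:
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - vals[0]))] = 1.0
            return grid, dens
        return grid, stats.gaussian_kde(vals)(grid)


def _validate_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least two members")
    return labels, classes


def min_distance_classify(activations: np.ndarray, labels,
                          property_name: str = "") -> ClassificationResult:
    """Nearest-mean-distance classification on doubly z-scored activations.

    Activations are z-scored across images (per unit) and then across units
    (per image); each image's mean pairwise Euclidean distance to the members
    of each class (excluding itself) decides its predicted class.  Distance
    ties break to the lexicographically first class label.
    """
    x = np.asarray(activations, dtype=float)
    labels, classes = _validate_labels(labels)
    if x.shape[0] != labels.size:
        raise ValueError("one label per image required")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        x = x[:, sd > 0]
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    sq = np.sum(x**2, axis=1)
    d = np.sqrt(np.clip(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0, None))
    n = x.shape[0]
    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        means = []
        for c in classes:
            members = (labels == c)
            members[i] = False
            means.append(d[i, members].mean())
        # classes are sorted; argmin takes the first (lexicographic) on ties
        preds[i] = classes[int(np.argmin(means))]
    n_correct = int((preds == labels).sum())
    return ClassificationResult(
        property=property_name, accuracy=100.0 * n_correct / n, n_images=n,
        classifier="min_distance", n_correct=n_correct, predictions=preds,
    )


def _loo_lda_predictions(x: np.ndarray, y01: np.ndarray,
                         shrinkage: float) -> np.ndarray:
    """Leave-one-out two-class LDA with a fixed-shrinkage pooled covariance.

    Per fold the class scatters are downdated by the held-out sample, the
    pooled covariance is shrunk toward its scaled identity,
    (1 - g) S + g (tr S / p) I, and the standard linear discriminant with the
    training class priors scores the held-out image.
    """
    n, p = x.shape
    idx0, idx1 = np.where(y01 == 0)[0], np.where(y01 == 1)[0]
    sums = [x[idx0].sum(axis=0), x[idx1].sum(axis=0)]
    outers = [x[idx0].T @ x[idx0], x[idx1].T @ x[idx1]]
    counts = [len(idx0), len(idx1)]
    preds = np.empty(n, dtype=int)
    eye = np.eye(p)
    for i in range(n):
        c = y01[i]
        n_c = counts[c] - 1
        n_o = counts[1 - c]
        if n_c < 1:
            raise ValueError("a class lost all training members in a fold")
        m_c = (sums[c] - x[i]) / n_c
        m_o = sums[1 - c] / n_o
        s_c = outers[c] - np.outer(x[i], x[i]) - n_c * np.outer(m_c, m_c)
        s_o = outers[1 - c] - n_o * np.outer(m_o, m_o)
        dof = n_c + n_o - 2
        cov = (s_c + s_o) / max(dof, 1)
        mu = np.trace(cov) / p
        cov = (1.0 - shrinkage) * cov + shrinkage * mu * eye
        means = [None, None]
        means[c], means[1 - c] = m_c, m_o
        w = np.linalg.solve(cov, means[1] - means[0])
        ns = [None, None]
        ns[c], ns[1 - c] = n_c, n_o
        thresh = 0.5 * w @ (means[1] + means[0]) - np.log(ns[1] / ns[0])
        preds[i] = int(x[i] @ w > thresh)
    return preds


def loo_lda_classify(
    activations: np.ndarray,
    labels,
    unit_subset=None,
    shrinkage: float = 0.1,
    property_name: str = "",
) -> ClassificationResult:
    """Leave-one-out linear-discriminant classification of a unit subset.

    ``shrinkage`` in (0, 1] regularizes the pooled covariance toward a scaled
    identity; with ~50 features and ~99 training images the unshrunk estimate
    is near-singular, so shrinkage is always applied.  Folds equal the image
    count and no image ever contributes to its own training set.
    """
    x = np.asarray(activations, dtype=float)
    labels, classes = _validate_labels(labels)
    if unit_subset is not None:
        x = x[:, np.asarray(unit_subset, dtype=int)]
    if x.shape[0] < 4:
        raise ValueError("need at least four images")
    if not 0.0 < shrinkage <= 1.0:
        raise ValueError("shrinkage must be in (0, 1]")
    y01 = (labels == classes[1]).astype(int)
    preds01 = _loo_lda_predictions(x, y01, shrinkage)
    preds = classes[preds01]
    n = x.shape[0]
    n_correct = int((preds == labels).sum())
    return ClassificationResult(
        property=property_name, accuracy=100.0 * n_correct / n, n_images=n,
        classifier="linear_discriminant", n_correct=n_correct, predictions=preds,
    )


def resampling_null(
    layer_activations: np.ndarray,
    focal_units,
    labels,
    n_iterations: int = 5000,
    seed: int = 0,
    shrinkage: float = 0.1,
    property_name: str = "",
) -> ResamplingNull:
    """Accuracy of the focal unit subset against random same-size subsets.

    Null subsets are drawn uniformly without replacement from all layer units
    (the focal units are not excluded from the draws).  The percentile is the
    strictly-less rank, 100 * #(null < focal) / n_iterations: ties with null
    draws do not inflate the rank.
    """
    x = np.asarray(layer_activations, dtype=float)
    focal = np.asarray(focal_units, dtype=int)
    if focal.size > x.shape[1]:
        raise ValueError("focal subset larger than the unit population")
    focal_acc = loo_lda_classify(x, labels, focal, shrinkage,
                                 property_name).accuracy
    rng = rng_from(seed)
    null = np.empty(n_iterations)
    for i in range(n_iterations):
        subset = rng.choice(x.shape[1], size=focal.size, replace=False)
        null[i] = loo_lda_classify(x, labels, subset, shrinkage).accuracy
    percentile = 100.0 * float((null < focal_acc).sum()) / n_iterations
    return ResamplingNull(focal_accuracy=focal_acc, null_accuracies=null,
                          percentile=percentile)


def compare_accuracies(result_a: ClassificationResult,
                       result_b: ClassificationResult,
                       n_comparisons: int = 1) -> dict:
    """2x2 chi-squared test for equality of two classification proportions.

    Uses the uncorrected (textbook) chi-squared statistic on the
    correct/incorrect counts of the two results; the p-value is Bonferroni
    multiplied by ``n_comparisons`` and capped at 1.  A warning flag is set
    when any expected cell count falls below 1.
    """
    if result_a.n_images < 1 or result_b.n_images < 1:
        raise ValueError("empty result")
    table = np.array([
        [result_a.n_correct, result_a.n_images - result_a.n_correct],
        [result_b.n_correct, result_b.n_images - result_b.n_correct],
    ], dtype=float)
    expected = stats.contingency.expected_freq(table)
    small = bool((expected < 1).any())
    if small:
        warnings.warn("expected cell count below 1; chi-squared unreliable",
                      stacklevel=2)
    if np.any(table.sum(axis=0) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "p_corrected": min(1.0, float(p) * n_comparisons),
        "small_sample_warning": small,
    }
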