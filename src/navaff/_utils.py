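"""Shared helpers: seeded RNG management and z-scoring conventions.

All stochastic operations in the package draw from ``numpy.random.Generator``
objects derived from explicit integer seeds, so every result is reproducible
from (parameters, seed) alone.  z-scores use the sample (n-1) denominator
throughout the package; this makes the squared-Euclidean / Pearson identity
d = 2(n-1)(1-r) exact for z-scored vectors.
"""

from __future__ import annotations

import numpy as np


def rng_from(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; pass through if one is given."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def zscore(x: np.ndarray, axis: int = -1, ddof: int = 1) -> np.ndarray:
    """Sample-sd z-score along ``axis``.

    Raises ValueError on zero-variance slices: callers that need a softer
    policy (dropping dead features, flagging degenerate histograms) handle
    those cases before calling.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance slice in z-score")
    return (x - mu) / sd


def check_finite(x: np.ndarray, name: str = "array") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {name}")
    return x
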