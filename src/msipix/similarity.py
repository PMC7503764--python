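"""Pairwise spectrum similarity (normalized dot product) and group CDFs.

The similarity index of two abundance vectors is their normalized dot
product ``<a, b> / (||a|| ||b||)`` — 1 for identical direction, 0 for
disjoint support — computed on component abundances, either all components
or an intensity-class subset.  Intra- and inter-ROI populations of pairwise
similarities are summarized as empirical cumulative distribution functions
whose value 0.5 marks the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .gmm import AbundanceMatrix


def similarity_index(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized dot product of two non-negative abundance vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise DataError("vectors must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


@dataclass
class SimilaritySummary:
    """Sampled pairwise similarities for one group pair."""

    group_a: str
    group_b: str
    n_pairs: int
    values: np.ndarray          # sorted ascending

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF: (sorted values, cumulative probabilities)."""
        n = self.values.size
        return self.values, np.arange(1, n + 1) / n


def group_similarity(matrix: AbundanceMatrix, group_a: str, group_b: str,
                     max_pairs: int = 100_000, seed: int = 0,
                     feature_idx: np.ndarray | None = None
                     ) -> SimilaritySummary:
    """Similarity CDF between (or within) ROI groups.

    All unordered pairs are used when their count is at most ``max_pairs``;
    otherwise ``max_pairs`` pairs are drawn uniformly at random (with
    replacement, seeded), an unbiased estimator of the same CDF.  Outlier
    pixels are excluded; ``feature_idx`` selects a component subset (e.g.
    the top intensity class).
    """
    labels = matrix.metadata["roi_label"].to_numpy()
    X = matrix.values if feature_idx is None else matrix.values[:, feature_idx]
    good = matrix.good
    idx_a = np.flatnonzero((labels == group_a) & good)
    idx_b = np.flatnonzero((labels == group_b) & good)
    if idx_a.size == 0 or idx_b.size == 0:
        raise DataError(f"empty group in ({group_a}, {group_b})")
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-norm pixels",
                      stacklevel=2)
        idx_a = idx_a[~zero[idx_a]]
        idx_b = idx_b[~zero[idx_b]]
        if idx_a.size == 0 or idx_b.size == 0:
            raise DataError("group became empty after zero-norm exclusion")
    Xn = X / norms[:, None]
    rng = np.random.default_rng(seed)
    intra = group_a == group_b
    if intra:
        n = idx_a.size
        if n < 2:
            raise DataError("intra-group similarity needs >= 2 pixels")
        total = n * (n - 1) // 2
        if total <= max_pairs:
            gram = Xn[idx_a] @ Xn[idx_a].T
            vals = gram[np.triu_indices(n, k=1)]
        else:
            i = rng.integers(0, n, max_pairs)
            j = rng.integers(0, n, max_pairs)
            redo = i == j
            while redo.any():
                j[redo] = rng.integers(0, n, int(redo.sum()))
                redo = i == j
            vals = np.einsum("ij,ij->i", Xn[idx_a[i]], Xn[idx_a[j]])
    else:
        total = idx_a.size * idx_b.size
        if total <= max_pairs:
            vals = (Xn[idx_a] @ Xn[idx_b].T).ravel()
        else:
            i = rng.integers(0, idx_a.size, max_pairs)
            j = rng.integers(0, idx_b.size, max_pairs)
            vals = np.einsum("ij,ij->i", Xn[idx_a[i]], Xn[idx_b[j]])
    vals = np.clip(vals, 0.0, 1.0)    # guard float round-off at the ends
    return SimilaritySummary(group_a=group_a, group_b=group_b,
                             n_pairs=int(vals.size), values=np.sort(vals))
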