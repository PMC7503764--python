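"""Effect-size screening of spectral components and exploratory PCA.

Differences in component abundance between tissue classes are quantified
by Cohen's d — the difference of group means divided by the pooled
standard deviation — deliberately without p-values: with tens of
thousands of pixels per group any difference is "significant", while the
standardized effect size is sample-size free.  |d| >= 0.5, 0.8 and 1.2
mark medium, large and very large effects.

The exploratory embedding scales abundances with the pseudo-logarithm
log10(x + 1), centers per feature and applies singular-value
decomposition (PCA).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .dataset import ROI_LABELS
from .exceptions import DataError, ParameterError
from .gmm import AbundanceMatrix

CATEGORIES = ("small", "medium", "large", "very large")
_THRESHOLDS = (0.5, 0.8, 1.2)


def categorize(d: float) -> str:
    """Effect-size category from |d|; a boundary value enters the higher
    class (|d| = 0.8 is 'large')."""
    a = abs(d)
    if a >= _THRESHOLDS[2]:
        return "very large"
    if a >= _THRESHOLDS[1]:
        return "large"
    if a >= _THRESHOLDS[0]:
        return "medium"
    return "small"


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD (signed)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise DataError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def _cohens_d_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Cohen's d for two groups of rows; NaN where pooled SD=0."""
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (A.mean(axis=0) - B.mean(axis=0)) / pooled
    d[pooled == 0] = np.nan
    return d


def effect_table(matrix: AbundanceMatrix,
                 feature_idx: np.ndarray | None = None,
                 groups: dict[str, list[str]] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohen's d per component per unordered ROI-pair, plus the category
    percentage summary.

    All non-outlier pixels of a ROI are pooled.  ``groups`` may define
    super-groups (e.g. WDTC = FTC + both PTC variants) as label lists;
    their pixels are pooled before computing d.  Returns ``(records,
    summary)``: records with columns mz/pair/d/category, and the per-pair
    percentage of components in each category.
    """
    labels = matrix.metadata["roi_label"].to_numpy()
    good = matrix.good
    X = matrix.values if feature_idx is None else matrix.values[:, feature_idx]
    mzs = matrix.component_mz if feature_idx is None \
        else matrix.component_mz[feature_idx]
    if groups is None:
        groups = {r: [r] for r in ROI_LABELS if (labels == r).any()}
    if len(groups) < 2:
        raise DataError("need at least 2 ROIs / groups")
    masks = {}
    for name, members in groups.items():
        mask = np.isin(labels, members) & good
        if not mask.any():
            raise DataError(f"group {name} has no usable pixels")
        masks[name] = mask
    records = []
    for ga, gb in itertools.combinations(groups, 2):
        d = _cohens_d_columns(X[masks[ga]], X[masks[gb]])
        pair = f"{ga}|{gb}"
        for mz, dv in zip(mzs, d):
            records.append((float(mz), pair, float(dv),
                            categorize(dv) if np.isfinite(dv) else "undefined"))
    records = pd.DataFrame(records, columns=["mz", "pair", "d", "category"])
    counts = (records[records["category"] != "undefined"]
              .groupby("pair")["category"].value_counts().unstack(fill_value=0))
    for cat in CATEGORIES:
        if cat not in counts:
            counts[cat] = 0
    summary = counts[list(CATEGORIES)]
    summary = summary.div(summary.sum(axis=1), axis=0) * 100.0
    return records, summary


def pca_embed(matrix: AbundanceMatrix, n_components: int = 3,
              per_core_sample: int | None = None, seed: int = 0
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pseudo-log PCA of pixel abundances.

    Transforms x -> log10(x + 1), centers per feature and computes an SVD.
    ``per_core_sample`` draws that many random non-outlier pixels per core
    first (seeded), the usual thinning for readable score plots.  Returns
    per-pixel scores (with metadata columns) and the explained-variance
    fractions of all principal axes.
    """
    if np.any(matrix.values < 0):
        raise DataError("abundances must be non-negative")
    good = np.flatnonzero(matrix.good)
    if per_core_sample is not None:
        rng = np.random.default_rng(seed)
        meta = matrix.metadata.iloc[good]
        chosen = []
        for _, grp in meta.groupby("core_id", sort=False):
            take = min(per_core_sample, len(grp))
            chosen.append(rng.choice(grp.index.to_numpy(), take, replace=False))
        good = np.sort(np.concatenate(chosen))
    if good.size < n_components:
        raise ParameterError("fewer pixels than requested components")
    X = np.log10(matrix.values[good] + 1.0)
    X -= X.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    explained = var / var.sum()
    scores = X @ vt[:n_components].T
    out = matrix.metadata.iloc[good][["pixel_id", "core_id", "patient_id",
                                      "roi_label"]].reset_index(drop=True)
    for i in range(n_components):
        out[f"PC{i + 1}"] = scores[:, i]
    return out, explained
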