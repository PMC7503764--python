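"""Gaussian-mixture modeling of the average MSI spectrum.

The average spectrum is treated as an unnormalized density over m/z: it is
split at near-zero valleys into independent segments, and within each
segment a one-dimensional Gaussian mixture is fitted by intensity-weighted
expectation-maximization, with the number of components chosen by a
Bayesian-information-criterion sweep (effective sample size via the Kish
formula, so the criterion is invariant to the arbitrary intensity scale).
Low-amplitude / overly broad components are pruned, components modeling
the same peak are merged (dominant member's location wins), and per-pixel
component abundances are estimated by convolving each spectrum with the
unit-area Gaussian profile of each component, i.e. on a peak-area scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .dataset import SpectraDataset
from .exceptions import DataError, ParameterError

__all__ = [
    "GaussComponent", "ComponentModel", "AbundanceMatrix", "IntensityClassModel",
    "average_spectrum", "fit_gmm", "prune_components", "merge_components",
    "estimate_abundances", "fit_intensity_classes",
    "AverageSpectrumGMM", "ComponentFitResults",
]


@dataclass(frozen=True)
class GaussComponent:
    """One Gaussian of the mixture: location mu (Da), width sigma (Da),
    amplitude (height, a.u.)."""

    mu: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2 * np.pi)

    def profile(self, mz: np.ndarray, unit_area: bool = False) -> np.ndarray:
        g = np.exp(-0.5 * ((mz - self.mu) / self.sigma) ** 2)
        if unit_area:
            return g / (self.sigma * np.sqrt(2 * np.pi))
        return self.amplitude * g


def average_spectrum(dataset: SpectraDataset) -> np.ndarray:
    """Channel-wise arithmetic mean over non-outlier pixels."""
    good = dataset.good
    if not good.any():
        raise DataError("all pixels are flagged as outliers")
    return dataset.intensities[good].mean(axis=0)


# ---------------------------------------------------------------------------
# weighted 1-D EM
# ---------------------------------------------------------------------------

def _weighted_em(x: np.ndarray, w: np.ndarray, k: int, max_iter: int,
                 tol: float, sigma_floor: float) -> tuple[np.ndarray, ...]:
    """EM for a k-component 1-D Gaussian mixture fit to weighted points.

    Returns (pi, mu, sigma, mean_loglik, converged); ``mean_loglik`` is the
    weight-averaged log density.
    """
    p = w / w.sum()
    # initialize means at evenly spaced weighted quantiles
    cdf = np.cumsum(p)
    mu = np.interp((np.arange(k) + 0.5) / k, cdf, x)
    overall_sd = np.sqrt(np.sum(p * (x - np.sum(p * x)) ** 2))
    sigma = np.full(k, max(overall_sd / k, sigma_floor))
    pi = np.full(k, 1.0 / k)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step in log space for stability
        log_dens = (np.log(pi)[None, :]
                    - 0.5 * np.log(2 * np.pi) - np.log(sigma)[None, :]
                    - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2)
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        resp = np.exp(log_dens - lse[:, None])
        loglik = float(np.sum(p * lse))
        # M step
        wk = (p[:, None] * resp).sum(axis=0)
        wk = np.maximum(wk, 1e-12)
        mu = (p[:, None] * resp * x[:, None]).sum(axis=0) / wk
        var = (p[:, None] * resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / wk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        pi = wk / wk.sum()
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return pi, mu, sigma, loglik, converged


def _segment_spectrum(intensity: np.ndarray, rel_threshold: float,
                      max_width: int) -> list[tuple[int, int]]:
    """Split the spectrum into independent fitting segments.

    First splits at near-zero valleys (below ``rel_threshold`` of the
    global maximum); any segment still wider than ``max_width`` channels
    is then split recursively at its lowest internal valley, so that no
    segment holds more peaks than the per-segment mixture can model.
    """
    thr = rel_threshold * intensity.max()
    above = intensity > thr
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    stops = list(edges[above[edges]] + 1) if edges.size else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [above.size]
    out: list[tuple[int, int]] = []

    def _split(a: int, b: int) -> None:
        if b - a <= max_width:
            out.append((a, b))
            return
        margin = max(3, (b - a) // 10)
        cut = a + margin + int(np.argmin(intensity[a + margin:b - margin]))
        _split(a, cut)
        _split(cut, b)

    for a, b in zip(starts, stops):
        if b - a >= 3:
            _split(a, b)
    return out


def fit_gmm(mz: np.ndarray, intensity: np.ndarray,
            max_components_per_segment: int = 8,
            em_tol: float = 1e-7, max_iter: int = 500,
            rel_threshold: float = 1e-3,
            max_segment_width_da: float = 40.0,
            target_residual: float = 0.05) -> list[GaussComponent]:
    """Detect peaks by segment-wise weighted EM with a BIC sweep.

    ``rel_threshold`` (fraction of the global maximum) defines the near-zero
    valleys where the spectrum is split; segments wider than
    ``max_segment_width_da`` are further split at their lowest internal
    valley.  Within each segment the number of Gaussians minimizes the
    weighted BIC, escalated while the segment's reconstruction residual
    exceeds ``target_residual`` of its intensity.
    """
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    if intensity.min() < 0:
        raise DataError("average spectrum must be non-negative")
    if not np.any(intensity > 0):
        raise DataError("average spectrum is all zero")
    dx = float(np.median(np.diff(mz)))
    max_width = max(6, int(round(max_segment_width_da / dx)))
    components: list[GaussComponent] = []
    for a, b in _segment_spectrum(intensity, rel_threshold, max_width):
        x, w = mz[a:b], intensity[a:b]
        area = float(w.sum() * dx)
        n_eff = float(w.sum() ** 2 / np.sum(w ** 2))
        k_cap = min(max_components_per_segment, max(1, (b - a) // 3))
        best: tuple[float, tuple] | None = None   # (bic, fit)
        fallback: tuple[float, tuple] | None = None  # (residual, fit)
        chosen = None
        for k in range(1, k_cap + 1):
            pi, mu, sigma, loglik, converged = _weighted_em(
                x, w, k, max_iter, em_tol, sigma_floor=dx / 2)
            if not converged:
                warnings.warn(
                    f"EM did not converge for segment {mz[a]:.1f}-{mz[b-1]:.1f}"
                    f" (k={k}); using best-so-far model", stacklevel=2)
            model = area * (pi[None, :] * np.exp(
                -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2)
                / (sigma[None, :] * np.sqrt(2 * np.pi))).sum(axis=1)
            residual = float(np.abs(model - w).sum() / w.sum())
            bic = -2.0 * n_eff * loglik + (3 * k - 1) * np.log(n_eff)
            fit = (pi, mu, sigma)
            if best is None or bic < best[0]:
                best = (bic, fit)
                chosen = (fit, residual)
            if fallback is None or residual < fallback[0]:
                fallback = (residual, fit)
        assert chosen is not None and fallback is not None
        fit, residual = chosen
        if residual > target_residual and fallback[0] < residual:
            fit = fallback[1]
        pi, mu, sigma = fit
        for j in range(len(pi)):
            comp_area = area * pi[j]
            if comp_area <= 0:
                continue
            components.append(GaussComponent(
                mu=float(mu[j]), sigma=float(sigma[j]),
                amplitude=float(comp_area / (sigma[j] * np.sqrt(2 * np.pi)))))
    components.sort(key=lambda c: c.mu)
    return components


# ---------------------------------------------------------------------------
# pruning and merging
# ---------------------------------------------------------------------------

def prune_components(raw: list[GaussComponent], amp_quantile: float = 0.05,
                     sigma_max_da: float | None = None,
                     amp_min: float | None = None
                     ) -> tuple[list[GaussComponent], list[int]]:
    """Remove low-amplitude and overly broad components.

    A component is dropped if its amplitude is below ``amp_min`` (or the
    ``amp_quantile`` quantile of all amplitudes when ``amp_min`` is None)
    or its sigma exceeds ``sigma_max_da``.  Returns survivors and their
    indices into ``raw``.
    """
    if not raw:
        raise DataError("no components to prune")
    amps = np.array([c.amplitude for c in raw])
    threshold = amp_min if amp_min is not None else \
        float(np.quantile(amps, amp_quantile)) if amp_quantile > 0 else 0.0
    keep = []
    for i, c in enumerate(raw):
        if amp_min is not None or amp_quantile > 0:
            if c.amplitude < threshold:
                continue
        if sigma_max_da is not None and c.sigma > sigma_max_da:
            continue
        keep.append(i)
    if not keep:
        raise DataError("pruning removed every component")
    return [raw[i] for i in keep], keep


@dataclass
class ComponentModel:
    """Pruned, merged mixture description of the average spectrum.

    ``components`` are the merged model components ordered by strictly
    increasing mu (location = dominant member's mu, amplitude = dominant
    member's height); ``members`` holds each merged component's retained raw
    Gaussians (their unit-area profiles are summed when estimating
    abundances, so a merged component's abundance is the sum of its
    members' integrals); ``provenance`` maps each merged component to the
    indices of its raw members.
    """

    components: list[GaussComponent]
    members: list[list[GaussComponent]]
    provenance: list[list[int]]

    def __post_init__(self) -> None:
        mus = self.mz_values
        if np.any(np.diff(mus) <= 0):
            raise DataError("component locations must be strictly increasing")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    def kernels(self, mz_axis: np.ndarray) -> np.ndarray:
        """(n_components, n_channels) matrix of summed unit-area member
        profiles."""
        out = np.zeros((self.n_components, mz_axis.size))
        for i, group in enumerate(self.members):
            for g in group:
                out[i] += g.profile(mz_axis, unit_area=True)
        return out

    def reconstruction(self, mz_axis: np.ndarray) -> np.ndarray:
        """Model spectrum from all member Gaussians."""
        out = np.zeros(mz_axis.size)
        for group in self.members:
            for g in group:
                out += g.profile(mz_axis)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mz": self.mz_values,
            "sigma": [c.sigma for c in self.components],
            "amplitude": [c.amplitude for c in self.components],
            "n_members": [len(m) for m in self.members],
            "provenance": [",".join(map(str, p)) for p in self.provenance],
        })


def merge_components(components: list[GaussComponent],
                     merge_factor: float = 1.0,
                     provenance: list[int] | None = None) -> ComponentModel:
    """Merge components modeling the same peak (transitive closure).

    Components with ``|mu_i - mu_j| < merge_factor * max(sigma_i, sigma_j)``
    are grouped transitively; each group is represented at the dominant
    (highest-amplitude) member's location.
    """
    if not components:
        raise DataError("no components to merge")
    order = np.argsort([c.mu for c in components])
    comps = [components[i] for i in order]
    prov = [provenance[i] for i in order] if provenance is not None \
        else list(order)
    n = len(comps)
    sigma_max = max(c.sigma for c in comps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = comps[j].mu - comps[i].mu
            if gap >= merge_factor * sigma_max:   # sorted by mu; safe early stop
                break
            if gap < merge_factor * max(comps[i].sigma, comps[j].sigma):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged, members, merged_prov = [], [], []
    for idxs in groups.values():
        dominant = max(idxs, key=lambda i: comps[i].amplitude)
        merged.append(comps[dominant])
        members.append([comps[i] for i in idxs])
        merged_prov.append([prov[i] for i in idxs])
    order2 = np.argsort([c.mu for c in merged])
    return ComponentModel(
        components=[merged[i] for i in order2],
        members=[members[i] for i in order2],
        provenance=[merged_prov[i] for i in order2])


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Pixels x components abundances (peak-area scale) with metadata."""

    values: np.ndarray
    component_mz: np.ndarray
    metadata: pd.DataFrame
    outlier: np.ndarray

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise DataError("abundances contain NaN")
        if self.values.shape[1] != self.component_mz.size:
            raise DataError("column count must equal number of components")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def good(self) -> np.ndarray:
        return ~self.outlier

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m:.4f}" for m in self.component_mz]
        return pd.DataFrame(self.values, columns=cols,
                            index=self.metadata["pixel_id"])


def estimate_abundances(dataset: SpectraDataset,
                        model: ComponentModel) -> AbundanceMatrix:
    """Per-pixel component abundances by convolution with unit-area kernels.

    ``abundance(p, k) = sum_m s_p(m) g_k(m) dm`` with ``g_k`` the sum of
    component k's unit-area member Gaussians.
    """
    lo, hi = dataset.mz_axis[0], dataset.mz_axis[-1]
    mus = model.mz_values
    if mus.min() < lo - 1 or mus.max() > hi + 1:
        raise DataError("component model lies outside the dataset m/z axis")
    kernels = model.kernels(dataset.mz_axis)
    dx = dataset.channel_width
    values = dataset.intensities @ kernels.T * dx
    np.clip(values, 0.0, None, out=values)
    return AbundanceMatrix(values=values, component_mz=mus,
                           metadata=dataset.metadata, outlier=dataset.outlier)


# ---------------------------------------------------------------------------
# intensity classes
# ---------------------------------------------------------------------------

@dataclass
class IntensityClassModel:
    """Partition of components into abundance classes.

    ``thresholds`` are ascending cut points on the mean-abundance scale
    (length ``n_classes - 1``); ``classes`` assigns each component the index
    of its class (0 = least abundant).
    """

    thresholds: np.ndarray
    classes: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise DataError("thresholds must be strictly ascending")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.classes, minlength=self.n_classes)

    @property
    def top_class_components(self) -> np.ndarray:
        """Indices of the most abundant class's components."""
        return np.flatnonzero(self.classes == self.n_classes - 1)


def fit_intensity_classes(matrix: AbundanceMatrix, n_classes: int = 5,
                          seed: int = 0) -> IntensityClassModel:
    """Fit a 1-D Gaussian mixture to log10 mean component abundances.

    Thresholds are placed where the posterior-most-probable class switches
    between adjacent (abundance-ordered) mixture components.  If the
    mixture degenerates (a class captures no component), ``n_classes`` is
    reduced with a warning.
    """
    if matrix.n_components < n_classes:
        raise ParameterError("need at least n_classes components")
    mean_ab = matrix.values[matrix.good].mean(axis=0)
    x = np.log10(np.maximum(mean_ab, 1e-12))
    while n_classes > 1:
        gm = GaussianMixture(n_components=n_classes, random_state=seed,
                             n_init=5)
        gm.fit(x[:, None])
        order = np.argsort(gm.means_[:, 0])
        grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 4096)
        post_cls = order.argsort()[gm.predict(grid[:, None])]  # rank on grid
        switches = np.flatnonzero(np.diff(post_cls) > 0)
        # degenerate if some rank never wins anywhere on the grid
        if len(np.unique(post_cls)) < n_classes or len(switches) != n_classes - 1:
            warnings.warn(f"degenerate intensity mixture; reducing classes to "
                          f"{n_classes - 1}", stacklevel=2)
            n_classes -= 1
            continue
        log_thresholds = 0.5 * (grid[switches] + grid[switches + 1])
        classes = np.searchsorted(log_thresholds, x, side="right")
        return IntensityClassModel(thresholds=10.0 ** log_thresholds,
                                   classes=classes, n_classes=n_classes)
    return IntensityClassModel(thresholds=np.empty(0),
                               classes=np.zeros(matrix.n_components, int),
                               n_classes=1)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class AverageSpectrumGMM:
    """Gaussian-mixture peak model of an average MSI spectrum.

    Parameters
    ----------
    mz_axis, intensity : ndarray
        The average spectrum, e.g. from :func:`average_spectrum`.

    ``fit()`` runs segment-wise weighted EM, pruning and merging, and
    returns a :class:`ComponentFitResults`.
    """

    def __init__(self, mz_axis: np.ndarray, intensity: np.ndarray):
        self.mz_axis = np.asarray(mz_axis, float)
        self.intensity = np.asarray(intensity, float)

    @classmethod
    def from_dataset(cls, dataset: SpectraDataset) -> "AverageSpectrumGMM":
        return cls(dataset.mz_axis, average_spectrum(dataset))

    def fit(self, max_components_per_segment: int = 8,
            rel_threshold: float = 1e-3, target_residual: float = 0.05,
            amp_quantile: float = 0.05, sigma_max_da: float | None = None,
            merge_factor: float = 1.0) -> "ComponentFitResults":
        raw = fit_gmm(self.mz_axis, self.intensity,
                      max_components_per_segment=max_components_per_segment,
                      rel_threshold=rel_threshold,
                      target_residual=target_residual)
        if sigma_max_da is None:
            # broad background Gaussians are several times wider than any
            # plausible peptide peak at the top of the mass range
            sigma_max_da = 5.0 * np.median([c.sigma for c in raw])
        pruned, kept = prune_components(raw, amp_quantile=amp_quantile,
                                        sigma_max_da=sigma_max_da)
        model = merge_components(pruned, merge_factor=merge_factor,
                                 provenance=kept)
        return ComponentFitResults(self, raw, model)


class ComponentFitResults:
    """Results of fitting :class:`AverageSpectrumGMM`."""

    def __init__(self, model: AverageSpectrumGMM,
                 raw_components: list[GaussComponent],
                 component_model: ComponentModel):
        self.model = model
        self.raw_components = raw_components
        self.component_model = component_model

    @property
    def n_components(self) -> int:
        return self.component_model.n_components

    @property
    def explained_intensity(self) -> float:
        """Fraction of total spectrum intensity captured by the retained
        model (1 - relative L1 residual)."""
        recon = self.component_model.reconstruction(self.model.mz_axis)
        total = self.model.intensity.sum()
        return float(1.0 - np.abs(recon - self.model.intensity).sum() / total)

    def estimate_abundances(self, dataset: SpectraDataset) -> AbundanceMatrix:
        return estimate_abundances(dataset, self.component_model)

    def summary(self) -> str:
        cm = self.component_model
        lines = [
            "Average-spectrum Gaussian mixture",
            "=" * 40,
            f"raw components:      {len(self.raw_components)}",
            f"retained components: {cm.n_components}",
            f"m/z range:           {cm.mz_values.min():.1f} - "
            f"{cm.mz_values.max():.1f}",
            f"explained intensity: {self.explained_intensity:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the model reconstruction on the average spectrum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.plot(self.model.mz_axis, self.model.intensity, lw=0.7,
                label="average spectrum")
        ax.plot(self.model.mz_axis,
                self.component_model.reconstruction(self.model.mz_axis),
                lw=0.7, label="GMM reconstruction")
        ax.set_xlabel("m/z (Da)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax
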