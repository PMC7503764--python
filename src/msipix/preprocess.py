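"""Preprocessing chain for pixel-level MSI spectra.

Fixed stage order: mass-channel unification -> baseline subtraction ->
TIC outlier flagging -> FFT alignment to the reference average spectrum ->
TIC normalization.  No stage reorders pixels or alters metadata; outlier
pixels are flagged, never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from statsmodels.stats.stattools import medcouple

from .dataset import SpectraDataset
from .exceptions import DataError, ParameterError

# medcouple is O(n^2) in memory; estimate it on a subsample beyond this size
_MEDCOUPLE_MAX_N = 5000


@dataclass
class PreprocessReport:
    """Record of what preprocessing did to each pixel."""

    n_outliers_flagged: int = 0
    tic_before: np.ndarray | None = None
    tic_after: np.ndarray | None = None
    shifts: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def unify_mass_channels(spectra: list[tuple[np.ndarray, np.ndarray]],
                        target_axis: np.ndarray) -> np.ndarray:
    """Resample per-spectrum (axis, intensity) pairs onto one target axis.

    Linear interpolation; channels outside a source axis are set to 0.
    """
    target_axis = np.asarray(target_axis, float)
    if np.any(np.diff(target_axis) <= 0):
        raise DataError("target_axis must be strictly increasing")
    out = np.zeros((len(spectra), target_axis.size))
    for i, (axis, values) in enumerate(spectra):
        axis = np.asarray(axis, float)
        if np.any(np.diff(axis) <= 0):
            raise DataError(f"spectrum {i}: m/z axis not strictly increasing")
        out[i] = np.interp(target_axis, axis, np.asarray(values, float),
                           left=0.0, right=0.0)
    return out


def estimate_baseline(intensities: np.ndarray, mz_axis: np.ndarray,
                      window_da: float = 50.0) -> np.ndarray:
    """Smoothed rolling-minimum baseline estimate, one row per spectrum."""
    if window_da <= 0:
        raise ParameterError("window_da must be > 0")
    dx = float(np.median(np.diff(mz_axis)))
    span = mz_axis[-1] - mz_axis[0]
    if window_da >= span:
        raise ParameterError(
            f"baseline window {window_da} Da exceeds the axis span {span:.0f} Da")
    w = max(3, int(round(window_da / dx)) | 1)     # odd window
    rough = minimum_filter1d(intensities, size=w, axis=-1, mode="nearest")
    return uniform_filter1d(rough, size=w, axis=-1, mode="nearest")


def subtract_baseline(dataset: SpectraDataset,
                      window_da: float = 50.0) -> SpectraDataset:
    """Subtract the smoothed rolling-minimum baseline; clip at zero."""
    out = dataset.copy()
    baseline = estimate_baseline(out.intensities, out.mz_axis, window_da)
    np.clip(out.intensities - baseline, 0.0, None, out=out.intensities)
    return out


def tic_outlier_fences(tics: np.ndarray, whisker: float = 1.5,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, float]:
    """Medcouple-adjusted boxplot fences for skewed, heavy-tailed samples.

    For medcouple MC >= 0 the fences are
    ``[Q1 - w*exp(-4*MC)*IQR, Q3 + w*exp(3*MC)*IQR]`` and for MC < 0
    ``[Q1 - w*exp(-3*MC)*IQR, Q3 + w*exp(4*MC)*IQR]``.
    """
    tics = np.asarray(tics, float)
    sample = tics
    if tics.size > _MEDCOUPLE_MAX_N:
        rng = rng or np.random.default_rng(0)
        sample = rng.choice(tics, _MEDCOUPLE_MAX_N, replace=False)
    mc = float(medcouple(sample))
    q1, q3 = np.percentile(tics, [25, 75])
    iqr = q3 - q1
    if mc >= 0:
        lo = q1 - whisker * np.exp(-4.0 * mc) * iqr
        hi = q3 + whisker * np.exp(3.0 * mc) * iqr
    else:
        lo = q1 - whisker * np.exp(-3.0 * mc) * iqr
        hi = q3 + whisker * np.exp(4.0 * mc) * iqr
    return float(lo), float(hi)


def flag_tic_outliers(dataset: SpectraDataset, whisker: float = 1.5
                      ) -> tuple[SpectraDataset, PreprocessReport]:
    """Flag pixels whose TIC lies outside the adjusted-boxplot fences.

    Flagged pixels stay in the container but are excluded from all
    downstream model fitting.
    """
    if dataset.n_pixels < 10:
        raise ParameterError("TIC outlier flagging needs at least 10 pixels")
    out = dataset.copy()
    tics = out.tic()
    lo, hi = tic_outlier_fences(tics, whisker)
    flags = (tics < lo) | (tics > hi)
    out.outlier = out.outlier | flags
    report = PreprocessReport(
        n_outliers_flagged=int(flags.sum()), tic_before=tics,
        params={"fence_low": lo, "fence_high": hi, "whisker": whisker})
    return out, report


def _apply_integer_shift(spectra: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Shift each row right by its integer shift, zero-filling vacated edges."""
    out = np.empty_like(spectra)
    for s in np.unique(shifts):
        sel = shifts == s
        rolled = np.roll(spectra[sel], s, axis=1)
        if s > 0:
            rolled[:, :s] = 0.0
        elif s < 0:
            rolled[:, s:] = 0.0
        out[sel] = rolled
    return out


def _best_lags(reference: np.ndarray, spectra: np.ndarray,
               shift_max: int) -> np.ndarray:
    """Integer lag in [-shift_max, shift_max] maximizing the circular
    cross-correlation of each spectrum with the reference."""
    n = reference.size
    fr = np.fft.rfft(reference)
    fs = np.fft.rfft(spectra, axis=-1)
    corr = np.fft.irfft(fr[None, :] * np.conj(fs), n=n, axis=-1)
    lags = np.concatenate([np.arange(0, shift_max + 1),
                           np.arange(-shift_max, 0)])
    cols = np.concatenate([np.arange(0, shift_max + 1),
                           np.arange(n - shift_max, n)])
    window = corr[:, cols]
    return lags[np.argmax(window, axis=1)]


def align_to_reference(dataset: SpectraDataset, shift_max: int = 10,
                       granularity: str = "spectrum", n_iter: int = 2
                       ) -> tuple[SpectraDataset, np.ndarray]:
    """Align spectra to the average of non-outlier pixels by integer shifts.

    The shift maximizing the FFT cross-correlation with the reference within
    ``+/-shift_max`` channels is applied per spectrum, or per core (using
    each core's mean spectrum) when ``granularity='core'``.  The reference
    is refined iteratively (default two passes): the first average over
    unaligned spectra is blurred by the very shifts being estimated, so a
    second pass against the average of the aligned spectra sharpens the
    consensus grid.  Returns the aligned dataset and the total applied
    per-pixel shifts.
    """
    if shift_max >= dataset.n_channels // 2:
        raise ParameterError("shift_max must be < n_channels / 2")
    if granularity not in ("spectrum", "core"):
        raise ParameterError("granularity must be 'spectrum' or 'core'")
    out = dataset.copy()
    good = out.good
    if not good.any():
        raise DataError("all pixels are flagged; no reference spectrum")
    core_ids = out.metadata["core_id"].to_numpy()
    total = np.zeros(out.n_pixels, dtype=int)
    current = out.intensities
    for _ in range(max(1, n_iter)):
        reference = current[good].mean(axis=0)
        if granularity == "spectrum":
            step = _best_lags(reference, current, shift_max)
        else:
            step = np.zeros(out.n_pixels, dtype=int)
            for core in np.unique(core_ids):
                sel = core_ids == core
                mean_spec = current[sel].mean(axis=0)
                step[sel] = _best_lags(reference, mean_spec[None, :],
                                       shift_max)[0]
        total = np.clip(total + step, -shift_max, shift_max)
        # reapply from the original data so zero-filled edges do not stack
        current = _apply_integer_shift(out.intensities, total)
        if not step.any():
            break
    out.intensities = current
    return out, total.astype(int)


def normalize_tic(dataset: SpectraDataset) -> SpectraDataset:
    """Scale each spectrum so its TIC equals the mean non-outlier TIC.

    Zero-TIC pixels are flagged as outliers, warned about and left as-is.
    """
    out = dataset.copy()
    tics = out.tic()
    zero = tics <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-TIC pixels flagged and skipped",
                      stacklevel=2)
        out.outlier = out.outlier | zero
    good = out.good
    if not good.any():
        raise DataError("no usable pixels for TIC normalization")
    target = tics[good].mean()
    scale = np.ones_like(tics)
    nz = ~zero
    scale[nz] = target / tics[nz]
    out.intensities *= scale[:, None]
    return out


def preprocess(dataset: SpectraDataset, baseline_window_da: float = 50.0,
               shift_max: int = 10, granularity: str = "spectrum",
               whisker: float = 1.5
               ) -> tuple[SpectraDataset, PreprocessReport]:
    """Run the full preprocessing chain in its fixed order."""
    tic0 = dataset.tic()
    ds = subtract_baseline(dataset, baseline_window_da)
    ds, report = flag_tic_outliers(ds, whisker)
    ds, shifts = align_to_reference(ds, shift_max, granularity)
    ds = normalize_tic(ds)
    report.tic_before = tic0
    report.tic_after = ds.tic()
    report.shifts = shifts
    report.params.update({
        "baseline_window_da": baseline_window_da,
        "shift_max": shift_max,
        "granularity": granularity,
    })
    return ds, report
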