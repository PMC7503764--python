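"""Synthetic MALDI-MSI dataset generator with planted ground truth.

The generator emulates the structure of a tissue-microarray MSI study of
seven thyroid tissue classes: a patient -> core -> pixel hierarchy, spectra
built from Gaussian peptide peaks on a 700-3700 Da axis, per-ROI signature
peaks with a controllable standardized effect size (Cohen's d), per-ROI
within-class heterogeneity (normal thyroid most homogeneous, anaplastic
carcinoma least), inter-patient random effects, and the acquisition
artifacts the preprocessing chain is designed to remove: a smooth baseline,
additive noise, per-pixel total-ion-current variation with occasional
aberrant-TIC outliers, and a per-core integer channel miscalibration shift.

Effect sizes are planted on the peak-area (abundance) scale.  Both the
patient and the pixel multiplicative log-normal effects are centered to
mean one, so for peak ``k`` the abundance of a pixel from ROI ``r`` has
mean ``M[r, k]`` and standard deviation ``M[r, k] * sqrt(expm1(s^2))``
where ``s^2 = patient_sd^2 + (pixel_cv * h_r)^2`` and ``h_r`` is the ROI's
heterogeneity multiplier.  The signature-peak elevation ``delta`` solving
``d_target = delta / (c * sqrt(((1 + delta)^2 + 1) / 2))`` (with
``c = sqrt(expm1(s^2))`` at the mean heterogeneity) is obtained in closed
form, which makes the planted d analytically exact for equal-heterogeneity
pairs and recorded exactly for all pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ROI_LABELS, GroundTruth, SpectraDataset
from .exceptions import ParameterError

#: Default per-ROI within-class heterogeneity multipliers.  Ordered so that
#: normal thyroid is the most homogeneous tissue and anaplastic carcinoma
#: the most heterogeneous, with medullary carcinoma in between.
DEFAULT_HETEROGENEITY: dict[str, float] = {
    "NT": 0.7, "FA": 0.8, "PTC-CV": 1.0, "PTC-FV": 1.0,
    "FTC": 1.1, "ATC": 1.5, "MTC": 1.2,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Counts are exact (``cores_per_patient`` cores for every patient).
    ``n_discriminative`` is the number of signature peaks elevated per ROI,
    so every ROI pair differs on ``2 * n_discriminative`` peaks at the
    planted effect size ``target_d``.
    """

    n_patients_per_roi: int = 2
    cores_per_patient: int = 3
    pixels_per_core: int = 50
    mz_range: tuple[float, float] = (700.0, 3700.0)
    n_channels: int = 4000
    n_peaks: int = 200
    peak_sigma_da: float = 1.0          # Gaussian sigma at m/z 1000; scales with m/z
    n_discriminative: int = 10          # signature peaks per ROI
    target_d: float = 1.5
    patient_sd: float = 0.15            # log-scale SD of per-(patient, peak) effect
    pixel_cv: float = 0.25              # log-scale SD of per-(pixel, peak) effect at h=1
    roi_heterogeneity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HETEROGENEITY))
    baseline_amp: float = 30.0
    noise_sd: float = 2.0
    tic_cv: float = 0.15
    shift_channels_max: int = 3
    outlier_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients_per_roi": self.n_patients_per_roi,
            "cores_per_patient": self.cores_per_patient,
            "pixels_per_core": self.pixels_per_core,
            "n_channels": self.n_channels,
            "n_peaks": self.n_peaks,
        }
        for name, value in counts.items():
            if value < 1:
                raise ParameterError(f"{name} must be >= 1, got {value}")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ParameterError("mz_range low must be < high")
        if self.target_d < 0:
            raise ParameterError("target_d must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ParameterError("outlier_fraction must be in [0, 1)")
        if self.n_discriminative * len(ROI_LABELS) > self.n_peaks:
            raise ParameterError(
                "n_discriminative * 7 signature peaks exceed n_peaks")
        if self.shift_channels_max < 0:
            raise ParameterError("shift_channels_max must be >= 0")
        missing = [r for r in ROI_LABELS if r not in self.roi_heterogeneity]
        if missing:
            raise ParameterError(f"roi_heterogeneity missing ROIs: {missing}")


def _signature_elevation(target_d: float, c: float) -> float:
    """Closed-form relative elevation delta achieving Cohen's d = target_d.

    Solves d = delta / (c * sqrt(((1+delta)^2 + 1)/2)) for delta >= 0, where
    c is the coefficient of variation of the per-pixel abundance.
    """
    if target_d == 0:
        return 0.0
    a = 0.5 * (target_d * c) ** 2
    if a >= 1:
        raise ParameterError(
            "target_d unreachable at this noise level (relative SD too large)")
    return (a + np.sqrt(2 * a - a * a)) / (1 - a)


def _analytic_d(m_a: float, m_b: float, c_a: float, c_b: float) -> float:
    """Cohen's d of two mean-1-lognormal-scaled abundances (equal group n)."""
    sd2 = 0.5 * ((m_a * c_a) ** 2 + (m_b * c_b) ** 2)
    if sd2 == 0:
        return 0.0
    return (m_a - m_b) / np.sqrt(sd2)


def generate_dataset(config: SynthConfig) -> tuple[SpectraDataset, GroundTruth]:
    """Generate a synthetic MSI dataset plus its ground truth.

    Returns a :class:`SpectraDataset` (7 * n_patients_per_roi patients,
    cores_per_patient cores each, pixels_per_core pixels per core) and a
    :class:`GroundTruth` with the planted peak locations, per-ROI mean
    areas, analytic pairwise Cohen's d, injected outliers and shifts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range
    mz = np.linspace(lo, hi, config.n_channels)

    # --- peak catalogue ---------------------------------------------------
    margin = 0.02 * (hi - lo)
    peak_mz = np.sort(rng.uniform(lo + margin, hi - margin, config.n_peaks))
    peak_sigma = config.peak_sigma_da * peak_mz / 1000.0
    # log-normal base areas give the wide, multi-decade intensity spread of
    # real tryptic-peptide spectra
    base_area = np.exp(rng.normal(np.log(300.0), 1.0, config.n_peaks))

    # --- per-ROI mean areas with planted signature blocks ------------------
    h = np.array([config.roi_heterogeneity[r] for r in ROI_LABELS])
    sigma2_roi = config.patient_sd ** 2 + (config.pixel_cv * h) ** 2
    c_roi = np.sqrt(np.expm1(sigma2_roi))
    c_mean = np.sqrt(np.expm1(config.patient_sd ** 2 +
                              (config.pixel_cv * h.mean()) ** 2))
    delta = _signature_elevation(config.target_d, c_mean)

    disc_flat = rng.choice(config.n_peaks,
                           size=config.n_discriminative * len(ROI_LABELS),
                           replace=False)
    discriminative = {
        roi: np.sort(disc_flat[i * config.n_discriminative:
                               (i + 1) * config.n_discriminative])
        for i, roi in enumerate(ROI_LABELS)
    }
    mean_area = np.tile(base_area, (len(ROI_LABELS), 1))
    for i, roi in enumerate(ROI_LABELS):
        mean_area[i, discriminative[roi]] *= 1.0 + delta

    # --- hierarchy ----------------------------------------------------------
    rows = []
    patient_rois = []
    for roi in ROI_LABELS:
        for p in range(config.n_patients_per_roi):
            patient_rois.append((f"pat-{roi}-{p:03d}", roi))
    pixel_id = 0
    side = int(np.ceil(np.sqrt(config.pixels_per_core)))
    for patient_id, roi in patient_rois:
        for c in range(config.cores_per_patient):
            core_id = f"{patient_id}-c{c}"
            for px in range(config.pixels_per_core):
                rows.append((pixel_id, core_id, patient_id, roi,
                             px % side, px // side))
                pixel_id += 1
    meta = pd.DataFrame(rows, columns=["pixel_id", "core_id", "patient_id",
                                       "roi_label", "x", "y"])
    n_pixels = len(meta)
    roi_idx = meta["roi_label"].map({r: i for i, r in enumerate(ROI_LABELS)})
    roi_idx = roi_idx.to_numpy()

    # --- per-pixel peak areas ----------------------------------------------
    patients = [p for p, _ in patient_rois]
    pat_pos = meta["patient_id"].map({p: i for i, p in enumerate(patients)})
    pat_pos = pat_pos.to_numpy()
    # mean-one lognormal patient effect, shared across a patient's cores
    pat_fx = np.exp(rng.normal(-0.5 * config.patient_sd ** 2, config.patient_sd,
                               size=(len(patients), config.n_peaks)))
    sx = config.pixel_cv * h[roi_idx]                       # per-pixel log SD
    pix_fx = np.exp(rng.normal(0.0, 1.0, size=(n_pixels, config.n_peaks))
                    * sx[:, None] - 0.5 * sx[:, None] ** 2)
    areas = mean_area[roi_idx] * pat_fx[pat_pos] * pix_fx   # pixels x peaks

    # --- spectra -------------------------------------------------------------
    dx = mz[1] - mz[0]
    kernel = np.exp(-0.5 * ((mz[None, :] - peak_mz[:, None]) / peak_sigma[:, None]) ** 2)
    kernel /= peak_sigma[:, None] * np.sqrt(2 * np.pi)      # unit area
    spectra = areas @ kernel

    # smooth per-core baseline: slow exponential decay plus two wide bumps
    core_ids = meta["core_id"].to_numpy()
    cores = meta["core_id"].drop_duplicates().to_numpy()
    if config.baseline_amp > 0:
        t = (mz - lo) / (hi - lo)
        for core in cores:
            sel = core_ids == core
            centers = rng.uniform(lo, hi, 2)
            widths = rng.uniform(300.0, 800.0, 2)
            amps = rng.uniform(0.4, 1.0, 2)
            b = np.exp(-3.0 * t)
            for ctr, wid, amp in zip(centers, widths, amps):
                b = b + amp * np.exp(-0.5 * ((mz - ctr) / wid) ** 2)
            spectra[sel] += config.baseline_amp * b
    # additive detector noise, truncated at zero on the summed signal
    if config.noise_sd > 0:
        spectra += rng.normal(0.0, config.noise_sd, size=spectra.shape)
        np.clip(spectra, 0.0, None, out=spectra)

    # per-pixel TIC factor + injected aberrant-TIC outliers
    tic_factor = np.exp(rng.normal(0.0, config.tic_cv, n_pixels)) \
        if config.tic_cv > 0 else np.ones(n_pixels)
    outlier_mask = rng.random(n_pixels) < config.outlier_fraction
    tic_factor[outlier_mask] *= rng.uniform(6.0, 12.0, int(outlier_mask.sum()))
    spectra *= tic_factor[:, None]

    # per-core integer channel shift (miscalibration); vacated channels -> 0
    shift_per_core: dict[str, int] = {}
    for core in cores:
        k = int(rng.integers(-config.shift_channels_max,
                             config.shift_channels_max + 1)) \
            if config.shift_channels_max > 0 else 0
        shift_per_core[str(core)] = k
        if k != 0:
            sel = core_ids == core
            shifted = np.roll(spectra[sel], k, axis=1)
            if k > 0:
                shifted[:, :k] = 0.0
            else:
                shifted[:, k:] = 0.0
            spectra[sel] = shifted

    dataset = SpectraDataset(mz_axis=mz, intensities=spectra, metadata=meta)

    pairs = list(itertools.combinations(range(len(ROI_LABELS)), 2))
    d_table = np.zeros((config.n_peaks, len(pairs)))
    for j, (a, b) in enumerate(pairs):
        d_table[:, j] = [
            _analytic_d(mean_area[a, k], mean_area[b, k], c_roi[a], c_roi[b])
            for k in range(config.n_peaks)
        ]
    planted_d = pd.DataFrame(
        d_table,
        columns=[f"{ROI_LABELS[a]}|{ROI_LABELS[b]}" for a, b in pairs])
    truth = GroundTruth(
        true_peak_mz=peak_mz,
        true_peak_sigma=peak_sigma,
        true_amplitudes=pd.DataFrame(mean_area, index=list(ROI_LABELS)),
        planted_d=planted_d,
        outlier_pixel_ids=np.flatnonzero(outlier_mask),
        shift_per_core=shift_per_core,
        discriminative_peaks=discriminative,
        true_pixel_areas=areas,
    )
    return dataset, truth


def write_dataset(dataset: SpectraDataset, truth: GroundTruth | None,
                  path: str | Path) -> None:
    """Write a dataset (and optionally its ground truth) to a directory."""
    path = Path(path)
    dataset.save(path)
    if truth is not None:
        truth.save(path / "truth")


def read_dataset(path: str | Path,
                 with_truth: bool = False
                 ) -> SpectraDataset | tuple[SpectraDataset, GroundTruth]:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    dataset = SpectraDataset.load(path)
    if not with_truth:
        return dataset
    return dataset, GroundTruth.load(path / "truth")
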