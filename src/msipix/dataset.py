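"""Containers for pixel-level MSI spectra and their metadata.

A :class:`SpectraDataset` holds all spectra of a study on one shared m/z
axis together with the pixel -> core -> patient hierarchy that the
classification machinery relies on.  Tissue classes (regions of interest)
follow the seven-label thyroid scheme used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Canonical ROI ordering; also the documented tie-break order.
ROI_LABELS: tuple[str, ...] = (
    "NT", "FA", "PTC-CV", "PTC-FV", "FTC", "ATC", "MTC",
)
NOT_CLASSIFIED = "NOT_CLASSIFIED"
NOT_DIAGNOSTIC = "NOT_DIAGNOSTIC"

METADATA_COLUMNS = ("pixel_id", "core_id", "patient_id", "roi_label", "x", "y")


@dataclass
class SpectraDataset:
    """Pixel spectra on a unified m/z axis plus pixel metadata.

    Parameters
    ----------
    mz_axis : ndarray, shape (n_channels,)
        Strictly increasing m/z values in Da.
    intensities : ndarray, shape (n_pixels, n_channels)
        Non-negative intensities in arbitrary units.
    metadata : DataFrame
        One row per pixel with columns ``pixel_id, core_id, patient_id,
        roi_label, x, y``.
    outlier : ndarray of bool, shape (n_pixels,)
        Pixels flagged as TIC outliers; retained in the container but
        excluded from all downstream model fitting.
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame
    outlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_axis.ndim != 1:
            raise DataError("mz_axis must be one-dimensional")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise DataError("mz_axis must be strictly increasing")
        if self.intensities.ndim != 2:
            raise DataError("intensities must be a pixels x channels matrix")
        if self.intensities.shape[1] != self.mz_axis.size:
            raise DataError(
                f"intensities have {self.intensities.shape[1]} channels, "
                f"mz_axis has {self.mz_axis.size}"
            )
        if np.isnan(self.intensities).any():
            raise DataError("intensities contain NaN")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise DataError(f"metadata is missing columns: {missing}")
        if len(self.metadata) != self.intensities.shape[0]:
            raise DataError("metadata row count does not match pixel count")
        # every core must belong to exactly one patient
        per_core = self.metadata.groupby("core_id")["patient_id"].nunique()
        if (per_core > 1).any():
            bad = per_core[per_core > 1].index.tolist()
            raise DataError(f"cores mapped to multiple patients: {bad}")
        if self.outlier is None:
            self.outlier = np.zeros(self.n_pixels, dtype=bool)
        self.outlier = np.asarray(self.outlier, dtype=bool)
        if self.outlier.shape != (self.n_pixels,):
            raise DataError("outlier flags must have one entry per pixel")
        self.metadata = self.metadata.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def channel_width(self) -> float:
        """Median channel spacing in Da."""
        return float(np.median(np.diff(self.mz_axis)))

    def tic(self) -> np.ndarray:
        """Total ion current (sum of intensities) per pixel."""
        return self.intensities.sum(axis=1)

    @property
    def good(self) -> np.ndarray:
        """Boolean mask of non-outlier pixels."""
        return ~self.outlier

    def copy(self) -> "SpectraDataset":
        return SpectraDataset(
            mz_axis=self.mz_axis.copy(),
            intensities=self.intensities.copy(),
            metadata=self.metadata.copy(),
            outlier=self.outlier.copy(),
        )

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the dataset to a directory (matrix + axis + metadata CSV)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "intensities.npy", self.intensities)
        np.save(path / "mz_axis.npy", self.mz_axis)
        meta = self.metadata.copy()
        meta["outlier"] = self.outlier
        meta.to_csv(path / "metadata.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SpectraDataset":
        path = Path(path)
        for name in ("intensities.npy", "mz_axis.npy", "metadata.csv"):
            if not (path / name).exists():
                raise IOError(f"missing dataset file: {path / name}")
        try:
            intensities = np.load(path / "intensities.npy")
            mz = np.load(path / "mz_axis.npy")
        except Exception as exc:  # corrupt / truncated npy
            raise IOError(f"could not read dataset matrix under {path}: {exc}") from exc
        try:
            meta = pd.read_csv(path / "metadata.csv")
        except Exception as exc:
            raise IOError(f"could not read {path / 'metadata.csv'}: {exc}") from exc
        outlier = meta.pop("outlier").to_numpy(bool) if "outlier" in meta else None
        return cls(mz_axis=mz, intensities=intensities, metadata=meta, outlier=outlier)

    # -- optional imzML export --------------------------------------------
    def to_imzml(self, filename: str | Path) -> None:
        """Export to continuous-mode imzML (requires the pyimzml extra)."""
        from pyimzml.ImzMLWriter import ImzMLWriter

        with ImzMLWriter(str(filename), mode="continuous") as writer:
            for i in range(self.n_pixels):
                x = int(self.metadata.at[i, "x"])
                y = int(self.metadata.at[i, "y"])
                writer.addSpectrum(self.mz_axis, self.intensities[i], (x + 1, y + 1, 1))


def read_imzml(filename: str | Path, metadata: pd.DataFrame | None = None) -> SpectraDataset:
    """Read a continuous-mode imzML file into a :class:`SpectraDataset`.

    If ``metadata`` (pixel table keyed by x, y) is not given, every pixel is
    assigned to a single UNKNOWN core/patient.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(filename))
    mz0, _ = parser.getspectrum(0)
    spectra = np.empty((len(parser.coordinates), len(mz0)))
    rows = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, ints = parser.getspectrum(i)
        if len(ints) != spectra.shape[1]:
            raise IOError(f"{filename}: spectrum {i} is not on the shared axis")
        spectra[i] = ints
        rows.append({"pixel_id": i, "x": x - 1, "y": y - 1})
    meta = pd.DataFrame(rows)
    if metadata is not None:
        meta = meta.merge(metadata, on=("x", "y"), how="left")
    for col, default in (("core_id", "core0"), ("patient_id", "pat0"),
                         ("roi_label", "UNKNOWN")):
        if col not in meta:
            meta[col] = default
    return SpectraDataset(mz_axis=np.asarray(mz0, float), intensities=spectra,
                          metadata=meta[list(METADATA_COLUMNS)])


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests.

    ``true_amplitudes`` are per-ROI mean peak *areas* (a.u.·Da); ``planted_d``
    holds the analytic Cohen's d per peak for every unordered ROI pair;
    ``true_pixel_areas`` are the noiseless-channel per-pixel peak areas the
    generator actually drew (signal before baseline/noise/TIC artifacts).
    """

    true_peak_mz: np.ndarray                    # (n_peaks,)
    true_peak_sigma: np.ndarray                 # (n_peaks,)
    true_amplitudes: pd.DataFrame               # ROI x peak mean areas
    planted_d: pd.DataFrame                     # index peak, columns "A|B" pairs
    outlier_pixel_ids: np.ndarray
    shift_per_core: dict[str, int]
    discriminative_peaks: dict[str, np.ndarray]  # ROI -> peak indices
    true_pixel_areas: np.ndarray                # (n_pixels, n_peaks)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "truth_arrays.npz",
                 true_peak_mz=self.true_peak_mz,
                 true_peak_sigma=self.true_peak_sigma,
                 outlier_pixel_ids=self.outlier_pixel_ids,
                 true_pixel_areas=self.true_pixel_areas)
        self.true_amplitudes.to_csv(path / "true_amplitudes.csv")
        self.planted_d.to_csv(path / "planted_d.csv")
        with open(path / "truth.json", "w") as fh:
            json.dump({
                "shift_per_core": self.shift_per_core,
                "discriminative_peaks": {k: v.tolist() for k, v in
                                         self.discriminative_peaks.items()},
            }, fh)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        path = Path(path)
        try:
            arrays = np.load(path / "truth_arrays.npz")
            amp = pd.read_csv(path / "true_amplitudes.csv", index_col=0)
            d = pd.read_csv(path / "planted_d.csv", index_col=0)
            with open(path / "truth.json") as fh:
                extra = json.load(fh)
        except Exception as exc:
            raise IOError(f"could not read ground truth under {path}: {exc}") from exc
        return cls(
            true_peak_mz=arrays["true_peak_mz"],
            true_peak_sigma=arrays["true_peak_sigma"],
            true_amplitudes=amp,
            planted_d=d,
            outlier_pixel_ids=arrays["outlier_pixel_ids"],
            shift_per_core={k: int(v) for k, v in extra["shift_per_core"].items()},
            discriminative_peaks={k: np.asarray(v, int) for k, v in
                                  extra["discriminative_peaks"].items()},
            true_pixel_areas=arrays["true_pixel_areas"],
        )
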