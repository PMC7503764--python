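"""Shared fixtures: synthetic studies reused across test modules.

The session-scoped studies are deliberately small (7 ROIs, 2 patients/ROI,
3 cores/patient, 50 pixels/core = 2100 pixels on 4000 channels) so the full
pipeline stays fast while keeping the hierarchical structure intact.
"""

import warnings

import numpy as np
import pytest

from msipix import ROI_LABELS, SynthConfig, generate_dataset, run_study
from msipix.gmm import AbundanceMatrix


def uniform_heterogeneity(value: float = 1.0) -> dict[str, float]:
    return {r: value for r in ROI_LABELS}


def true_area_matrix(dataset, truth) -> AbundanceMatrix:
    """Abundance matrix built from the generator's noiseless peak areas."""
    return AbundanceMatrix(values=truth.true_pixel_areas,
                           component_mz=truth.true_peak_mz,
                           metadata=dataset.metadata,
                           outlier=np.zeros(dataset.n_pixels, bool))


@pytest.fixture(scope="session")
def default_study():
    """Full pipeline on the default planted-effect configuration."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(seed=11)


@pytest.fixture(scope="session")
def zero_effect_study():
    """Full pipeline with no planted effects and uniform heterogeneity."""
    config = SynthConfig(target_d=0.0,
                         roi_heterogeneity=uniform_heterogeneity())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(config=config, seed=12,
                         approaches=("single-pixel",))


@pytest.fixture(scope="session")
def high_heterogeneity_study():
    """Planted effects with amplified within-class noise and stronger
    inter-patient variation — the regime where core-mean training data are
    scarce and patient-confounded."""
    from msipix.synth import DEFAULT_HETEROGENEITY

    config = SynthConfig(
        roi_heterogeneity={r: 1.5 * h for r, h in
                           DEFAULT_HETEROGENEITY.items()},
        patient_sd=0.3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(config=config, seed=13,
                         approaches=("single-pixel", "mean-spectrum"))


@pytest.fixture(scope="session")
def flat_effect_areas():
    """Generator truth areas with zero planted effects, 2000 pixels/ROI.
    Patient clustering is switched off so the pooled d estimator has pure
    pixel-sampling noise (the quantity the planting mechanism controls);
    the sample is large enough that a |d| < 0.15 bound sits at ~4.7 sigma
    of the estimator.  Channels/peaks are reduced: only the planted areas
    are consumed."""
    config = SynthConfig(n_patients_per_roi=10, cores_per_patient=1,
                         pixels_per_core=200, target_d=0.0, patient_sd=0.0,
                         n_channels=600, n_peaks=80,
                         roi_heterogeneity=uniform_heterogeneity(), seed=21)
    dataset, truth = generate_dataset(config)
    return true_area_matrix(dataset, truth), truth


@pytest.fixture(scope="session")
def planted_effect_areas():
    """Generator truth areas with planted d = 1.5, 500 pixels/ROI."""
    config = SynthConfig(n_patients_per_roi=10, cores_per_patient=1,
                         pixels_per_core=50, target_d=1.5, patient_sd=0.05,
                         roi_heterogeneity=uniform_heterogeneity(), seed=22)
    dataset, truth = generate_dataset(config)
    return true_area_matrix(dataset, truth), truth
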