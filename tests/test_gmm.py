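"""Gaussian-mixture peak model: recovery of planted peaks, pruning,
merging, abundance estimation, intensity classes."""

import numpy as np
import pytest

from msipix import (DataError, GaussComponent, average_spectrum,
                    estimate_abundances, fit_gmm, fit_intensity_classes,
                    merge_components, prune_components)
from msipix.gmm import AbundanceMatrix, AverageSpectrumGMM

from test_preprocess import make_dataset


def gauss(mz, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((mz - mu) / sigma) ** 2)


class TestAverageSpectrum:
    def test_single_pixel_is_its_own_average(self):
        ds = make_dataset(np.arange(12.0))
        np.testing.assert_allclose(average_spectrum(ds), np.arange(12.0))

    def test_two_pixel_mean(self):
        ds = make_dataset(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(average_spectrum(ds), [1.0, 1.0])

    def test_outliers_excluded(self):
        ds = make_dataset(np.array([[1.0, 1.0], [100.0, 100.0]]))
        ds.outlier[1] = True
        np.testing.assert_allclose(average_spectrum(ds), [1.0, 1.0])

    def test_all_flagged_raises(self):
        ds = make_dataset(np.ones((2, 4)))
        ds.outlier[:] = True
        with pytest.raises(DataError):
            average_spectrum(ds)

    def test_generated_average_matches_expectation(self, default_study):
        pre = default_study.gmm_results.model
        # the average must be non-negative and peaked where intensity is
        assert pre.intensity.min() >= 0
        assert pre.intensity.max() > 10 * np.median(pre.intensity)


class TestFitGmm:
    def test_single_planted_peak_recovered(self):
        mz = np.arange(995.0, 1005.0, 0.02)
        comps = fit_gmm(mz, gauss(mz, 1000.0, 0.5, 100.0))
        assert len(comps) == 1
        assert abs(comps[0].mu - 1000.0) < 0.05
        assert abs(comps[0].sigma - 0.5) < 0.1

    def test_two_separated_peaks_recovered(self):
        mz = np.arange(990.0, 1030.0, 0.02)
        spec = gauss(mz, 1000.0, 0.5, 100.0) + gauss(mz, 1020.0, 0.6, 60.0)
        comps = fit_gmm(mz, spec)
        assert len(comps) == 2
        assert abs(comps[0].mu - 1000.0) < 0.05
        assert abs(comps[1].mu - 1020.0) < 0.05

    def test_all_zero_spectrum_raises(self):
        with pytest.raises(DataError):
            fit_gmm(np.linspace(700, 800, 100), np.zeros(100))

    def test_negative_spectrum_raises(self):
        with pytest.raises(DataError):
            fit_gmm(np.linspace(700, 800, 100), -np.ones(100))


class TestPruneMerge:
    def make(self, mus, sigmas, amps):
        return [GaussComponent(m, s, a) for m, s, a in zip(mus, sigmas, amps)]

    def test_amplitude_threshold(self):
        comps = self.make([1000, 1010, 1020], [0.5] * 3, [1.0, 100.0, 100.0])
        kept, idx = prune_components(comps, amp_min=10.0)
        assert len(kept) == 2 and idx == [1, 2]

    def test_no_thresholds_is_identity(self):
        comps = self.make([1000, 1010], [0.5, 0.5], [1.0, 2.0])
        kept, idx = prune_components(comps, amp_quantile=0.0)
        assert kept == comps and idx == [0, 1]

    def test_broad_component_removed(self):
        comps = self.make([1000, 1010], [50.0, 0.5], [100.0, 100.0])
        kept, _ = prune_components(comps, amp_quantile=0.0, sigma_max_da=5.0)
        assert len(kept) == 1 and kept[0].sigma == 0.5

    def test_all_pruned_raises(self):
        comps = self.make([1000], [0.5], [1.0])
        with pytest.raises(DataError):
            prune_components(comps, amp_min=10.0)

    def test_merge_keeps_dominant_location(self):
        comps = self.make([1000.0, 1000.2], [0.5, 0.5], [10.0, 30.0])
        model = merge_components(comps)
        assert model.n_components == 1
        assert model.components[0].mu == pytest.approx(1000.2)
        assert len(model.members[0]) == 2

    def test_separated_components_unchanged(self):
        comps = self.make([1000.0, 1010.0], [0.5, 0.5], [10.0, 30.0])
        model = merge_components(comps)
        assert model.n_components == 2

    def test_transitive_chain_merges_to_one(self):
        comps = self.make([1000.0, 1000.3, 1000.6], [0.5] * 3,
                          [10.0, 20.0, 30.0])
        model = merge_components(comps)
        assert model.n_components == 1
        assert model.components[0].mu == pytest.approx(1000.6)
        assert sorted(model.provenance[0]) == [0, 1, 2]


class TestAbundances:
    def test_matches_analytic_gaussian_inner_product(self):
        mz = np.arange(990.0, 1030.0, 0.01)
        sigma, area = 0.5, 80.0
        spec = area * np.exp(-0.5 * ((mz - 1000.0) / sigma) ** 2) \
            / (sigma * np.sqrt(2 * np.pi))
        ds = make_dataset(spec, mz)
        model = merge_components([GaussComponent(1000.0, sigma,
                                                 area / (sigma * np.sqrt(2 * np.pi))),
                                  GaussComponent(1020.0, sigma, 5.0)])
        matrix = estimate_abundances(ds, model)
        # <A*g, g> = A / (2 sigma sqrt(pi)) for a unit-area kernel g
        expected = area / (2 * sigma * np.sqrt(np.pi))
        assert matrix.values[0, 0] == pytest.approx(expected, rel=1e-3)
        assert matrix.values[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_pixel_gives_zero_row(self):
        mz = np.linspace(990, 1010, 500)
        ds = make_dataset(np.vstack([np.ones(500), np.zeros(500)]), mz)
        model = merge_components([GaussComponent(1000.0, 0.5, 10.0)])
        matrix = estimate_abundances(ds, model)
        assert matrix.values[1].sum() == 0.0

    def test_axis_mismatch_raises(self):
        ds = make_dataset(np.ones((1, 100)), np.linspace(700, 800, 100))
        model = merge_components([GaussComponent(2000.0, 0.5, 10.0)])
        with pytest.raises(DataError):
            estimate_abundances(ds, model)

    def test_mean_abundance_tracks_true_amplitudes(self):
        """Convolution quantification recovers generator peak areas where
        they are identifiable: artifact-free spectra and peaks resolved
        from their neighbors (overlapping peaks share intensity through the
        kernel tails by construction)."""
        from msipix import SynthConfig, generate_dataset

        config = SynthConfig(n_patients_per_roi=1, cores_per_patient=1,
                             pixels_per_core=30, baseline_amp=0.0,
                             noise_sd=0.0, tic_cv=0.0, shift_channels_max=0,
                             outlier_fraction=0.0, seed=11)
        dataset, truth = generate_dataset(config)
        results = AverageSpectrumGMM.from_dataset(dataset).fit()
        matrix = results.estimate_abundances(dataset)
        cm = results.component_model
        mean_ab = matrix.values.mean(axis=0)
        sigma = np.array([c.sigma for c in cm.components])
        n_members = np.array([len(m) for m in cm.members])
        true_mean = truth.true_amplitudes.mean(axis=0).to_numpy()
        pk, sg = truth.true_peak_mz, truth.true_peak_sigma
        isolated = np.minimum(np.diff(pk, prepend=-np.inf),
                              np.diff(pk, append=np.inf)) > 6 * sg
        est, tru = [], []
        for k in np.flatnonzero(isolated):
            j = np.argmin(np.abs(cm.mz_values - pk[k]))
            if abs(cm.mz_values[j] - pk[k]) < 1.0:
                # back to the area scale; merged members each contribute one
                # unit-area kernel over the same peak
                est.append(mean_ab[j] * 2 * sigma[j] * np.sqrt(np.pi)
                           / n_members[j])
                tru.append(true_mean[k])
        assert len(tru) >= 0.8 * isolated.sum()
        r = np.corrcoef(est, tru)[0, 1]
        assert r > 0.95


class TestIntensityClasses:
    def _matrix_from_means(self, means):
        values = np.tile(means, (4, 1))
        meta = make_dataset(np.ones((4, 2))).metadata
        return AbundanceMatrix(values=values,
                               component_mz=np.linspace(1000, 2000, means.size),
                               metadata=meta, outlier=np.zeros(4, bool))

    def test_five_planted_modes_recovered(self):
        rng = np.random.default_rng(1)
        centers = [1.0, 2.0, 3.0, 4.0, 5.0]   # log10 scale, well separated
        x = np.concatenate([rng.normal(c, 0.08, 60) for c in centers])
        matrix = self._matrix_from_means(10.0 ** x)
        model = fit_intensity_classes(matrix, n_classes=5, seed=0)
        assert model.n_classes == 5
        logt = np.log10(model.thresholds)
        for t, (lo, hi) in zip(logt, zip(centers[:-1], centers[1:])):
            assert lo < t < hi
        assert model.counts.tolist() == [60] * 5

    def test_single_class_has_no_thresholds(self):
        matrix = self._matrix_from_means(np.linspace(10, 20, 8))
        model = fit_intensity_classes(matrix, n_classes=1)
        assert model.thresholds.size == 0
        assert (model.classes == 0).all()

    def test_top_class_on_pipeline_output(self, default_study):
        model = default_study.intensity_model
        top = model.top_class_components
        assert top.size > 0
        # the top class is the most abundant one
        matrix = default_study.abundance
        mean_ab = matrix.values[matrix.good].mean(axis=0)
        assert mean_ab[top].min() >= np.median(mean_ab)


class TestModelInvariants:
    def test_data_reduction_contract(self, default_study):
        n_channels = default_study.dataset.n_channels
        assert default_study.gmm_results.n_components * 2 <= n_channels

    def test_reconstruction_explains_intensity(self, default_study):
        assert default_study.gmm_results.explained_intensity >= 0.90

    def test_abundance_bounded_by_spectrum_intensity(self, default_study):
        # per pixel, summed convolution abundances cannot exceed the total
        # spectrum intensity (near-partition; unit-area kernels)
        matrix = default_study.abundance
        totals = default_study.preprocessed.intensities.sum(axis=1)
        assert (matrix.values.sum(axis=1) <= 1.1 * totals).all()

    def test_summary_mentions_component_count(self, default_study):
        text = default_study.gmm_results.summary()
        assert str(default_study.gmm_results.n_components) in text
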