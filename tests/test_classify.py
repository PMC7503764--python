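"""One-vs-one ensemble, univocal voting, fold plans, core aggregation,
quality indices."""

import numpy as np
import pandas as pd
import pytest

from msipix import (DataError, NOT_DIAGNOSTIC, ParameterError,
                    ROI_LABELS, assign_patient_class, classify_pixel,
                    decide_from_votes, evaluate, fit_ensemble, make_folds)
from msipix.classify import (NC_INDEX, PAIRS, ROI_INDEX, CoreClassifier,
                             aggregate_core)
from msipix.gmm import AbundanceMatrix


def metadata_from_cores(cores):
    """cores: list of (patient_id, core_id, roi)."""
    rows = []
    for i, (p, c, r) in enumerate(cores):
        rows.append((i, c, p, r, 0, 0))
    return pd.DataFrame(rows, columns=["pixel_id", "core_id", "patient_id",
                                       "roi_label", "x", "y"])


def separable_blobs(n_per_class=30, n_features=14, gap=12.0, seed=0,
                    n_patients_per_class=5):
    """Linearly separable 7-class data with patient/core structure."""
    rng = np.random.default_rng(seed)
    X, rows = [], []
    pid = 0
    for ci, roi in enumerate(ROI_LABELS):
        center = np.zeros(n_features)
        center[2 * ci] = gap
        center[2 * ci + 1] = -gap
        for p in range(n_patients_per_class):
            patient = f"p{ci}_{p}"
            for i in range(n_per_class // n_patients_per_class):
                X.append(center + rng.normal(0, 1.0, n_features))
                rows.append((pid, f"{patient}-c0", patient, roi, 0, 0))
                pid += 1
    meta = pd.DataFrame(rows, columns=["pixel_id", "core_id", "patient_id",
                                       "roi_label", "x", "y"])
    return np.array(X), meta


class TestPatientClass:
    def test_majority_core_roi(self):
        meta = metadata_from_cores([("p1", "a", "NT"), ("p1", "b", "NT"),
                                    ("p1", "c", "FA")])
        assert assign_patient_class(meta) == {"p1": "NT"}

    def test_single_core_patient(self):
        meta = metadata_from_cores([("p1", "a", "MTC")])
        assert assign_patient_class(meta) == {"p1": "MTC"}

    def test_tie_breaks_by_canonical_order(self):
        meta = metadata_from_cores([("p1", "a", "FA"), ("p1", "b", "NT")])
        assert assign_patient_class(meta) == {"p1": "NT"}


class TestFoldPlan:
    def _meta_35_patients(self):
        cores = []
        for ci, roi in enumerate(ROI_LABELS):
            for p in range(5):
                cores.append((f"p{ci}_{p}", f"p{ci}_{p}-c0", roi))
        return metadata_from_cores(cores)

    def test_balanced_classes_fill_each_fold(self):
        meta = self._meta_35_patients()
        plan = make_folds(meta, k=5, seed=0)
        by_fold = {}
        for p, f in plan.patient_to_fold.items():
            by_fold.setdefault(f, []).append(plan.patient_class[p])
        for f in range(5):
            assert sorted(by_fold[f]) == sorted(ROI_LABELS)

    def test_no_leakage(self):
        meta = self._meta_35_patients()
        plan = make_folds(meta, k=5, seed=1)
        plan.assert_no_leakage(meta)

    def test_seeded_plan_is_deterministic(self):
        meta = self._meta_35_patients()
        a = make_folds(meta, k=5, seed=7)
        b = make_folds(meta, k=5, seed=7)
        assert a.patient_to_fold == b.patient_to_fold

    def test_k_below_two_raises(self):
        with pytest.raises(ParameterError):
            make_folds(self._meta_35_patients(), k=1)

    def test_few_patients_warns(self):
        cores = [(f"p{ci}", f"p{ci}-c0", roi)
                 for ci, roi in enumerate(ROI_LABELS)]
        with pytest.warns(UserWarning):
            make_folds(metadata_from_cores(cores), k=5)


class TestEnsemble:
    def test_seven_classes_give_21_binaries_each_class_in_six(self):
        X, meta = separable_blobs()
        model = fit_ensemble(X, meta["roi_label"].to_numpy())
        assert model.n_binaries == 21
        counts = {r: 0 for r in range(7)}
        for i, j in model.pairs:
            counts[i] += 1
            counts[j] += 1
        assert all(c == 6 for c in counts.values())

    def test_separable_data_trains_perfectly(self):
        X, meta = separable_blobs()
        y = meta["roi_label"].map(ROI_INDEX).to_numpy()
        model = fit_ensemble(X, meta["roi_label"].to_numpy())
        votes = model.votes(X)
        for m, (i, j) in enumerate(model.pairs):
            sel = (y == i) | (y == j)
            assert (votes[sel, m] == y[sel]).all()

    def test_missing_class_raises_with_name(self):
        X, meta = separable_blobs()
        labels = meta["roi_label"].to_numpy().copy()
        labels[labels == "MTC"] = "NT"
        with pytest.raises(DataError, match="MTC"):
            fit_ensemble(X, labels)

    def test_permuted_labels_give_chance_binary_accuracy(self):
        rng = np.random.default_rng(12)
        X, meta = separable_blobs(n_per_class=120, gap=0.0, seed=12)
        labels = meta["roi_label"].to_numpy()
        train = rng.random(len(labels)) < 0.6
        model = fit_ensemble(X[train], labels[train])
        votes = model.votes(X[~train])
        y = meta["roi_label"].map(ROI_INDEX).to_numpy()[~train]
        accs = []
        for m, (i, j) in enumerate(model.pairs):
            sel = (y == i) | (y == j)
            accs.append(np.mean(votes[sel, m] == y[sel]))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)


class TestUnivocalRule:
    def _votes_for_winner(self, winner):
        votes = []
        for i, j in PAIRS:
            if winner in (i, j):
                votes.append(winner)
            else:
                votes.append(i)
        return np.array(votes, dtype=np.int8)

    def test_class_winning_all_six_is_chosen(self):
        votes = self._votes_for_winner(ROI_INDEX["NT"])
        assert decide_from_votes(votes)[0] == ROI_INDEX["NT"]

    def test_cyclic_votes_leave_pixel_unclassified(self):
        # regular tournament: i beats j iff (j - i) mod 7 in {1, 2, 3};
        # every class has out-degree 3, so no class is univocal
        votes = np.array([i if (j - i) % 7 in (1, 2, 3) else j
                          for i, j in PAIRS], dtype=np.int8)
        assert decide_from_votes(votes)[0] == NC_INDEX

    def test_classify_pixel_wraps_rule(self):
        X, meta = separable_blobs()
        model = fit_ensemble(X, meta["roi_label"].to_numpy())
        decision = classify_pixel(X[0], model, pixel_id=42)
        assert decision.final == meta["roi_label"].iloc[0]
        assert decision.votes.shape == (21,)
        assert decision.pixel_id == 42


class TestCoreAggregation:
    def test_majority_roi_wins(self):
        finals = np.array([ROI_INDEX["NT"]] * 5 + [ROI_INDEX["FA"]] * 3
                          + [NC_INDEX] * 2)
        assert aggregate_core(finals) == "NT"

    def test_all_unclassified_is_not_diagnostic(self):
        assert aggregate_core(np.full(10, NC_INDEX)) == NOT_DIAGNOSTIC

    def test_tie_prefers_roi_over_unclassified(self):
        finals = np.array([ROI_INDEX["NT"]] * 4 + [NC_INDEX] * 4)
        assert aggregate_core(finals) == "NT"

    def test_roi_tie_breaks_canonically(self):
        finals = np.array([ROI_INDEX["FA"]] * 3 + [ROI_INDEX["NT"]] * 3)
        assert aggregate_core(finals) == "NT"

    def test_empty_core_raises(self):
        with pytest.raises(DataError):
            aggregate_core(np.array([], dtype=int))


class TestEvaluate:
    def test_perfect_decisions_have_unit_sensitivity(self):
        table = pd.DataFrame({"true": list(ROI_LABELS) * 3,
                              "predicted": list(ROI_LABELS) * 3})
        conf, metrics = evaluate(table)
        assert metrics["overall_correct_fraction"] == 1.0
        assert (metrics["per_class"]["sensitivity"] == 1.0).all()
        assert np.trace(conf.iloc[:, :7].to_numpy()) == 21

    def test_hand_confusion_sensitivity(self):
        # NT: TP=3, FN=1; FA: 6 correct -> sens(NT) = 0.75, no false NT
        table = pd.DataFrame({
            "true": ["NT"] * 4 + ["FA"] * 6,
            "predicted": ["NT"] * 3 + ["FA"] * 7,
        })
        _, metrics = evaluate(table)
        assert metrics["per_class"].at["NT", "sensitivity"] == pytest.approx(0.75)
        assert metrics["per_class"].at["NT", "precision"] == pytest.approx(1.0)

    def test_unknown_label_raises(self):
        table = pd.DataFrame({"true": ["XX"], "predicted": ["NT"]})
        with pytest.raises(DataError):
            evaluate(table)

    def test_not_diagnostic_fraction(self):
        table = pd.DataFrame({"true": ["NT", "FA"],
                              "predicted": ["NT", NOT_DIAGNOSTIC]})
        _, metrics = evaluate(table)
        assert metrics["not_diagnostic_fraction"] == 0.5


class TestStrategies:
    def _single_pixel_cores(self):
        """1 pixel per core: all three strategies must coincide."""
        X, meta = separable_blobs(n_per_class=20, n_patients_per_class=5,
                                  seed=6)
        meta = meta.copy()
        meta["core_id"] = meta["patient_id"] + "-c" + meta.groupby(
            "patient_id").cumcount().astype(str)
        matrix = AbundanceMatrix(values=np.abs(X),
                                 component_mz=np.arange(X.shape[1], dtype=float),
                                 metadata=meta,
                                 outlier=np.zeros(len(meta), bool))
        return matrix

    @pytest.mark.parametrize("other", ["hybrid", "mean-spectrum"])
    def test_one_pixel_cores_make_strategies_identical(self, other):
        matrix = self._single_pixel_cores()
        base = CoreClassifier(matrix).fit("single-pixel", k=5, seed=3)
        alt = CoreClassifier(matrix).fit(other, k=5, seed=3)
        merged = base.core_table.merge(alt.core_table, on="core_id",
                                       suffixes=("_a", "_b"))
        assert (merged["predicted_a"] == merged["predicted_b"]).all()

    def test_core_table_counts_match_confusion_rows(self, default_study):
        res = default_study.classification["single-pixel"]
        conf = res.confusion_matrix
        counts = res.core_table.groupby("true").size()
        for roi in ROI_LABELS:
            assert conf.loc[roi].sum() == counts.get(roi, 0)

    def test_summary_reports_key_metrics(self, default_study):
        res = default_study.classification["single-pixel"]
        text = res.summary()
        assert "correct fraction" in text and "Confusion matrix" in text

    def test_feature_ablation_runs_on_top_class(self, default_study):
        clf = CoreClassifier(default_study.abundance, feature_set="top",
                             intensity_model=default_study.intensity_model)
        res = clf.fit("single-pixel", k=5, seed=4)
        assert 0.0 <= res.overall_correct_fraction <= 1.0
        assert res.feature_set == "top"
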