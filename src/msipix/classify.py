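"""Single-pixel tissue classification with a one-vs-one linear-SVM ensemble.

Seven tissue classes give C(7,2) = 21 binary linear SVMs.  A pixel is
assigned class C only if the decision is *univocal*: all six binaries
featuring C vote C (a tournament vertex of out-degree 6 — at most one can
exist); otherwise the pixel is NOT_CLASSIFIED.  A tissue core is labeled by
the modal class of its pixels over the eight outcomes (7 ROIs +
NOT_CLASSIFIED); a NOT_CLASSIFIED mode yields NOT_DIAGNOSTIC.  Model
selection uses patient-stratified k-fold cross-validation: every patient
(assigned the majority ROI of its cores) sits in exactly one fold, so no
patient contributes pixels to both training and validation of a fold.

Three core-level strategies are supported: ``single-pixel`` (majority over
per-pixel univocal calls), ``mean-spectrum`` (ensemble trained and applied
on core-mean abundance vectors) and ``hybrid`` (pixel-trained ensemble
applied to core means).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .dataset import NOT_CLASSIFIED, NOT_DIAGNOSTIC, ROI_LABELS
from .exceptions import DataError, ParameterError
from .gmm import AbundanceMatrix, IntensityClassModel

ROI_INDEX = {r: i for i, r in enumerate(ROI_LABELS)}
PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(len(ROI_LABELS)), 2))
NC_INDEX = len(ROI_LABELS)          # integer code of NOT_CLASSIFIED


# ---------------------------------------------------------------------------
# patient classes and fold plans
# ---------------------------------------------------------------------------

def assign_patient_class(metadata: pd.DataFrame) -> dict[str, str]:
    """Majority ROI over each patient's cores; ties break by canonical
    ROI order (NT, FA, PTC-CV, PTC-FV, FTC, ATC, MTC)."""
    cores = metadata.drop_duplicates("core_id")[["patient_id", "roi_label"]]
    out: dict[str, str] = {}
    for patient, grp in cores.groupby("patient_id", sort=False):
        counts = grp["roi_label"].value_counts()
        top = counts[counts == counts.max()].index
        out[str(patient)] = min(top, key=lambda r: ROI_INDEX.get(r, 99))
    return out


@dataclass
class FoldPlan:
    """Patient-level k-fold partition; cores and pixels inherit the fold."""

    k: int
    patient_to_fold: dict[str, int]
    patient_class: dict[str, str] = field(default_factory=dict)

    def fold_of_pixels(self, metadata: pd.DataFrame) -> np.ndarray:
        return metadata["patient_id"].map(self.patient_to_fold).to_numpy()

    def assert_no_leakage(self, metadata: pd.DataFrame) -> None:
        """Every fold's training and validation patient sets are disjoint."""
        patients = metadata["patient_id"].unique()
        unassigned = [p for p in patients if p not in self.patient_to_fold]
        if unassigned:
            raise DataError(f"patients without a fold: {unassigned}")
        for fold in range(self.k):
            val = {p for p, f in self.patient_to_fold.items() if f == fold}
            train = {p for p, f in self.patient_to_fold.items() if f != fold}
            if val & train:
                raise DataError(f"fold {fold}: patient appears in both "
                                f"train and validation: {sorted(val & train)}")


def make_folds(metadata: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified patient-level folds: within each patient class, patients
    are shuffled and dealt round-robin, so the two-or-more patients of a
    class always land in different folds when possible."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    patient_class = assign_patient_class(metadata)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for roi in list(ROI_LABELS) + sorted(
            set(patient_class.values()) - set(ROI_LABELS)):
        members = sorted(p for p, c in patient_class.items() if c == roi)
        if not members:
            continue
        if len(members) < k:
            warnings.warn(f"class {roi} has {len(members)} patients for "
                          f"{k} folds; fold sizes will be uneven", stacklevel=2)
        rng.shuffle(members)
        for i, p in enumerate(members):
            assignment[p] = (offset + i) % k
        offset += len(members)
    return FoldPlan(k=k, patient_to_fold=assignment,
                    patient_class=patient_class)


# ---------------------------------------------------------------------------
# the one-vs-one ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """21 binary linear decision functions plus Z-score standardization."""

    weights: np.ndarray          # (21, n_kept)
    intercepts: np.ndarray       # (21,)
    mean: np.ndarray             # (n_features,)
    sd: np.ndarray               # (n_features,)
    kept: np.ndarray             # indices of non-zero-variance features
    pairs: tuple[tuple[int, int], ...] = PAIRS

    @property
    def n_binaries(self) -> int:
        return self.weights.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        Xz = (X[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]
        return Xz

    def votes(self, X: np.ndarray) -> np.ndarray:
        """(n, 21) int votes: class index chosen by each binary."""
        D = self.standardize(X) @ self.weights.T + self.intercepts
        votes = np.empty((X.shape[0], self.n_binaries), dtype=np.int8)
        for m, (i, j) in enumerate(self.pairs):
            votes[:, m] = np.where(D[:, m] > 0, j, i)
        return votes

    def decide(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (votes, finals); finals hold ROI indices or NC_INDEX."""
        votes = self.votes(X)
        return votes, decide_from_votes(votes, self.pairs)


def decide_from_votes(votes: np.ndarray,
                      pairs: tuple[tuple[int, int], ...] = PAIRS) -> np.ndarray:
    """Univocal rule applied to (n, 21) vote matrices.

    A row's final class is the ROI that wins all 6 of its binaries; if no
    ROI does, the code NC_INDEX (NOT_CLASSIFIED).  At most one ROI can win
    all its matches, which is asserted.
    """
    votes = np.atleast_2d(votes)
    n = votes.shape[0]
    wins = np.zeros((n, len(ROI_LABELS)), dtype=np.int8)
    for m, (i, j) in enumerate(pairs):
        wins[:, i] += votes[:, m] == i
        wins[:, j] += votes[:, m] == j
    univocal = wins == len(ROI_LABELS) - 1
    n_winners = univocal.sum(axis=1)
    assert n_winners.max(initial=0) <= 1, "two univocal winners are impossible"
    return np.where(n_winners == 1, univocal.argmax(axis=1), NC_INDEX)


def fit_ensemble(X: np.ndarray, labels: np.ndarray, C: float = 0.1,
                 class_weight: str | dict | None = "balanced"
                 ) -> EnsembleModel:
    """Fit the 21 one-vs-one linear SVMs on training pixels.

    Features are Z-scored with training-set statistics (zero-variance
    features dropped with record); each binary is a soft-margin linear SVM
    on the corresponding pair's pixels.  The fairly strong default
    regularization (C=0.1) guards against overfitting patient-specific
    abundance offsets when few patients are available per class.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    y = np.array([ROI_INDEX.get(l, -1) for l in labels])
    for roi, idx in ROI_INDEX.items():
        if np.sum(y == idx) < 2:
            raise DataError(f"training data lack class {roi}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise DataError("all features have zero variance")
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xz = (X[:, kept] - mean[kept]) / sd_safe[kept]
    weights = np.empty((len(PAIRS), kept.size))
    intercepts = np.empty(len(PAIRS))
    for m, (i, j) in enumerate(PAIRS):
        sel = (y == i) | (y == j)
        svc = LinearSVC(C=C, class_weight=class_weight, dual=False,
                        max_iter=5000)
        svc.fit(Xz[sel], (y[sel] == j).astype(int))
        weights[m] = svc.coef_[0]
        intercepts[m] = svc.intercept_[0]
    return EnsembleModel(weights=weights, intercepts=intercepts,
                         mean=mean, sd=sd_safe, kept=kept)


@dataclass
class PixelDecision:
    """Votes and final call for one pixel."""

    pixel_id: int
    votes: np.ndarray
    final: str


def classify_pixel(x: np.ndarray, ensemble: EnsembleModel,
                   pixel_id: int = 0) -> PixelDecision:
    """Apply the univocal rule to a single feature vector."""
    votes, finals = ensemble.decide(np.atleast_2d(np.asarray(x, float)))
    final = ROI_LABELS[finals[0]] if finals[0] != NC_INDEX else NOT_CLASSIFIED
    return PixelDecision(pixel_id=pixel_id, votes=votes[0], final=final)


# ---------------------------------------------------------------------------
# core aggregation and evaluation
# ---------------------------------------------------------------------------

def aggregate_core(finals: np.ndarray) -> str:
    """Modal class of a core's pixel decisions over the eight outcomes.

    Ties prefer any ROI over NOT_CLASSIFIED, then canonical ROI order; a
    NOT_CLASSIFIED mode yields NOT_DIAGNOSTIC.
    """
    finals = np.asarray(finals)
    if finals.size == 0:
        raise DataError("core has no pixels to aggregate")
    counts = np.bincount(finals, minlength=NC_INDEX + 1)
    top = counts.max()
    candidates = np.flatnonzero(counts == top)
    roi_candidates = candidates[candidates < NC_INDEX]
    if roi_candidates.size:
        return ROI_LABELS[roi_candidates[0]]
    return NOT_DIAGNOSTIC


def evaluate(decisions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Confusion matrix (7 true x 8 predicted) and one-vs-rest indices.

    ``decisions`` needs columns ``true`` (ROI labels) and ``predicted``
    (ROI labels or NOT_DIAGNOSTIC).
    """
    pred_labels = list(ROI_LABELS) + [NOT_DIAGNOSTIC]
    bad_true = set(decisions["true"]) - set(ROI_LABELS)
    bad_pred = set(decisions["predicted"]) - set(pred_labels)
    if bad_true or bad_pred:
        raise DataError(f"unknown labels: {bad_true | bad_pred}")
    conf = pd.DataFrame(0, index=list(ROI_LABELS), columns=pred_labels)
    for t, p in zip(decisions["true"], decisions["predicted"]):
        conf.at[t, p] += 1
    n = len(decisions)
    correct = sum(conf.at[r, r] for r in ROI_LABELS)
    per_class = {}
    for r in ROI_LABELS:
        tp = conf.at[r, r]
        fn = conf.loc[r].sum() - tp
        fp = conf[r].sum() - tp
        tn = n - tp - fn - fp
        per_class[r] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "accuracy": (tp + tn) / n if n else np.nan,
        }
    metrics = {
        "n": n,
        "overall_correct_fraction": correct / n if n else np.nan,
        "not_diagnostic_fraction":
            conf[NOT_DIAGNOSTIC].sum() / n if n else np.nan,
        "per_class": pd.DataFrame(per_class).T,
    }
    return conf, metrics


# ---------------------------------------------------------------------------
# cross-validated core classification
# ---------------------------------------------------------------------------

def _core_means(X: np.ndarray, metadata: pd.DataFrame, good: np.ndarray
                ) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean abundance vector per core over non-outlier pixels."""
    cores = metadata.loc[:, ["core_id", "patient_id", "roi_label"]]
    cores = cores.drop_duplicates("core_id").reset_index(drop=True)
    core_ids = metadata["core_id"].to_numpy()
    means = np.zeros((len(cores), X.shape[1]))
    keep = np.ones(len(cores), bool)
    for i, core in enumerate(cores["core_id"]):
        sel = (core_ids == core) & good
        if not sel.any():
            warnings.warn(f"core {core} has no usable pixels", stacklevel=2)
            keep[i] = False
            continue
        means[i] = X[sel].mean(axis=0)
    return means[keep], cores[keep].reset_index(drop=True)


def _binary_accuracies(votes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Validation accuracy of each binary on the pixels of its own pair."""
    acc = np.full(len(PAIRS), np.nan)
    for m, (i, j) in enumerate(PAIRS):
        sel = (y == i) | (y == j)
        if sel.any():
            acc[m] = np.mean(votes[sel, m] == y[sel])
    return acc


class CoreClassifier:
    """Cross-validated core classification model.

    Parameters
    ----------
    abundance : AbundanceMatrix
        Pixels x components feature matrix with metadata; outlier pixels
        are excluded from training and prediction.
    feature_set : {"all", "top"}
        Use all components or the top intensity class (requires
        ``intensity_model``).
    C : float
        SVM soft-margin regularization (class weights balanced).
    """

    def __init__(self, abundance: AbundanceMatrix, feature_set: str = "all",
                 intensity_model: IntensityClassModel | None = None,
                 C: float = 0.1):
        self.abundance = abundance
        self.feature_set = feature_set
        self.C = C
        if feature_set == "all":
            self.feature_idx = np.arange(abundance.n_components)
        elif feature_set == "top":
            if intensity_model is None:
                raise ParameterError(
                    "feature_set='top' requires an intensity_model")
            self.feature_idx = intensity_model.top_class_components
        else:
            raise ParameterError("feature_set must be 'all' or 'top'")
        if self.feature_idx.size == 0:
            raise DataError("selected feature set is empty")

    def fit(self, approach: str = "single-pixel", k: int = 5,
            seed: int = 0) -> "CoreClassificationResults":
        """Run patient-stratified k-fold CV with the requested strategy."""
        if approach not in ("single-pixel", "mean-spectrum", "hybrid"):
            raise ParameterError(f"unknown approach: {approach}")
        meta = self.abundance.metadata
        X = self.abundance.values[:, self.feature_idx]
        good = self.abundance.good
        plan = make_folds(meta, k=k, seed=seed)
        plan.assert_no_leakage(meta)
        fold_of_pixel = plan.fold_of_pixels(meta)
        y_pixel = meta["roi_label"].map(ROI_INDEX).to_numpy()

        core_means, core_meta = _core_means(X, meta, good)
        core_fold = core_meta["patient_id"].map(plan.patient_to_fold)
        core_fold = core_fold.to_numpy()
        y_core = core_meta["roi_label"].map(ROI_INDEX).to_numpy()

        pixel_finals = np.full(len(meta), -1, dtype=int)
        core_pred = np.full(len(core_meta), -1, dtype=int)
        fold_binary_acc = []
        for fold in range(k):
            train_px = good & (fold_of_pixel != fold)
            val_px = good & (fold_of_pixel == fold)
            if approach == "mean-spectrum":
                tr = core_fold != fold
                ensemble = fit_ensemble(
                    core_means[tr],
                    core_meta.loc[tr, "roi_label"].to_numpy(), C=self.C)
                va = core_fold == fold
                votes, finals = ensemble.decide(core_means[va])
                core_pred[va] = finals
                fold_binary_acc.append(_binary_accuracies(votes, y_core[va]))
                continue
            ensemble = fit_ensemble(X[train_px],
                                    meta.loc[train_px, "roi_label"].to_numpy(),
                                    C=self.C)
            votes, finals = ensemble.decide(X[val_px])
            pixel_finals[np.flatnonzero(val_px)] = finals
            fold_binary_acc.append(_binary_accuracies(votes, y_pixel[val_px]))
            va = core_fold == fold
            if approach == "hybrid":
                _, cf = ensemble.decide(core_means[va])
                core_pred[va] = cf
            else:  # single-pixel: modal class over the core's pixel calls
                core_idx = np.flatnonzero(va)
                core_ids = meta["core_id"].to_numpy()
                for ci in core_idx:
                    sel = (core_ids == core_meta.at[ci, "core_id"]) & good
                    core_pred[ci] = _label_code(aggregate_core(pixel_finals[sel]))

        predicted = [ROI_LABELS[c] if c < NC_INDEX else NOT_DIAGNOSTIC
                     for c in core_pred]
        table = core_meta.copy()
        table["predicted"] = predicted
        table = table.rename(columns={"roi_label": "true"})
        conf, metrics = evaluate(table)
        metrics["mean_binary_accuracy"] = float(
            np.nanmean(np.vstack(fold_binary_acc)))
        if approach in ("single-pixel", "hybrid"):
            decided = pixel_finals[good & (pixel_finals >= 0)]
            metrics["pixel_not_classified_fraction"] = float(
                np.mean(decided == NC_INDEX))
        pixel_table = None
        if approach in ("single-pixel", "hybrid"):
            pixel_table = pd.DataFrame({
                "pixel_id": meta["pixel_id"],
                "final": [ROI_LABELS[c] if 0 <= c < NC_INDEX else
                          (NOT_CLASSIFIED if c == NC_INDEX else "EXCLUDED")
                          for c in pixel_finals],
            })
        return CoreClassificationResults(
            approach=approach, feature_set=self.feature_set, core_table=table,
            confusion_matrix=conf, metrics=metrics, fold_plan=plan,
            pixel_decisions=pixel_table)


def _label_code(label: str) -> int:
    if label == NOT_DIAGNOSTIC:
        return NC_INDEX
    return ROI_INDEX[label]


@dataclass
class CoreClassificationResults:
    """Cross-validated core decisions, confusion matrix and quality indices."""

    approach: str
    feature_set: str
    core_table: pd.DataFrame
    confusion_matrix: pd.DataFrame
    metrics: dict
    fold_plan: FoldPlan
    pixel_decisions: pd.DataFrame | None = None

    @property
    def overall_correct_fraction(self) -> float:
        return self.metrics["overall_correct_fraction"]

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Core classification ({self.approach}, features={self.feature_set})",
            "=" * 56,
            f"cores evaluated:        {m['n']}",
            f"correct fraction:       {m['overall_correct_fraction']:.3f}",
            f"not diagnostic:         {m['not_diagnostic_fraction']:.3f}",
            f"mean binary accuracy:   {m['mean_binary_accuracy']:.3f}",
        ]
        if "pixel_not_classified_fraction" in m:
            lines.append(
                f"pixels not classified:  {m['pixel_not_classified_fraction']:.3f}")
        lines.append("")
        lines.append("One-vs-rest quality indices:")
        lines.append(m["per_class"].round(3).to_string())
        lines.append("")
        lines.append("Confusion matrix (rows true, columns predicted):")
        lines.append(self.confusion_matrix.to_string())
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        conf = self.confusion_matrix
        ax.imshow(conf.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(conf.columns)), conf.columns, rotation=45)
        ax.set_yticks(range(len(conf.index)), conf.index)
        for i in range(conf.shape[0]):
            for j in range(conf.shape[1]):
                ax.text(j, i, str(conf.iat[i, j]), ha="center", va="center")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        return ax
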