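"""Leakage-safe PCA-LDA classification of purified Raman spectra.

The classifier follows the clinical protocol: spectra restricted to the
550-1800 cm^-1 fingerprint, stratified 5-fold cross-validation (80%
training / 20% test), a principal component analysis fitted on each fold's
training rows only (centring included), and a linear discriminant analysis
on the retained scores.  Reports mirror the study's panels: one multiclass
summary and six binary comparisons with cutaneous neurofibroma as the
positive class throughout (vs all physiological tissue pooled, and vs fat,
bone, nerve, mucosa, skin individually, using only the two groups' rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import PurifiedSpectrum

POSITIVE_CLASS = "neurofibroma"
PHYSIOLOGICAL = ("skin", "nerve", "fat", "bone", "mucosa")
BINARY_COMPARISONS = ("all", "fat", "bone", "nerve", "mucosa", "skin")

#: Published reference confusion counts for the cutaneous-neurofibroma
#: discrimination panels (positive class: neurofibroma).  Used to
#: recompute the reported sensitivity/specificity/accuracy figures.
REFERENCE_CONFUSIONS: dict[str, dict[str, int]] = {
    "all":    {"tp": 9, "fp": 2, "fn": 0, "tn": 71},
    "fat":    {"tp": 9, "fp": 0, "fn": 0, "tn": 13},
    "bone":   {"tp": 9, "fp": 0, "fn": 0, "tn": 15},
    "nerve":  {"tp": 9, "fp": 0, "fn": 0, "tn": 6},
    "mucosa": {"tp": 9, "fp": 2, "fn": 0, "tn": 25},
    "skin":   {"tp": 8, "fp": 0, "fn": 1, "tn": 12},
}


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no positives or no negatives)."""


@dataclass
class LabelledDataset:
    """Purified spectra as a (loci x bins) matrix with row metadata."""

    X: np.ndarray
    shift_cm1: np.ndarray
    labels: np.ndarray
    locus_ids: np.ndarray
    specimen_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per spectrum row required")
        if self.X.shape[1] != np.asarray(self.shift_cm1).shape[0]:
            raise ValueError("column count must match the shift axis")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("dataset must not contain missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(self.X[mask], self.shift_cm1, self.labels[mask],
                               self.locus_ids[mask], self.specimen_ids[mask])


def restrict_range(spectrum: PurifiedSpectrum, low: float, high: float
                   ) -> PurifiedSpectrum:
    """Keep bins with low <= shift <= high (inclusive both ends)."""
    if low >= high:
        raise ValueError("low must be < high")
    keep = (spectrum.shift_cm1 >= low) & (spectrum.shift_cm1 <= high)
    if not keep.any():
        raise ValueError(f"no bins inside [{low}, {high}] cm^-1")
    return PurifiedSpectrum(shift_cm1=spectrum.shift_cm1[keep],
                            values=spectrum.values[keep],
                            locus_id=spectrum.locus_id, label=spectrum.label,
                            purifier_id=spectrum.purifier_id)


def assemble_dataset(spectra: list[PurifiedSpectrum],
                     low: float = 550.0, high: float = 1800.0,
                     specimen_ids: list[str] | None = None) -> LabelledDataset:
    """Stack purified spectra into a dataset, range-restricted and row-normalized.

    Each row is scaled to unit maximum absolute value; Raman intensity is
    in arbitrary units, so only the spectral shape carries class information.
    """
    restricted = [restrict_range(s, low, high) for s in spectra]
    axis = restricted[0].shift_cm1
    rows = []
    for s in restricted:
        if not np.array_equal(s.shift_cm1, axis):
            raise ValueError("all spectra must share one shift axis")
        m = np.max(np.abs(s.values))
        rows.append(s.values / m if m > 0 else s.values)
    return LabelledDataset(
        X=np.vstack(rows), shift_cm1=axis,
        labels=np.array([s.label for s in restricted]),
        locus_ids=np.array([s.locus_id for s in restricted]),
        specimen_ids=np.array(specimen_ids if specimen_ids is not None
                              else [""] * len(restricted)))


@dataclass
class FoldModel:
    """Fold-local PCA basis + LDA, fitted on training rows only."""

    mean: np.ndarray
    components: np.ndarray            # (k, bins), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    lda: LinearDiscriminantAnalysis
    classes: np.ndarray
    fold_index: int = -1


def fit_fold(X_train: np.ndarray, y_train: np.ndarray,
             variance_target: float = 0.95, fold_index: int = -1) -> FoldModel:
    """Fit centring, PCA and multiclass LDA on training rows only.

    Retains the smallest component count explaining >= ``variance_target``
    of the training variance, capped at n_train - n_classes so the LDA
    within-class scatter stays well-conditioned.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes, counts = np.unique(y_train, return_counts=True)
    if classes.size < 2:
        raise ValueError("training rows must contain at least two classes")
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has < 2 training rows "
            "(stratification failure)")
    cap = max(1, X_train.shape[0] - classes.size)
    pca = PCA(n_components=min(X_train.shape[0] - 1, X_train.shape[1]),
              svd_solver="full")
    scores = pca.fit_transform(X_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = min(int(np.searchsorted(cum, variance_target) + 1), cap)
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores[:, :k], y_train)
    return FoldModel(mean=pca.mean_, components=pca.components_[:k],
                     explained_variance_ratio=pca.explained_variance_ratio_[:k],
                     n_components=k, lda=lda, classes=lda.classes_,
                     fold_index=fold_index)


def predict_fold(model: FoldModel, X_test: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class scores for test rows.

    Test rows are centred with the *training* mean and projected on the
    training PCA basis — never re-fitted.  Scores are the posterior
    probability of the positive class when it is among the fold's classes,
    otherwise the first class's posterior.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.mean.shape[0]:
        raise ValueError("test rows do not match the training bin axis")
    scores = (X_test - model.mean) @ model.components.T
    labels = model.lda.predict(scores)
    proba = model.lda.predict_proba(scores)
    if POSITIVE_CLASS in model.classes:
        col = int(np.where(model.classes == POSITIVE_CLASS)[0][0])
    else:
        col = 0
    return labels, proba[:, col]


def binary_metrics(tp: int, fp: int, fn: int, tn: int,
                   positive_class: str = POSITIVE_CLASS) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/error (percent) from confusion counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    if tp + fn == 0:
        raise UndefinedMetricError(
            f"sensitivity undefined: no observations of positive class {positive_class!r}")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative observations")
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    accuracy = 100.0 * (tp + tn) / total
    return {"sensitivity": sensitivity, "specificity": specificity,
            "accuracy": accuracy, "error": 100.0 - accuracy}


def roc_auc(scores, labels, positive_class: str = POSITIVE_CLASS) -> float:
    """Area under the ROC curve (percent) via the Mann-Whitney rank statistic.

    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with mid-ranks for
    ties, i.e. the probability that a random positive scores above a random
    negative (ties counting one half).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


@dataclass
class ClassificationReport:
    """Confusion counts plus the derived panel metrics for one comparison."""

    comparison: str
    positive_class: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    error: float
    auc: float
    assignments: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MulticlassReport:
    """Out-of-fold summary of the six-class LDA."""

    accuracy: float
    confusion: pd.DataFrame
    assignments: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _stratified_out_of_fold(X, y, k, seed, variance_target):
    """Run stratified k-fold CV; returns out-of-fold predictions and scores."""
    n = y.shape[0]
    pred = np.empty(n, dtype=y.dtype)
    score = np.empty(n, dtype=float)
    fold_of = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = fit_fold(X[tr], y[tr], variance_target, fold_index=fold)
        labels, s = predict_fold(model, X[te])
        pred[te], score[te], fold_of[te] = labels, s, fold
    return pred, score, fold_of


def cross_validate(data: LabelledDataset, k: int = 5, seed: int = 0,
                   variance_target: float = 0.95
                   ) -> tuple[MulticlassReport, dict[str, ClassificationReport]]:
    """Stratified k-fold PCA-LDA evaluation with the study's report panels.

    Every row is tested exactly once.  The multiclass report uses all six
    classes jointly; each binary panel refits PCA-LDA on only the rows of
    the two groups involved ("all" pools the five physiological classes
    into one negative group).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(data.labels, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k rows for stratified folding")

    pred, _, fold_of = _stratified_out_of_fold(
        data.X, data.labels, k, seed, variance_target)
    classes = sorted(np.unique(data.labels))
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for truth, p in zip(data.labels, pred):
        confusion.loc[truth, p] += 1
    multiclass = MulticlassReport(
        accuracy=100.0 * float(np.mean(pred == data.labels)),
        confusion=confusion,
        assignments=pd.DataFrame({"locus": data.locus_ids, "truth": data.labels,
                                  "predicted": pred, "fold": fold_of}))

    reports: dict[str, ClassificationReport] = {}
    for comparison in BINARY_COMPARISONS:
        if comparison == "all":
            sub = data
            y = np.where(sub.labels == POSITIVE_CLASS, POSITIVE_CLASS,
                         "physiological")
        else:
            mask = np.isin(data.labels, [POSITIVE_CLASS, comparison])
            sub = data.subset(mask)
            y = sub.labels
        pred_b, score_b, fold_b = _stratified_out_of_fold(
            sub.X, y, k, seed, variance_target)
        is_pos = y == POSITIVE_CLASS
        pred_pos = pred_b == POSITIVE_CLASS
        tp = int(np.sum(is_pos & pred_pos))
        fn = int(np.sum(is_pos & ~pred_pos))
        fp = int(np.sum(~is_pos & pred_pos))
        tn = int(np.sum(~is_pos & ~pred_pos))
        metrics = binary_metrics(tp, fp, fn, tn)
        reports[comparison] = ClassificationReport(
            comparison=f"{POSITIVE_CLASS} vs {comparison}",
            positive_class=POSITIVE_CLASS, tp=tp, fp=fp, fn=fn, tn=tn,
            auc=roc_auc(score_b, y), **metrics,
            assignments=pd.DataFrame({"locus": sub.locus_ids, "truth": y,
                                      "predicted": pred_b, "score": score_b,
                                      "fold": fold_b}))
    return multiclass, reports
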