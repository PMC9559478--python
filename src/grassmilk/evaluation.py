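"""Cross-validation, ROC/AUC, confusion metrics and probability diagnostics.

AUC is computed in its Mann–Whitney concordance form (probability that a
random GRASS record scores above a random NOGRASS record, ties counting
one half), which equals the trapezoidal area under the empirical ROC curve
exactly.  External validation follows the month-restricted protocol: truth
comes from the calendar (December/January = NOGRASS, July/August = GRASS)
regardless of which labelling scheme trained the model, so all three
schemes are validated on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedMetricError
from .plsda import PlsDaModel, fit_pls

__all__ = [
    "CvResult",
    "stratified_folds",
    "roc_auc",
    "confusion_metrics",
    "cross_validate",
    "external_validation_accuracy",
    "monthly_probability_curve",
    "intermodel_probability_correlation",
    "adjusted_rand_index",
    "VALIDATION_MONTHS",
]

#: months used in external validation and the month-derived truth there
VALIDATION_MONTHS = {12, 1, 7, 8}
_VALIDATION_GRASS = {7, 8}


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each record to one of ``k`` folds, stratified on the two classes.

    Within each class the (seeded) shuffled members are dealt round-robin,
    so every fold's class proportion is within one record of the global one.
    """
    y = np.asarray(labels).ravel()
    if k < 2:
        raise InputError("k must be >= 2")
    classes = np.unique(y)
    if len(classes) != 2:
        raise InputError(f"need exactly 2 classes, got {len(classes)}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise InputError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by rank-based concordance (ties count ½)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if len(s) != len(y):
        raise InputError("scores and labels length mismatch")
    pos = y == np.max(y)
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0 or len(np.unique(y)) != 2:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks give ties half credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(predicted, actual) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with GRASS/1 as positive class."""
    p = np.asarray(predicted).ravel()
    a = np.asarray(actual).ravel()
    if len(p) != len(a):
        raise InputError("predicted and actual length mismatch")
    if len(p) == 0:
        raise InputError("empty input")
    p, a = p.astype(bool), a.astype(bool)
    tp = int(np.sum(p & a))
    tn = int(np.sum(~p & ~a))
    fp = int(np.sum(p & ~a))
    fn = int(np.sum(~p & a))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / len(p)
    return sens, spec, acc


@dataclass
class CvResult:
    """Per-fold cross-validated metrics at a fixed component count."""

    n_components: int
    fold_auc: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray

    @property
    def k(self) -> int:
        return len(self.fold_auc)

    def summary(self) -> dict[str, float]:
        return {
            "n_components": self.n_components,
            "auc_mean": float(self.fold_auc.mean()),
            "auc_sd": float(self.fold_auc.std(ddof=1)),
            "sensitivity_mean": float(np.nanmean(self.fold_sensitivity)),
            "sensitivity_sd": float(np.nanstd(self.fold_sensitivity, ddof=1)),
            "specificity_mean": float(np.nanmean(self.fold_specificity)),
            "specificity_sd": float(np.nanstd(self.fold_specificity, ddof=1)),
        }


def cross_validate(
    X, y, n_components: int, k: int = 10, seed: int = 0
) -> CvResult:
    """Stratified k-fold CV of a PLS-DA fit at a fixed component count."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = stratified_folds(y, k=k, seed=seed)
    auc = np.empty(k)
    sens = np.empty(k)
    spec = np.empty(k)
    for fold in range(k):
        test = folds == fold
        model = fit_pls(X[~test], y[~test], n_components)
        prob = model.predict_grass_probability(X[test])
        auc[fold] = roc_auc(prob, y[test])
        sens[fold], spec[fold], _ = confusion_metrics(prob >= 0.5, y[test] == 1)
    return CvResult(n_components, auc, sens, spec)


def external_validation_accuracy(
    model: PlsDaModel, validation: pd.DataFrame
) -> tuple[float, int]:
    """Month-restricted validation accuracy and the record count used.

    Only December/January (truth NOGRASS) and July/August (truth GRASS)
    records enter; everything else is excluded, whatever the labelling
    scheme the model was trained under.
    """
    if "month" not in validation.columns:
        raise InputError("validation records need a 'month' column")
    sub = validation[validation["month"].isin(VALIDATION_MONTHS)]
    if len(sub) == 0:
        raise InputError("no December/January/July/August records to validate on")
    truth = sub["month"].isin(_VALIDATION_GRASS).to_numpy()
    predicted = model.predict_grass_probability(sub) >= 0.5
    _, _, acc = confusion_metrics(predicted, truth)
    return acc, len(sub)


def monthly_probability_curve(predictions: pd.DataFrame) -> pd.DataFrame:
    """Mean GRASS probability per (year, month), with record counts.

    ``predictions`` must carry ``year, month, probability`` (all validation
    records, including OTHERS months — the curve is what reveals the
    feeding transition the models were never trained on).
    """
    required = {"year", "month", "probability"}
    missing = required - set(predictions.columns)
    if missing:
        raise InputError(f"predictions missing columns {sorted(missing)}")
    grouped = (
        predictions.groupby(["year", "month"], as_index=False)
        .agg(mean_probability=("probability", "mean"), n=("probability", "size"),
             sd_probability=("probability", "std"))
        .sort_values(["year", "month"], ignore_index=True)
    )
    return grouped


def intermodel_probability_correlation(*probabilities) -> np.ndarray:
    """Pearson correlation matrix between aligned probability vectors."""
    arrays = [np.asarray(p, dtype=float).ravel() for p in probabilities]
    if len(arrays) < 2:
        raise InputError("need at least two probability vectors")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise InputError("probability vectors must be aligned (same length)")
    return np.corrcoef(np.vstack(arrays))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if len(a) != len(b):
        raise InputError("partitions must label the same items")
    n = len(a)
    if n == 0:
        raise InputError("empty partitions")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
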