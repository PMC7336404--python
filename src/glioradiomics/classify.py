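"""Random-forest stratification under repeated stratified cross-validation.

Two tasks: IDH mutation status (binary; positive class = mutant) and WHO
grade (3-class, nominal for the classifier but ordinal for the error
metric, grades encoded 2/3/4).  Each task trains a random forest on the
extracted features plus one-hot encoded acquisition-parameter bins, in a
stratified 2-fold cross-validation repeated ``n_repeats`` times, so every
subject is predicted exactly once per repeat.

Aggregation follows the consensus rule: a subject's final label is the class
with the highest mean vote proportion across all repeats (ties resolved to
the lower ordinal class).  From the consensus confusion matrix the overall
accuracy, sensitivity/specificity (binary task) and the fraction of
subjects predicted within one grade (grade task) are derived.  Per-subject
mean signed error and mean absolute error across repeats are compared
between acquisition-parameter bins with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .stats import acquisition_design, dichotomize_covariates

__all__ = [
    "RFSettings",
    "CVResult",
    "ConfusionSummary",
    "repeated_stratified_cv",
    "consensus_confusion",
    "error_by_parameter",
]


@dataclass
class RFSettings:
    """Random-forest and cross-validation settings for one task."""

    task: str
    n_trees: int
    max_depth: int
    min_samples_leaf: int = 4
    n_repeats: int = 250
    n_folds: int = 2
    master_seed: int = 0

    @classmethod
    def for_task(cls, task: str, n_repeats: int = 250, master_seed: int = 0) -> "RFSettings":
        """Default hyperparameters: IDH task 200 trees / depth 10; grade
        task 800 trees / depth 50; min samples per leaf 4 for both."""
        if task == "idh":
            return cls("idh", 200, 10, 4, n_repeats, 2, master_seed)
        if task == "grade":
            return cls("grade", 800, 50, 4, n_repeats, 2, master_seed)
        raise ValueError(f"task must be 'idh' or 'grade', got {task!r}")


@dataclass
class CVResult:
    """Per-repeat, per-subject predictions from repeated stratified CV."""

    task: str
    subject_ids: list[str]
    classes: np.ndarray  # sorted class codes (idh: 0=wildtype,1=mutant; grade: 2,3,4)
    y_true: np.ndarray  # (n_subjects,)
    predictions: np.ndarray  # (n_repeats, n_subjects) class codes
    proba: np.ndarray  # (n_repeats, n_subjects, n_classes) vote proportions

    @property
    def n_repeats(self) -> int:
        return self.predictions.shape[0]

    def errors(self) -> np.ndarray:
        """Signed numeric error (predicted - true) per repeat and subject."""
        return self.predictions - self.y_true[None, :]


@dataclass
class ConfusionSummary:
    """Consensus confusion matrix and derived rates."""

    classes: np.ndarray
    matrix: np.ndarray  # rows = truth, columns = prediction
    consensus: np.ndarray  # per-subject consensus class codes
    accuracy: float
    sensitivity: float | None = None
    specificity: float | None = None
    within_distance_1: float | None = None


IDH_CODES = {"wildtype": 0, "mutant": 1}


def encode_labels(labels: pd.Series, task: str) -> np.ndarray:
    if task == "idh":
        return labels.astype(str).map(IDH_CODES).to_numpy(dtype=np.int64)
    return labels.to_numpy(dtype=np.int64)


def _repeat_seeds(master_seed: int, repeat: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed, spawn_key=(repeat,))
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def build_inputs(features: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Classifier input matrix: the 29 features plus one-hot acquisition bins."""
    from .core import FEATURE_NAMES

    feat_cols = [c for c in features.columns if c in FEATURE_NAMES]
    X = features[feat_cols].reset_index(drop=True).copy()
    acq = acquisition_design(manifest).reset_index(drop=True)
    return pd.concat([X, acq], axis=1)


def repeated_stratified_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    settings: RFSettings,
    subject_ids: list[str] | None = None,
) -> CVResult:
    """Run the repeated stratified-CV random forest for one task.

    Per repeat: a fresh stratified ``n_folds``-fold split (shuffled with a
    repeat-specific seed derived from ``master_seed``); each fold is
    predicted by a forest trained on the remaining folds, so every subject
    receives exactly one prediction (and one vote-proportion vector) per
    repeat.
    """
    Xv = X.to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite values in the feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < settings.n_folds:
        lab = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {lab} has {counts.min()} members; needs >= {settings.n_folds} "
            f"for stratified {settings.n_folds}-fold CV"
        )
    n = y.size
    ids = list(subject_ids) if subject_ids is not None else [f"sub-{i:04d}" for i in range(n)]
    preds = np.empty((settings.n_repeats, n), dtype=np.int64)
    proba = np.empty((settings.n_repeats, n, classes.size), dtype=np.float64)

    for r in range(settings.n_repeats):
        seeds = _repeat_seeds(settings.master_seed, r, settings.n_folds + 1)
        skf = StratifiedKFold(
            n_splits=settings.n_folds, shuffle=True, random_state=seeds[0]
        )
        for f, (train, test) in enumerate(skf.split(Xv, y)):
            rf = RandomForestClassifier(
                n_estimators=settings.n_trees,
                max_depth=settings.max_depth,
                min_samples_leaf=settings.min_samples_leaf,
                random_state=seeds[f + 1],
                n_jobs=1,
            )
            rf.fit(Xv[train], y[train])
            p = rf.predict_proba(Xv[test])
            # align fold-local class order with the global one
            full = np.zeros((test.size, classes.size))
            for k, c in enumerate(rf.classes_):
                full[:, np.searchsorted(classes, c)] = p[:, k]
            proba[r, test] = full
            preds[r, test] = classes[np.argmax(full, axis=1)]

    return CVResult(settings.task, ids, classes, y, preds, proba)


def consensus_confusion(result: CVResult) -> ConfusionSummary:
    """Aggregate a CV run into its consensus confusion matrix and rates.

    Consensus label = argmax of the mean vote proportions across repeats;
    exact ties go to the lower ordinal class (argmax picks the first
    maximum over the ascending class order).
    """
    mean_votes = result.proba.mean(axis=0)  # (n_subjects, n_classes)
    consensus = result.classes[np.argmax(mean_votes, axis=1)]
    k = result.classes.size
    matrix = np.zeros((k, k), dtype=np.int64)
    code_to_idx = {c: i for i, c in enumerate(result.classes)}
    for t, p in zip(result.y_true, consensus):
        matrix[code_to_idx[t], code_to_idx[p]] += 1
    total = matrix.sum()
    accuracy = float(np.trace(matrix) / total)
    sens = spec = within1 = None
    if result.task == "idh":
        # rows/cols ordered (wildtype=0, mutant=1); positive class = mutant
        tn, fp, fn, tp = matrix[0, 0], matrix[0, 1], matrix[1, 0], matrix[1, 1]
        sens = float(tp / (tp + fn)) if (tp + fn) else float("nan")
        spec = float(tn / (tn + fp)) if (tn + fp) else float("nan")
    if result.task == "grade":
        within1 = float(np.mean(np.abs(consensus - result.y_true) <= 1))
    return ConfusionSummary(result.classes, matrix, consensus, accuracy, sens, spec, within1)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or b.size < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def error_by_parameter(result: CVResult, manifest: pd.DataFrame) -> pd.DataFrame:
    """Compare per-subject mean error across acquisition-parameter bins.

    For every dichotomized acquisition parameter and every pair of its bins,
    the per-subject mean signed error and mean absolute error (averaged over
    repeats) are compared with Welch's two-sample t-test.  Bins with fewer
    than two subjects are skipped with a warning.
    """
    errors = result.errors()
    mean_err = errors.mean(axis=0)
    mean_abs = np.abs(errors).mean(axis=0)
    bins = dichotomize_covariates(manifest).reset_index(drop=True)
    rows = []
    for param in bins.columns:
        levels = sorted(bins[param].unique())
        if len(levels) < 2:
            continue
        for la, lb in combinations(levels, 2):
            ia = (bins[param] == la).to_numpy()
            ib = (bins[param] == lb).to_numpy()
            if ia.sum() < 2 or ib.sum() < 2:
                warnings.warn(
                    f"{param}: bin with < 2 subjects, comparison skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "parameter": param,
                    "bin_a": la,
                    "bin_b": lb,
                    "n_a": int(ia.sum()),
                    "n_b": int(ib.sum()),
                    "mean_error_a": float(mean_err[ia].mean()),
                    "mean_error_b": float(mean_err[ib].mean()),
                    "p_error": _welch_p(mean_err[ia], mean_err[ib]),
                    "mean_abs_error_a": float(mean_abs[ia].mean()),
                    "mean_abs_error_b": float(mean_abs[ib].mean()),
                    "p_abs_error": _welch_p(mean_abs[ia], mean_abs[ib]),
                }
            )
    return pd.DataFrame(rows)
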