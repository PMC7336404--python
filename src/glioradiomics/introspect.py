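"""Misclassification introspection.

For every error category (truth = a, consensus prediction = b, a != b) the
covariate-corrected features of the misclassified subjects are contrasted
against their correctly classified counterpart (by default the subjects of
true class a that were predicted a; alternatively the correctly classified
subjects of the predicted class b).  Features are first standardized to
cohort z-scores so mean differences are comparable across features; group
differences are tested with the two-sided Mann-Whitney test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES
from .stats import mann_whitney

__all__ = ["misclassification_contrast"]


def _zscore_columns(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = table.copy()
    for c in cols:
        v = out[c].to_numpy(dtype=np.float64)
        sd = v.std(ddof=1)
        if sd == 0:
            out[c] = 0.0
        else:
            out[c] = (v - v.mean()) / sd
    return out


def misclassification_contrast(
    corrected: pd.DataFrame,
    predictions: pd.Series | np.ndarray,
    truth: pd.Series | np.ndarray,
    reference: str = "same_truth",
    min_group: int = 2,
) -> pd.DataFrame:
    """Contrast features between each error category and its correct group.

    ``reference="same_truth"`` compares (truth=a, predicted=b) against
    (truth=a, predicted=a); ``reference="predicted_class"`` compares against
    (truth=b, predicted=b).  Categories where either group has fewer than
    ``min_group`` subjects are skipped with a warning.  With no
    misclassifications at all the result is an empty table.

    Returns one row per (category, feature): mean z-score difference
    (error group minus correct group) and the Mann-Whitney p-value.
    """
    if reference not in ("same_truth", "predicted_class"):
        raise ValueError(f"unknown reference {reference!r}")
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.shape[0] != len(corrected) or predictions.shape[0] != len(corrected):
        raise ValueError("truth/prediction length must match the feature table")

    feature_cols = [c for c in corrected.columns if c in FEATURE_NAMES]
    z = _zscore_columns(corrected, feature_cols)

    rows = []
    categories = sorted(
        {(a, b) for a, b in zip(truth, predictions) if a != b},
        key=lambda ab: (str(ab[0]), str(ab[1])),
    )
    for a, b in categories:
        err_idx = (truth == a) & (predictions == b)
        if reference == "same_truth":
            ok_idx = (truth == a) & (predictions == a)
        else:
            ok_idx = (truth == b) & (predictions == b)
        if err_idx.sum() < min_group or ok_idx.sum() < min_group:
            warnings.warn(
                f"error category {a}->{b}: fewer than {min_group} subjects in "
                "error or reference group, skipped",
                stacklevel=2,
            )
            continue
        for feat in feature_cols:
            ve = z.loc[err_idx, feat].to_numpy(dtype=np.float64)
            vo = z.loc[ok_idx, feat].to_numpy(dtype=np.float64)
            rows.append(
                {
                    "error_category": f"{a}->{b}",
                    "true_class": str(a),
                    "predicted_class": str(b),
                    "feature": feat,
                    "n_error": int(err_idx.sum()),
                    "n_correct": int(ok_idx.sum()),
                    "mean_zscore_diff": float(ve.mean() - vo.mean()),
                    "p_value": mann_whitney(ve, vo),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "error_category",
            "true_class",
            "predicted_class",
            "feature",
            "n_error",
            "n_correct",
            "mean_zscore_diff",
            "p_value",
        ],
    )
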