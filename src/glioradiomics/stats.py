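"""Covariate correction and nonparametric group comparison.

Feature tables are corrected for acquisition covariates (scanner
manufacturer, field strength, TR, TE, flip angle, slice thickness, matrix
size, in-plane resolution — each dichotomized to its analysis bins), age and
sex by least-squares residualization.  Corrected features are then compared
between groups (IDH status; pairs of WHO grades) with the two-sample
Wilcoxon / Mann-Whitney test and Cliff's delta effect size.  P-values are
reported unadjusted with significance declared at p <= 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FEATURE_NAMES, SHAPE_FEATURES, AcquisitionCovariates

__all__ = [
    "dichotomize_covariates",
    "acquisition_design",
    "residualize",
    "mann_whitney",
    "cliffs_delta",
    "group_compare",
    "GRADE_PAIRS",
]

#: Grade pairs in the fixed comparison order (lower grade first).
GRADE_PAIRS: tuple[tuple[int, int], ...] = ((2, 3), (2, 4), (3, 4))

#: Manifest columns holding raw acquisition covariates.
_ACQ_COLUMNS = (
    "manufacturer",
    "field_T",
    "TR_ms",
    "TE_ms",
    "FA_deg",
    "slice_mm",
    "matrix",
    "inplane_mm",
)


def dichotomize_covariates(manifest: pd.DataFrame) -> pd.DataFrame:
    """Map raw acquisition covariates to their categorical analysis bins.

    Expects manifest columns ``manufacturer, field_T, TR_ms, TE_ms, FA_deg,
    slice_mm, matrix, inplane_mm``; returns one categorical column per
    parameter.
    """
    missing = [c for c in _ACQ_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks acquisition columns: {missing}")
    out = {}
    for _, row in manifest.iterrows():
        cov = AcquisitionCovariates(
            manufacturer=row["manufacturer"],
            field_strength_T=float(row["field_T"]),
            TR_ms=float(row["TR_ms"]),
            TE_ms=float(row["TE_ms"]),
            FA_deg=float(row["FA_deg"]),
            slice_thickness_mm=float(row["slice_mm"]),
            matrix_size=int(row["matrix"]),
            inplane_resolution_mm=float(row["inplane_mm"]),
        )
        for k, v in cov.dichotomize().items():
            out.setdefault(k, []).append(v)
    return pd.DataFrame(out, index=manifest.index)


def acquisition_design(manifest: pd.DataFrame) -> pd.DataFrame:
    """One-hot indicator matrix of the dichotomized acquisition bins
    (first level of each parameter dropped as reference)."""
    bins = dichotomize_covariates(manifest)
    return pd.get_dummies(bins, drop_first=True, dtype=float)


def _design_matrix(manifest: pd.DataFrame) -> pd.DataFrame:
    design = acquisition_design(manifest)
    design["age"] = manifest["age"].astype(float).to_numpy()
    design["sex_M"] = (manifest["sex"].astype(str) == "M").astype(float).to_numpy()
    design.insert(0, "intercept", 1.0)
    return design


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns (QR with column pivoting), keeping
    the intercept and earlier columns preferentially."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, names
    keep: list[int] = []
    for k in range(X.shape[1]):
        cand = keep + [k]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            keep.append(k)
    dropped = [names[k] for k in range(X.shape[1]) if k not in keep]
    warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[k] for k in keep]


def residualize(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    correct_shape: bool = True,
) -> pd.DataFrame:
    """Residualize features on acquisition bins, age and sex.

    Returns a table with the same feature columns holding least-squares
    residuals (mean 0 over the fitting cohort).  With
    ``correct_shape=False`` the four shape features are passed through
    uncorrected (centred only), for the reading that only intensity-based
    features were adjusted.
    """
    feature_cols = [c for c in features.columns if c in FEATURE_NAMES]
    if not feature_cols:
        raise ValueError("no canonical feature columns found")
    design = _design_matrix(manifest)
    X = design.to_numpy(dtype=np.float64)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more subjects ({X.shape[0]}) than model parameters ({X.shape[1]})"
        )
    X, _ = _drop_aliased(X, list(design.columns))
    Y = features[feature_cols].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite feature values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = features.copy()
    out[feature_cols] = resid
    if not correct_shape:
        shape_cols = [c for c in SHAPE_FEATURES if c in features.columns]
        raw = features[shape_cols].to_numpy(dtype=np.float64)
        out[shape_cols] = raw - raw.mean(axis=0)
    return out


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney (rank-sum) p-value.

    Exact null distribution when ``n_a + n_b <= 12`` with no ties; normal
    approximation with tie correction and continuity correction otherwise.
    Two samples that are completely identical in value return p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def cliffs_delta(a, b) -> float:
    """Cliff's delta: ``(#{a_i > b_j} - #{a_i < b_j}) / (n_a n_b)``.

    Positive values mean the first sample is stochastically larger.
    Computed in O((n_a + n_b) log n_b) via sorted rank counting.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    bs = np.sort(b)
    n_less = np.searchsorted(bs, a, side="left")  # b values < a_i
    n_leq = np.searchsorted(bs, a, side="right")
    greater = n_less.sum()  # pairs with a_i > b_j
    less = (b.size - n_leq).sum()  # pairs with a_i < b_j
    return float((greater - less) / (a.size * b.size))


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def group_compare(
    corrected: pd.DataFrame,
    grouping: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature group comparisons of a corrected feature table.

    ``grouping`` is ``"idh"`` (wildtype vs mutant, in that order: a positive
    delta means the wildtype values are larger) or ``"grade"`` (all three
    ordered pairs, lower grade first).  Requires >= 2 subjects per group.

    Returns one row per (comparison, feature) with group medians/IQRs, the
    two-sided Mann-Whitney p and Cliff's delta.
    """
    feature_cols = [c for c in corrected.columns if c in FEATURE_NAMES]
    if grouping == "idh":
        pairs = [("wildtype", "mutant")]
        labels = corrected["idh"].astype(str)
    elif grouping == "grade":
        pairs = list(GRADE_PAIRS)
        labels = corrected["grade"].astype(int)
    else:
        raise ValueError(f"grouping must be 'idh' or 'grade', got {grouping!r}")

    rows = []
    for ga, gb in pairs:
        ia = labels == ga
        ib = labels == gb
        if ia.sum() < 2 or ib.sum() < 2:
            raise ValueError(f"group {ga if ia.sum() < 2 else gb} has < 2 subjects")
        for feat in feature_cols:
            va = corrected.loc[ia, feat].to_numpy(dtype=np.float64)
            vb = corrected.loc[ib, feat].to_numpy(dtype=np.float64)
            p = mann_whitney(va, vb)
            rows.append(
                {
                    "comparison": f"{ga}_vs_{gb}",
                    "feature": feat,
                    "group_a": str(ga),
                    "group_b": str(gb),
                    "n_a": int(ia.sum()),
                    "n_b": int(ib.sum()),
                    "median_a": float(np.median(va)),
                    "iqr_a": _iqr(va),
                    "median_b": float(np.median(vb)),
                    "iqr_b": _iqr(vb),
                    "p_value": p,
                    "cliffs_delta": cliffs_delta(va, vb),
                    "significant": bool(p <= alpha),
                }
            )
    return pd.DataFrame(rows)
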