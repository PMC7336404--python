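"""Radiomic feature extraction over a masked, z-scored tumour volume.

Twenty-nine features in three families:

* **Shape (4)** — volume, surface area, surface-to-volume ratio (SAV) and
  non-compactness, all from the binary tumour mask on an isotropic grid.
  Surface area counts exposed voxel faces (6-connectivity); non-compactness
  is the sphere-normalized ratio ``surface^3 / (36 pi volume^2)``, equal to
  1 for a perfect sphere and growing with boundary irregularity.
* **Histogram (13)** — mean, skewness, excess kurtosis, standard deviation,
  min, max and the 1/5/25/50/75/95/99th percentiles of the masked z-values.
* **Texture (12)** — rotation-invariant Haralick statistics from 3D grey
  level co-occurrence matrices (GLCMs).  Masked z-values are quantized to
  ``n_bins`` equal-width levels, co-occurrences are accumulated symmetrically
  at distance 1 voxel along each of the 13 unique 3D directions (both
  endpoints inside the mask), and each statistic is averaged over the
  non-empty directions.

Conventions: logarithms are base 2 with ``0 log 0 := 0``; correlation with a
zero marginal variance is 0; IMC1 uses ``(HXY - HXY1)/max(HX, HY)`` with
``0/0 := 0``; kurtosis is Fisher (excess); skewness/kurtosis of a
zero-variance sample are 0; percentiles interpolate linearly between order
statistics; "sum square" is the GLCM sum-of-squares variance computed
against the row-marginal mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import TEXTURE_FEATURES, FeatureVector, ImageVolume, LabelMask

__all__ = [
    "DIRECTIONS_3D",
    "CooccurrenceMatrix",
    "shape_features",
    "histogram_features",
    "quantize",
    "glcm_3d",
    "haralick_from_matrix",
    "haralick_features",
    "extract_features",
    "extract_all",
]

#: The 13 unique direction offsets at distance 1 voxel (26-neighbourhood
#: modulo point symmetry): first non-zero component positive.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class CooccurrenceMatrix:
    """Symmetric GLCM for one direction offset."""

    probabilities: np.ndarray
    direction: tuple[int, int, int]
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def _require_isotropic(mask: LabelMask) -> float:
    s = mask.spacing_mm
    if not np.allclose(s, s[0], rtol=1e-6):
        raise ValueError(f"isotropic spacing required, got {s}")
    return float(s[0])


def shape_features(mask: LabelMask) -> dict[str, float]:
    """Volume, surface area, SAV and non-compactness of a binary mask.

    Surface counts voxel faces exposed to the outside (grid boundary counts
    as outside); exact on axis-aligned boxes.
    """
    s = _require_isotropic(mask)
    m = mask.values
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValueError("empty mask")
    padded = np.pad(m, 1, constant_values=False)
    faces = 0
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(padded, shift, axis=axis)
            faces += int(np.sum(padded & ~neighbour))
    volume = n_vox * s**3
    surface = faces * s**2
    return {
        "volume_mm3": volume,
        "surface_mm2": surface,
        "sav": surface / volume,
        "non_compactness": surface**3 / (36.0 * np.pi * volume**2),
    }


def histogram_features(z_values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the masked z-values.

    Kurtosis is excess (Fisher); skewness/kurtosis of a zero-variance input
    are 0 by convention; percentiles use linear interpolation.
    """
    v = np.asarray(z_values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty value set")
    std = float(v.std(ddof=0))
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=True, bias=True))
    pct = np.percentile(v, [1, 5, 25, 50, 75, 95, 99], method="linear")
    out = {
        "mean": float(v.mean()),
        "skewness": skew,
        "kurtosis": kurt,
        "std": std,
        "min": float(v.min()),
        "max": float(v.max()),
    }
    out.update({f"p{p}": float(x) for p, x in zip((1, 5, 25, 50, 75, 95, 99), pct)})
    return out


def quantize(z_values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Equal-width quantization of values to ``{0, ..., n_bins - 1}``.

    Bins span ``[min, max]`` of the input; the maximum maps to the top bin.
    A constant input maps entirely to bin 0 (degenerate path).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(z_values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros(v.shape, dtype=np.int64)
    q = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(q, 0, n_bins - 1)


def glcm_3d(
    quantized: np.ndarray, mask: LabelMask, n_bins: int | None = None
) -> list[CooccurrenceMatrix]:
    """Symmetric GLCMs at distance 1 voxel for the 13 unique 3D directions.

    Only pairs with both endpoints inside the mask are counted; each pair
    contributes to (i, j) and (j, i).  Directions with no valid pair are
    flagged empty (zero matrix) and excluded from feature averaging.
    """
    _require_isotropic(mask)
    q = np.asarray(quantized)
    m = mask.values
    if q.shape != m.shape:
        raise ValueError("quantized lattice and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    ng = int(n_bins) if n_bins is not None else int(q[m].max()) + 1
    shape = q.shape
    out = []
    for offset in DIRECTIONS_3D:
        src = tuple(
            slice(max(0, -o), n + min(0, -o)) for o, n in zip(offset, shape)
        )
        dst = tuple(slice(max(0, o), n + min(0, o)) for o, n in zip(offset, shape))
        valid = m[src] & m[dst]
        i = q[src][valid]
        j = q[dst][valid]
        counts = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(counts, (i, j), 1.0)
        counts = counts + counts.T
        n_pairs = int(counts.sum())
        probs = counts / n_pairs if n_pairs else counts
        out.append(CooccurrenceMatrix(probs, offset, n_pairs))
    return out


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The 12 Haralick statistics of one GLCM probability matrix."""
    ng = P.shape[0]
    idx = np.arange(ng, dtype=np.float64)
    ii = idx[:, None]
    jj = idx[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    var_y = float(((idx - mu_y) ** 2 * py).sum())

    # distributions of i+j (0..2ng-2) and |i-j| (0..ng-1)
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    sums = (ii + jj).astype(np.int64)
    diffs = np.abs(ii - jj).astype(np.int64)
    np.add.at(p_sum, sums.ravel(), P.ravel())
    np.add.at(p_diff, diffs.ravel(), P.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=np.float64)
    k_diff = idx

    asm = float((P**2).sum())
    contrast = float((((ii - jj) ** 2) * P).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    sum_square = float((((ii - mu_x) ** 2) * P).sum())
    sum_average = float((k_sum * p_sum).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    mu_diff = float((k_diff * p_diff).sum())
    difference_variance = float((((k_diff - mu_diff) ** 2) * p_diff).sum())
    sum_variance = float((((k_sum - sum_average) ** 2) * p_sum).sum())
    difference_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    # HXY1 = -sum p(i,j) log2(px(i) py(j)); terms with p(i,j)=0 vanish
    outer = px[:, None] * py[None, :]
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_square": sum_square,
        "sum_average": sum_average,
        "idm": idm,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "sum_variance": sum_variance,
        "difference_entropy": difference_entropy,
        "imc1": float(imc1),
    }


def haralick_features(matrices: list[CooccurrenceMatrix]) -> dict[str, float]:
    """Rotation-invariant Haralick features: per-direction statistics
    arithmetically averaged over the non-empty directions."""
    valid = [m for m in matrices if not m.empty]
    if not valid:
        raise ValueError("all co-occurrence directions are empty")
    per_dir = [haralick_from_matrix(m.probabilities) for m in valid]
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in TEXTURE_FEATURES
    }


def extract_features(
    z_map: ImageVolume, tumour_mask: LabelMask, n_bins: int = 32
) -> FeatureVector:
    """Extract all 29 features from a z-scored map over a tumour mask."""
    if not z_map.same_grid(tumour_mask):
        raise ValueError("z-map and tumour mask must share a grid")
    values: dict[str, float] = {}
    values.update(shape_features(tumour_mask))
    masked = z_map.values[tumour_mask.values]
    values.update(histogram_features(masked))
    q = np.zeros(z_map.shape, dtype=np.int64)
    q[tumour_mask.values] = quantize(masked, n_bins)
    matrices = glcm_3d(q, tumour_mask, n_bins=n_bins)
    values.update(haralick_features(matrices))
    return FeatureVector(values)


def extract_all(case, z_map: ImageVolume, tumour_mask: LabelMask | None = None,
                n_bins: int = 32) -> FeatureVector:
    """Extract the feature vector for one subject, with id context on error."""
    mask = tumour_mask if tumour_mask is not None else case.tumour_mask
    try:
        return extract_features(z_map, mask, n_bins=n_bins)
    except ValueError as err:
        raise ValueError(f"{case.subject_id}: {err}") from err
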