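"""Spatial and intensity normalisation.

Volumes are resampled to an isotropic grid (texture features assume equal
spacing in all directions), the basal-ganglia reference region is restricted
to the tumour-free hemisphere and cleared of any tumour voxels, and tumour
rCBV intensities are converted to z-scores with respect to the intensity
distribution over that clean reference region.  The z-scoring makes
intensity features comparable across subjects and scanners: it is invariant
under any affine rescaling of the raw map.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelMask, hemisphere_mask

__all__ = [
    "resample_isotropic",
    "resample_mask_isotropic",
    "sanitize_reference",
    "zscore_normalise",
    "normalise_case",
]


def _output_grid(shape, spacing, target):
    out_shape = tuple(int(np.ceil(n * s / target)) for n, s in zip(shape, spacing))
    return out_shape


def _resample_array(values, spacing, target, order):
    """Cell-centred resampling onto a grid anchored at the input origin."""
    out_shape = _output_grid(values.shape, spacing, target)
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * target / s - 0.5
            for n, s in zip(out_shape, spacing)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        values, coords, order=order, mode="nearest", prefilter=False
    )


def resample_isotropic(
    volume: ImageVolume, target_mm: float = 1.0, mode: str = "trilinear"
) -> ImageVolume:
    """Resample a volume to isotropic ``target_mm`` spacing.

    The output grid is anchored at the input origin with extent
    ``ceil(input_extent / target)`` per axis; interpolation is cell-centred.
    ``mode`` is ``"trilinear"`` for scalar volumes or ``"nearest"`` (required
    for label data).  An input already at the target spacing is returned
    unchanged (copy).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"mode must be 'trilinear' or 'nearest', got {mode!r}")
    if np.allclose(volume.spacing_mm, target_mm):
        return ImageVolume(volume.values.copy(), (target_mm,) * 3)
    order = 1 if mode == "trilinear" else 0
    out = _resample_array(volume.values, volume.spacing_mm, target_mm, order)
    return ImageVolume(out, (target_mm,) * 3)


def resample_mask_isotropic(mask: LabelMask, target_mm: float = 1.0) -> LabelMask:
    """Nearest-neighbour resampling of a binary mask, re-binarized (>0.5)."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.allclose(mask.spacing_mm, target_mm):
        return LabelMask(mask.values.copy(), (target_mm,) * 3)
    out = _resample_array(mask.values.astype(np.float64), mask.spacing_mm, target_mm, 0)
    return LabelMask(out > 0.5, (target_mm,) * 3)


def sanitize_reference(
    reference_mask: LabelMask, tumour_mask: LabelMask, tumour_hemisphere: str
) -> LabelMask:
    """Restrict the reference region to the tumour-free hemisphere and
    remove any tumour voxels from it.

    Raises ``ValueError`` if no reference voxel survives (no valid
    normalisation region for this subject).
    """
    if not reference_mask.same_grid(tumour_mask):
        raise ValueError("reference and tumour masks must share a grid")
    free_side = "right" if tumour_hemisphere == "left" else "left"
    clean = (
        reference_mask.values
        & hemisphere_mask(reference_mask.shape, free_side)
        & ~tumour_mask.values
    )
    if not clean.any():
        raise ValueError(
            "empty reference region after removing tumour voxels: "
            "no valid normalisation area"
        )
    return LabelMask(clean, reference_mask.spacing_mm)


def zscore_normalise(
    rcbv: ImageVolume, tumour_mask: LabelMask, clean_reference: LabelMask
) -> ImageVolume:
    """z-score the rCBV map against the clean reference region.

    ``z = (rcbv - mean_ref) / sd_ref`` with the sample standard deviation
    (n-1 denominator) of the reference voxels.  The returned map is computed
    on the whole grid but is only meaningful over the tumour mask; all
    downstream feature extraction reads it through the mask.
    """
    for m in (tumour_mask, clean_reference):
        if not rcbv.same_grid(m):
            raise ValueError("masks must share the rCBV grid")
    ref_vals = rcbv.values[clean_reference.values]
    if ref_vals.size == 0:
        raise ValueError("clean reference region is empty")
    mean_ref = float(ref_vals.mean())
    sd_ref = float(ref_vals.std(ddof=1)) if ref_vals.size > 1 else 0.0
    if sd_ref == 0.0:
        raise ValueError("degenerate reference region: zero intensity spread")
    z = (rcbv.values - mean_ref) / sd_ref
    return ImageVolume(z, rcbv.spacing_mm)


def normalise_case(case, target_mm: float = 1.0):
    """Resample a subject to isotropic spacing and return
    ``(z_map, tumour_mask_iso)``.

    Resampling happens first (declared pipeline order), then reference
    sanitisation and z-scoring on the isotropic grid.
    """
    rcbv = resample_isotropic(case.rcbv, target_mm, mode="trilinear")
    tumour = resample_mask_isotropic(case.tumour_mask, target_mm)
    reference = resample_mask_isotropic(case.reference_mask, target_mm)
    clean = sanitize_reference(reference, tumour, case.tumour_hemisphere)
    z_map = zscore_normalise(rcbv, tumour, clean)
    return z_map, tumour
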