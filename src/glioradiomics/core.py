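"""Core data containers shared across the pipeline.

The pipeline works on 3D scalar volumes (rCBV perfusion maps, later z-score
maps) and binary label masks (tumour, basal-ganglia reference region) that
live on a common voxel grid with known physical spacing.  A ``SubjectCase``
bundles one subject's volumes, masks, diagnostic labels and MR acquisition
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMask",
    "AcquisitionCovariates",
    "SubjectCase",
    "FeatureVector",
    "SHAPE_FEATURES",
    "HISTOGRAM_FEATURES",
    "TEXTURE_FEATURES",
    "FEATURE_NAMES",
    "hemisphere_mask",
]

#: Canonical feature roster: 4 shape + 13 histogram + 12 Haralick texture.
SHAPE_FEATURES: tuple[str, ...] = (
    "volume_mm3",
    "surface_mm2",
    "sav",
    "non_compactness",
)
HISTOGRAM_FEATURES: tuple[str, ...] = (
    "mean",
    "skewness",
    "kurtosis",
    "std",
    "min",
    "max",
    "p1",
    "p5",
    "p25",
    "p50",
    "p75",
    "p95",
    "p99",
)
TEXTURE_FEATURES: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "sum_square",
    "sum_average",
    "idm",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "sum_variance",
    "difference_entropy",
    "imc1",
)
FEATURE_NAMES: tuple[str, ...] = SHAPE_FEATURES + HISTOGRAM_FEATURES + TEXTURE_FEATURES


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive reals, got {spacing_mm!r}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar lattice with per-axis voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"ImageVolume requires 3D data, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm
        )


@dataclass
class LabelMask:
    """A binary 3D lattice aligned with an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"LabelMask requires 3D data, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("LabelMask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.values = arr
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def same_grid(self, other: "ImageVolume | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm
        )


def hemisphere_mask(shape: tuple[int, int, int], side: str) -> np.ndarray:
    """Boolean mask of one hemisphere, split at the mid-plane of axis 0.

    ``side`` is ``"left"`` (low axis-0 indices) or ``"right"``.  For odd
    axis-0 extents the middle slice is assigned to the right half.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    mid = shape[0] // 2
    out = np.zeros(shape, dtype=bool)
    if side == "left":
        out[:mid] = True
    else:
        out[mid:] = True
    return out


# Dichotomization bins for the acquisition covariates used both in the
# covariate correction and as classifier inputs.
def _bin_tr(tr_ms: float) -> str:
    return "<=1499" if tr_ms <= 1499 else ">=1500"


def _bin_te(te_ms: float) -> str:
    return "25-44" if te_ms < 45 else "45-55"


def _bin_fa(fa_deg: float) -> str:
    return "90" if fa_deg >= 90 else "<90"


def _bin_slice(slice_mm: float) -> str:
    return "<5" if slice_mm < 5 else ">=5"


def _bin_matrix(matrix: int) -> str:
    return "<128" if matrix < 128 else ">=128"


def _bin_inplane(res_mm: float) -> str:
    if res_mm <= 1:
        return "<=1"
    if res_mm < 2:
        return "(1,2)"
    return ">=2"


@dataclass
class AcquisitionCovariates:
    """Scanner and protocol covariates for one DSC-MRI acquisition."""

    manufacturer: str
    field_strength_T: float
    TR_ms: float
    TE_ms: float
    FA_deg: float
    slice_thickness_mm: float
    matrix_size: int
    inplane_resolution_mm: float

    def dichotomize(self) -> dict[str, str]:
        """Map each parameter to its analysis bin.

        Bins: field strength 1.5 vs 3 T; TR <=1499 vs >=1500 ms; TE 25-44 vs
        45-55 ms; FA 90 vs <90 deg; slice thickness <5 vs >=5 mm; matrix
        <128 vs >=128; in-plane resolution <=1, (1,2), >=2 mm.
        """
        return {
            "manufacturer": str(self.manufacturer),
            "field_T": "1.5" if self.field_strength_T < 2.0 else "3.0",
            "TR_ms": _bin_tr(self.TR_ms),
            "TE_ms": _bin_te(self.TE_ms),
            "FA_deg": _bin_fa(self.FA_deg),
            "slice_mm": _bin_slice(self.slice_thickness_mm),
            "matrix": _bin_matrix(self.matrix_size),
            "inplane_mm": _bin_inplane(self.inplane_resolution_mm),
        }


@dataclass
class SubjectCase:
    """One subject: volumes, masks, labels and covariates."""

    subject_id: str
    rcbv: ImageVolume
    tumour_mask: LabelMask
    reference_mask: LabelMask
    tumour_hemisphere: str
    grade: int
    idh: str
    age: float
    sex: str
    covariates: AcquisitionCovariates
    centre: int = 0

    def __post_init__(self) -> None:
        if self.grade not in (2, 3, 4):
            raise ValueError(f"grade must be 2, 3 or 4, got {self.grade}")
        if self.idh not in ("mutant", "wildtype"):
            raise ValueError(f"idh must be 'mutant' or 'wildtype', got {self.idh!r}")
        if self.tumour_hemisphere not in ("left", "right"):
            raise ValueError(f"invalid hemisphere {self.tumour_hemisphere!r}")
        if self.tumour_mask.n_voxels == 0:
            raise ValueError(f"{self.subject_id}: empty tumour mask")
        for m in (self.tumour_mask, self.reference_mask):
            if not self.rcbv.same_grid(m):
                raise ValueError(f"{self.subject_id}: mask grid differs from rCBV grid")


@dataclass
class FeatureVector:
    """The 29 named radiomic features for one tumour."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(
                f"FeatureVector requires exactly the 29 canonical features; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.values[name]) for name in FEATURE_NAMES}
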