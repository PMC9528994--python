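"""Core data model and volume/table I/O.

Volumes are stored as (x, y, z)-indexed arrays with physical metadata
(spacing, origin in mm).  All per-patient arrays are brought onto the
planning-CT grid before any feature computation: trilinear interpolation
for scalar fields (dose, perfusion), nearest neighbour for masks.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger("fwlomics")

VALID_UNITS = ("HU", "Gy", "perfusion-arb", "normalized")


class FormatError(ValueError):
    """Raised for malformed volumes or tables."""


class DegenerateROIError(ValueError):
    """Raised when an operation requires a non-empty region of interest."""


@dataclasses.dataclass
class ScalarVolume:
    """A 3D scalar grid with physical metadata.

    values : float array indexed (x, y, z)
    spacing : voxel size (sx, sy, sz) in mm, strictly positive
    origin : world position of voxel (0,0,0) in mm
    unit : one of HU, Gy, perfusion-arb, normalized
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D payload, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit tag {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclasses.dataclass
class BinaryMask:
    """A boolean ROI on the same grid as its reference volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def require_nonempty(self, what: str = "ROI") -> None:
        if not self.values.any():
            raise DegenerateROIError(f"{what} contains no voxels")

    def same_grid(self, other, atol: float = 1e-6) -> bool:
        return ScalarVolume.same_grid(self, other, atol)  # type: ignore[arg-type]


@dataclasses.dataclass
class PatientRecord:
    """One patient: imaging, dose, anatomy, perfusion, outcome."""

    id: str
    ct: ScalarVolume
    dose: ScalarVolume
    lung: BinaryMask
    gtv: BinaryMask
    perfusion: ScalarVolume
    prescription: float
    rp: int | None = None
    covariates: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise FormatError("prescription dose must be positive")
        for name in ("dose", "lung", "gtv", "perfusion"):
            obj = getattr(self, name)
            if not self.ct.same_grid(obj):
                raise FormatError(f"{name} is not on the CT grid for patient {self.id}")


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI / NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); ours are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).T
    return np.asarray(arr, dtype=np.float64), tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path: str | Path, kind: str = "normalized") -> ScalarVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume as a ScalarVolume."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - sitk error text varies
        raise IOError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path} holds a {img.GetDimension()}D payload, expected 3D")
    values, spacing, origin = _from_sitk(img)
    return ScalarVolume(values, spacing, origin, unit=kind)


def write_volume(vol: ScalarVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI/NRRD (format chosen by extension)."""
    values = vol.values.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.values
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(v.values > 0.5, v.spacing, v.origin)


def resample_to_grid(
    src: ScalarVolume, ref: ScalarVolume | BinaryMask, mode: str = "trilinear"
) -> ScalarVolume:
    """Resample ``src`` onto ``ref``'s grid (shared world frame).

    mode 'trilinear' for scalar fields, 'nearest' for label-like payloads.
    Regions of the reference grid outside the source support are zero-filled.
    """
    if src.same_grid(ref):
        return ScalarVolume(src.values.copy(), src.spacing, src.origin, src.unit)
    interp = {"trilinear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[mode]
    src_img = _to_sitk(src.values, src.spacing, src.origin)
    out = sitk.Resample(
        src_img,
        size=[int(n) for n in ref.values.shape],
        transform=sitk.Transform(),
        interpolator=interp,
        outputOrigin=tuple(float(o) for o in ref.origin),
        outputSpacing=tuple(float(s) for s in ref.spacing),
        outputDirection=src_img.GetDirection(),
        defaultPixelValue=0.0,
    )
    values, spacing, origin = _from_sitk(out)
    unit = src.unit
    src_lo = np.array(src.origin)
    src_hi = src_lo + (np.array(src.values.shape) - 1) * np.array(src.spacing)
    ref_lo = np.array(ref.origin)
    ref_hi = ref_lo + (np.array(ref.values.shape) - 1) * np.array(ref.spacing)
    if np.any(ref_lo < src_lo - 1e-9) or np.any(ref_hi > src_hi + 1e-9):
        logger.warning("resample_to_grid: reference extends outside source; zero-filled")
    return ScalarVolume(values, spacing, origin, unit)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise FormatError("feature table is empty")
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].tolist()
        raise FormatError(f"duplicate feature names: {dups[:5]}")
    all_nan = table.columns[table.isna().all(axis=0)].tolist()
    if all_nan:
        raise FormatError(f"all-NaN feature columns: {all_nan[:5]}")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a patients x features table as CSV (12 significant digits)."""
    validate_feature_table(table)
    table.to_csv(path, index=True, index_label="patient_id", float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
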