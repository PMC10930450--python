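"""Reading and writing volumes, masks and cohort tables.

Volumes and masks travel as NIfTI-1 (``.nii`` / ``.nii.gz``); the cohort
table and all reports are plain CSV. Hounsfield values are held as float64
after ingestion so that later interpolation does not truncate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import FormatError, GeometryError, InputError, ValidationError
from .geometry import ReferenceGrid

__all__ = [
    "CTVolume",
    "ThrombusMask",
    "PatientRecord",
    "TICI_TOKENS",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "records_to_frame",
]

#: Reperfusion grades present in the cohort (lower grades are rejected).
TICI_TOKENS = ("IIa", "IIb", "IIc", "III")

_PHASES = ("NCCT", "CTA", "CTV")


@dataclass
class CTVolume:
    """One 3D CT image in Hounsfield units with its grid geometry.

    ``validity`` marks voxels that carry real measurements; voxels filled in
    from outside the source field of view (e.g. after resampling) are False.
    ``None`` means every voxel is valid.
    """

    voxels: np.ndarray
    grid: ReferenceGrid
    phase: Optional[str] = None
    delay_s: Optional[float] = None
    validity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"CT volume must be 3D, got {self.voxels.ndim}D")
        if tuple(self.voxels.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("CT volume contains non-finite HU values")
        if self.phase is not None and self.phase not in _PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}, expected one of {_PHASES}")
        if self.delay_s is not None and self.phase not in (None, "CTV"):
            raise ValidationError("delay_s is defined only for the CTV phase")
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.voxels.shape:
                raise GeometryError("validity mask shape differs from voxel shape")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    def valid_mask(self) -> np.ndarray:
        if self.validity is None:
            return np.ones(self.voxels.shape, dtype=bool)
        return self.validity

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return replace(self, voxels=voxels)

    # -- SimpleITK bridge ---------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(self.voxels, (2, 1, 0)))
        )
        img.SetSpacing([float(s) for s in self.grid.spacing])
        img.SetOrigin([float(o) for o in self.grid.origin])
        img.SetDirection([float(d) for d in self.grid.direction])
        return img

    @classmethod
    def from_sitk(
        cls, img: sitk.Image, phase: Optional[str] = None, delay_s: Optional[float] = None
    ) -> "CTVolume":
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(float)
        grid = ReferenceGrid(
            shape=tuple(int(s) for s in img.GetSize()),
            spacing=tuple(float(s) for s in img.GetSpacing()),
            origin=tuple(float(o) for o in img.GetOrigin()),
            direction=tuple(float(d) for d in img.GetDirection()),
        )
        return cls(voxels=arr, grid=grid, phase=phase, delay_s=delay_s)


@dataclass
class ThrombusMask:
    """Binary clot segmentation on the reference (NCCT) grid."""

    voxels: np.ndarray
    grid: ReferenceGrid

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"mask must be 3D, got {vox.ndim}D")
        self.voxels = (vox != 0).astype(np.uint8)
        if tuple(self.voxels.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if not self.voxels.any():
            raise ValidationError("empty thrombus mask")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates for one patient."""

    patient_id: str
    nihss_admission: int
    tici: str
    n_passes: int
    cta_ctv_delay_s: float

    def __post_init__(self):
        if not (0 <= int(self.nihss_admission) <= 42):
            raise ValidationError(
                f"nihss_admission {self.nihss_admission} outside [0, 42]"
            )
        if self.tici not in TICI_TOKENS:
            raise ValidationError(f"unknown TICI token {self.tici!r}, expected {TICI_TOKENS}")
        if int(self.n_passes) < 1:
            raise ValidationError(f"n_passes must be >= 1, got {self.n_passes}")
        if float(self.cta_ctv_delay_s) < 0:
            raise ValidationError("cta_ctv_delay_s must be non-negative")
        object.__setattr__(self, "nihss_admission", int(self.nihss_admission))
        object.__setattr__(self, "n_passes", int(self.n_passes))
        object.__setattr__(self, "cta_ctv_delay_s", float(self.cta_ctv_delay_s))


# ---------------------------------------------------------------------------
# volumes


def read_volume(path, phase: Optional[str] = None, delay_s: Optional[float] = None) -> CTVolume:
    """Read a NIfTI volume; geometry comes from the header, HU untouched."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, got {img.GetDimension()}D"
        )
    vol = CTVolume.from_sitk(img, phase=phase, delay_s=delay_s)
    if not np.all(np.isfinite(vol.voxels)):  # pragma: no cover - caught in __post_init__
        raise FormatError(f"{path}: non-finite voxel values")
    return vol


def write_volume(vol: CTVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path))
    return path


# ---------------------------------------------------------------------------
# masks


def read_mask(path, reference: CTVolume) -> ThrombusMask:
    """Read a label volume and collapse any nonzero label to 1.

    The mask must live on exactly the reference grid (shape equal; spacing and
    origin within 1e-3 mm; direction within 1e-3).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {img.GetDimension()}D")
    mvol = CTVolume.from_sitk(img)
    if not mvol.grid.matches(reference.grid, tol_mm=1e-3):
        raise GeometryError(
            "mask grid does not match reference grid: "
            f"mask {mvol.grid}, reference {reference.grid}"
        )
    return ThrombusMask(voxels=mvol.voxels, grid=reference.grid)


def write_mask(mask: ThrombusMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0)))
    )
    img.SetSpacing([float(s) for s in mask.grid.spacing])
    img.SetOrigin([float(o) for o in mask.grid.origin])
    img.SetDirection([float(d) for d in mask.grid.direction])
    sitk.WriteImage(img, str(path))
    return path


# ---------------------------------------------------------------------------
# cohort table

_COHORT_COLUMNS = ["patient_id", "nihss_admission", "tici", "n_passes", "cta_ctv_delay_s"]


def read_cohort_table(path) -> list[PatientRecord]:
    """Read the clinical covariate CSV; one validated record per row."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    nihss_admission=int(row.nihss_admission),
                    tici=str(row.tici),
                    n_passes=int(row.n_passes),
                    cta_ctv_delay_s=float(row.cta_ctv_delay_s),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i + 1}: {exc}") from exc
    return records


def write_cohort_table(records: Iterable[PatientRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    return path


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "nihss_admission": r.nihss_admission,
                "tici": r.tici,
                "n_passes": r.n_passes,
                "cta_ctv_delay_s": r.cta_ctv_delay_s,
            }
            for r in records
        ],
        columns=_COHORT_COLUMNS,
    )
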