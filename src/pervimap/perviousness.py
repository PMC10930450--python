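"""Voxel-wise perviousness (thrombus attenuation increase) maps.

The thrombus attenuation increase (TAI) between two CT phases is the
voxel-wise HU difference of the co-registered images. Three maps are
computed over the whole volume:

* ``P1 = CTA - NCCT`` — standard perviousness (contrast arrived by the
  arterial phase),
* ``P2 = CTV - CTA`` — late contrast uptake,
* ``P3 = CTA - CTV`` — early contrast washout.

Negative voxels are clipped to zero so each map carries only its own
component; consequently ``P2 - P3`` reconstructs the raw ``CTV - CTA``
difference and a voxel can never be positive in both P2 and P3. Per-thrombus
summaries are means over the segmented clot volume (clipped zeros included).

The classical scalar measures are provided for comparison: the two-phase
TAI from three small spherical ROIs on the clot, and the void fraction
(clot attenuation increase over contralateral-artery attenuation increase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, UndefinedRatioError, ValidationError
from .geometry import ReferenceGrid
from .io import CTVolume, ThrombusMask

__all__ = [
    "MAP_KINDS",
    "PerviousnessMap",
    "ThrombusSummary",
    "SphericalROI",
    "compute_map",
    "compute_all_maps",
    "summarize",
    "two_roi_tai",
    "void_fraction",
]

MAP_KINDS = ("P1", "P2", "P3")

#: (minuend phase, subtrahend phase) defining each map kind.
MAP_DEFINITIONS = {"P1": ("CTA", "NCCT"), "P2": ("CTV", "CTA"), "P3": ("CTA", "CTV")}


@dataclass
class PerviousnessMap:
    """One non-negative voxel-wise TAI map on the reference grid."""

    kind: str
    voxels: np.ndarray
    validity: np.ndarray
    grid: ReferenceGrid

    def __post_init__(self):
        if self.kind not in MAP_KINDS:
            raise ValidationError(f"unknown map kind {self.kind!r}")
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.voxels.shape != self.validity.shape:
            raise GeometryError("map and validity shapes differ")
        if np.any(self.voxels[self.validity] < 0):
            raise ValidationError("perviousness map contains negative valid voxels")

    def to_volume(self) -> CTVolume:
        return CTVolume(voxels=self.voxels, grid=self.grid, validity=self.validity)


@dataclass(frozen=True)
class ThrombusSummary:
    """Per-thrombus map means and volume."""

    patient_id: str
    mean_P1: float
    mean_P2: float
    mean_P3: float
    volume_mm3: float
    n_voxels: int

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mean_P1": self.mean_P1,
            "mean_P2": self.mean_P2,
            "mean_P3": self.mean_P3,
            "volume_mm3": self.volume_mm3,
            "n_voxels": self.n_voxels,
        }


def _check_same_grid(a: CTVolume, b: CTVolume) -> None:
    if not a.grid.matches(b.grid):
        raise GeometryError(
            f"volumes are not on the same reference grid: {a.grid} vs {b.grid}"
        )


def compute_map(minuend: CTVolume, subtrahend: CTVolume, kind: str) -> PerviousnessMap:
    """``max(minuend - subtrahend, 0)`` voxel-wise, on the shared grid.

    Validity is the intersection of the operands' validity masks; values at
    invalid voxels are kept at zero.
    """
    _check_same_grid(minuend, subtrahend)
    validity = minuend.valid_mask() & subtrahend.valid_mask()
    diff = np.clip(minuend.voxels - subtrahend.voxels, 0.0, None)
    diff = np.where(validity, diff, 0.0)
    return PerviousnessMap(kind=kind, voxels=diff, validity=validity, grid=minuend.grid)


def compute_all_maps(
    ncct: CTVolume, cta: CTVolume, ctv: CTVolume
) -> dict[str, PerviousnessMap]:
    """Compute P1 = CTA - NCCT, P2 = CTV - CTA and P3 = CTA - CTV."""
    phases = {"NCCT": ncct, "CTA": cta, "CTV": ctv}
    return {
        kind: compute_map(phases[minu], phases[subt], kind)
        for kind, (minu, subt) in MAP_DEFINITIONS.items()
    }


def summarize(
    maps: dict[str, PerviousnessMap], mask: ThrombusMask, patient_id: str
) -> ThrombusSummary:
    """Mean map values over the clot mask (clipped zeros included).

    Means are taken over mask voxels valid in every map (one common voxel set
    so the three means describe the same clot volume); the thrombus volume is
    that voxel count times the voxel volume of the reference grid.
    """
    missing = [k for k in MAP_KINDS if k not in maps]
    if missing:
        raise ValidationError(f"missing map(s) {missing}")
    grid = maps["P1"].grid
    if tuple(mask.grid.shape) != tuple(grid.shape):
        raise GeometryError("mask is not on the maps' reference grid")
    common = mask.as_bool()
    for k in MAP_KINDS:
        common = common & maps[k].validity
    n = int(common.sum())
    if n == 0:
        raise ValidationError("thrombus outside valid field")
    means = {k: float(maps[k].voxels[common].mean()) for k in MAP_KINDS}
    return ThrombusSummary(
        patient_id=patient_id,
        mean_P1=means["P1"],
        mean_P2=means["P2"],
        mean_P3=means["P3"],
        volume_mm3=n * grid.voxel_volume_mm3,
        n_voxels=n,
    )


# ---------------------------------------------------------------------------
# classical scalar measures


@dataclass(frozen=True)
class SphericalROI:
    """Small spherical ROI: centre in world mm, diameter in mm (typ. 1-2)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValidationError("ROI diameter must be positive")


def _roi_mean(vol: CTVolume, roi: SphericalROI, coords: np.ndarray) -> float:
    radius = roi.diameter_mm / 2.0
    center = np.asarray(roi.center_mm, dtype=float)
    # voxel membership: voxel centre inside the sphere
    d2 = ((coords - center) ** 2).sum(axis=-1)
    inside = d2 <= radius**2
    if not inside.any():
        raise GeometryError(
            f"ROI at {tuple(center)} mm (d={roi.diameter_mm} mm) contains no voxel centre"
        )
    lo = center - radius
    hi = center + radius
    ext_lo = vol.grid.index_to_world((0, 0, 0))
    ext_hi = vol.grid.index_to_world(tuple(s - 1 for s in vol.grid.shape))
    bb_lo, bb_hi = np.minimum(ext_lo, ext_hi), np.maximum(ext_lo, ext_hi)
    if np.any(lo < bb_lo - 1e-9) or np.any(hi > bb_hi + 1e-9):
        raise GeometryError(f"ROI at {tuple(center)} mm extends outside the volume")
    return float(vol.voxels[inside].mean())


def two_roi_tai(
    ncct: CTVolume, cta: CTVolume, rois: Sequence[SphericalROI]
) -> float:
    """Classical two-phase TAI from spherical clot ROIs.

    Each ROI's mean HU is computed on NCCT and on CTA; the ROI means are
    averaged into rho_NCCT and rho_CTA and ``TAI = rho_CTA - rho_NCCT``.
    Unlike the voxel-wise maps this scalar may be negative (no clipping).
    """
    _check_same_grid(ncct, cta)
    if len(rois) == 0:
        raise ValidationError("at least one ROI is required")
    coords = ncct.grid.world_coordinates()
    rho_ncct = float(np.mean([_roi_mean(ncct, r, coords) for r in rois]))
    rho_cta = float(np.mean([_roi_mean(cta, r, coords) for r in rois]))
    return rho_cta - rho_ncct


def void_fraction(
    ncct: CTVolume,
    cta: CTVolume,
    thrombus_rois: Sequence[SphericalROI],
    contralateral_rois: Sequence[SphericalROI],
) -> float:
    """Void fraction: clot attenuation increase over contralateral increase.

    ``delta_thrombus / delta_blood`` where each delta is a two-phase TAI from
    its own ROI set; 1.0 means fully pervious, 0.0 impervious.
    """
    delta_thrombus = two_roi_tai(ncct, cta, thrombus_rois)
    delta_blood = two_roi_tai(ncct, cta, contralateral_rois)
    if delta_blood <= 0:
        raise UndefinedRatioError(
            f"contralateral attenuation increase must be positive, got {delta_blood:.3f} HU"
        )
    return delta_thrombus / delta_blood
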