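"""Grid geometry, world coordinates and rigid transforms.

Conventions
-----------
* Voxel arrays are indexed ``(i, j, k)`` (fastest-varying index first, the
  NIfTI convention), so ``voxels.shape == grid.shape``.
* World coordinates are in millimetres in the ITK (LPS) frame:
  ``world = origin + direction @ (spacing * index)``.
* All geometry comparisons are done in world space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ValidationError

__all__ = ["ReferenceGrid", "RigidTransform", "CLINICAL_GRID_SHAPE", "CLINICAL_GRID_SPACING"]

#: Uniform acquisition-independent analysis grid: 512 x 512 x 240 voxels at
#: 0.5 x 0.5 x 0.7 mm.
CLINICAL_GRID_SHAPE = (512, 512, 240)
CLINICAL_GRID_SPACING = (0.5, 0.5, 0.7)


def _as_float3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass(frozen=True)
class ReferenceGrid:
    """A 3D sampling lattice: shape, spacing (mm), origin (mm), direction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = field(
        default=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    )

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValidationError(f"grid shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be strictly positive, got {self.spacing}")
        d = self.direction_matrix
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValidationError("direction matrix is not orthonormal within 1e-6")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the lattice bounding box."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def world_center(self) -> np.ndarray:
        idx_center = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(idx_center)

    def index_to_world(self, index) -> np.ndarray:
        """Map (possibly fractional, possibly (N,3)) voxel indices to mm."""
        idx = np.asarray(index, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + scaled @ self.direction_matrix.T

    def world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        return self.index_to_world(idx.reshape(-1, 3)).reshape(*self.shape, 3)

    def to_sitk_image(self, pixel_type=sitk.sitkFloat64) -> sitk.Image:
        img = sitk.Image([int(s) for s in self.shape], pixel_type)
        img.SetSpacing([float(s) for s in self.spacing])
        img.SetOrigin([float(o) for o in self.origin])
        img.SetDirection([float(d) for d in self.direction])
        return img

    @classmethod
    def clinical_default(cls) -> "ReferenceGrid":
        return cls(shape=CLINICAL_GRID_SHAPE, spacing=CLINICAL_GRID_SPACING)

    def matches(self, other: "ReferenceGrid", tol_mm: float = 1e-3) -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=1e-3)
        )


@dataclass
class RigidTransform:
    """6-DOF rigid transform: ZYX Euler angles (rad) + translation (mm).

    Acts on world points as ``x' = R (x - c) + c + t`` with rotation centre
    ``c`` — the same parameterisation as ITK's Euler3DTransform, so it can be
    passed directly to the resampler.
    """

    rotation: np.ndarray  # (3,) radians
    translation: np.ndarray  # (3,) mm
    center: np.ndarray  # (3,) mm

    def __post_init__(self):
        self.rotation = _as_float3(self.rotation)
        self.translation = _as_float3(self.translation)
        self.center = _as_float3(self.center)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), _as_float3(center))

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center])
        t.SetRotation(*(float(a) for a in self.rotation))
        t.SetTranslation([float(v) for v in self.translation])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        e = sitk.Euler3DTransform(t)
        return cls(
            rotation=np.asarray(e.GetParameters()[:3]),
            translation=np.asarray(e.GetParameters()[3:]),
            center=np.asarray(e.GetFixedParameters()[:3]),
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_sitk(sitk.Euler3DTransform(self.to_sitk().GetInverse()))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of world points."""
        m = np.asarray(self.to_sitk().GetMatrix()).reshape(3, 3)
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ m.T + self.center + self.translation

    @property
    def rotation_matrix(self) -> np.ndarray:
        return np.asarray(self.to_sitk().GetMatrix()).reshape(3, 3)

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation part."""
        tr = np.trace(self.rotation_matrix)
        return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))

    # -- plain-text serialization ------------------------------------------

    def to_text(self) -> str:
        lines = ["# pervimap rigid transform (Euler ZYX)"]
        for key, val in (
            ("rotation_rad", self.rotation),
            ("translation_mm", self.translation),
            ("center_mm", self.center),
        ):
            lines.append(f"{key} = {float(val[0])!r} {float(val[1])!r} {float(val[2])!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform":
        vals = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("=")
            vals[key.strip()] = np.array([float(v) for v in rest.split()])
        try:
            return cls(vals["rotation_rad"], vals["translation_mm"], vals["center_mm"])
        except KeyError as exc:
            raise ValidationError(f"transform file missing field {exc}") from exc
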