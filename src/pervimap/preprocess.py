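"""Resampling to the common analysis grid and rigid inter-phase registration.

All three phases of one patient are brought onto a single reference grid
(default 512 x 512 x 240 at 0.5 x 0.5 x 0.7 mm): each volume is resampled
onto the grid and the contrast phases (CTA, CTV) are rigidly co-registered
to the non-contrast scan. Registration is 6-DOF rigid with a Mattes
mutual-information metric, three resolution levels and a regular-step
gradient-descent optimizer; metric sampling is seeded so runs are
reproducible. Voxels that fall outside a source field of view are filled
with air (-1024 HU) and excluded via the volume's validity mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

from .errors import GeometryError, InputError
from .geometry import ReferenceGrid, RigidTransform
from .io import CTVolume

__all__ = [
    "AIR_HU",
    "RegistrationResult",
    "resample_to_grid",
    "register_rigid",
    "apply_transform",
]

log = logging.getLogger(__name__)

#: Fill value for voxels outside the source field of view.
AIR_HU = -1024.0

_INTERPOLATORS = {
    "trilinear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def _interpolator(name: str):
    try:
        return _INTERPOLATORS[name]
    except KeyError:
        raise InputError(
            f"unknown interpolation {name!r}; expected one of {sorted(_INTERPOLATORS)}"
        ) from None


def _resample_with_validity(
    vol: CTVolume,
    transform: sitk.Transform,
    grid: ReferenceGrid,
    interpolation: str,
    fill_value: float,
) -> CTVolume:
    src = vol.to_sitk()
    ref = grid.to_sitk_image()
    interp = _interpolator(interpolation)
    out = sitk.Resample(src, ref, transform, interp, float(fill_value), sitk.sitkFloat64)

    # Track which output voxels sampled inside the source field of view by
    # pushing a ones-image through the identical transform.
    ones = sitk.Image(src.GetSize(), sitk.sitkUInt8) + 1
    ones.CopyInformation(src)
    val = sitk.Resample(ones, ref, transform, sitk.sitkNearestNeighbor, 0.0, sitk.sitkUInt8)
    validity = np.transpose(sitk.GetArrayFromImage(val), (2, 1, 0)).astype(bool)
    if vol.validity is not None:
        src_val = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(vol.validity.astype(np.uint8), (2, 1, 0)))
        )
        src_val.CopyInformation(src)
        carried = sitk.Resample(
            src_val, ref, transform, sitk.sitkNearestNeighbor, 0.0, sitk.sitkUInt8
        )
        validity &= np.transpose(sitk.GetArrayFromImage(carried), (2, 1, 0)).astype(bool)

    if not validity.any():
        raise GeometryError(
            "no overlap between source volume and target grid in world space"
        )
    voxels = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))
    return CTVolume(
        voxels=voxels, grid=grid, phase=vol.phase, delay_s=vol.delay_s, validity=validity
    )


def resample_to_grid(
    vol: CTVolume,
    grid: ReferenceGrid,
    interpolation: str = "trilinear",
    fill_value: float = AIR_HU,
) -> CTVolume:
    """Resample ``vol`` onto ``grid`` (no registration, geometry only)."""
    return _resample_with_validity(
        vol, sitk.Transform(3, sitk.sitkIdentity), grid, interpolation, fill_value
    )


def apply_transform(
    vol: CTVolume,
    transform: RigidTransform,
    grid: ReferenceGrid,
    interpolation: str = "trilinear",
    fill_value: float = AIR_HU,
) -> CTVolume:
    """Resample ``vol`` through a rigid transform onto ``grid``.

    Registration and grid resampling are composed into a single interpolation
    pass: the transform maps target-grid world points into the source volume.
    """
    return _resample_with_validity(vol, transform.to_sitk(), grid, interpolation, fill_value)


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration run."""

    transform: RigidTransform
    metric_value: float
    converged: bool
    stop_condition: str
    n_iterations: int

    def __iter__(self):  # allow ``transform, result = ...`` unpacking patterns
        yield self.transform
        yield self


def register_rigid(
    moving: CTVolume,
    fixed: CTVolume,
    seed: int = 1,
    max_iterations: int = 150,
    sampling_fraction: float = 0.2,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
) -> RegistrationResult:
    """Rigidly register ``moving`` to ``fixed`` (same-patient multiphase CT).

    Returns the transform that maps fixed-image world points into the moving
    image, i.e. exactly what :func:`apply_transform` needs to resample the
    moving phase onto the fixed phase's grid. The optimizer schedule and the
    metric-sampling seed are fixed, so results are deterministic for a given
    ``seed``.

    Non-convergence within the iteration budget does not raise; it is
    reported via ``converged`` / ``stop_condition`` and logged as a warning.
    """
    fixed_img = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    moving_img = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(float(sampling_fraction), int(seed) % (2**31 - 1) + 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=5e-5,
        numberOfIterations=int(max_iterations),
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    initial = sitk.CenteredTransformInitializer(
        fixed_img,
        moving_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(initial, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    final = reg.Execute(fixed_img, moving_img)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    result = RegistrationResult(
        transform=RigidTransform.from_sitk(final),
        metric_value=float(reg.GetMetricValue()),
        converged=converged,
        stop_condition=stop,
        n_iterations=int(reg.GetOptimizerIteration()),
    )
    if not converged:
        log.warning("registration unconverged after %d iterations: %s", max_iterations, stop)
    return result


def resample_mask_to_grid(mask_vol: CTVolume, grid: ReferenceGrid) -> CTVolume:
    """Nearest-neighbour resampling for label volumes (keeps masks binary)."""
    out = resample_to_grid(mask_vol, grid, interpolation="nearest", fill_value=0.0)
    return replace(out, voxels=(out.voxels != 0).astype(float))
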