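"""Synthetic multiphase-CT patients with known contrast-uptake dynamics.

Each phantom patient is a simple head: an ellipsoidal brain (with a smooth
random HU texture) inside a bony shell, air outside, and one straight
vessel running through the brain. A segment of the vessel is occluded by a
hyperdense clot (baseline 55-75 HU); inside the clot a thin longitudinal
channel has elevated contrast uptake, emulating the pervious path seen on
late-uptake maps of real clots. Three phases are rendered from one anatomy:

* NCCT at t = 0 (no contrast),
* CTA at the arterial time ``t_a``,
* CTV at ``t_a + delay`` with the delay drawn from 70 +/- 28 s (>= 10 s),
  the spread of a real acute multiphase protocol.

Contrast kinetics are mono-exponential saturating uptake per region,
``u(t) = A (1 - exp(-t / tau))``, optionally followed by linear washout
after the arterial time; the patent lumen enhances fully at CTA and decays
linearly afterwards. These kinetics are this package's modelling choice —
they are the simplest law that produces distinct standard-perviousness,
late-uptake and early-washout signatures — and they give closed-form
expected map values that the pipeline can be tested against exactly.

Phases can be independently jittered by small rigid transforms (patient
motion between acquisitions); the applied transforms and the transforms a
registration should recover are recorded in the ground truth.

Cohort mode draws per-patient uptake amplitudes (lognormal biological
variability), delays, and clinical covariates consistent with a requested
group structure, so group-comparison power and type-I error can be measured
against a known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import SpecError
from .geometry import ReferenceGrid, RigidTransform
from .io import CTVolume, PatientRecord, ThrombusMask, TICI_TOKENS

__all__ = [
    "UptakeKinetics",
    "Misalignment",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomPatient",
    "AnatomyTemplate",
    "GroupEffect",
    "PhantomCohort",
    "generate_patient",
    "generate_cohort",
]


@dataclass(frozen=True)
class UptakeKinetics:
    """Saturating uptake ``A (1 - exp(-t/tau))`` with optional linear washout.

    ``washout_per_s`` > 0 switches the region to linear decay of the arterial
    value after ``t_a`` (fraction per second); 0 keeps uptake monotone.
    """

    amp_hu: float
    tau_s: float
    washout_per_s: float = 0.0

    def at(self, t: float, t_a: float) -> float:
        up = self.amp_hu * (1.0 - np.exp(-t / self.tau_s))
        if t <= t_a or self.washout_per_s <= 0:
            return float(up)
        at_a = self.amp_hu * (1.0 - np.exp(-t_a / self.tau_s))
        return float(at_a * max(0.0, 1.0 - self.washout_per_s * (t - t_a)))


@dataclass(frozen=True)
class Misalignment:
    """Uniform rigid jitter bounds per moved phase (NCCT stays fixed)."""

    max_translation_mm: float = 2.0
    max_rotation_deg: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic multiphase patient."""

    grid: ReferenceGrid = field(
        default_factory=lambda: ReferenceGrid((96, 96, 96), (0.5, 0.5, 0.7))
    )
    # anatomy
    vessel_radius_mm: float = 2.0
    vessel_offset_mm: tuple[float, float] = (2.0, 0.0)  # axis offset from centre (x, y)
    clot_z_frac: tuple[float, float] = (0.38, 0.62)
    clot_hu_range: tuple[float, float] = (55.0, 75.0)  # hyperdense clot baseline
    blood_hu: float = 45.0
    background_hu: float = 35.0
    texture_sd_hu: float = 6.0
    n_texture_blobs: int = 24
    bone_hu: float = 900.0
    air_hu: float = -1000.0
    # contrast dynamics
    lumen_enhancement_range: tuple[float, float] = (200.0, 400.0)
    lumen_washout_per_s: float = 0.004
    clot_uptake: UptakeKinetics = UptakeKinetics(amp_hu=10.0, tau_s=12.0, washout_per_s=0.002)
    channel_uptake: UptakeKinetics = UptakeKinetics(amp_hu=50.0, tau_s=120.0)
    channel_radius_frac: float = 0.4
    channel_offset_frac: float = 0.3
    #: length of unenhanced (stagnant) lumen adjacent to each clot face —
    #: contrast stasis at the occlusion, so enhancement does not abut the mask
    stasis_margin_mm: float = 1.5
    cta_time_s: float = 20.0
    # acquisition
    delay_mean_s: float = 70.0
    delay_sd_s: float = 28.0
    delay_min_s: float = 10.0
    delay_s: Optional[float] = None  # fixed delay override
    #: width (mm) of the smooth partial-volume transition at tissue
    #: boundaries; band-limits the anatomy in world space so that renders are
    #: consistent under sub-voxel rigid motion
    edge_sigma_mm: float = 0.5
    #: optional additional image-space reconstruction blur (Gaussian sigma, mm)
    psf_sigma_mm: float = 0.0
    noise_sd_hu: float = 4.0
    misalignment: Optional[Misalignment] = field(default_factory=Misalignment)
    # cohort-mode biological variability of uptake amplitudes (lognormal CV)
    uptake_amp_cv: float = 0.35
    seed: int = 0
    anatomy_seed: Optional[int] = None  # defaults to seed; shared in cohort mode

    def __post_init__(self):
        if self.noise_sd_hu < 0:
            raise SpecError("noise_sd_hu must be >= 0")
        if not (0.0 <= self.clot_z_frac[0] < self.clot_z_frac[1] <= 1.0):
            raise SpecError(f"invalid clot_z_frac {self.clot_z_frac}")
        if self.channel_radius_frac <= 0 or self.channel_offset_frac < 0:
            raise SpecError("channel geometry fractions must be positive")
        if self.channel_radius_frac + self.channel_offset_frac > 1.0:
            raise SpecError("pervious channel must lie entirely inside the clot")
        if self.vessel_radius_mm <= 0:
            raise SpecError("vessel_radius_mm must be positive")
        if self.delay_s is not None and self.delay_s <= 0:
            raise SpecError("delay_s must be positive")
        if self.delay_min_s <= 0:
            raise SpecError("delay_min_s must be positive")
        if self.edge_sigma_mm <= 0:
            raise SpecError("edge_sigma_mm must be positive")
        half_extent = self.grid.extent_mm[:2] / 2.0
        if np.any(
            np.abs(np.asarray(self.vessel_offset_mm)) + self.vessel_radius_mm
            >= 0.9 * half_extent
        ):
            raise SpecError("vessel does not fit inside the phantom head")

    @classmethod
    def cohort_default(cls, **overrides) -> "PhantomSpec":
        """Desk-scale cohort configuration: 24^3 voxels at 1 mm in-plane.

        Misalignment is off (cohort simulations exercise the map and
        statistics stages; registration has its own dedicated phantoms).
        """
        base = dict(
            grid=ReferenceGrid((24, 24, 24), (1.0, 1.0, 1.0)),
            vessel_radius_mm=2.5,
            misalignment=None,
        )
        base.update(overrides)
        return cls(**base)


class AnatomyTemplate:
    """Deterministic anatomy layout for one spec (shareable across a cohort).

    Holds everything that does not vary between cohort patients: the brain /
    skull geometry, texture blobs, vessel and clot/channel axes, the world
    coordinates of the grid, and cached region masks on the unjittered grid.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.grid = spec.grid
        seed = spec.anatomy_seed if spec.anatomy_seed is not None else spec.seed
        rng = np.random.default_rng(int(seed))

        self.center = self.grid.world_center()
        # triaxial head (axially non-circular, as real heads are) so that
        # orientation is determined by the high-contrast bone boundary
        self.brain_semiaxes = np.array([0.45, 0.38, 0.42]) * self.grid.extent_mm
        self.vessel_axis_xy = self.center[:2] + np.asarray(spec.vessel_offset_mm)
        ext_z = self.grid.extent_mm[2]
        z0 = self.center[2] - ext_z / 2.0
        self.clot_z_mm = (z0 + spec.clot_z_frac[0] * ext_z, z0 + spec.clot_z_frac[1] * ext_z)
        self.channel_axis_xy = self.vessel_axis_xy + np.array(
            [0.0, spec.channel_offset_frac * spec.vessel_radius_mm]
        )
        self.channel_radius_mm = spec.channel_radius_frac * spec.vessel_radius_mm

        # smooth texture: sum of random Gaussian blobs inside the brain
        n = spec.n_texture_blobs
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = 0.75 * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1 / 3)
        self.blob_centers = self.center + u * radii * self.brain_semiaxes
        self.blob_sigmas = rng.uniform(2.0, 6.0, size=n)
        self.blob_amps = rng.normal(0.0, spec.texture_sd_hu, size=n)

        # asymmetric internal landmarks (paired CSF-dark ventricles and one
        # calcified bright spot) so that rigid orientation is well determined
        ext = self.grid.extent_mm
        self.ventricle_centers = np.array(
            [
                self.center + np.array([-0.25 * ext[0], 0.08 * ext[1], 0.0]),
                self.center + np.array([0.25 * ext[0], -0.04 * ext[1], 0.05 * ext[2]]),
            ]
        )
        self.ventricle_semiaxes = np.array(
            [[0.08, 0.16, 0.12], [0.07, 0.13, 0.10]]
        ) * ext
        self.calcification_center = self.center + np.array(
            [0.10 * ext[0], -0.15 * ext[1], 0.12 * ext[2]]
        )
        self.calcification_radius_mm = max(1.5, 1.5 * float(np.min(spec.grid.spacing)))

        self.world = self.grid.world_coordinates().reshape(-1, 3)
        self._weights_unjittered = self.weights(self.world)
        self._texture_unjittered = self.texture(self.world)

    # -- geometry queries ---------------------------------------------------

    def weights(self, pts: np.ndarray) -> dict[str, np.ndarray]:
        """Smooth region-membership weights in [0, 1] for (N, 3) world points.

        Boundaries are sigmoid profiles of the signed distance to the region
        surface, width ``edge_sigma_mm``: an analytic partial-volume model
        that band-limits the anatomy in world space, so renders of the same
        patient under different rigid jitters are mutually consistent.
        """
        from scipy.special import expit

        sig = self.spec.edge_sigma_mm
        rel = (pts - self.center) / self.brain_semiaxes
        r = np.sqrt((rel**2).sum(axis=1))
        scale = float(np.exp(np.mean(np.log(self.brain_semiaxes))))  # mm per unit r
        w_head = expit((1.02 - r) * scale / sig)
        w_brain = expit((0.9 - r) * scale / sig)
        w_vent = np.zeros(len(pts))
        for c, sa in zip(self.ventricle_centers, self.ventricle_semiaxes):
            rv = np.sqrt((((pts - c) / sa) ** 2).sum(axis=1))
            sv = float(np.exp(np.mean(np.log(sa))))
            w_vent = np.maximum(w_vent, expit((1.0 - rv) * sv / sig))
        d_calc = np.linalg.norm(pts - self.calcification_center, axis=1)
        w_calc = expit((self.calcification_radius_mm - d_calc) / sig)
        d_vessel = np.hypot(
            pts[:, 0] - self.vessel_axis_xy[0], pts[:, 1] - self.vessel_axis_xy[1]
        )
        w_vessel = expit((self.spec.vessel_radius_mm - d_vessel) / sig) * w_brain
        z0, z1 = self.clot_z_mm
        w_z = expit((pts[:, 2] - z0) / sig) * expit((z1 - pts[:, 2]) / sig)
        m = self.spec.stasis_margin_mm
        w_z_wide = expit((pts[:, 2] - (z0 - m)) / sig) * expit(((z1 + m) - pts[:, 2]) / sig)
        d_channel = np.hypot(
            pts[:, 0] - self.channel_axis_xy[0], pts[:, 1] - self.channel_axis_xy[1]
        )
        w_chan_rad = expit((self.channel_radius_mm - d_channel) / sig)
        w_clot = w_vessel * w_z
        return {
            "head": w_head,
            "brain": w_brain,
            "ventricle": w_vent * w_brain,
            "calcification": w_calc * w_brain,
            "vessel": w_vessel,
            "clot": w_clot,
            "lumen": w_vessel * (1.0 - w_z_wide),
            "clot_body": w_clot * (1.0 - w_chan_rad),
            "channel": w_clot * w_chan_rad,
        }

    def texture(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[0])
        for c, s, a in zip(self.blob_centers, self.blob_sigmas, self.blob_amps):
            d2 = ((pts - c) ** 2).sum(axis=1)
            out += a * np.exp(-d2 / (2.0 * s * s))
        return out

    def unjittered_weights(self) -> dict[str, np.ndarray]:
        return self._weights_unjittered

    def mask(self) -> ThrombusMask:
        vox = (self._weights_unjittered["clot"] >= 0.5).reshape(self.grid.shape)
        return ThrombusMask(voxels=vox.astype(np.uint8), grid=self.grid)


@dataclass
class PhantomTruth:
    """Ground truth accompanying one phantom patient.

    ``early_uptake`` is the noise-free enhancement at the arterial time;
    ``late_uptake`` / ``washout`` are the positive / negative parts of the
    noise-free CTV - CTA difference — i.e. the expected P1 / P2 / P3 values
    on perfectly aligned, noise-free data.
    """

    mask: ThrombusMask
    early_uptake: np.ndarray
    late_uptake: np.ndarray
    washout: np.ndarray
    applied_misalignment: dict[str, Optional[RigidTransform]]
    expected_alignment: dict[str, Optional[RigidTransform]]
    delay_s: float
    clot_hu: float
    lumen_enhancement_hu: float
    #: noise-free in-mask NCCT mean; below the baseline clot HU because
    #: boundary voxels are partial-volume blends with blood and brain
    expected_ncct_clot_mean: float = float("nan")
    group: Optional[str] = None

    def expected_means(self) -> dict[str, float]:
        m = self.mask.as_bool()
        return {
            "mean_P1": float(self.early_uptake[m].mean()),
            "mean_P2": float(self.late_uptake[m].mean()),
            "mean_P3": float(self.washout[m].mean()),
        }


@dataclass
class PhantomPatient:
    patient_id: str
    ncct: CTVolume
    cta: CTVolume
    ctv: CTVolume
    mask: ThrombusMask
    truth: PhantomTruth
    spec: Optional[PhantomSpec] = None


def _draw_misalignment(rng: np.random.Generator, m: Misalignment, center) -> RigidTransform:
    rot = rng.uniform(-1.0, 1.0, size=3) * np.radians(m.max_rotation_deg)
    tra = rng.uniform(-1.0, 1.0, size=3) * m.max_translation_mm
    return RigidTransform(rotation=rot, translation=tra, center=np.asarray(center))


def _region_enhancements(spec: PhantomSpec, lumen_enh: float, t: float) -> dict[str, float]:
    t_a = spec.cta_time_s
    if t <= 0:
        return {"lumen": 0.0, "clot_body": 0.0, "channel": 0.0}
    if t <= t_a:
        lum = lumen_enh
    else:
        lum = lumen_enh * max(0.0, 1.0 - spec.lumen_washout_per_s * (t - t_a))
    return {
        "lumen": lum,
        "clot_body": spec.clot_uptake.at(t, t_a),
        "channel": spec.channel_uptake.at(t, t_a),
    }


def _enhancement_field(
    spec: PhantomSpec, w: dict[str, np.ndarray], lumen_enh: float, t: float
) -> np.ndarray:
    """Noise-free contrast enhancement (HU) at time ``t``, weight-blended."""
    enh = _region_enhancements(spec, lumen_enh, t)
    return (
        enh["lumen"] * w["lumen"]
        + enh["clot_body"] * w["clot_body"]
        + enh["channel"] * w["channel"]
    )


def _apply_psf(field: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Band-limit a rendered field with the scanner PSF (Gaussian, mm)."""
    if spec.psf_sigma_mm <= 0:
        return field
    from scipy.ndimage import gaussian_filter

    sigma_vox = spec.psf_sigma_mm / np.asarray(spec.grid.spacing)
    return gaussian_filter(field, sigma=sigma_vox, mode="nearest")


def _render_phase(
    template: AnatomyTemplate,
    spec: PhantomSpec,
    clot_hu: float,
    lumen_enh: float,
    t: float,
    jitter: Optional[RigidTransform],
    rng: np.random.Generator,
) -> np.ndarray:
    if jitter is None:
        w = template.unjittered_weights()
        tex = template._texture_unjittered
    else:
        pts = jitter.apply_points(template.world)
        w = template.weights(pts)
        tex = template.texture(pts)
    hu = _compose_base(spec, w, tex, clot_hu)
    hu = hu + _enhancement_field(spec, w, lumen_enh, t)
    hu = _apply_psf(hu.reshape(template.grid.shape), spec)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    return hu


def _compose_base(
    spec: PhantomSpec, w: dict[str, np.ndarray], tex: np.ndarray, clot_hu: float
) -> np.ndarray:
    """Noise-free pre-contrast anatomy, blended outside-in by region weight."""

    def lerp(cur, val, wt):
        return cur * (1.0 - wt) + val * wt

    hu = np.full(len(tex), spec.air_hu)
    hu = lerp(hu, spec.bone_hu, w["head"])
    hu = lerp(hu, spec.background_hu + tex, w["brain"])
    hu = lerp(hu, 8.0, w["ventricle"])  # CSF
    hu = lerp(hu, 150.0, w["calcification"])
    hu = lerp(hu, spec.blood_hu, w["vessel"])
    return lerp(hu, clot_hu, w["clot"])


def generate_patient(
    spec: PhantomSpec,
    patient_id: str = "phantom",
    template: Optional[AnatomyTemplate] = None,
) -> PhantomPatient:
    """Render one synthetic patient (NCCT, CTA, CTV, mask, ground truth).

    Deterministic for a given spec: the same seed yields bit-identical
    volumes. A prebuilt :class:`AnatomyTemplate` may be passed to share one
    anatomy across a cohort; it must have been built from a spec with the
    same grid and anatomy seed.
    """
    if template is None:
        template = AnatomyTemplate(spec)
    elif not template.grid.matches(spec.grid):
        raise SpecError("anatomy template grid does not match spec grid")

    rng = np.random.default_rng(int(spec.seed))
    clot_hu = float(rng.uniform(*spec.clot_hu_range))
    lumen_enh = float(rng.uniform(*spec.lumen_enhancement_range))
    if spec.delay_s is not None:
        delay = float(spec.delay_s)
    else:
        delay = float(rng.normal(spec.delay_mean_s, spec.delay_sd_s))
        while delay < spec.delay_min_s:
            delay = float(rng.normal(spec.delay_mean_s, spec.delay_sd_s))

    jitters: dict[str, Optional[RigidTransform]] = {"NCCT": None, "CTA": None, "CTV": None}
    if spec.misalignment is not None:
        for phase in ("CTA", "CTV"):
            jitters[phase] = _draw_misalignment(rng, spec.misalignment, template.center)

    t_a = spec.cta_time_s
    ncct_vox = _render_phase(template, spec, clot_hu, lumen_enh, 0.0, jitters["NCCT"], rng)
    cta_vox = _render_phase(template, spec, clot_hu, lumen_enh, t_a, jitters["CTA"], rng)
    ctv_vox = _render_phase(
        template, spec, clot_hu, lumen_enh, t_a + delay, jitters["CTV"], rng
    )

    grid = template.grid
    ncct = CTVolume(ncct_vox, grid, phase="NCCT")
    cta = CTVolume(cta_vox, grid, phase="CTA")
    ctv = CTVolume(ctv_vox, grid, phase="CTV", delay_s=delay)
    mask = template.mask()

    # noise-free per-voxel truth on the unjittered grid; the base anatomy is
    # identical across phases, so the true phase differences are the blended
    # signed enhancement fields (blurred like the renders — blur is linear)
    w = template.unjittered_weights()
    early = _enhancement_field(spec, w, lumen_enh, t_a)
    late_signed = _enhancement_field(spec, w, lumen_enh, t_a + delay) - early
    shape = grid.shape
    early = _apply_psf(early.reshape(shape), spec)
    late_signed = _apply_psf(late_signed.reshape(shape), spec)
    base = _apply_psf(
        _compose_base(spec, w, template._texture_unjittered, clot_hu).reshape(shape), spec
    )
    ncct_clot_mean = float(base[mask.as_bool()].mean())
    truth = PhantomTruth(
        mask=mask,
        early_uptake=np.clip(early, 0.0, None),
        late_uptake=np.clip(late_signed, 0.0, None),
        washout=np.clip(-late_signed, 0.0, None),
        applied_misalignment=jitters,
        expected_alignment={
            k: (None if t is None else t.inverse()) for k, t in jitters.items()
        },
        delay_s=delay,
        clot_hu=clot_hu,
        lumen_enhancement_hu=lumen_enh,
        expected_ncct_clot_mean=ncct_clot_mean,
    )
    return PhantomPatient(patient_id, ncct, cta, ctv, mask, truth, spec=spec)


# ---------------------------------------------------------------------------
# cohort mode


@dataclass(frozen=True)
class GroupEffect:
    """How one clinical group differs: uptake effect and covariate ranges."""

    late_amp_multiplier: float = 1.0
    nihss_range: tuple[int, int] = (0, 42)
    tici_choices: tuple[str, ...] = TICI_TOKENS
    passes_range: tuple[int, int] = (1, 8)
    delay_shift_s: float = 0.0


@dataclass
class CohortMember:
    patient_id: str
    group: str
    spec: PhantomSpec
    record: PatientRecord


@dataclass
class PhantomCohort:
    members: list[CohortMember]
    base_spec: PhantomSpec
    template: AnatomyTemplate

    @property
    def records(self) -> list[PatientRecord]:
        return [m.record for m in self.members]

    def iter_patients(self):
        """Yield ``(PhantomPatient, PatientRecord)`` lazily (volumes are
        rendered on demand and can be dropped by the caller)."""
        for m in self.members:
            yield generate_patient(m.spec, m.patient_id, template=self.template), m.record


def generate_cohort(
    base_spec: PhantomSpec,
    n_per_group: int,
    group_effects: dict[str, GroupEffect],
    seed: int = 0,
) -> PhantomCohort:
    """Plan a cohort of phantom patients with a known group structure.

    Per patient, the late-uptake (channel) amplitude is the base amplitude
    times the group multiplier times a lognormal biological factor
    (CV ``base_spec.uptake_amp_cv``); the clot-body amplitude gets an
    independent lognormal factor. Delays are drawn iid from the base delay
    distribution (plus any per-group shift for planted-bias experiments) and
    covariates are drawn from the group's ranges. Volumes are rendered
    lazily by :meth:`PhantomCohort.iter_patients`; all patients share the
    base spec's anatomy template.
    """
    if not group_effects:
        raise SpecError("group_effects must not be empty")
    if int(n_per_group) < 1:
        raise SpecError(f"n_per_group must be >= 1, got {n_per_group}")

    anatomy_seed = (
        base_spec.anatomy_seed if base_spec.anatomy_seed is not None else base_spec.seed
    )
    base_spec = replace(base_spec, anatomy_seed=anatomy_seed)
    template = AnatomyTemplate(base_spec)

    n_total = int(n_per_group) * len(group_effects)
    children = np.random.SeedSequence(int(seed)).spawn(n_total + 1)
    cov_rng = np.random.default_rng(children[0])
    sigma = float(np.sqrt(np.log1p(base_spec.uptake_amp_cv**2)))

    members: list[CohortMember] = []
    i = 0
    for group, effect in group_effects.items():
        for _ in range(int(n_per_group)):
            i += 1
            pid = f"sim{i:03d}"
            child_seed = int(children[i].generate_state(1)[0] % (2**31))

            delay = float(cov_rng.normal(base_spec.delay_mean_s, base_spec.delay_sd_s))
            while delay < base_spec.delay_min_s:
                delay = float(cov_rng.normal(base_spec.delay_mean_s, base_spec.delay_sd_s))
            delay += effect.delay_shift_s

            chan_factor = effect.late_amp_multiplier * float(
                np.exp(cov_rng.normal(0.0, sigma))
            )
            body_factor = float(np.exp(cov_rng.normal(0.0, sigma)))
            spec_i = replace(
                base_spec,
                seed=child_seed,
                delay_s=delay,
                channel_uptake=replace(
                    base_spec.channel_uptake,
                    amp_hu=base_spec.channel_uptake.amp_hu * chan_factor,
                ),
                clot_uptake=replace(
                    base_spec.clot_uptake,
                    amp_hu=base_spec.clot_uptake.amp_hu * body_factor,
                ),
            )
            record = PatientRecord(
                patient_id=pid,
                nihss_admission=int(cov_rng.integers(effect.nihss_range[0], effect.nihss_range[1] + 1)),
                tici=str(cov_rng.choice(list(effect.tici_choices))),
                n_passes=int(cov_rng.integers(effect.passes_range[0], effect.passes_range[1] + 1)),
                cta_ctv_delay_s=delay,
            )
            members.append(CohortMember(pid, group, spec_i, record))
    return PhantomCohort(members=members, base_spec=base_spec, template=template)
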