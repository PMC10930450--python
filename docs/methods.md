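# Methods

This note records the models, parameter choices and numerical decisions
behind `pervimap`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Pipeline model

One patient contributes three CT volumes — non-contrast (NCCT), arterial
(CTA) and late venous (CTV, acquired a variable delay after CTA) — and a
binary clot segmentation on the NCCT grid. Processing is:

1. **Resampling.** All phases are resampled to a uniform reference grid,
   by default 512 × 512 × 240 voxels at 0.5 × 0.5 × 0.7 mm. Images use
   trilinear interpolation, masks nearest-neighbour (masks must stay
   binary). Voxels outside a source field of view are filled with air
   (−1024 HU) and excluded through an explicit validity mask, so volume
   borders can never produce spurious attenuation differences.
2. **Rigid co-registration.** CTA and CTV are registered to the NCCT:
   6-DOF Euler transform, Mattes mutual-information metric (32 bins, 20%
   random sampling with a fixed seed), three resolution levels
   (shrink 4/2/1, smoothing 2/1/0 voxels), regular-step gradient descent
   (learning rate 1.0, minimum step 5 × 10⁻⁵, ≤150 iterations per level).
   Mutual information is retained rather than a mono-modality metric
   because contrast enhancement changes the intensity relationship between
   phases. Registration and grid resampling are composed into a single
   interpolation pass. Non-convergence is reported, never raised.
   On structured phantoms this recovers perturbations ≤5 mm / ≤3° with
   median errors ≈0.01 mm and ≈0.35°; the rotation noise floor of the
   sampled metric is ~0.1–0.3°, which is why the self-registration test
   uses a 5 × 10⁻³ rad tolerance rather than zero.
3. **Perviousness maps.** Voxel-wise thrombus attenuation increase (TAI):
   P1 = CTA − NCCT, P2 = CTV − CTA, P3 = CTA − CTV, each clipped at zero so
   it carries only standard perviousness, late uptake, or early washout.
   Two invariants follow and are property-tested: P2 − P3 = CTV − CTA on
   valid voxels, and min(P2, P3) = 0 voxel-wise. No smoothing or denoising
   is applied before subtraction.
4. **Summaries.** Per-thrombus means of each map are taken over the mask
   intersected with the common validity of all maps — one voxel set for all
   three means — with clipped zeros included (the mean describes the whole
   segmented volume, not only enhancing voxels). Thrombus volume is voxel
   count × voxel volume (0.175 mm³ on the default grid).
5. **Group statistics.** Patients are binned by NIHSS at admission
   (0–4, 5–15, 16–20, 21–42), TICI (IIa,b / IIc / III, plus a merged
   IIa,b,c vs III scheme) and MT passes (<4 / ≥4). Contrasts are the
   severe NIHSS bin against each lower bin, TICI III against each partial
   group, and the two pass bins. Each contrast uses the two-sided
   Wilcoxon–Mann–Whitney test: exact p by full enumeration when
   n₁ + n₂ ≤ 12 and the data are tie-free, otherwise the normal
   approximation with tie-corrected variance and continuity correction
   (the same large-sample treatment as Matlab's `ranksum`). Requesting the
   exact method on tied data warns and falls back to the approximation.
   Raw p-values are reported with the strict rule p < 0.05; values in
   [0.05, 0.06) are flagged "borderline" separately, and a Holm-adjusted
   column is available but off by default (single-test reporting is the
   field's convention for these small exploratory cohorts). The same
   machinery applied to the CTA→CTV delay serves as an acquisition-bias
   check. Groups with fewer than two members are skipped with a warning.

The classical scalar measures are included for comparison: the two-phase
TAI from three small spherical ROIs (voxel membership: voxel centre inside
the sphere; the scalar may be negative — no clipping) and the void fraction
Δthrombus/Δblood, undefined for non-positive contralateral enhancement.

## Synthetic phantom

The generator renders a simplified head in world coordinates: a triaxial
brain ellipsoid (semiaxes 0.45/0.38/0.42 of the grid extent — axially
non-circular so that rigid orientation is observable) inside a bony shell,
two CSF-dark ventricles and one small calcification as asymmetric
landmarks, a smooth Gaussian-blob texture (SD 6 HU), and one straight
vessel (radius 2 mm, blood 45 HU) carrying a clot segment (baseline drawn
from 55–75 HU — the hyperdense artery sign) with an off-centre pervious
channel (radius 0.4, offset 0.3 of the vessel radius).

**Partial volume.** All region boundaries are sigmoid profiles of the
signed distance with width `edge_sigma_mm` = 0.5 mm. This world-space
band-limiting is essential: binary regions sampled at different sub-voxel
phases alias tens of HU at the ~300 HU lumen/clot interface, which would
make renders of the same patient under different rigid jitters mutually
inconsistent no matter how good the registration. A consequence is that
the in-mask NCCT mean sits a few HU below the nominal clot baseline
(boundary voxels blend with blood and brain); the generator reports its own
constructed value (`truth.expected_ncct_clot_mean`) for tests.

**Contrast kinetics** (the package's own model — two sampling times cannot
identify a kinetic law, so the simplest one producing distinct P1/P2/P3
signatures was chosen): each region takes up contrast as
u(t) = A·(1 − e^(−t/τ)) from contrast arrival, optionally decaying
linearly after the arterial time t_a = 20 s. Defaults: clot body
A = 10 HU, τ = 12 s, washout 0.002 s⁻¹ (fast, saturating, slowly washing
out → contributes to P1 and P3); channel A = 50 HU, τ = 120 s (slow,
unsaturated → dominates P2); patent lumen enhances by 200–400 HU at CTA and
decays at 0.004 s⁻¹. Enhanced lumen stops 1.5 mm short of the clot faces
(`stasis_margin_mm` — contrast stasis at an occlusion), so lumen
enhancement does not bleed into the mask. The CTA→CTV delay is drawn from
N(70 s, 28 s) truncated at ≥10 s, the spread of an acute multiphase
protocol. Gaussian noise (SD 4 HU) is added per phase; CTA and CTV can be
independently jittered by rigid transforms (default ≤2 mm, ≤1°), with both
the applied and the to-be-recovered transforms recorded.

Because base anatomy cancels in phase differences and all blending is
linear, the expected P1/P2/P3 maps are closed-form (the blended signed
enhancement fields, clipped), and the noise-free aligned pipeline
reproduces them to machine precision — the basis of the oracle-equivalence
test.

**Cohort mode** plans n patients per clinical group. Per patient, the
channel amplitude is (base × group multiplier × lognormal factor with
CV 0.35) — the biological variability chosen to reproduce group SDs of the
same order as group means, as reported for real cohorts; the body amplitude
gets an independent lognormal factor; covariates (NIHSS, TICI, passes) are
drawn from the group's ranges and delays are drawn iid across groups unless
a shift is planted deliberately. All patients in a simulated cohort share
one anatomy template (a standardized-anatomy simplification that makes
1000-replicate simulations tractable; the group statistics operate on
per-patient summaries, which remain fully heterogeneous in amplitude, clot
density, delay and noise). Cohort simulations default to a 24³ voxel,
1 mm-in-plane grid with misalignment off; single-patient phantoms default
to 96³ at 0.5/0.5/0.7 mm with misalignment on.

## What the simulations show — and what they do not

The simulation suite establishes that (i) the map algebra and summaries are
exact; (ii) the rank-sum implementation matches a full-enumeration oracle;
(iii) the end-to-end cohort comparison holds its nominal type-I error
(exactly computable as 0.0491 for n = 20 + 20 at the asymptotic rule; 1000
replicates land within ±0.02 of 0.05); (iv) a 2:1 late-uptake amplitude
contrast at n = 20 per group and 4 HU noise is detected in ≥95% of
replicates; (v) registration recovers rigid perturbations to well under
half a voxel; and (vi) iid delays almost never produce a spurious delay
"bias" signal. They do not establish anything about scanner-specific HU
calibration, beam hardening, motion artifacts, anatomical variability,
segmentation error, or the clinical validity of the late-uptake effect —
the phantom's kinetics are a modelling convenience, not a physiological
claim.

## Numerical and design choices

- HU are held as float64 after ingestion; NIfTI-1 is the interchange
  format; all geometry comparisons are in world millimetres (ITK/LPS
  frame), with 10⁻³ mm tolerance for grid identity checks.
- Masks are assumed aligned to the NCCT and are carried to the reference
  grid by nearest-neighbour resampling; they are not propagated through the
  registration transforms (the NCCT is the fixed image, so its mask applies
  to the registered phases).
- The registration-adequacy check compares misaligned-then-registered
  against perfectly aligned phantoms on noise-free data with a tolerance of
  max(10% of the reference mean, 0.75 HU): noise-free isolates registration
  and resampling from the clipping-bias asymmetry that interpolation
  introduces on noisy data, and the absolute floor covers map means that
  are themselves far below CT noise (a relative bound on a 0.2 HU mean is
  not meaningful).
- Lower TICI grades (0, I) are rejected at ingestion; the cohort schemes
  are total over NIHSS 0–42, passes ≥1 and TICI {IIa, IIb, IIc, III}
  (property-swept).
- Exact Mann–Whitney mode refuses tied data (falls back with a warning)
  because midrank ties break the permutation-count identity the exact
  distribution assumes.
- Problem sizes in tests and in `scripts/acceptance.py` — 24³ cohort
  phantoms, 96³ registration phantoms, 1000/100/1000 replicates for
  type-I/power/delay-null — are the package's desk-scale defaults; all are
  parameters, and the full clinical 512 × 512 × 240 grid is supported
  throughout.

## Known limitations

- The phantom vessel is straight and the anatomy is schematic; mutual
  information behaves differently on real, texture-rich brains.
- Clipped-difference means are biased upward by noise (E[max(X, 0)] > 0 for
  zero-mean X); the bias is identical across groups and therefore cancels
  in the comparisons, but absolute map means depend on noise level.
- The delay enters the kinetics only through the uptake law; perfusion
  physics (bolus shape, recirculation) is not modelled.
- DICOM ingestion, deformable registration, skull stripping and automatic
  clot segmentation are out of scope.
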