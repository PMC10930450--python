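# pervimap

Voxel-wise **dynamic perviousness** mapping of occlusive thrombi from
multiphase CT in acute ischemic stroke.

## The problem

When a clot occludes a cerebral artery, the degree to which iodinated
contrast penetrates it — its *perviousness* — reflects clot structure and
has been studied as a predictor of mechanical-thrombectomy (MT) success.
The classical measure is the thrombus attenuation increase (TAI): the mean
Hounsfield-unit (HU) difference of the clot between non-contrast CT (NCCT)
and CT angiography (CTA), usually from three small spherical ROIs on a
single slice. That measure ignores both the third acquisition of a
three-phase stroke protocol (a late venous-phase scan, CTV, acquired tens of
seconds after CTA) and the spatial heterogeneity of the 3D clot.

`pervimap` implements the *dynamic* extension for whole-clot volumes. After
resampling all phases to a common grid and rigidly co-registering CTA and
CTV to the NCCT, it computes three voxel-wise maps

```
P1 = CTA − NCCT    (standard perviousness)
P2 = CTV − CTA     (late contrast uptake)
P3 = CTA − CTV     (early contrast washout)
```

with negative voxels set to zero, so that each map carries only its own
component (hence `P2 − P3` reconstructs the raw `CTV − CTA` difference and
no voxel is positive in both). Mean `P1`/`P2`/`P3` over the segmented 3D
clot are summarized per patient and compared between clinical groups —
stroke severity (NIHSS at admission: 0–4 / 5–15 / 16–20 / 21–42),
reperfusion grade (TICI IIa,b / IIc / III, plus III vs the merged partial
grades), and number of MT passes (<4 / ≥4) — with the two-sided
Wilcoxon–Mann–Whitney test (significance at p < 0.05). A companion check
compares the CTA→CTV delay between the same groups, since a delay imbalance
could masquerade as an uptake effect.

Because no patient data ship with the package, a synthetic multiphase
phantom generator (`pervimap.phantom`) produces NCCT/CTA/CTV triplets with a
hyperdense clot, a pervious channel with saturating contrast kinetics,
partial-volume boundaries, CT noise, inter-phase rigid motion, and clinical
covariates — with closed-form expected map values, so every pipeline stage
is testable against known truth.

Intended users: neuroimaging researchers reproducing or extending
perviousness analyses, and methodologists who need a fully synthetic,
ground-truthed multiphase-CT test bed.

## Worked example

Simulate a 2×5-patient cohort in which group A's pervious channel takes up
contrast twice as fast as group B's, then run the full pipeline on the
written NIfTI volumes:

```bash
pervimap simulate --out sim --n-per-group 5 --effect 2.0 --grid-size 32 --seed 7
pervimap process --manifest sim/manifest.csv --cohort-table sim/cohort.csv \
    --out results --grid 32x32x32@1x1x1 --schemes PASSES --no-registration
```

which prints:

```
wrote sim001 (delay 52 s)
wrote sim002 (delay 96 s)
...
wrote sim010 (delay 89 s)
cohort of 10 phantom patients in sim
processed 10 patient(s); 4 comparison(s), 3 significant; report in results
```

`results/summaries.csv` holds one row per patient (mean P1/P2/P3 in HU,
clot volume in mm³); `results/comparisons.csv` holds the group contrasts
(values rounded here):

```
scheme,metric,          group_a,group_b,n_a,n_b,mean_a,sd_a, mean_b,sd_b, u_statistic,p_value,method,significant
PASSES,mean_P2,         <4,     >=4,    5,  5,  11.03, 3.42, 4.52,  0.73, 24.0,       0.0159, exact, True
PASSES,cta_ctv_delay_s, <4,     >=4,    5,  5,  63.61, 22.61,77.83, 6.39, 8.0,        0.4206, exact, False
```

Read: the five patients needing fewer than four passes average 11.0 HU of
late uptake against 4.5 HU for the others — the planted 2:1 effect —
significant even at n = 5 + 5 (exact p = 0.016), while their CTA→CTV delays
do not differ (p = 0.42), so the uptake contrast is not an acquisition
artifact. On real data you would drop `--no-registration` and point the
manifest at your NCCT/CTA/CTV volumes and NCCT-space clot masks (NIfTI-1).

The same machinery is available as a library:

```python
import pervimap as pm

patient = pm.generate_patient(pm.PhantomSpec(seed=7))
maps = pm.compute_all_maps(patient.ncct, patient.cta, patient.ctv)
print(pm.summarize(maps, patient.mask, "demo"))
```

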