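"""Per-patient processing and cohort analysis orchestration.

``run_patient`` executes the four postprocessing stages for one patient —
resample to the reference grid, rigid co-registration of CTA/CTV to NCCT,
perviousness-map computation, per-thrombus summary — and ``run_cohort``
joins the summaries to the clinical table and runs the group comparisons
plus the delay bias check. One failing patient never stops the cohort: the
failure is recorded and processing continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import cohort as cohort_stats
from .errors import InputError, PervimapError
from .geometry import ReferenceGrid
from .io import (
    CTVolume,
    PatientRecord,
    ThrombusMask,
    read_cohort_table,
    read_mask,
    read_volume,
    write_volume,
)
from .perviousness import ThrombusSummary, compute_all_maps, summarize
from .phantom import PhantomCohort
from .preprocess import apply_transform, register_rigid, resample_mask_to_grid, resample_to_grid

__all__ = [
    "RunConfig",
    "PatientResult",
    "run_patient",
    "run_cohort",
    "process_phantom_cohort",
    "summaries_to_frame",
]

log = logging.getLogger(__name__)

DEFAULT_SCHEMES = ("NIHSS", "TICI", "TICI_MERGED", "PASSES")
DEFAULT_METRICS = ("mean_P1", "mean_P2", "mean_P3")

MANIFEST_COLUMNS = ["patient_id", "ncct_path", "cta_path", "ctv_path", "mask_path"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    manifest: Path
    cohort_table: Path
    output_dir: Path
    grid: ReferenceGrid = field(default_factory=ReferenceGrid.clinical_default)
    registration_enabled: bool = True
    registration_max_iterations: int = 200
    schemes: tuple[str, ...] = DEFAULT_SCHEMES
    metrics: tuple[str, ...] = DEFAULT_METRICS
    exact_test: str = "auto"
    figures: bool = False
    write_maps: bool = True
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        grid = ReferenceGrid.clinical_default()
        if "grid" in raw:
            g = raw["grid"]
            grid = ReferenceGrid(
                shape=tuple(int(v) for v in g["shape"]),
                spacing=tuple(float(v) for v in g["spacing"]),
                origin=tuple(float(v) for v in g.get("origin", (0.0, 0.0, 0.0))),
            )
        reg = raw.get("registration", {})
        try:
            return cls(
                manifest=_resolve(raw["manifest"]),
                cohort_table=_resolve(raw["cohort_table"]),
                output_dir=_resolve(raw.get("output_dir", "pervimap_out")),
                grid=grid,
                registration_enabled=bool(reg.get("enabled", True)),
                registration_max_iterations=int(reg.get("max_iterations", 200)),
                schemes=tuple(raw.get("schemes", DEFAULT_SCHEMES)),
                metrics=tuple(raw.get("metrics", DEFAULT_METRICS)),
                exact_test=str(raw.get("exact_test", "auto")),
                figures=bool(raw.get("figures", False)),
                write_maps=bool(raw.get("write_maps", True)),
                seed=int(raw.get("seed", 1)),
            )
        except KeyError as exc:
            raise InputError(f"config {path} missing required key {exc}") from exc

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = {
            "manifest": str(self.manifest),
            "cohort_table": str(self.cohort_table),
            "output_dir": str(self.output_dir),
            "grid": {
                "shape": list(self.grid.shape),
                "spacing": list(self.grid.spacing),
                "origin": list(self.grid.origin),
            },
            "registration": {
                "enabled": self.registration_enabled,
                "max_iterations": self.registration_max_iterations,
            },
            "schemes": list(self.schemes),
            "metrics": list(self.metrics),
            "exact_test": self.exact_test,
            "figures": self.figures,
            "write_maps": self.write_maps,
            "seed": self.seed,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path


@dataclass
class PatientResult:
    patient_id: str
    summary: Optional[ThrombusSummary]
    error: Optional[str] = None
    registration_converged: Optional[bool] = None

    @property
    def ok(self) -> bool:
        return self.summary is not None


def run_patient(
    patient_id: str,
    ncct: CTVolume,
    cta: CTVolume,
    ctv: CTVolume,
    mask: ThrombusMask,
    grid: ReferenceGrid,
    register: bool = True,
    seed: int = 1,
    max_iterations: int = 200,
    out_dir: Optional[Path] = None,
) -> tuple[ThrombusSummary, dict]:
    """Resample -> register -> map -> summarize for one patient.

    The clot mask is defined on the native NCCT grid and is carried onto the
    reference grid by nearest-neighbour resampling; the registration of
    CTA/CTV to NCCT means the NCCT-defined mask applies to all phases.
    Returns the summary and a per-stage info dict (timings, convergence).
    """
    info: dict = {"patient_id": patient_id}

    t0 = time.perf_counter()
    ncct_g = resample_to_grid(ncct, grid)
    mask_vol = CTVolume(mask.voxels.astype(float), mask.grid)
    mask_g = ThrombusMask(resample_mask_to_grid(mask_vol, grid).voxels, grid)
    info["t_resample_s"] = time.perf_counter() - t0

    aligned = {"NCCT": ncct_g}
    info["registration"] = {}
    t0 = time.perf_counter()
    for phase, vol in (("CTA", cta), ("CTV", ctv)):
        if register:
            reg = register_rigid(vol, ncct_g, seed=seed, max_iterations=max_iterations)
            aligned[phase] = apply_transform(vol, reg.transform, grid)
            info["registration"][phase] = {
                "converged": reg.converged,
                "metric": reg.metric_value,
                "iterations": reg.n_iterations,
            }
            if not reg.converged:
                log.warning("%s: %s registration unconverged", patient_id, phase)
        else:
            aligned[phase] = resample_to_grid(vol, grid)
    info["t_register_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    maps = compute_all_maps(aligned["NCCT"], aligned["CTA"], aligned["CTV"])
    summary = summarize(maps, mask_g, patient_id)
    info["t_maps_s"] = time.perf_counter() - t0

    if out_dir is not None:
        out_dir = Path(out_dir)
        for kind, pmap in maps.items():
            write_volume(pmap.to_volume(), out_dir / f"{patient_id}_{kind}.nii.gz")
    log.info(
        "%s: mean P1/P2/P3 = %.2f/%.2f/%.2f HU over %d voxels",
        patient_id, summary.mean_P1, summary.mean_P2, summary.mean_P3, summary.n_voxels,
    )
    return summary, info


def _run_patient_from_paths(row, config: RunConfig) -> tuple[ThrombusSummary, dict]:
    paths = {
        "NCCT": row["ncct_path"],
        "CTA": row["cta_path"],
        "CTV": row["ctv_path"],
    }
    for phase, p in paths.items():
        if not p or pd.isna(p) or not Path(p).exists():
            raise InputError(f"missing phase: {phase}")
    if not row["mask_path"] or pd.isna(row["mask_path"]) or not Path(row["mask_path"]).exists():
        raise InputError("missing mask")
    ncct = read_volume(paths["NCCT"], phase="NCCT")
    cta = read_volume(paths["CTA"], phase="CTA")
    ctv = read_volume(paths["CTV"], phase="CTV")
    mask = read_mask(row["mask_path"], reference=ncct)
    return run_patient(
        str(row["patient_id"]), ncct, cta, ctv, mask,
        grid=config.grid,
        register=config.registration_enabled,
        seed=config.seed,
        max_iterations=config.registration_max_iterations,
        out_dir=(config.output_dir / "maps") if config.write_maps else None,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])


def run_cohort(config: RunConfig) -> dict:
    """Run the whole pipeline from a resolved config; returns result frames."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(config.output_dir / "resolved_config.yaml")

    manifest = pd.read_csv(config.manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest {config.manifest} missing column(s) {missing}")
    records = read_cohort_table(config.cohort_table)

    record_ids = {r.patient_id for r in records}
    manifest_ids = {str(p) for p in manifest["patient_id"]}
    orphans = sorted(record_ids ^ manifest_ids)
    if orphans:
        raise InputError(
            f"cohort table and manifest do not match; orphan patient id(s): {orphans}"
        )

    results: list[PatientResult] = []
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        try:
            summary, info = _run_patient_from_paths(row, config)
            results.append(PatientResult(pid, summary))
        except PervimapError as exc:
            log.error("patient %s failed: %s", pid, exc)
            results.append(PatientResult(pid, None, error=str(exc)))

    ok = [r for r in results if r.ok]
    status = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "status": ["ok" if r.ok else "failed" for r in results],
            "error": [r.error or "" for r in results],
        }
    )
    status.to_csv(config.output_dir / "patients.csv", index=False)
    if len(ok) < 2:
        raise InputError(f"only {len(ok)} patient(s) processed successfully; need >= 2")

    summaries = summaries_to_frame([r.summary for r in ok])
    summaries.to_csv(config.output_dir / "summaries.csv", index=False)

    comparisons = []
    if not config.schemes:
        log.warning("no comparison schemes requested; writing summaries only")
    for scheme_name in config.schemes:
        scheme = cohort_stats.SCHEMES[scheme_name]()
        for metric in config.metrics:
            comparisons.extend(
                cohort_stats.compare_groups(
                    summaries, metric, scheme, records=records, mode=config.exact_test
                )
            )
        comparisons.extend(
            cohort_stats.delay_bias_check(
                [r for r in records if r.patient_id in {x.patient_id for x in ok}],
                scheme,
                mode=config.exact_test,
            )
        )
    report = cohort_stats.comparisons_to_frame(comparisons)
    report.to_csv(config.output_dir / "comparisons.csv", index=False)

    if config.figures and comparisons:
        _write_figures(summaries, records, config)
    return {"summaries": summaries, "comparisons": report, "status": status}


def _write_figures(summaries: pd.DataFrame, records, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_id = {r.patient_id: r for r in records}
    fig_dir = config.output_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for scheme_name in config.schemes:
        scheme = cohort_stats.SCHEMES[scheme_name]()
        groups = [cohort_stats.assign_group(by_id[p], scheme) for p in summaries["patient_id"]]
        for metric in list(config.metrics) + ["cta_ctv_delay_s"]:
            if metric == "cta_ctv_delay_s":
                values = [by_id[p].cta_ctv_delay_s for p in summaries["patient_id"]]
            else:
                values = summaries[metric].tolist()
            data = {lab: [] for lab in scheme.labels}
            for g, v in zip(groups, values):
                data[g].append(v)
            fig, ax = plt.subplots(figsize=(4, 3))
            labels = [lab for lab in scheme.labels if data[lab]]
            ax.boxplot([data[lab] for lab in labels], tick_labels=labels)
            ax.set_ylabel("delay [s]" if metric == "cta_ctv_delay_s" else f"{metric} [HU]")
            ax.set_title(f"{scheme.name}")
            fig.tight_layout()
            fig.savefig(fig_dir / f"{scheme.name}_{metric}.png", dpi=120)
            plt.close(fig)


# ---------------------------------------------------------------------------
# phantom cohorts


def process_phantom_cohort(
    cohort: PhantomCohort, register: bool = False, seed: int = 1
) -> pd.DataFrame:
    """Summaries for every phantom patient, joined to covariates and group.

    Volumes are rendered, mapped and discarded one patient at a time. With
    ``register=False`` the phases are used as generated (appropriate when
    the cohort was generated without misalignment).
    """
    grid = cohort.base_spec.grid
    rows = []
    for patient, record in cohort.iter_patients():
        if register:
            summary, _ = run_patient(
                patient.patient_id, patient.ncct, patient.cta, patient.ctv,
                patient.mask, grid=grid, register=True, seed=seed,
            )
        else:
            maps = compute_all_maps(patient.ncct, patient.cta, patient.ctv)
            summary = summarize(maps, patient.mask, patient.patient_id)
        row = summary.as_dict()
        row.update(
            {
                "phantom_group": next(
                    m.group for m in cohort.members if m.patient_id == patient.patient_id
                ),
                "nihss_admission": record.nihss_admission,
                "tici": record.tici,
                "n_passes": record.n_passes,
                "cta_ctv_delay_s": record.cta_ctv_delay_s,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
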