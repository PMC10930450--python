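"""Clinical grouping and nonparametric group comparison.

Patients are stratified by stroke severity (NIHSS at admission), angiographic
reperfusion grade (TICI) or number of thrombectomy passes, and per-thrombus
map means are compared between groups with the two-sided
Wilcoxon-Mann-Whitney rank-sum test. The same machinery applied to the
CTA->CTV acquisition delay serves as a bias check: a real uptake effect
should not be explainable by systematically longer delays in one group.

Comparison plans follow the clinical contrasts of interest: the most severe
NIHSS bin against each milder bin; complete reperfusion (TICI III) against
partial grades; few (<4) against many (>=4) passes. Raw p-values are
reported without multiple-testing correction (an optional Holm-adjusted
column is available); the strict rule p < 0.05 flags significance and
borderline values (0.05 <= p < 0.06) are flagged separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ValidationError
from .io import PatientRecord

__all__ = [
    "GroupingScheme",
    "GroupComparison",
    "MannWhitneyResult",
    "SCHEMES",
    "nihss_scheme",
    "tici_scheme",
    "tici_merged_scheme",
    "passes_scheme",
    "assign_group",
    "mann_whitney_u",
    "compare_groups",
    "delay_bias_check",
    "comparisons_to_frame",
    "holm_adjust",
]

log = logging.getLogger(__name__)

ALPHA = 0.05
BORDERLINE_UPPER = 0.06

#: Largest combined sample size for which the exact null distribution is
#: enumerated in auto mode (tie-free data only).
EXACT_N_MAX = 12


@dataclass(frozen=True)
class GroupingScheme:
    """Ordered, exhaustive, disjoint bins over valid patient records."""

    name: str
    labels: tuple[str, ...]
    _assign: Callable[[PatientRecord], str]
    #: ordered (group_a, group_b) contrasts evaluated by compare_groups
    comparison_pairs: tuple[tuple[str, str], ...]

    def assign(self, record: PatientRecord) -> str:
        label = self._assign(record)
        if label not in self.labels:  # pragma: no cover - scheme defect guard
            raise ValidationError(f"scheme {self.name} produced unknown label {label!r}")
        return label


def _nihss_label(r: PatientRecord) -> str:
    n = r.nihss_admission
    if n <= 4:
        return "0-4"
    if n <= 15:
        return "5-15"
    if n <= 20:
        return "16-20"
    return "21-42"


def nihss_scheme() -> GroupingScheme:
    """Stroke-severity bins 0-4, 5-15, 16-20, 21-42; severe bin vs each."""
    return GroupingScheme(
        name="NIHSS",
        labels=("0-4", "5-15", "16-20", "21-42"),
        _assign=_nihss_label,
        comparison_pairs=(("21-42", "16-20"), ("21-42", "5-15"), ("21-42", "0-4")),
    )


def tici_scheme() -> GroupingScheme:
    """Reperfusion bins IIa,b / IIc / III; complete (III) vs partial."""
    return GroupingScheme(
        name="TICI",
        labels=("IIa,b", "IIc", "III"),
        _assign=lambda r: "III" if r.tici == "III" else ("IIc" if r.tici == "IIc" else "IIa,b"),
        comparison_pairs=(("III", "IIa,b"), ("III", "IIc")),
    )


def tici_merged_scheme() -> GroupingScheme:
    """TICI III against the union of all partial grades IIa,b,c."""
    return GroupingScheme(
        name="TICI_MERGED",
        labels=("IIa,b,c", "III"),
        _assign=lambda r: "III" if r.tici == "III" else "IIa,b,c",
        comparison_pairs=(("III", "IIa,b,c"),),
    )


def passes_scheme() -> GroupingScheme:
    """Fewer than four retrieval attempts vs four or more."""
    return GroupingScheme(
        name="PASSES",
        labels=("<4", ">=4"),
        _assign=lambda r: "<4" if r.n_passes < 4 else ">=4",
        comparison_pairs=(("<4", ">=4"),),
    )


SCHEMES: dict[str, Callable[[], GroupingScheme]] = {
    "NIHSS": nihss_scheme,
    "TICI": tici_scheme,
    "TICI_MERGED": tici_merged_scheme,
    "PASSES": passes_scheme,
}


def assign_group(record: PatientRecord, scheme: GroupingScheme) -> str:
    """Exactly one bin label for a valid record (schemes are exhaustive)."""
    return scheme.assign(record)


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_tie_corrected"


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    U is computed from midranks for the first sample. The exact two-sided p
    (full enumeration of rank assignments) is used when the data are tie-free
    and, in auto mode, n_x + n_y <= 12; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used — the same
    large-sample treatment as Matlab's ``ranksum``. Requesting exact mode on
    tied data falls back to the approximation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise InputError(f"unknown mode {mode!r}")

    ties = _has_ties(x, y)
    use_exact = False
    if mode == "exact":
        if ties:
            warnings.warn(
                "exact Mann-Whitney requested on tied data; "
                "falling back to tie-corrected normal approximation",
                stacklevel=2,
            )
        else:
            use_exact = True
    elif mode == "auto":
        use_exact = (x.size + y.size) <= EXACT_N_MAX and not ties

    if use_exact:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_tie_corrected"
    p = float(min(res.pvalue, 1.0))
    p = max(p, np.finfo(float).tiny)
    return MannWhitneyResult(u_statistic=float(res.statistic), p_value=p, method=method)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    scheme: str
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    method: str
    significant: bool
    borderline: bool
    p_holm: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def compare_groups(
    data: pd.DataFrame,
    metric: str,
    scheme: GroupingScheme,
    records: Optional[Sequence[PatientRecord]] = None,
    mode: str = "auto",
    min_group_size: int = 2,
    holm: bool = False,
) -> list[GroupComparison]:
    """Pairwise Wilcoxon-Mann-Whitney contrasts of ``metric`` between bins.

    ``data`` is the per-patient table (thrombus summaries joined to clinical
    records). If it lacks a ``group`` column, ``records`` must be given and
    bins are assigned with ``scheme``. Contrasts with a group below
    ``min_group_size`` members are skipped with a warning.
    """
    df = data.copy()
    if "group" not in df.columns:
        if records is not None:
            by_id = {r.patient_id: r for r in records}
            try:
                df["group"] = [assign_group(by_id[p], scheme) for p in df["patient_id"]]
            except KeyError as exc:
                raise InputError(f"no clinical record for patient {exc}") from exc
        elif {"nihss_admission", "tici", "n_passes", "cta_ctv_delay_s"} <= set(df.columns):
            df["group"] = [
                assign_group(
                    PatientRecord(
                        patient_id=str(r.patient_id),
                        nihss_admission=int(r.nihss_admission),
                        tici=str(r.tici),
                        n_passes=int(r.n_passes),
                        cta_ctv_delay_s=float(r.cta_ctv_delay_s),
                    ),
                    scheme,
                )
                for r in df.itertuples(index=False)
            ]
        else:
            raise InputError(
                "need a 'group' column, records, or covariate columns to assign groups"
            )
    if metric not in df.columns:
        raise InputError(f"metric column {metric!r} not in data")

    comparisons: list[GroupComparison] = []
    for a, b in scheme.comparison_pairs:
        va = df.loc[df["group"] == a, metric].to_numpy(dtype=float)
        vb = df.loc[df["group"] == b, metric].to_numpy(dtype=float)
        if va.size < min_group_size or vb.size < min_group_size:
            small = a if va.size < min_group_size else b
            log.warning(
                "scheme %s, metric %s: group %r has %d member(s) (<%d); comparison skipped",
                scheme.name, metric, small,
                min(va.size, vb.size), min_group_size,
            )
            continue
        mw = mann_whitney_u(va, vb, mode=mode)
        comparisons.append(
            GroupComparison(
                scheme=scheme.name,
                metric=metric,
                group_a=a,
                group_b=b,
                n_a=int(va.size),
                n_b=int(vb.size),
                mean_a=float(va.mean()),
                sd_a=_sd(va),
                mean_b=float(vb.mean()),
                sd_b=_sd(vb),
                u_statistic=mw.u_statistic,
                p_value=mw.p_value,
                method=mw.method,
                significant=mw.p_value < ALPHA,
                borderline=ALPHA <= mw.p_value < BORDERLINE_UPPER,
            )
        )
    if holm and comparisons:
        adj = holm_adjust([c.p_value for c in comparisons])
        for c, p in zip(comparisons, adj):
            c.p_holm = p
    return comparisons


def delay_bias_check(
    records: Sequence[PatientRecord],
    scheme: GroupingScheme,
    mode: str = "auto",
    min_group_size: int = 2,
) -> list[GroupComparison]:
    """Compare the CTA->CTV delay between clinical bins (acquisition bias).

    A dynamic-perviousness group effect would be suspect if the groups also
    differed systematically in acquisition delay; all contrasts should be
    non-significant when delays are drawn independently of group.
    """
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "cta_ctv_delay_s": [r.cta_ctv_delay_s for r in records],
            "group": [assign_group(r, scheme) for r in records],
        }
    )
    return compare_groups(df, "cta_ctv_delay_s", scheme, mode=mode, min_group_size=min_group_size)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    cols = [
        "scheme", "metric", "group_a", "group_b", "n_a", "n_b",
        "mean_a", "sd_a", "mean_b", "sd_b",
        "u_statistic", "p_value", "method", "significant", "borderline", "p_holm",
    ]
    return pd.DataFrame([c.as_dict() for c in comparisons], columns=cols)
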