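"""Cohort-level aggregation: eligibility counts, per-entity ranges, derived statistics.

Consumes either a cohort table (one row per case: id, entity group, overall
percent, hot-spot percent or missing) or per-case pipeline results. A case is
"immunopositive" when its overall positivity strictly exceeds the eligibility
threshold (0.05% by default); below-threshold cases were never submitted for
hot-spot analysis, so their hot-spot field is missing — excluded from extrema,
never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .hotspot import HotspotParams, HotspotResult, NoHotspot, find_hotspot
from .io import NEUROBLASTOMA_GROUPS, CellTable, RegionSet
from .positivity import FilterReport, filter_cells, overall_positivity

__all__ = [
    "DEFAULT_THRESHOLD",
    "CaseResult",
    "EntitySummary",
    "CohortSummary",
    "classify_case",
    "quantify_slide",
    "cases_to_table",
    "summarize_cohort",
    "derived_statistics",
    "format_report",
]

#: Eligibility / immunopositivity cutoff, percent of total cells.
DEFAULT_THRESHOLD = 0.05

IMMUNOPOSITIVE = "immunopositive"
IMMUNONEGATIVE = "immunonegative"


@dataclass
class CaseResult:
    """Per-slide pipeline output."""

    case_id: str
    entity_group: str
    overall_percent: float
    eligible: bool
    hotspot: HotspotResult | None
    hotspot_reason: str | None
    filter_report: FilterReport
    qc_flags: list[str] = field(default_factory=list)

    @property
    def hotspot_percent(self) -> float:
        """Hot-spot percent positivity, NaN when not applicable."""
        return self.hotspot.percent_positive if self.hotspot else float("nan")


@dataclass
class EntitySummary:
    entity_group: str
    n: int
    mean_overall: float
    min_overall: float
    max_overall: float
    min_hotspot: float | None
    max_hotspot: float | None


@dataclass
class CohortSummary:
    per_entity: list[EntitySummary]
    n_above_threshold: int
    n_total: int
    threshold: float


def classify_case(overall_percent: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Immunopositive iff overall percent positivity is strictly above the threshold.

    A case at exactly the threshold is immunonegative: the rule is "above",
    not "at least".
    """
    return IMMUNOPOSITIVE if overall_percent > threshold else IMMUNONEGATIVE


def quantify_slide(
    cells: CellTable,
    regions: RegionSet | None = None,
    params: HotspotParams | None = None,
    case_id: str | None = None,
    entity_group: str = "",
) -> CaseResult:
    """Full per-slide pipeline: artifact exclusion → overall % → hot spot → QC flags.

    QC flags replace manual review of the automated output with auditable
    machine warnings: ``zero-positive`` (no positive cell at all),
    ``low-count`` (fewer than 1000 retained cells, so percentages are
    unstable), ``high-exclusion`` (artifact regions removed more than half of
    all detections).
    """
    params = params or HotspotParams()
    retained, report = filter_cells(cells, regions or RegionSet())
    if len(retained) == 0:
        raise EmptyInputError(
            "no cells remain after artifact exclusion; cannot quantify the slide"
        )
    overall = overall_positivity(retained)
    eligible = classify_case(overall, params.eligibility_threshold) == IMMUNOPOSITIVE

    outcome = find_hotspot(retained, params)
    if isinstance(outcome, NoHotspot):
        hotspot, reason = None, outcome.reason
    else:
        hotspot, reason = outcome, None

    qc_flags = []
    if retained.n_positive == 0:
        qc_flags.append("zero-positive")
    if len(retained) < 1000:
        qc_flags.append("low-count")
    if report.n_input and report.n_excluded / report.n_input > 0.5:
        qc_flags.append("high-exclusion")

    return CaseResult(
        case_id=case_id if case_id is not None else cells.slide_id,
        entity_group=entity_group,
        overall_percent=overall,
        eligible=eligible,
        hotspot=hotspot,
        hotspot_reason=reason,
        filter_report=report,
        qc_flags=qc_flags,
    )


def cases_to_table(cases: list[CaseResult]) -> pd.DataFrame:
    """Cohort table (case_id, entity_group, overall_percent, hotspot_percent)
    from pipeline results; ineligible cases get a missing hot-spot value."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "entity_group": [c.entity_group for c in cases],
            "overall_percent": [c.overall_percent for c in cases],
            "hotspot_percent": [c.hotspot_percent for c in cases],
        }
    )


def summarize_cohort(cohort: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> CohortSummary:
    """Per-entity n / mean / range of overall %, range of present hot-spot values,
    and the global count of cases above the threshold."""
    if len(cohort) == 0:
        raise EmptyInputError("cohort table is empty")
    per_entity = []
    for entity, grp in cohort.groupby("entity_group", sort=False):
        hs = grp["hotspot_percent"].dropna()
        per_entity.append(
            EntitySummary(
                entity_group=str(entity),
                n=len(grp),
                mean_overall=float(grp["overall_percent"].mean()),
                min_overall=float(grp["overall_percent"].min()),
                max_overall=float(grp["overall_percent"].max()),
                min_hotspot=float(hs.min()) if len(hs) else None,
                max_hotspot=float(hs.max()) if len(hs) else None,
            )
        )
    n_above = int((cohort["overall_percent"] > threshold).sum())
    return CohortSummary(
        per_entity=per_entity,
        n_above_threshold=n_above,
        n_total=len(cohort),
        threshold=threshold,
    )


def _range_stats(grp: pd.DataFrame) -> dict:
    """Min/max of overall and hot-spot percent with contributing case ids."""
    if len(grp) == 0:
        return {"present": False}
    out = {"present": True, "n": len(grp)}
    for col, key in (("overall_percent", "overall"), ("hotspot_percent", "hotspot")):
        vals = grp[col].dropna()
        if len(vals):
            out[f"{key}_min"] = float(vals.min())
            out[f"{key}_max"] = float(vals.max())
            out[f"{key}_min_case"] = str(grp.loc[vals.idxmin(), "case_id"])
            out[f"{key}_max_case"] = str(grp.loc[vals.idxmax(), "case_id"])
        else:
            out[f"{key}_min"] = out[f"{key}_max"] = None
    return out


def derived_statistics(cohort: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> dict:
    """The cohort's headline numbers, each with its contributing case ids.

    Reported quantities: cases above the threshold overall; ETMR cases above
    threshold and their overall / hot-spot ranges; neuroblastoma (primary +
    metastatic) ranges; and the count of remaining CNS cases (non-ETMR,
    non-PLAGL2) that fall below the threshold, i.e. are essentially
    immunonegative. A missing entity group is reported as absent rather than
    raising. No diffuse-vs-focal call is made: the overall and hot-spot
    percentages and their ratio are reported and the qualitative judgement is
    left to the reader.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort table is empty")
    above = cohort["overall_percent"] > threshold

    etmr = cohort[cohort["entity_group"] == "ETMR"]
    nb = cohort[cohort["entity_group"].isin(NEUROBLASTOMA_GROUPS)]
    cns_other = cohort[
        ~cohort["entity_group"].isin(NEUROBLASTOMA_GROUPS + ("ETMR", "PLAGL2-NEC"))
    ]
    cns_other_below = cns_other[cns_other["overall_percent"] <= threshold]

    return {
        "threshold": threshold,
        "n_total": len(cohort),
        "n_above_threshold": int(above.sum()),
        "etmr": {
            **_range_stats(etmr),
            "n_above_threshold": int((etmr["overall_percent"] > threshold).sum()),
        },
        "neuroblastoma": _range_stats(nb),
        "cns_other_below_threshold": {
            "n": len(cns_other_below),
            "n_cns_other": len(cns_other),
            "case_ids": [str(c) for c in cns_other_below["case_id"]],
        },
    }


def _fmt(value: float | None) -> str:
    if value is None:
        return "N/A"
    return f"{value:.4g}"


def format_report(summary: CohortSummary, derived: dict) -> str:
    """Human-readable cohort report."""
    lines = [
        f"Cohort: {summary.n_total} cases; "
        f"{summary.n_above_threshold}/{summary.n_total} above {summary.threshold}% overall",
        "",
        f"{'entity':<26}{'n':>3}  {'mean ov%':>9}  {'ov% range':>17}  {'hot-spot% range':>17}",
    ]
    for e in summary.per_entity:
        ov = f"{_fmt(e.min_overall)}-{_fmt(e.max_overall)}"
        hs = "N/A" if e.min_hotspot is None else f"{_fmt(e.min_hotspot)}-{_fmt(e.max_hotspot)}"
        lines.append(f"{e.entity_group:<26}{e.n:>3}  {e.mean_overall:>9.4g}  {ov:>17}  {hs:>17}")
    lines.append("")

    etmr = derived["etmr"]
    if etmr.get("present"):
        lines.append(
            f"ETMR: {etmr['n_above_threshold']}/{etmr['n']} above threshold; "
            f"overall {_fmt(etmr['overall_min'])}-{_fmt(etmr['overall_max'])}% "
            f"(cases {etmr['overall_min_case']}, {etmr['overall_max_case']}); "
            f"hot spot up to {_fmt(etmr['hotspot_max'])}%"
            + (f" (case {etmr['hotspot_max_case']})" if etmr.get("hotspot_max") else "")
        )
    else:
        lines.append("ETMR: no cases in table")
    nb = derived["neuroblastoma"]
    if nb.get("present"):
        lines.append(
            f"Neuroblastoma: overall {_fmt(nb['overall_min'])}-{_fmt(nb['overall_max'])}%; "
            f"hot spot minimum {_fmt(nb['hotspot_min'])}%"
            + (f" (case {nb['hotspot_min_case']})" if nb.get("hotspot_min") else "")
        )
    else:
        lines.append("Neuroblastoma: no cases in table")
    other = derived["cns_other_below_threshold"]
    lines.append(
        f"Other CNS tumors (non-ETMR, non-PLAGL2): {other['n']}/{other['n_cns_other']} "
        f"below {derived['threshold']}% (immunonegative)"
    )
    return "\n".join(lines) + "\n"
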