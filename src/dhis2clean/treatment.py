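"""The treatment phase: iterative cleaning cycles with full accounting.

Cleaning proceeds through ordered cycles, each screening for one class of
abnormality, diagnosing it, and deleting the affected rows.  The default
order is:

1. *non-reporting facility-years* — records whose average CPC, RR and RRT
   are all zero across the six areas (the facility filed nothing that
   year);
2. *erroneous records* — records with any area whose RR or RRT exceeds
   100% or whose RRT exceeds its RR (logically impossible values);
3. *duplicates* — repeated (facility, county, year) rows: conflicting
   groups are deleted entirely, identical groups keep one representative;
4. *disaggregation* — the surviving facility-records fan out into six
   per-area datasets (facilities offer different services, so each area is
   analysed on its own);
5. *per-area situation treatment* — each area row is diagnosed and only
   situations G and H are retained.

Every cycle reports rows in / removed / out, and every removed row leaves
an audit entry with its reason, so the whole reduction from raw extract to
clean dataset is reproducible from the artifacts.  The snapshot taken
after the record-level error cycles but before duplicate removal is the
denominator population for the distribution analysis (the *analysis
dataset*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .areas import AREA_CODES
from .classify import (
    ERRONEOUS_LABELS,
    RETAINED_LABELS,
    DuplicateGroup,
    classify_labels,
    detect_duplicates,
)

__all__ = [
    "CleaningCycleReport",
    "CleaningResult",
    "drop_nonreporting_facility_years",
    "drop_erroneous",
    "treat_duplicates",
    "disaggregate_by_area",
    "apply_situation_treatment",
    "run_cleaning_cycles",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER: tuple[str, ...] = ("nonreporting", "erroneous", "duplicates")

_META_COLS = ["level", "facility_type", "ownership", "has_emr"]


@dataclass
class CleaningCycleReport:
    """Accounting for one cleaning cycle: n_in = n_removed + n_out."""

    cycle_id: int
    rule: str
    n_in: int
    n_removed: int
    n_out: int
    granularity: str = "facility_record"  # or "area_row"
    removed_keys: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cycle_id": self.cycle_id,
            "rule": self.rule,
            "granularity": self.granularity,
            "n_in": self.n_in,
            "n_removed": self.n_removed,
            "n_out": self.n_out,
        }


def _removed_entries(
    removed: pd.DataFrame, rule: str, reason: str, area: str | None = None
) -> list[dict]:
    entries = []
    for row in removed.itertuples():
        entry = {
            "facility": row.facility_name,
            "county": row.county,
            "year": int(row.year),
            "rule": rule,
            "reason": reason,
        }
        if area is not None:
            entry["area"] = area
        entries.append(entry)
    return entries


def drop_nonreporting_facility_years(
    records: pd.DataFrame, cycle_id: int = 0
) -> tuple[pd.DataFrame, CleaningCycleReport]:
    """Remove facility-years whose average CPC, RR and RRT are all zero.

    An all-zero average across the six areas means not a single report or
    indicator value was filed that year: the facility-year did not report.
    """
    mask = (
        (records["avg_cpc"] == 0)
        & (records["avg_rr"] == 0)
        & (records["avg_rrt"] == 0)
    )
    removed = records[mask]
    report = CleaningCycleReport(
        cycle_id=cycle_id,
        rule="nonreporting",
        n_in=len(records),
        n_removed=len(removed),
        n_out=len(records) - len(removed),
        removed_keys=_removed_entries(
            removed, "nonreporting", "average CPC, RR and RRT all zero"
        ),
    )
    return records[~mask], report


def drop_erroneous(
    records: pd.DataFrame, cycle_id: int = 0
) -> tuple[pd.DataFrame, CleaningCycleReport]:
    """Remove facility-years with any logically impossible area triple
    (RR > 100, RRT > 100, or RRT > RR)."""
    mask = pd.Series(False, index=records.index)
    per_area_reason: dict[int, list[str]] = {}
    for code in AREA_CODES:
        labels = classify_labels(
            records[f"{code}_cpc"], records[f"{code}_rr"], records[f"{code}_rrt"]
        )
        bad = pd.Series([l in ERRONEOUS_LABELS for l in labels], index=records.index)
        for i in records.index[bad]:
            per_area_reason.setdefault(i, []).append(code)
        mask |= bad
    removed = records[mask]
    entries = []
    for row in removed.itertuples():
        entries.append(
            {
                "facility": row.facility_name,
                "county": row.county,
                "year": int(row.year),
                "rule": "erroneous",
                "reason": "impossible RR/RRT in areas "
                + ",".join(per_area_reason[row.Index]),
            }
        )
    report = CleaningCycleReport(
        cycle_id=cycle_id,
        rule="erroneous",
        n_in=len(records),
        n_removed=len(removed),
        n_out=len(records) - len(removed),
        removed_keys=entries,
    )
    return records[~mask], report


def treat_duplicates(
    records: pd.DataFrame,
    groups: Sequence[DuplicateGroup] | None = None,
    cycle_id: int = 0,
) -> tuple[pd.DataFrame, CleaningCycleReport]:
    """Delete duplicate facility-records.

    Conflicting groups (scenario 1) lose every member — none of the
    disagreeing rows can be trusted.  Identical groups (scenario 2) keep
    the first row in a stable sort by record key and lose the rest.
    """
    if groups is None:
        groups = detect_duplicates(records)
    drop: list[int] = []
    entries: list[dict] = []
    for group in groups:
        ordered = sorted(group.rows)
        victims = ordered if group.scenario == "scenario1" else ordered[1:]
        reason = (
            "duplicate rows with conflicting RR/RRT (all deleted)"
            if group.scenario == "scenario1"
            else "identical duplicate rows (one kept)"
        )
        for idx in victims:
            drop.append(idx)
            row = records.loc[idx]
            entries.append(
                {
                    "facility": row["facility_name"],
                    "county": row["county"],
                    "year": int(row["year"]),
                    "rule": f"duplicates:{group.scenario}",
                    "reason": reason,
                }
            )
    kept = records.drop(index=drop)
    report = CleaningCycleReport(
        cycle_id=cycle_id,
        rule="duplicates",
        n_in=len(records),
        n_removed=len(drop),
        n_out=len(kept),
        removed_keys=entries,
    )
    return kept, report


def disaggregate_by_area(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Fan the facility-record table out into six per-area datasets.

    Each area row carries the single-area triple, the facility metadata,
    and a freshly diagnosed ``situation`` label for its triple.
    """
    meta = [c for c in _META_COLS if c in records.columns]
    out: dict[str, pd.DataFrame] = {}
    for code in AREA_CODES:
        area = records[
            ["facility_name", "county", "name_norm", "county_norm", "year"] + meta
        ].copy()
        area["area_code"] = code
        area["cpc"] = records[f"{code}_cpc"].to_numpy()
        area["rr"] = records[f"{code}_rr"].to_numpy()
        area["rrt"] = records[f"{code}_rrt"].to_numpy()
        area["situation"] = classify_labels(area["cpc"], area["rr"], area["rrt"])
        out[code] = area
    return out


def apply_situation_treatment(
    area_dataset: pd.DataFrame, cycle_id: int = 0
) -> tuple[pd.DataFrame, dict[str, int], CleaningCycleReport]:
    """Retain only situations G and H; count every label seen."""
    counts = area_dataset["situation"].value_counts().to_dict()
    keep = area_dataset["situation"].isin(RETAINED_LABELS)
    removed = area_dataset[~keep]
    code = str(area_dataset["area_code"].iloc[0]) if len(area_dataset) else "?"
    entries = []
    for row in removed.itertuples():
        entries.append(
            {
                "facility": row.facility_name,
                "county": row.county,
                "year": int(row.year),
                "area": code,
                "rule": "situation_treatment",
                "reason": f"situation {row.situation} excluded",
            }
        )
    report = CleaningCycleReport(
        cycle_id=cycle_id,
        rule=f"situation_treatment[{code}]",
        n_in=len(area_dataset),
        n_removed=len(removed),
        n_out=int(keep.sum()),
        granularity="area_row",
        removed_keys=entries,
    )
    return area_dataset[keep], {str(k): int(v) for k, v in counts.items()}, report


@dataclass
class CleaningResult:
    """Everything a cleaning run produces.

    ``analysis_dataset`` is the record table after the record-level error
    cycles but before duplicate removal: the denominator population for
    the situation-distribution analysis.  ``area_records`` are the
    disaggregated (pre-situation-treatment) per-area rows with labels;
    ``clean_areas`` are the final G/H-only datasets.
    """

    clean_areas: dict[str, pd.DataFrame]
    area_records: dict[str, pd.DataFrame]
    cycle_reports: list[CleaningCycleReport]
    audit: list[dict]
    analysis_dataset: pd.DataFrame
    records_after_dedup: pd.DataFrame
    area_situation_counts: dict[str, dict[str, int]]
    duplicate_removals: dict[str, int]

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_dataset)


_RECORD_STAGES: dict[str, Callable] = {
    "nonreporting": drop_nonreporting_facility_years,
    "erroneous": drop_erroneous,
    "duplicates": treat_duplicates,
}


def run_cleaning_cycles(
    records: pd.DataFrame, order: Iterable[str] = DEFAULT_ORDER
) -> CleaningResult:
    """Execute the full treatment pipeline with cycle accounting.

    ``order`` permutes the three record-level cycles; disaggregation and
    per-area situation treatment always follow.  Conservation holds at
    every cycle (n_in = n_removed + n_out) and across cycles within each
    granularity; the fan-out from records to area rows multiplies counts
    by six.
    """
    order = tuple(order)
    unknown = set(order) - set(_RECORD_STAGES)
    if unknown:
        raise ValueError(f"unknown cleaning stages {sorted(unknown)}")

    reports: list[CleaningCycleReport] = []
    audit: list[dict] = []
    current = records
    cycle = 0
    analysis_dataset = records
    duplicate_removals = {"scenario1": 0, "scenario2": 0}
    for stage in order:
        cycle += 1
        if stage == "duplicates":
            analysis_dataset = current  # population entering duplicate screening
            groups = detect_duplicates(current)
            current, report = treat_duplicates(current, groups, cycle_id=cycle)
            for entry in report.removed_keys:
                scenario = entry["rule"].split(":", 1)[1]
                duplicate_removals[scenario] += 1
        else:
            current, report = _RECORD_STAGES[stage](current, cycle_id=cycle)
        audit.extend(dict(e, cycle=cycle) for e in report.removed_keys)
        reports.append(report)
    if "duplicates" not in order:
        analysis_dataset = current

    area_records = disaggregate_by_area(current)
    clean_areas: dict[str, pd.DataFrame] = {}
    area_counts: dict[str, dict[str, int]] = {}
    cycle += 1
    n_in = sum(len(df) for df in area_records.values())
    n_removed = 0
    entries_all: list[dict] = []
    for code, area_df in area_records.items():
        kept, counts, area_report = apply_situation_treatment(area_df, cycle_id=cycle)
        clean_areas[code] = kept
        area_counts[code] = counts
        n_removed += area_report.n_removed
        entries_all.extend(area_report.removed_keys)
    combined = CleaningCycleReport(
        cycle_id=cycle,
        rule="situation_treatment",
        n_in=n_in,
        n_removed=n_removed,
        n_out=n_in - n_removed,
        granularity="area_row",
        removed_keys=entries_all,
    )
    audit.extend(dict(e, cycle=cycle) for e in entries_all)
    reports.append(combined)

    return CleaningResult(
        clean_areas=clean_areas,
        area_records=area_records,
        cycle_reports=reports,
        audit=audit,
        analysis_dataset=analysis_dataset,
        records_after_dedup=current,
        area_situation_counts=area_counts,
        duplicate_removals=duplicate_removals,
    )
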