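"""Reading the three source datasets and building the evaluation dataset.

The evaluation dataset has one row per facility per year (a *facility
record*): the (CPC, RR, RRT) triple for each of the six programmatic
areas, their facility-year averages, and facility metadata (level, type,
ownership, EMR status) joined from the master list.

Facility matching uses a case-folded, whitespace-collapsed name plus the
county, because master-list and platform spellings of the same facility
routinely differ in casing and spacing.  Duplicated facility-year rows in
the sources are carried through *unmerged* — row multiplicity is
preserved — so the duplicate scenarios remain visible to the classifier.

Triple components missing because a facility-year appears in only one
extract are coerced to zero for classification (indicator data with no
submission rates is exactly the situation-D pattern); the raw missing/zero
distinction is kept in ``{area}_{var}_missing`` columns for audit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .areas import AREAS, AREA_BY_CODE, AREA_CODES, INDICATOR_COLUMNS
from .classify import normalize_name
from .errors import FormatError, ParseError

__all__ = [
    "read_reporting_extract",
    "read_indicator_extract",
    "read_facility_list",
    "read_emr_list",
    "build_registry",
    "merge_sources",
    "RECORD_TRIPLE_COLUMNS",
]

REPORTING_COLUMNS = [
    "facility_name",
    "county",
    "year",
    "area_code",
    "expected_reports",
    "actual_reports",
    "actual_on_time",
    "reporting_rate_pct",
    "reporting_rate_on_time_pct",
]

_REPORTING_NUMERIC = [
    "expected_reports",
    "actual_reports",
    "actual_on_time",
    "reporting_rate_pct",
    "reporting_rate_on_time_pct",
]

#: The 18 per-area triple columns of a facility record, in area order.
RECORD_TRIPLE_COLUMNS = [
    f"{code}_{var}" for code in AREA_CODES for var in ("cpc", "rr", "rrt")
]


def _read_csv(path: str | Path) -> pd.DataFrame:
    # all-string read so that blanks stay distinguishable from zeros and
    # bad numerics can be reported with a row number
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def _parse_float(value: str) -> float | None:
    if value == "":
        return np.nan
    try:
        # Python's strtod round-trips shortest-repr floats exactly; pandas'
        # fast parser may lose the last digit, which would break the
        # write -> read round-trip guarantee.
        return float(value)
    except ValueError:
        return None


def _to_numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    raw = df[column].str.strip()
    values = raw.map(_parse_float)
    bad = raw.ne("") & values.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based plus header line
        raise ParseError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{column!r} at line {row}"
        )
    return values.astype(float)


def read_reporting_extract(path: str | Path) -> pd.DataFrame:
    """Parse the per-facility/year/area reporting extract.

    Percentages are kept exactly as exported — values above 100% must
    survive ingestion because they are what the diagnosis stage looks for.
    Missing cells stay missing (NaN).
    """
    df = _read_csv(path)
    _require_columns(df, REPORTING_COLUMNS, path)
    out = df[["facility_name", "county", "area_code"]].copy()
    out["year"] = _to_numeric(df, "year", path).astype("Int64")
    for col in _REPORTING_NUMERIC:
        out[col] = _to_numeric(df, col, path)
    unknown = set(out["area_code"]) - set(AREA_CODES)
    if unknown:
        raise FormatError(f"{path}: unknown programmatic areas {sorted(unknown)}")
    return out[REPORTING_COLUMNS]


def read_indicator_extract(path: str | Path, areas: Iterable = AREAS) -> pd.DataFrame:
    """Parse the annual indicator-element extract.

    The file is rectangular over the widest area's indicator columns; a
    row may only carry values in its own area's first ``n_indicators``
    columns.  A value beyond that width means the row has the wrong
    indicator column count for its area and is a format error.  Blank
    cells are missing values; literal ``0`` is an explicit zero — the two
    states are distinct and both survive parsing.
    """
    areas = list(areas)
    df = _read_csv(path)
    base_cols = ["facility_name", "county", "year", "area_code"]
    _require_columns(df, base_cols, path)
    ind_cols = [c for c in INDICATOR_COLUMNS if c in df.columns]
    by_code = {a.code: a for a in areas}
    widths = {a.code: a.n_indicators for a in areas}
    need = max((a.n_indicators for a in areas), default=0)
    if len(ind_cols) < need:
        raise FormatError(
            f"{path}: expected at least {need} indicator columns, found {len(ind_cols)}"
        )

    out = df[["facility_name", "county", "area_code"]].copy()
    out["year"] = _to_numeric(df, "year", path).astype("Int64")
    unknown = set(out["area_code"]) - set(by_code)
    if unknown:
        raise FormatError(f"{path}: unknown programmatic areas {sorted(unknown)}")
    for col in ind_cols:
        out[col] = _to_numeric(df, col, path)

    for code, width in widths.items():
        beyond = [c for c in ind_cols[width:]]
        if not beyond:
            continue
        rows = out["area_code"] == code
        overflow = out.loc[rows, beyond].notna().any(axis=1)
        if overflow.any():
            raise FormatError(
                f"{path}: area {code} expects {width} indicator columns but a "
                f"row carries values beyond them (line "
                f"{int(overflow.idxmax()) + 2})"
            )
    return out[base_cols + ind_cols]


def read_facility_list(path: str | Path) -> pd.DataFrame:
    """Parse the facility master list (name, county, level, type, ownership)."""
    df = _read_csv(path)
    cols = ["facility_name", "county", "level", "facility_type", "ownership"]
    _require_columns(df, cols, path)
    out = df[cols].copy()
    out["name_norm"] = out["facility_name"].map(normalize_name)
    out["county_norm"] = out["county"].map(normalize_name)
    dup = out.duplicated(["name_norm", "county_norm"])
    if dup.any():
        first = out.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate facility entry "
            f"({first['facility_name']!r}, {first['county']!r})"
        )
    return out


def read_emr_list(path: str | Path) -> pd.DataFrame:
    """Parse the EMR-status list (facilities running an electronic record)."""
    df = _read_csv(path)
    _require_columns(df, ["facility_name", "county"], path)
    out = df[["facility_name", "county"]].copy()
    out["name_norm"] = out["facility_name"].map(normalize_name)
    out["county_norm"] = out["county"].map(normalize_name)
    return out.drop_duplicates(["name_norm", "county_norm"])


def build_registry(facilities: pd.DataFrame, emr: pd.DataFrame) -> pd.DataFrame:
    """Master list augmented with ``has_emr``: ``"true"`` for facilities on
    the EMR list, ``"false"`` otherwise."""
    emr_keys = set(zip(emr["name_norm"], emr["county_norm"]))
    registry = facilities.copy()
    registry["has_emr"] = [
        "true" if key in emr_keys else "false"
        for key in zip(registry["name_norm"], registry["county_norm"])
    ]
    return registry


def _occurrence(df: pd.DataFrame) -> pd.Series:
    """Per (facility, county, year, area) copy counter, preserving duplicate
    multiplicity through the wide pivot."""
    return df.groupby(["name_norm", "county_norm", "year", "area_code"]).cumcount()


def _area_cpc(indicators: pd.DataFrame) -> pd.Series:
    """Vectorised CPC per indicator row (non-blank share of the area's slots)."""
    ind_cols = [c for c in INDICATOR_COLUMNS if c in indicators.columns]
    nonblank = indicators[ind_cols].notna()
    cpc = pd.Series(0.0, index=indicators.index)
    for code in indicators["area_code"].unique():
        area = AREA_BY_CODE[code]
        rows = indicators["area_code"] == code
        counts = nonblank.loc[rows, ind_cols[: area.n_indicators]].sum(axis=1)
        cpc.loc[rows] = 100.0 * counts / area.n_indicators
    return cpc


def merge_sources(
    reporting: pd.DataFrame,
    indicators: pd.DataFrame,
    registry: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Merge the parsed sources into the facility-record table.

    Returns the record table (one row per facility, county, year and
    duplicate occurrence) and a merge log with one entry per record that
    had any one-sided join plus one per master-list facility matching no
    extract row (those are dropped).
    """
    rep = reporting.copy()
    rep["name_norm"] = rep["facility_name"].map(normalize_name)
    rep["county_norm"] = rep["county"].map(normalize_name)
    rep["occurrence"] = _occurrence(rep)

    ind = indicators.copy()
    ind["name_norm"] = ind["facility_name"].map(normalize_name)
    ind["county_norm"] = ind["county"].map(normalize_name)
    ind["occurrence"] = _occurrence(ind)
    ind["cpc"] = _area_cpc(ind)

    key = ["name_norm", "county_norm", "year", "occurrence"]

    rep_w = rep.pivot_table(
        index=key,
        columns="area_code",
        values=["reporting_rate_pct", "reporting_rate_on_time_pct"],
        aggfunc="first",
    )
    ind_w = ind.pivot_table(
        index=key, columns="area_code", values="cpc", aggfunc="first"
    )

    union = rep_w.index.union(ind_w.index)

    def _col(frame: pd.DataFrame, column) -> pd.Series:
        if column in frame.columns:
            return frame[column].reindex(union)
        return pd.Series(np.nan, index=union)

    frames = {}
    for code in AREA_CODES:
        frames[f"{code}_cpc"] = _col(ind_w, code)
        frames[f"{code}_rr"] = _col(rep_w, ("reporting_rate_pct", code))
        frames[f"{code}_rrt"] = _col(rep_w, ("reporting_rate_on_time_pct", code))
    wide = pd.DataFrame(frames, index=union)

    # representative display name/county: first spelling seen per key
    names = pd.concat(
        [
            rep[["name_norm", "county_norm", "facility_name", "county"]],
            ind[["name_norm", "county_norm", "facility_name", "county"]],
        ]
    ).drop_duplicates(["name_norm", "county_norm"])
    wide = wide.reset_index().merge(names, on=["name_norm", "county_norm"], how="left")

    for col in RECORD_TRIPLE_COLUMNS:
        wide[f"{col}_missing"] = wide[col].isna()
        wide[col] = wide[col].fillna(0.0)

    cpc_cols = [f"{c}_cpc" for c in AREA_CODES]
    rr_cols = [f"{c}_rr" for c in AREA_CODES]
    rrt_cols = [f"{c}_rrt" for c in AREA_CODES]
    wide["avg_cpc"] = wide[cpc_cols].mean(axis=1)
    wide["avg_rr"] = wide[rr_cols].mean(axis=1)
    wide["avg_rrt"] = wide[rrt_cols].mean(axis=1)

    merge_log: list[dict] = []
    if registry is not None:
        meta = registry[
            ["name_norm", "county_norm", "level", "facility_type", "ownership", "has_emr"]
        ]
        wide = wide.merge(meta, on=["name_norm", "county_norm"], how="left")
        unmatched = wide["level"].isna()
        for col in ("level", "facility_type", "ownership", "has_emr"):
            wide[col] = wide[col].fillna("unknown")
        extract_keys = set(zip(wide["name_norm"], wide["county_norm"]))
        for row in registry.itertuples(index=False):
            if (row.name_norm, row.county_norm) not in extract_keys:
                merge_log.append(
                    {
                        "facility": row.facility_name,
                        "county": row.county,
                        "year": None,
                        "issue": "facility-list entry matched no extract row; dropped",
                    }
                )
    else:
        unmatched = pd.Series(False, index=wide.index)
        for col in ("level", "facility_type", "ownership", "has_emr"):
            wide[col] = "unknown"

    missing_cols = [f"{c}_missing" for c in RECORD_TRIPLE_COLUMNS]
    any_missing = wide[missing_cols].any(axis=1)
    for i in wide.index[any_missing | unmatched]:
        issues = []
        row = wide.loc[i]
        missing_areas_rep = [
            c for c in AREA_CODES if row[f"{c}_rr_missing"] or row[f"{c}_rrt_missing"]
        ]
        missing_areas_ind = [c for c in AREA_CODES if row[f"{c}_cpc_missing"]]
        if missing_areas_rep:
            issues.append(f"no reporting rows for areas {missing_areas_rep}")
        if missing_areas_ind:
            issues.append(f"no indicator rows for areas {missing_areas_ind}")
        if bool(unmatched.loc[i]):
            issues.append("facility not in facility list")
        merge_log.append(
            {
                "facility": row["facility_name"],
                "county": row["county"],
                "year": int(row["year"]),
                "issue": "; ".join(issues),
            }
        )

    wide["year"] = wide["year"].astype(int)
    front = [
        "facility_name",
        "county",
        "name_norm",
        "county_norm",
        "year",
        "occurrence",
    ]
    ordered = front + RECORD_TRIPLE_COLUMNS + [
        "avg_cpc",
        "avg_rr",
        "avg_rrt",
        "level",
        "facility_type",
        "ownership",
        "has_emr",
    ] + missing_cols
    return wide[ordered], merge_log
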