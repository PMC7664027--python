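"""Screening and diagnosis: the situation taxonomy and duplicate detection.

Every (CPC, RR, RRT) triple is diagnosed into exactly one *situation*.
Reading the three percentages as zero / positive / above-100 patterns:

====  ====  =======  =======  ==========================================
code  CPC   RR       RRT      reading
====  ====  =======  =======  ==========================================
A     0     0        0        facility did not report at all
B     0     >0       >0       reports submitted (some on time) but empty
C     0     >0       0        reports submitted late and empty
D     >0    0        0        indicator data present, no submission rates
E     any   >100     <=100    impossible reporting rate
F     any   >100     >100     impossible reporting and timeliness rates
G     >0    >0       >0       ideal: timely reports with content
H     >0    >0       0        reports with content but never on time
ERRX  any   <=100    >RR      impossible timeliness (on-time > submitted)
====  ====  =======  =======  ==========================================

A-F and ERRX are excluded by the treatment phase; only G and H feed the
final clean dataset.  ``ERRX`` is this package's catch-all for triples the
eight named patterns cannot host (RRT exceeding RR, or RRT above 100 while
RR is in range): on-time reports are a subset of submitted reports, so such
values are as logically impossible as an RR above 100 and get the same
exclude action.

Duplicate facility-records — same facility name, county and year appearing
on more than one row — come in two scenarios with different treatments:
scenario 1 rows disagree on at least one RR/RRT value (all rows are
deleted, none can be trusted); scenario 2 rows are identical on every
RR/RRT value (one representative is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .areas import AREA_CODES

__all__ = [
    "Action",
    "Situation",
    "SITUATIONS",
    "EXCLUDED_LABELS",
    "RETAINED_LABELS",
    "classify_situation",
    "classify_labels",
    "DuplicateGroup",
    "detect_duplicates",
    "frequency_screen",
    "screen_out_of_range",
    "normalize_name",
]


class Action(str, Enum):
    EXCLUDE = "exclude"
    INCLUDE = "include"


@dataclass(frozen=True)
class Situation:
    label: str
    action: Action
    description: str


SITUATIONS: dict[str, Situation] = {
    s.label: s
    for s in (
        Situation("A", Action.EXCLUDE, "no reports and no indicator data; facility not reporting"),
        Situation("B", Action.EXCLUDE, "reports submitted, some on time, but all empty"),
        Situation("C", Action.EXCLUDE, "reports submitted late and all empty"),
        Situation("D", Action.EXCLUDE, "indicator data present but no submission rates recorded"),
        Situation("E", Action.EXCLUDE, "reporting rate above 100%: impossible"),
        Situation("F", Action.EXCLUDE, "reporting rate and timeliness above 100%: impossible"),
        Situation("G", Action.INCLUDE, "timely reports with indicator content: ideal"),
        Situation("H", Action.INCLUDE, "reports with content but none on time"),
        Situation("ERRX", Action.EXCLUDE, "timeliness rate exceeds reporting rate: impossible"),
    )
}

EXCLUDED_LABELS: frozenset[str] = frozenset(
    l for l, s in SITUATIONS.items() if s.action is Action.EXCLUDE
)
RETAINED_LABELS: frozenset[str] = frozenset({"G", "H"})

#: Labels whose pattern is an impossible rate rather than a reporting gap.
ERRONEOUS_LABELS: frozenset[str] = frozenset({"E", "F", "ERRX"})


def classify_labels(
    cpc: np.ndarray | Sequence[float],
    rr: np.ndarray | Sequence[float],
    rrt: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Vectorised situation labelling of (CPC, RR, RRT) triples.

    The branches are evaluated in precedence order so that the nine labels
    partition the whole non-negative octant: out-of-range rates trump the
    zero/positive patterns, and RRT inconsistencies trump both zero
    patterns.  Classification is a pure function of the triple.
    """
    cpc = np.asarray(cpc, dtype=float)
    rr = np.asarray(rr, dtype=float)
    rrt = np.asarray(rrt, dtype=float)
    if np.any(cpc < 0) or np.any(rr < 0) or np.any(rrt < 0):
        raise ValueError("CPC, RR and RRT must be non-negative percentages")

    conditions = [
        (rr > 100) & (rrt > 100),
        (rr > 100),
        (rrt > 100) | (rrt > rr),
        (cpc == 0) & (rr == 0) & (rrt == 0),
        (cpc == 0) & (rr > 0) & (rrt > 0),
        (cpc == 0) & (rr > 0) & (rrt == 0),
        (cpc > 0) & (rr == 0) & (rrt == 0),
        (cpc > 0) & (rr > 0) & (rrt > 0),
        (cpc > 0) & (rr > 0) & (rrt == 0),
    ]
    labels = ["F", "E", "ERRX", "A", "B", "C", "D", "G", "H"]
    out = np.select(conditions, labels, default="")
    if np.any(out == ""):  # pragma: no cover - the branches are exhaustive
        raise AssertionError("situation branches failed to cover a triple")
    return out


def classify_situation(cpc: float, rr: float, rrt: float) -> Situation:
    """Diagnose a single (CPC, RR, RRT) triple. Total over non-negatives."""
    label = classify_labels([cpc], [rr], [rrt])[0]
    return SITUATIONS[str(label)]


def normalize_name(name: object) -> str:
    """Case-folded, whitespace-collapsed facility/county matching key."""
    return " ".join(str(name).split()).casefold()


# ---------------------------------------------------------------------------
# duplicates


@dataclass
class DuplicateGroup:
    """Rows sharing (facility, county, year); at least two of them."""

    key: tuple[str, str, int]  # (normalised name, normalised county, year)
    rows: list[int] = field(default_factory=list)  # record-table index labels
    scenario: str = "scenario2"  # scenario1 = conflicting, scenario2 = identical


_RATE_COLS = [f"{c}_{v}" for c in AREA_CODES for v in ("rr", "rrt")]


def detect_duplicates(records: pd.DataFrame) -> list[DuplicateGroup]:
    """Group repeated (facility, county, year) rows and tag each scenario.

    Scenario 1 holds as soon as any two rows of a group differ in any area's
    RR or RRT; scenario 2 requires all rows identical on every RR/RRT value.
    Values are compared exactly as parsed — duplicates originate from the
    same export, so no tolerance is warranted.
    """
    if records.empty:
        return []
    key_cols = ["name_norm", "county_norm", "year"]
    groups: list[DuplicateGroup] = []
    for key, sub in records.groupby(key_cols, sort=True):
        if len(sub) < 2:
            continue
        distinct = sub[_RATE_COLS].drop_duplicates()
        scenario = "scenario2" if len(distinct) == 1 else "scenario1"
        groups.append(
            DuplicateGroup(key=tuple(key), rows=list(sub.index), scenario=scenario)
        )
    return groups


def frequency_screen(
    area_records: pd.DataFrame, year_span: int | None = None
) -> list[tuple[str, str]]:
    """Flag facilities with more annual reports in one area than years.

    A facility can file at most one annual report per area per calendar
    year, so a count above the year-span length (8 for a 2011-2018 window)
    betrays duplication.  ``year_span`` defaults to the number of distinct
    years present in ``area_records``.
    """
    if area_records.empty:
        return []
    if year_span is None:
        year_span = int(area_records["year"].nunique())
    counts = area_records.groupby(["name_norm", "county_norm"]).size()
    return [tuple(k) for k in counts.index[counts > year_span]]


def screen_out_of_range(records: pd.DataFrame) -> pd.DataFrame:
    """Boolean flag per (record, area) where RR or RRT exceeds 100%.

    100.0 exactly is in range; anything above is flagged.
    """
    flags = {}
    for code in AREA_CODES:
        flags[code] = (records[f"{code}_rr"] > 100) | (records[f"{code}_rrt"] > 100)
    return pd.DataFrame(flags, index=records.index)
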