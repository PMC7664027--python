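"""Completeness and timeliness metrics for annual facility reports.

Three percentages summarise one facility's annual reporting in one
programmatic area:

* Reporting Rate (RR)          = 100 * submitted reports / expected reports
* Reporting Rate on Time (RRT) = 100 * on-time reports  / expected reports
* Cumulative Percent Completion (CPC)
                               = 100 * non-blank indicator values / indicators

RR and RRT measure report *submission*, not content; a submitted-but-empty
report still counts toward them.  CPC measures content: the share of the
area's indicator slots that carry a value in the annual extract.  An
explicit zero is a value and counts as non-blank; only empty cells are
blank.  RR and RRT can exceed 100% in dirty data (more submissions recorded
than expected) and are deliberately not clipped here, because out-of-range
values drive downstream diagnosis.  CPC is bounded in [0, 100] by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .areas import AREA_CODES, ProgrammaticArea
from .errors import FormatError, UndefinedDenominatorError


@dataclass(frozen=True)
class ReportCounts:
    """Annual report-submission counts for one facility, year, area."""

    expected: int
    actual: int
    on_time: int

    def __post_init__(self) -> None:
        for field in ("expected", "actual", "on_time"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")


def compute_rr(counts: ReportCounts) -> float:
    """Reporting Rate: 100 * actual / expected, unrounded.

    Raises
    ------
    UndefinedDenominatorError
        If no reports were expected.
    """
    if counts.expected == 0:
        raise UndefinedDenominatorError("expected report count is zero")
    return 100.0 * counts.actual / counts.expected


def compute_rrt(counts: ReportCounts) -> float:
    """Reporting Rate on Time: 100 * on_time / expected, unrounded."""
    if counts.expected == 0:
        raise UndefinedDenominatorError("expected report count is zero")
    return 100.0 * counts.on_time / counts.expected


def is_blank(value: object) -> bool:
    """True for the cell states DHIS2 renders as empty.

    Blank means no value at all: ``None``, an empty/whitespace string, or a
    float NaN.  The number 0 is an explicit value, never blank.
    """
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip() == ""
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def compute_cpc(
    indicator_values: Sequence[object], area: ProgrammaticArea
) -> float:
    """Cumulative Percent Completion of one annual area report.

    Counts non-blank entries among the area's indicator slots and expresses
    them as a percentage of the area's indicator count.  For instance a
    40-indicator area report carrying 10 values is 25% complete.
    """
    if len(indicator_values) != area.n_indicators:
        raise FormatError(
            f"area {area.code} expects {area.n_indicators} indicator values, "
            f"got {len(indicator_values)}"
        )
    n_nonblank = sum(0 if is_blank(v) else 1 for v in indicator_values)
    return 100.0 * n_nonblank / area.n_indicators


def facility_year_averages(
    record: Mapping[str, object], area_codes: Iterable[str] = AREA_CODES
) -> tuple[float, float, float]:
    """Mean CPC, RR and RRT of one facility-year record across its areas.

    ``record`` maps ``{code}_cpc`` / ``{code}_rr`` / ``{code}_rrt`` keys to
    percentages.  Missing components (``None`` or NaN) are treated as zero,
    so a facility that never appears in one extract averages down rather
    than dropping the area — the all-zero average is the non-reporting
    signature used for facility-level exclusion.
    """
    sums = {"cpc": 0.0, "rr": 0.0, "rrt": 0.0}
    codes = list(area_codes)
    for code in codes:
        for var in sums:
            value = record.get(f"{code}_{var}")
            if value is None or is_blank(value):
                continue
            sums[var] += float(value)  # type: ignore[arg-type]
    n = len(codes)
    return (sums["cpc"] / n, sums["rr"] / n, sums["rrt"] / n)
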