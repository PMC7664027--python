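"""The six HIV programmatic areas of Kenya's MOH 731 reporting form.

Each facility offering HIV services submits one monthly report per
programmatic area, so twelve reports are expected per area per year.
The indicator counts are fixed properties of the 2011-2018 form revision.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProgrammaticArea:
    """One MOH 731 programmatic area (an independent monthly report)."""

    code: str
    name: str
    n_indicators: int
    expected_reports_per_year: int = 12

    def __post_init__(self) -> None:
        if self.n_indicators < 1:
            raise ValueError(f"n_indicators must be >= 1, got {self.n_indicators}")
        if self.expected_reports_per_year < 1:
            raise ValueError(
                f"expected_reports_per_year must be >= 1, "
                f"got {self.expected_reports_per_year}"
            )


AREAS: tuple[ProgrammaticArea, ...] = (
    ProgrammaticArea("HCT", "HIV Counselling and Testing", 14),
    ProgrammaticArea("PMTCT", "Prevention of Mother-to-Child Transmission", 40),
    ProgrammaticArea("CrT", "Care and Treatment", 65),
    ProgrammaticArea("VMMC", "Voluntary Medical Male Circumcision", 13),
    ProgrammaticArea("PEP", "Post-Exposure Prophylaxis", 14),
    ProgrammaticArea("BS", "Blood Safety", 3),
)

AREA_BY_CODE: dict[str, ProgrammaticArea] = {a.code: a for a in AREAS}
AREA_CODES: tuple[str, ...] = tuple(a.code for a in AREAS)

#: Widest indicator set across areas; the single indicator CSV is padded to this.
MAX_INDICATORS: int = max(a.n_indicators for a in AREAS)

#: Column names used for indicator values in the flat indicator extract.
INDICATOR_COLUMNS: tuple[str, ...] = tuple(
    f"ind_{i:03d}" for i in range(1, MAX_INDICATORS + 1)
)
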