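"""Synthetic DHIS2-like source files with injected, labelled anomalies.

The generator emits the three source datasets the cleaning pipeline
consumes — a per-facility/year/area reporting extract, an annual
indicator-element extract, and a facility master list plus EMR-status
list — together with ground-truth labels for every injected anomaly, so
each pipeline stage can be tested for exact recovery without access to a
national DHIS2 instance.

What is emulated
----------------
* six programmatic areas with their fixed indicator counts and 12 expected
  monthly reports per area-year;
* the situation taxonomy: each (facility, year, area) draws a situation
  from a per-area mixture and the emitted counts/indicator cells follow
  that situation's (CPC, RR, RRT) pattern;
* whole-facility non-reporting (situation A across all six areas at once),
  drawn per facility-year with its own weight, so facility-level
  exclusion has targets;
* zeros rendered as blanks: a drawn zero is written as an empty cell with
  probability ``blank_zero_rate`` (default 1, the platform's behaviour);
* above-100% rates for situations E/F, produced by submission counts
  exceeding the expected 12 (rates fall in (100, 200]);
* both duplicate scenarios: copied facility-year rows with conflicting
  (scenario 1) or identical (scenario 2) RR/RRT values.

Randomness is organised as one root seed with a child stream per
(facility, year, area) derived by counter, so enlarging ``n_facilities``
or extending ``years`` never reshuffles records already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .areas import AREAS, AREA_CODES, INDICATOR_COLUMNS, MAX_INDICATORS
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "DEFAULT_SITUATION_MIX",
    "SyntheticExtracts",
    "generate_facility_registry",
    "generate_extracts",
    "inject_duplicates",
    "write_sources",
    "write_truth",
]

# Stream families for SeedSequence spawn keys (first component).
_REGISTRY_STREAM = 0
_AREA_STREAM = 1
_FACILITY_YEAR_STREAM = 2
_DUP_STREAM = 3

_GENERATED_LABELS = frozenset("ABCDEFGH")

#: Situations whose annual report content is empty (all cells drawn as zeros).
_EMPTY_LABELS = frozenset("ABC")


def _default_mix() -> dict[str, dict[str, float]]:
    """Per-area situation mixtures echoing the error burden observed in a
    national HIV-reporting dataset: content-bearing areas (HCT, PMTCT)
    dominated by the ideal situation G, low-volume services (VMMC, BS)
    dominated by area-level non-reporting, empty submissions concentrated
    in PEP, and a trace of impossible >100% rates everywhere."""
    base = {
        "HCT": {"B": 0.0268, "C": 0.0075, "D": 0.0066, "G": 0.9244, "H": 0.0157},
        "PMTCT": {"B": 0.0615, "C": 0.0075, "D": 0.0197, "G": 0.8152, "H": 0.0213},
        "CrT": {"B": 0.0132, "C": 0.0032, "D": 0.0166, "G": 0.4260, "H": 0.0120},
        "VMMC": {"B": 0.0281, "C": 0.0113, "D": 0.0078, "G": 0.0063, "H": 0.0003},
        "PEP": {"B": 0.1804, "C": 0.0076, "D": 0.0071, "G": 0.2182, "H": 0.0028},
        "BS": {"B": 0.0170, "C": 0.0019, "D": 0.0009, "G": 0.0045, "H": 0.0001},
    }
    mixes: dict[str, dict[str, float]] = {}
    for code, weights in base.items():
        mix = dict(weights)
        mix["E"] = 0.00003
        mix["F"] = 0.00002
        mix["A"] = 1.0 - sum(mix.values())  # area-level non-reporting residual
        mixes[code] = mix
    return mixes


DEFAULT_SITUATION_MIX: dict[str, dict[str, float]] = _default_mix()

_DEFAULT_COUNTIES = tuple(f"County-{i:02d}" for i in range(1, 48))

_LEVELS = ("II", "III", "IV", "V", "VI")
_LEVEL_P = (0.55, 0.28, 0.12, 0.04, 0.01)
_TYPES_BY_LEVEL = {
    "II": ("Dispensary", "Medical Clinic"),
    "III": ("Health Centre", "Medical Clinic"),
    "IV": ("Sub-County Hospital",),
    "V": ("County Referral Hospital",),
    "VI": ("National Referral Hospital",),
}
_OWNERSHIP = ("MoH", "Private Practice", "Faith-Based", "NGO")
_OWNERSHIP_P = (0.48, 0.32, 0.14, 0.06)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic DHIS2 source generator.

    ``situation_mix`` maps each programmatic-area code to a mixture over
    situation labels A-H (a flat label->probability mapping is accepted and
    broadcast to all areas).  ``facility_level_a_rate`` is the probability
    that an entire facility-year is situation A across all six areas at
    once, modelling facilities registered on the platform that never
    report; it acts before the per-area mixtures.  ``dup_scenario1_rate``
    and ``dup_scenario2_rate`` are the fractions of facility-year rows
    copied with conflicting vs identical RR/RRT values.
    ``blank_zero_rate`` is the probability that a drawn zero is rendered
    as an empty cell rather than a literal 0.
    """

    n_facilities: int = 100
    years: tuple[int, ...] = tuple(range(2011, 2019))
    counties: tuple[str, ...] = _DEFAULT_COUNTIES
    situation_mix: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None
    facility_level_a_rate: float = 0.50
    dup_scenario1_rate: float = 0.0002
    dup_scenario2_rate: float = 0.0002
    blank_zero_rate: float = 1.0
    seed: int = 0

    def resolved_mix(self) -> dict[str, dict[str, float]]:
        """Per-area mixtures after broadcasting and validation."""
        raw = self.situation_mix
        if raw is None:
            return {c: dict(m) for c, m in DEFAULT_SITUATION_MIX.items()}
        keys = set(raw)
        if keys <= _GENERATED_LABELS:  # flat mixture: broadcast to all areas
            return {code: dict(raw) for code in AREA_CODES}  # type: ignore[arg-type]
        if keys != set(AREA_CODES):
            raise ConfigurationError(
                "situation_mix: keys must be the six area codes "
                f"{sorted(AREA_CODES)} or situation labels, got {sorted(keys)}"
            )
        return {code: dict(raw[code]) for code in AREA_CODES}  # type: ignore[index]

    def validate(self) -> None:
        if self.n_facilities < 1:
            raise ConfigurationError("n_facilities: must be >= 1")
        if not self.years:
            raise ConfigurationError("years: must be non-empty")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ConfigurationError("years: must be strictly increasing")
        if not self.counties:
            raise ConfigurationError("counties: must be non-empty")
        for name in (
            "facility_level_a_rate",
            "dup_scenario1_rate",
            "dup_scenario2_rate",
            "blank_zero_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}: must be in [0, 1], got {value}")
        for code, mix in self.resolved_mix().items():
            bad = set(mix) - _GENERATED_LABELS
            if bad:
                raise ConfigurationError(
                    f"situation_mix[{code}]: unknown labels {sorted(bad)}"
                )
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(
                    f"situation_mix[{code}]: probabilities must be non-negative"
                )
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"situation_mix[{code}]: probabilities sum to {total!r}, not 1"
                )


@dataclass
class SyntheticExtracts:
    """Generated source tables plus the ground truth behind them.

    ``truth_labels`` holds one row per (facility, county, year, area) with
    the injected situation; rows copied as duplicates share their source's
    labels.  ``truth_duplicates`` holds one row per injected duplicate
    group with its scenario.
    """

    reporting: pd.DataFrame
    indicators: pd.DataFrame
    truth_labels: pd.DataFrame
    truth_duplicates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["facility_name", "county", "year", "scenario"]
        )
    )


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def generate_facility_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic facility master list: name, county, level, type,
    ownership and an EMR flag, one row per facility."""
    config.validate()
    rows = []
    for fi in range(config.n_facilities):
        rng = _rng(config.seed, _REGISTRY_STREAM, fi)
        county = config.counties[int(rng.integers(len(config.counties)))]
        level = str(rng.choice(_LEVELS, p=_LEVEL_P))
        ftype = str(rng.choice(_TYPES_BY_LEVEL[level]))
        ownership = str(rng.choice(_OWNERSHIP, p=_OWNERSHIP_P))
        has_emr = bool(rng.random() < 0.30)
        rows.append(
            {
                "facility_name": f"Facility-{fi + 1:05d}",
                "county": county,
                "level": level,
                "facility_type": ftype,
                "ownership": ownership,
                "has_emr": has_emr,
            }
        )
    return pd.DataFrame(rows)


def _draw_counts(label: str, rng: np.random.Generator, expected: int) -> tuple[int, int]:
    """(actual, on_time) submission counts satisfying the label's pattern."""
    if label == "A" or label == "D":
        return 0, 0
    if label == "B" or label == "G":
        actual = int(rng.integers(1, expected + 1))
        return actual, int(rng.integers(1, actual + 1))
    if label == "C" or label == "H":
        return int(rng.integers(1, expected + 1)), 0
    if label == "E":
        # more submissions than expected -> RR in (100, 200]; timeliness in range
        return int(rng.integers(expected + 1, 2 * expected + 1)), int(
            rng.integers(1, expected + 1)
        )
    if label == "F":
        actual = int(rng.integers(expected + 1, 2 * expected + 1))
        return actual, int(rng.integers(expected + 1, actual + 1))
    raise AssertionError(f"unhandled label {label}")


def _draw_indicators(
    label: str, n: int, rng: np.random.Generator, blank_zero_rate: float
) -> list[float]:
    """Annual indicator cells for one area report (NaN = blank cell).

    Empty-report situations (A/B/C) draw every cell as zero; content
    situations pick 1..n reported cells, the first of which is forced
    positive so the emitted CPC stays above zero even when every zero is
    blanked.
    """
    cells = [np.nan] * n
    if label in _EMPTY_LABELS:
        drawn = np.zeros(n, dtype=int)
        positions = range(n)
    else:
        k = int(rng.integers(1, n + 1))
        positions = rng.choice(n, size=k, replace=False)
        drawn = rng.integers(0, 500, size=k)
        drawn[0] = rng.integers(1, 500)
    for pos, value in zip(positions, np.atleast_1d(drawn)):
        if value == 0 and rng.random() < blank_zero_rate:
            continue  # zero rendered as blank by the platform
        cells[int(pos)] = float(value)
    return cells


def generate_extracts(
    registry: pd.DataFrame, config: GeneratorConfig
) -> SyntheticExtracts:
    """Draw a situation per (facility, year, area) and emit matching rows.

    Each reporting row carries both the submission counts and the derived
    percentages (100*actual/expected, 100*on_time/expected); each indicator
    row carries the area's annual cells padded with blanks to the widest
    area.  Every emitted (facility, year, area) gets a truth label.
    """
    config.validate()
    if registry.empty:
        raise ConfigurationError("n_facilities: registry is empty")
    mixes = config.resolved_mix()
    mix_arrays = {
        code: (list(mix.keys()), np.array(list(mix.values()), dtype=float))
        for code, mix in mixes.items()
    }

    reporting_rows: list[dict] = []
    indicator_rows: list[dict] = []
    truth_rows: list[dict] = []
    for fi, facility in enumerate(registry.itertuples(index=False)):
        for yi, year in enumerate(config.years):
            fy_rng = _rng(config.seed, _FACILITY_YEAR_STREAM, fi, yi)
            facility_a = fy_rng.random() < config.facility_level_a_rate
            for ai, area in enumerate(AREAS):
                rng = _rng(config.seed, _AREA_STREAM, fi, yi, ai)
                if facility_a:
                    label = "A"
                else:
                    labels, probs = mix_arrays[area.code]
                    label = labels[int(rng.choice(len(labels), p=probs))]
                expected = area.expected_reports_per_year
                actual, on_time = _draw_counts(label, rng, expected)
                cells = _draw_indicators(
                    label, area.n_indicators, rng, config.blank_zero_rate
                )
                padded = cells + [np.nan] * (MAX_INDICATORS - area.n_indicators)
                base = {
                    "facility_name": facility.facility_name,
                    "county": facility.county,
                    "year": int(year),
                    "area_code": area.code,
                }
                reporting_rows.append(
                    {
                        **base,
                        "expected_reports": expected,
                        "actual_reports": actual,
                        "actual_on_time": on_time,
                        "reporting_rate_pct": 100.0 * actual / expected,
                        "reporting_rate_on_time_pct": 100.0 * on_time / expected,
                    }
                )
                indicator_rows.append(
                    {**base, **dict(zip(INDICATOR_COLUMNS, padded))}
                )
                truth_rows.append(
                    {**base, "situation": label, "facility_level_a": facility_a}
                )

    return SyntheticExtracts(
        reporting=pd.DataFrame(reporting_rows),
        indicators=pd.DataFrame(indicator_rows),
        truth_labels=pd.DataFrame(truth_rows),
    )


_DUPLICATABLE = frozenset("BCGH")


def inject_duplicates(
    extracts: SyntheticExtracts, config: GeneratorConfig
) -> SyntheticExtracts:
    """Copy facility-year rows to create both duplicate scenarios.

    Scenario 1 copies get one area's submission counts resampled (so at
    least one RR/RRT value conflicts); scenario 2 copies are verbatim.
    Only facility-years that will survive the earlier facility-level
    cleaning stages are eligible (no whole-facility situation A, no E/F
    area, at least one area with a positive submission count), so the
    injected groups reach the duplicate-treatment stage intact and recovery
    is exact.  Finally all rows are shuffled deterministically.
    """
    config.validate()
    labels = extracts.truth_labels
    per_fy = labels.groupby(["facility_name", "county", "year"], sort=True)
    eligible: list[tuple[str, str, int]] = []
    all_keys: list[tuple[str, str, int]] = []
    for key, sub in per_fy:
        all_keys.append(key)
        situations = set(sub["situation"])
        if bool(sub["facility_level_a"].iloc[0]):
            continue
        if situations & {"E", "F"}:
            continue
        if situations & _DUPLICATABLE:
            eligible.append(key)

    n_rows = len(all_keys)
    n1 = int(round(config.dup_scenario1_rate * n_rows))
    n2 = int(round(config.dup_scenario2_rate * n_rows))
    if n1 + n2 == 0:
        return extracts
    if n1 + n2 > len(eligible):
        raise ConfigurationError(
            "dup_scenario1_rate/dup_scenario2_rate: request "
            f"{n1 + n2} duplicates but only {len(eligible)} eligible rows"
        )

    rng = _rng(config.seed, _DUP_STREAM)
    chosen_idx = rng.choice(len(eligible), size=n1 + n2, replace=False)
    chosen = [eligible[i] for i in chosen_idx]
    scenario1 = set(chosen[:n1])

    rep = extracts.reporting.set_index(["facility_name", "county", "year"], drop=False)
    ind = extracts.indicators.set_index(["facility_name", "county", "year"], drop=False)
    lab = labels.set_index(
        ["facility_name", "county", "year", "area_code"], drop=False
    )

    new_rep: list[pd.DataFrame] = [extracts.reporting]
    new_ind: list[pd.DataFrame] = [extracts.indicators]
    dup_rows: list[dict] = []
    for gi, key in enumerate(chosen):
        grng = _rng(config.seed, _DUP_STREAM, 1, gi)
        rep_copy = rep.loc[[key]].reset_index(drop=True).copy()
        ind_copy = ind.loc[[key]].reset_index(drop=True).copy()
        scenario = "scenario1" if key in scenario1 else "scenario2"
        if scenario == "scenario1":
            # resample the first perturbable area's counts to force a conflict
            for i, row in rep_copy.iterrows():
                label = lab.loc[(*key, row["area_code"]), "situation"]
                if label not in _DUPLICATABLE:
                    continue
                expected = int(row["expected_reports"])
                old_actual = int(row["actual_reports"])
                choices = [a for a in range(1, expected + 1) if a != old_actual]
                actual = int(grng.choice(choices))
                on_time = (
                    int(grng.integers(1, actual + 1)) if label in {"B", "G"} else 0
                )
                rep_copy.loc[i, "actual_reports"] = actual
                rep_copy.loc[i, "actual_on_time"] = on_time
                rep_copy.loc[i, "reporting_rate_pct"] = 100.0 * actual / expected
                rep_copy.loc[i, "reporting_rate_on_time_pct"] = (
                    100.0 * on_time / expected
                )
                break
        new_rep.append(rep_copy)
        new_ind.append(ind_copy)
        dup_rows.append(
            {
                "facility_name": key[0],
                "county": key[1],
                "year": key[2],
                "scenario": scenario,
            }
        )

    reporting = pd.concat(new_rep, ignore_index=True)
    indicators = pd.concat(new_ind, ignore_index=True)
    shuffle_rng = _rng(config.seed, _DUP_STREAM, 2)
    reporting = reporting.iloc[
        shuffle_rng.permutation(len(reporting))
    ].reset_index(drop=True)
    indicators = indicators.iloc[
        shuffle_rng.permutation(len(indicators))
    ].reset_index(drop=True)
    return SyntheticExtracts(
        reporting=reporting,
        indicators=indicators,
        truth_labels=extracts.truth_labels,
        truth_duplicates=pd.DataFrame(dup_rows),
    )


def write_sources(
    registry: pd.DataFrame, extracts: SyntheticExtracts, out_dir: str | Path
) -> dict[str, Path]:
    """Write the four delimited-text source files.

    Blank indicator cells are written as empty fields (never a marker
    string), matching how the platform exports unreported zeros.
    """
    if registry.empty:
        raise ConfigurationError("n_facilities: registry is empty, nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "facility_list": out / "facility_list.csv",
        "emr_list": out / "emr_list.csv",
        "reporting_extract": out / "reporting_extract.csv",
        "indicator_extract": out / "indicator_extract.csv",
    }
    registry.drop(columns=["has_emr"]).to_csv(paths["facility_list"], index=False)
    registry.loc[registry["has_emr"], ["facility_name", "county"]].to_csv(
        paths["emr_list"], index=False
    )
    extracts.reporting.to_csv(paths["reporting_extract"], index=False)
    indicators = extracts.indicators.copy()
    for col in INDICATOR_COLUMNS:
        indicators[col] = indicators[col].astype("Int64")
    indicators.to_csv(paths["indicator_extract"], index=False)
    return paths


def write_truth(extracts: SyntheticExtracts, out_dir: str | Path) -> dict[str, Path]:
    """Write the generator's ground truth (labels and duplicate groups)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_labels": out / "truth_labels.csv",
        "truth_duplicates": out / "truth_duplicates.csv",
    }
    extracts.truth_labels.to_csv(paths["truth_labels"], index=False)
    extracts.truth_duplicates.to_csv(paths["truth_duplicates"], index=False)
    return paths
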