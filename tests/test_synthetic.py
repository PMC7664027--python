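"""The synthetic generator: determinism, pattern fidelity, mixtures,
duplicate injection and source-file writing."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dhis2clean.areas import AREAS, AREA_CODES, INDICATOR_COLUMNS
from dhis2clean.classify import classify_labels
from dhis2clean.errors import ConfigurationError
from dhis2clean.synthetic import (
    DEFAULT_SITUATION_MIX,
    GeneratorConfig,
    generate_extracts,
    generate_facility_registry,
    inject_duplicates,
    write_sources,
)

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


def _triples(extracts):
    """(situation, cpc, rr, rrt) per generated (facility, year, area)."""
    ind_cols = list(INDICATOR_COLUMNS)
    widths = {a.code: a.n_indicators for a in AREAS}
    ind = extracts.indicators.set_index(
        ["facility_name", "county", "year", "area_code"]
    )
    rows = []
    for r in extracts.reporting.itertuples():
        key = (r.facility_name, r.county, r.year, r.area_code)
        cells = ind.loc[key, ind_cols[: widths[r.area_code]]]
        cpc = 100.0 * cells.notna().sum() / widths[r.area_code]
        rows.append((key, cpc, r.reporting_rate_pct, r.reporting_rate_on_time_pct))
    return rows


def test_registry_cardinality_and_domains():
    registry = generate_facility_registry(GeneratorConfig(n_facilities=3, seed=1))
    assert len(registry) == 3
    assert registry["facility_name"].is_unique
    assert set(registry["level"]) <= {"II", "III", "IV", "V", "VI"}


def test_registry_seeded_determinism():
    cfg = GeneratorConfig(n_facilities=10, seed=42)
    a = generate_facility_registry(cfg)
    b = generate_facility_registry(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_prefix_stability_under_growth():
    """Adding facilities or years must not reshuffle earlier draws."""
    small = GeneratorConfig(n_facilities=5, seed=9, years=(2011, 2012))
    big = GeneratorConfig(n_facilities=8, seed=9, years=(2011, 2012, 2013))
    ex_small = generate_extracts(generate_facility_registry(small), small)
    ex_big = generate_extracts(generate_facility_registry(big), big)
    key = ["facility_name", "year", "area_code"]
    sub = ex_big.reporting.merge(
        ex_small.reporting[key], on=key
    ).sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        sub, ex_small.reporting.sort_values(key).reset_index(drop=True)
    )


@pytest.mark.parametrize("bad", [dict(n_facilities=0), dict(blank_zero_rate=1.5),
                                 dict(years=()), dict(years=(2012, 2011))])
def test_invalid_config_names_field(bad):
    with pytest.raises(ConfigurationError):
        GeneratorConfig(**bad).validate()


def test_mix_must_sum_to_one():
    with pytest.raises(ConfigurationError, match="situation_mix"):
        GeneratorConfig(situation_mix={"G": 0.5, "H": 0.4}).validate()


_PATTERNS = {
    "A": lambda c, rr, rrt: c == 0 and rr == 0 and rrt == 0,
    "B": lambda c, rr, rrt: c == 0 and 0 < rrt <= rr <= 100,
    "C": lambda c, rr, rrt: c == 0 and 0 < rr <= 100 and rrt == 0,
    "D": lambda c, rr, rrt: c > 0 and rr == 0 and rrt == 0,
    "E": lambda c, rr, rrt: c > 0 and rr > 100 and 0 < rrt <= 100,
    "F": lambda c, rr, rrt: c > 0 and rr > 100 and rrt > 100,
    "G": lambda c, rr, rrt: c > 0 and 0 < rrt <= rr <= 100,
    "H": lambda c, rr, rrt: c > 0 and 0 < rr <= 100 and rrt == 0,
}


@pytest.mark.parametrize("label", sorted(_PATTERNS))
def test_pure_mixture_reproduces_pattern(label):
    """A single-situation mixture emits only that situation's pattern."""
    cfg = GeneratorConfig(
        n_facilities=6,
        seed=2,
        years=(2011, 2012),
        situation_mix={label: 1.0},
        facility_level_a_rate=0.0,
        dup_scenario1_rate=0,
        dup_scenario2_rate=0,
    )
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    for key, cpc, rr, rrt in _triples(extracts):
        assert _PATTERNS[label](cpc, rr, rrt), (key, cpc, rr, rrt)


def test_truth_labels_match_emitted_patterns_under_default_mix():
    """Re-classifying every emitted triple recovers its truth label."""
    cfg = GeneratorConfig(
        n_facilities=60, seed=5, dup_scenario1_rate=0, dup_scenario2_rate=0
    )
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    truth = extracts.truth_labels.set_index(
        ["facility_name", "county", "year", "area_code"]
    )["situation"]
    for key, cpc, rr, rrt in _triples(extracts):
        label = classify_labels([cpc], [rr], [rrt])[0]
        assert label == truth.loc[key], key


def test_count_percentage_coherence():
    cfg = GeneratorConfig(n_facilities=30, seed=8, dup_scenario1_rate=0,
                          dup_scenario2_rate=0)
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    rep = extracts.reporting
    np.testing.assert_allclose(
        rep["reporting_rate_pct"],
        100.0 * rep["actual_reports"] / rep["expected_reports"],
    )
    np.testing.assert_allclose(
        rep["reporting_rate_on_time_pct"],
        100.0 * rep["actual_on_time"] / rep["expected_reports"],
    )


def test_mixture_recovery_within_three_standard_errors():
    """Empirical per-area situation frequencies track the configured mix."""
    cfg = GeneratorConfig(
        n_facilities=250,  # x 8 years = 2000 facility-years per area
        seed=13,
        facility_level_a_rate=0.0,
        dup_scenario1_rate=0,
        dup_scenario2_rate=0,
    )
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    n = 250 * 8
    counts = (
        extracts.truth_labels.groupby(["area_code", "situation"]).size()
    )
    for code in AREA_CODES:
        for label, p in cfg.resolved_mix()[code].items():
            observed = counts.get((code, label), 0) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= max(3 * se, 1e-12) or (
                p < 3 / n  # too rare to expect a draw either way
            ), (code, label, observed, p)


def test_facility_level_nonreporting_rate():
    cfg = GeneratorConfig(n_facilities=125, seed=21, dup_scenario1_rate=0,
                          dup_scenario2_rate=0)
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    per_fy = extracts.truth_labels.groupby(["facility_name", "year"])[
        "facility_level_a"
    ].first()
    share = per_fy.mean()
    se = np.sqrt(0.5 * 0.5 / len(per_fy))
    assert abs(share - 0.5) <= 3 * se


def test_duplicate_injection_counts_and_scenarios():
    cfg = GeneratorConfig(
        n_facilities=25, seed=4, dup_scenario1_rate=0.05, dup_scenario2_rate=0.1
    )
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    n_rows = 25 * 8
    with_dups = inject_duplicates(extracts, cfg)
    n1, n2 = round(0.05 * n_rows), round(0.1 * n_rows)
    assert len(with_dups.truth_duplicates) == n1 + n2
    assert (with_dups.truth_duplicates["scenario"] == "scenario1").sum() == n1
    # each duplicated facility-year contributes 6 extra area rows
    assert len(with_dups.reporting) == len(extracts.reporting) + 6 * (n1 + n2)

    rep = with_dups.reporting
    rates = ["reporting_rate_pct", "reporting_rate_on_time_pct"]
    for r in with_dups.truth_duplicates.itertuples():
        group = rep[
            (rep.facility_name == r.facility_name) & (rep.year == r.year)
        ]
        distinct = group.groupby("area_code")[rates].nunique().max().max()
        if r.scenario == "scenario2":
            assert distinct == 1, "verbatim copy must match everywhere"
        else:
            assert distinct == 2, "conflicting copy must differ somewhere"


def test_duplicate_injection_identity_and_overflow():
    cfg = GeneratorConfig(n_facilities=5, seed=4)
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    same = inject_duplicates(
        extracts,
        GeneratorConfig(n_facilities=5, seed=4, dup_scenario1_rate=0,
                        dup_scenario2_rate=0),
    )
    pd.testing.assert_frame_equal(same.reporting, extracts.reporting)
    with pytest.raises(ConfigurationError):
        inject_duplicates(
            extracts,
            GeneratorConfig(n_facilities=5, seed=4, dup_scenario1_rate=1.0,
                            dup_scenario2_rate=1.0),
        )


def test_write_sources_deterministic_bytes(tmp_path):
    cfg = GeneratorConfig(n_facilities=8, seed=3, dup_scenario1_rate=0.02,
                          dup_scenario2_rate=0.02)

    def digest(sub):
        registry = generate_facility_registry(cfg)
        extracts = inject_duplicates(generate_extracts(registry, cfg), cfg)
        paths = write_sources(registry, extracts, tmp_path / sub)
        return {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in paths.items()
        }

    assert digest("a") == digest("b")


def test_write_sources_blanks_are_empty_fields(tmp_path):
    cfg = GeneratorConfig(n_facilities=4, seed=6, situation_mix={"B": 1.0},
                          facility_level_a_rate=0.0, blank_zero_rate=1.0,
                          dup_scenario1_rate=0, dup_scenario2_rate=0)
    registry = generate_facility_registry(cfg)
    extracts = generate_extracts(registry, cfg)
    paths = write_sources(registry, extracts, tmp_path)
    text = Path(paths["indicator_extract"]).read_text()
    header, first = text.splitlines()[:2]
    # all-zero service counts render as empty fields, never a marker token
    assert "NA" not in first and "nan" not in first
    assert first.rstrip(",").count(",") < header.count(",")


def test_write_sources_refuses_empty_registry(tmp_path):
    cfg = GeneratorConfig(n_facilities=2, seed=1)
    extracts = generate_extracts(generate_facility_registry(cfg), cfg)
    with pytest.raises(ConfigurationError):
        write_sources(pd.DataFrame(), extracts, tmp_path)
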