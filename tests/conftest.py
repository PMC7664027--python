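"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from dhis2clean import ingest
from dhis2clean.synthetic import (
    GeneratorConfig,
    generate_extracts,
    generate_facility_registry,
    inject_duplicates,
    write_sources,
    write_truth,
)

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_facilities=40,
        seed=11,
        dup_scenario1_rate=0.02,
        dup_scenario2_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_world(small_config, tmp_path_factory):
    """Registry, extracts (with duplicates) and written source files."""
    out = tmp_path_factory.mktemp("sources")
    registry = generate_facility_registry(small_config)
    extracts = inject_duplicates(
        generate_extracts(registry, small_config), small_config
    )
    paths = write_sources(registry, extracts, out)
    paths.update(write_truth(extracts, out))
    return {
        "config": small_config,
        "registry": registry,
        "extracts": extracts,
        "paths": paths,
    }


@pytest.fixture(scope="session")
def merged(small_world) -> tuple[pd.DataFrame, list]:
    paths = small_world["paths"]
    reporting = ingest.read_reporting_extract(paths["reporting_extract"])
    indicators = ingest.read_indicator_extract(paths["indicator_extract"])
    registry = ingest.build_registry(
        ingest.read_facility_list(paths["facility_list"]),
        ingest.read_emr_list(paths["emr_list"]),
    )
    return ingest.merge_sources(reporting, indicators, registry)


@pytest.fixture(scope="session")
def merged_records(merged) -> pd.DataFrame:
    return merged[0]
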