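"""Rank tests against independent oracles, and the distribution table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dhis2clean.areas import AREA_CODES
from dhis2clean.errors import NoVariationError
from dhis2clean.stats import (
    friedman_test,
    per_year_counts,
    posthoc_pairwise,
    situation_distribution,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# Friedman


def test_friedman_dominant_column_gets_top_mean_rank():
    rng = np.random.default_rng(1)
    matrix = rng.integers(0, 50, size=(8, 6)).astype(float)
    matrix[:, 4] = matrix.max(axis=1) + rng.integers(1, 10, size=8)
    result = friedman_test(pd.DataFrame(matrix, columns=AREA_CODES))
    assert result.mean_ranks["PEP"] == 6.0


def test_friedman_identical_treatments_degenerate():
    matrix = np.tile([3.0, 3.0, 3.0, 3.0, 3.0, 3.0], (8, 1))
    result = friedman_test(matrix)
    assert result.statistic == 0.0 and result.p_value == 1.0
    assert all(r == 3.5 for r in result.mean_ranks.values())


def test_friedman_mean_ranks_sum_invariant():
    rng = np.random.default_rng(2)
    for _ in range(20):
        k = int(rng.integers(2, 8))
        matrix = rng.normal(size=(int(rng.integers(2, 10)), k))
        result = friedman_test(matrix)
        assert sum(result.mean_ranks.values()) == pytest.approx(k * (k + 1) / 2)


def test_friedman_invariant_under_monotone_block_transform():
    rng = np.random.default_rng(3)
    matrix = rng.integers(0, 100, size=(6, 4)).astype(float)
    transformed = matrix.copy()
    transformed[0] = np.exp(matrix[0] / 50.0)  # strictly increasing per block
    transformed[1] = matrix[1] ** 3 + 5
    a, b = friedman_test(matrix), friedman_test(transformed)
    assert a.statistic == pytest.approx(b.statistic)


def test_friedman_agrees_with_scipy():
    rng = np.random.default_rng(4)
    matrix = rng.integers(0, 30, size=(8, 6)).astype(float)
    ours = friedman_test(matrix)
    ref = sps.friedmanchisquare(*matrix.T)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


@pytest.mark.parametrize(
    "matrix",
    [
        [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.5, 3.5, 2.0]],
        [[10.0, 5.0, 1.0], [8.0, 6.0, 2.0], [9.0, 4.0, 3.0]],
    ],
)
def test_friedman_p_near_exhaustive_permutation_oracle(matrix):
    """Chi-square p tracks the exact within-block permutation distribution.

    On 3 blocks x 3 treatments all (3!)^3 = 216 within-block orderings are
    enumerable; the chi-square approximation at N=3 is known to be coarse,
    so agreement is asserted to 0.1.
    """
    matrix = np.asarray(matrix)
    observed = friedman_test(matrix)
    stats = [
        friedman_test(np.asarray(perm)).statistic
        for perm in itertools.product(
            *[list(itertools.permutations(row)) for row in matrix]
        )
    ]
    p_exact = float(np.mean(np.asarray(stats) >= observed.statistic - 1e-12))
    assert abs(observed.p_value - p_exact) <= 0.1


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def test_wilcoxon_all_same_sign_distinct_magnitudes():
    """All 8 differences one-signed: W=0, Z = -18/sqrt(51) = -2.521."""
    x = np.arange(1.0, 9.0)
    y = x + np.arange(1.0, 9.0)
    result = wilcoxon_signed_rank(y, x)
    assert result.statistic == 0.0
    assert abs(result.z_value) == pytest.approx(18 / np.sqrt(51))
    assert round(abs(result.z_value), 3) == 2.521
    assert result.p_value == pytest.approx(0.0117, abs=5e-4)
    # the exact tail 2/2^8 is reported alongside the approximation
    assert result.p_exact == pytest.approx(2 / 256)


def test_wilcoxon_minority_ranksum_three():
    """Two smallest-magnitude differences opposing: W=3, |Z| = 15/sqrt(51)."""
    d = np.array([-1.0, -2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    result = wilcoxon_signed_rank(d, np.zeros(8))
    assert result.statistic == 3.0
    assert round(abs(result.z_value), 3) == 2.100


def test_wilcoxon_z_is_negative_by_convention():
    x = np.arange(1.0, 9.0)
    assert wilcoxon_signed_rank(x + 1, x).z_value < 0
    assert wilcoxon_signed_rank(x - 1, x).z_value < 0


def test_wilcoxon_matches_scipy_approximation():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.integers(0, 40, size=8).astype(float)
        y = rng.integers(0, 40, size=8).astype(float)
        if np.all(x == y):
            continue
        ours = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=False, method="approx")
        assert abs(ours.z_value) == pytest.approx(abs(ref.zstatistic))
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_wilcoxon_exact_matches_scipy_exact():
    x = np.arange(1.0, 9.0)
    y = x + np.array([3.0, -1.0, 4.0, 2.0, -5.0, 9.0, 7.0, 6.0])
    ours = wilcoxon_signed_rank(y, x)
    ref = sps.wilcoxon(y, x, method="exact")
    assert ours.p_exact == pytest.approx(ref.pvalue)


def test_wilcoxon_no_variation_is_explicit():
    x = np.arange(1.0, 9.0)
    with pytest.raises(NoVariationError):
        wilcoxon_signed_rank(x, x)


def test_wilcoxon_max_z_attained_iff_one_signed():
    """|Z| caps at n(n+1)/4 / sqrt(n(n+1)(2n+1)/24) for untied differences."""
    n = 8
    z_max = (n * (n + 1) / 4) / np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    rng = np.random.default_rng(6)
    for _ in range(20):
        signs = rng.choice([-1.0, 1.0], size=n)
        d = signs * np.arange(1.0, n + 1)
        z = abs(wilcoxon_signed_rank(d, np.zeros(n)).z_value)
        assert z <= z_max + 1e-12
        assert (z == pytest.approx(z_max)) == (len(set(signs)) == 1)


# ---------------------------------------------------------------------------
# pairwise post hoc


def test_posthoc_pair_count_and_direction():
    rng = np.random.default_rng(7)
    matrix = pd.DataFrame(
        rng.integers(0, 30, size=(8, 6)), columns=AREA_CODES, index=range(2011, 2019)
    )
    # PEP strictly dominates every year, with distinct untied margins over HCT
    matrix["PEP"] = matrix["HCT"] + matrix.max(axis=1) + np.arange(1, 9) * 100
    results = posthoc_pairwise(matrix)
    assert len(results) == 15
    pep_vs_hct = next(r for r in results if set(r.pair) == {"PEP", "HCT"})
    assert pep_vs_hct.direction_summary == "Higher in PEP for 8 years"
    assert round(abs(pep_vs_hct.z_value), 3) == 2.521


def test_posthoc_identical_columns_no_variation():
    matrix = pd.DataFrame(
        {"X": [1, 2, 3, 4], "Y": [1, 2, 3, 4], "Z": [2, 3, 4, 5]}
    )
    results = posthoc_pairwise(matrix)
    xy = next(r for r in results if set(r.pair) == {"X", "Y"})
    assert "no variation" in xy.direction_summary
    assert xy.p_value == 1.0


def test_posthoc_bonferroni_option():
    rng = np.random.default_rng(8)
    matrix = pd.DataFrame(rng.integers(0, 30, size=(8, 6)), columns=AREA_CODES)
    adjusted = posthoc_pairwise(matrix, bonferroni=True)
    for r in adjusted:
        if r.p_adjusted is not None:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 15))


# ---------------------------------------------------------------------------
# distribution table and count matrices


def test_distribution_table_percentages_partition():
    counts = {code: {"G": 92, "H": 8} for code in AREA_CODES}
    table = situation_distribution(counts, 100)
    assert (table.percentages.loc["total_retained_pct"] == 100.0).all()
    assert (table.percentages.loc["total_removed_pct"] == 0.0).all()

    counts = {"HCT": {"B": 50, "G": 50}}
    table = situation_distribution(counts, 100)
    assert table.percentages.loc["B", "HCT"] == 50.0
    assert table.percentages.loc["total_retained_pct", "HCT"] == 50.0


def test_distribution_table_includes_duplicates_row():
    counts = {"HCT": {"G": 90}}
    table = situation_distribution(counts, 100, duplicate_removed=10)
    assert table.percentages.loc["duplicates", "HCT"] == 10.0
    removed = table.percentages.loc["total_removed_pct", "HCT"]
    retained = table.percentages.loc["total_retained_pct", "HCT"]
    assert removed + retained == 100.0


def test_distribution_zero_denominator_is_undefined():
    table = situation_distribution({"BS": {"G": 0}}, 0)
    assert table.percentages["BS"].isna().all()


def test_per_year_counts_marginals():
    rows = []
    for year in range(2011, 2019):
        for code in AREA_CODES:
            for s in ["B"] * (2 if code == "PEP" else 1) + ["G"]:
                rows.append({"year": year, "area_code": code, "situation": s})
    df = pd.DataFrame(rows)
    area_records = {c: df[df.area_code == c] for c in AREA_CODES}
    matrix = per_year_counts(area_records, "B")
    assert matrix.shape == (8, 6)
    assert (matrix["PEP"] == 2).all() and (matrix["HCT"] == 1).all()
    totals = {
        c: (area_records[c]["situation"] == "B").sum() for c in AREA_CODES
    }
    assert matrix.sum(axis=0).to_dict() == totals


def test_per_year_counts_single_record():
    df = pd.DataFrame([{"year": 2013, "area_code": "HCT", "situation": "B"}])
    matrix = per_year_counts({"HCT": df}, "B")
    assert matrix.loc[2013, "HCT"] == 1 and matrix.to_numpy().sum() == 1
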