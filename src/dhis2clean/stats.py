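"""Distribution analysis of error situations across programmatic areas.

Two families of outputs:

* the per-area situation distribution table — for each programmatic area,
  the percentage of analysis-dataset records falling in each situation,
  plus the total removed/retained split;
* nonparametric rank tests on yearly counts of a selected situation.  The
  counts form an N-year x 6-area matrix of related samples (the same
  years observed in every area), so differences between areas are tested
  with a Friedman analysis of variance by ranks, followed by pairwise
  Wilcoxon signed-rank post hoc tests.

The rank tests are implemented directly from the rank formulas rather
than delegated, because the analysis needs the per-area mean ranks (ranks
ascend with count, so the most-affected area approaches mean rank 6), the
tie-corrected statistic, and a Z convention where the smaller rank-sum
side makes Z negative.  ``scipy`` equivalents serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .areas import AREA_CODES
from .classify import EXCLUDED_LABELS, RETAINED_LABELS
from .errors import NoVariationError

__all__ = [
    "RankTestResult",
    "SituationDistributionTable",
    "situation_distribution",
    "per_year_counts",
    "friedman_test",
    "wilcoxon_signed_rank",
    "posthoc_pairwise",
]


@dataclass
class RankTestResult:
    """Outcome of one rank test."""

    method: str
    statistic: float
    p_value: float
    z_value: float | None = None
    p_exact: float | None = None
    mean_ranks: dict[str, float] | None = None
    n: int = 0
    pair: tuple[str, str] | None = None
    direction_summary: str | None = None
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
        }
        for key in (
            "z_value",
            "p_exact",
            "mean_ranks",
            "pair",
            "direction_summary",
            "p_adjusted",
        ):
            value = getattr(self, key)
            if value is not None:
                out[key] = list(value) if key == "pair" else value
        return out


# ---------------------------------------------------------------------------
# distribution table


@dataclass
class SituationDistributionTable:
    """Per-area situation percentages over the analysis dataset.

    ``percentages`` is rounded for presentation; ``fractions`` keeps the
    raw ratios.  Columns whose area had no analysis-dataset rows are
    undefined (NaN), not zero.
    """

    percentages: pd.DataFrame
    fractions: pd.DataFrame
    n_analysis: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_analysis": self.n_analysis,
            "percentages": {
                col: {
                    row: (None if pd.isna(v) else float(v))
                    for row, v in self.percentages[col].items()
                }
                for col in self.percentages.columns
            },
        }


def situation_distribution(
    area_counts: dict[str, dict[str, int]],
    n_analysis: dict[str, int] | int,
    duplicate_removed: int = 0,
    ndigits: int = 2,
) -> SituationDistributionTable:
    """Build the per-area situation distribution table.

    ``area_counts`` are the label counts from the per-area treatment
    stage; ``n_analysis`` is the analysis-dataset record count (the
    denominator), either one number for all areas or one per area.
    ``duplicate_removed`` is the number of facility-records deleted at the
    duplicate stage; each of those affected all six areas, so the same
    count forms the duplicates row in every column.  Per area, situation
    rows plus the duplicates row partition the analysis dataset, so
    removed + retained is exactly 100.
    """
    if isinstance(n_analysis, int):
        n_analysis = {code: n_analysis for code in AREA_CODES}
    labels = sorted(EXCLUDED_LABELS - {"E", "F", "ERRX"}) + sorted(RETAINED_LABELS)
    rows = labels + ["duplicates", "total_removed_pct", "total_retained_pct"]
    frac = pd.DataFrame(index=rows, columns=list(area_counts), dtype=float)
    for code, counts in area_counts.items():
        n = n_analysis.get(code, 0)
        if n == 0:
            frac[code] = np.nan
            continue
        for label in labels:
            frac.loc[label, code] = counts.get(label, 0) / n
        frac.loc["duplicates", code] = duplicate_removed / n
        retained = sum(counts.get(l, 0) for l in RETAINED_LABELS) / n
        frac.loc["total_retained_pct", code] = retained
        frac.loc["total_removed_pct", code] = 1.0 - retained
    return SituationDistributionTable(
        percentages=(frac * 100).round(ndigits),
        fractions=frac,
        n_analysis={c: int(n_analysis.get(c, 0)) for c in area_counts},
    )


def per_year_counts(
    area_records: dict[str, pd.DataFrame],
    situation: str,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Years x areas matrix of records in the given situation.

    Input is the disaggregated, classified (pre-situation-treatment)
    per-area datasets; each cell counts that area's rows carrying the
    selected situation label in that year.
    """
    if years is None:
        seen: set[int] = set()
        for df in area_records.values():
            seen.update(int(y) for y in df["year"].unique())
        years = sorted(seen)
    matrix = pd.DataFrame(0, index=years, columns=list(area_records), dtype=int)
    for code, df in area_records.items():
        counts = df.loc[df["situation"] == situation, "year"].value_counts()
        for year, count in counts.items():
            matrix.loc[int(year), code] = int(count)
    return matrix


# ---------------------------------------------------------------------------
# Friedman


def _block_ranks(matrix: np.ndarray) -> np.ndarray:
    """Within-block ranks, ascending in value, average ranks for ties."""
    return np.apply_along_axis(sps.rankdata, 1, matrix)


def friedman_test(
    matrix: pd.DataFrame | np.ndarray, tie_correction: bool = True
) -> RankTestResult:
    """Friedman two-way analysis of variance by ranks.

    Blocks are rows (years), treatments are columns (areas).  Values are
    ranked ascending within each block (largest value -> rank k), ties get
    average ranks.  The chi-square statistic with tie correction is

        chi2 = (k - 1) * sum_j (R_j - N(k+1)/2)^2 / (A - C),

    with R_j the column rank sums, A the sum of squared ranks and
    C = N k (k+1)^2 / 4; without ties the denominator reduces to the
    classical N k (k+1) (k-1) / 12.  p comes from the chi-square
    distribution with k-1 degrees of freedom.  Identical columns in every
    block give statistic 0 and p 1.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = [str(c) for c in matrix.columns]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        columns = [str(j) for j in range(values.shape[1])]
    n_blocks, k = values.shape
    if n_blocks < 2 or k < 2:
        raise ValueError("Friedman test needs at least 2 blocks and 2 treatments")

    ranks = _block_ranks(values)
    rank_sums = ranks.sum(axis=0)
    mean_ranks = rank_sums / n_blocks

    ss_treat = float(np.sum((rank_sums - n_blocks * (k + 1) / 2.0) ** 2))
    if tie_correction:
        denom = float(np.sum(ranks**2)) - n_blocks * k * (k + 1) ** 2 / 4.0
    else:
        denom = n_blocks * k * (k + 1) * (k - 1) / 12.0
    if denom <= 0:  # every block entirely tied
        statistic, p_value = 0.0, 1.0
    else:
        statistic = (k - 1) * ss_treat / denom
        p_value = float(sps.chi2.sf(statistic, df=k - 1))
    return RankTestResult(
        method="friedman",
        statistic=float(statistic),
        p_value=p_value,
        mean_ranks={c: float(r) for c, r in zip(columns, mean_ranks)},
        n=n_blocks,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_two_sided_p(abs_ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided tail of the signed-rank statistic by sign enumeration.

    Under the null every difference is independently positive or negative
    with probability 1/2, so the distribution of the positive rank sum is
    the convolution over sign vectors; it is symmetric about half the
    total rank sum, so twice the lower tail of min(R+, R-) is the
    two-sided p.  Feasible for the small n of year-blocked counts.
    """
    n = len(abs_ranks)
    total = float(abs_ranks.sum())
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        r_pos = float(np.dot(signs, abs_ranks))
        if min(r_pos, total - r_pos) <= w_obs + 1e-12:
            count += 1
    return min(1.0, count / 2.0**n)


def wilcoxon_signed_rank(
    x: np.ndarray | list, y: np.ndarray | list, exact_limit: int = 16
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; absolute differences are ranked with
    average ranks for ties; the statistic is W = min(positive rank sum,
    negative rank sum).  The normal approximation without continuity
    correction gives

        Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48),

    negative by construction since W is the smaller side.  The exact
    sign-enumeration p is reported alongside whenever n <= ``exact_limit``
    — for very small n the normal approximation is known to overstate the
    tail (e.g. n = 8 all-same-sign: approximate p 0.0117 vs exact 0.0078).

    Raises
    ------
    NoVariationError
        If every difference is zero, the test is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d paired samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise NoVariationError("all paired differences are zero")
    abs_ranks = sps.rankdata(np.abs(d))
    r_pos = float(abs_ranks[d > 0].sum())
    r_neg = float(abs_ranks[d < 0].sum())
    w = min(r_pos, r_neg)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(abs_ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise NoVariationError("zero variance after tie correction")
    z = (w - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    p_exact = _exact_two_sided_p(abs_ranks, w) if n <= exact_limit else None
    return RankTestResult(
        method="wilcoxon-signed-rank",
        statistic=w,
        z_value=float(z),
        p_value=p,
        p_exact=p_exact,
        n=n,
    )


def _direction(later: np.ndarray, earlier: np.ndarray, name: str) -> str:
    higher = int(np.sum(later > earlier))
    lower = int(np.sum(later < earlier))
    if higher >= lower:
        return f"Higher in {name} for {higher} years"
    return f"Lower in {name} for {lower} years"


def posthoc_pairwise(
    matrix: pd.DataFrame, bonferroni: bool = False
) -> list[RankTestResult]:
    """Wilcoxon signed-rank tests for all unordered column pairs.

    Pairs are labelled later-column versus earlier-column, and the
    direction summary counts the years in which the later column's count
    strictly exceeds (or falls below) the earlier one's.  Columns with no
    variation yield a result with p 1 and a "no variation" summary rather
    than an error.  ``bonferroni`` multiplies p-values by the number of
    pairs (capped at 1); the raw p is always kept.
    """
    columns = [str(c) for c in matrix.columns]
    values = matrix.to_numpy(dtype=float)
    pairs = list(itertools.combinations(range(len(columns)), 2))
    results: list[RankTestResult] = []
    for i, j in pairs:
        earlier, later = values[:, i], values[:, j]
        name_e, name_l = columns[i], columns[j]
        try:
            res = wilcoxon_signed_rank(later, earlier)
        except NoVariationError:
            res = RankTestResult(
                method="wilcoxon-signed-rank",
                statistic=0.0,
                p_value=1.0,
                z_value=None,
                n=0,
                direction_summary="no variation between the two areas",
            )
            res.pair = (name_l, name_e)
            results.append(res)
            continue
        res.pair = (name_l, name_e)
        res.direction_summary = _direction(later, earlier, name_l)
        if bonferroni:
            res.p_adjusted = min(1.0, res.p_value * len(pairs))
        results.append(res)
    return results
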