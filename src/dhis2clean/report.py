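"""Human-readable markdown report tying the cleaning stages together.

The renderer only formats numbers that already exist in the JSON
artifacts (cycle reports, distribution table, rank-test results); it
never computes anything of its own, so every figure in the report is
recomputable from the artifacts.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence


def _table(header: Sequence[str], rows: Iterable[Sequence[object]]) -> str:
    lines = [
        "| " + " | ".join(str(h) for h in header) + " |",
        "|" + "|".join(" --- " for _ in header) + "|",
    ]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def _fmt(value: object) -> str:
    if value is None:
        return "undefined"
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def render_report(
    cycles: Sequence[Mapping],
    distribution: Mapping | None = None,
    stats_results: Mapping | None = None,
) -> str:
    """Assemble the cleaning report from stage artifacts.

    ``cycles`` are cycle-report dicts; ``distribution`` is the
    situation-distribution dict (``percentages`` keyed area -> row);
    ``stats_results`` maps situation label -> {"friedman": ..,
    "pairwise": [..]} dicts as serialised by the stats stage.
    """
    parts: list[str] = ["# Data-cleaning report", ""]

    parts.append("## Cleaning cycles")
    parts.append("")
    parts.append(
        _table(
            ["cycle", "rule", "granularity", "rows in", "removed", "rows out"],
            [
                [
                    c["cycle_id"],
                    c["rule"],
                    c.get("granularity", "facility_record"),
                    c["n_in"],
                    c["n_removed"],
                    c["n_out"],
                ]
                for c in cycles
            ],
        )
    )
    parts.append("")

    if distribution:
        percentages = distribution["percentages"]
        areas = list(percentages)
        rows = list(next(iter(percentages.values())))
        parts.append("## Situation distribution by programmatic area (%)")
        parts.append("")
        parts.append(
            _table(
                ["situation"] + areas,
                [
                    [name] + [_fmt(percentages[a].get(name)) for a in areas]
                    for name in rows
                ],
            )
        )
        parts.append("")

    if stats_results:
        for situation, block in stats_results.items():
            parts.append(f"## Rank tests — situation {situation}")
            parts.append("")
            friedman = block.get("friedman")
            if friedman:
                parts.append(
                    f"Friedman chi-square = {_fmt(friedman['statistic'])}, "
                    f"p = {friedman['p_value']:.3f} over {friedman['n']} year blocks."
                )
                parts.append("")
                parts.append(
                    _table(
                        ["area", "mean rank"],
                        [
                            [area, _fmt(rank)]
                            for area, rank in friedman["mean_ranks"].items()
                        ],
                    )
                )
                parts.append("")
            pairwise = block.get("pairwise") or []
            if pairwise:
                parts.append(
                    _table(
                        ["pair", "Z", "p", "direction"],
                        [
                            [
                                "—".join(r.get("pair", ["?", "?"])),
                                _fmt(
                                    round(r["z_value"], 3)
                                    if r.get("z_value") is not None
                                    else None
                                ),
                                f"{r['p_value']:.3f}",
                                r.get("direction_summary", ""),
                            ]
                            for r in pairwise
                        ],
                    )
                )
                parts.append("")

    return "\n".join(parts).rstrip() + "\n"
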