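# dhis2clean

Systematic, auditable cleaning of facility-level HIV-indicator reports
extracted from a DHIS2 national reporting system.

## The problem

National aggregate reporting platforms such as DHIS2 hold years of
facility-level indicator data that analysts want to reuse, but the raw
extracts are dirty in characteristic ways: facilities registered on the
platform that never report, reports submitted on time yet completely
empty, indicator data with no recorded submission rates, reporting rates
above 100%, and duplicated facility-year rows.  `dhis2clean` implements an
iterative screening–diagnosis–treatment pipeline for such data, aimed at
monitoring-and-evaluation teams and researchers preparing facility
reporting data for secondary analyses.  The reference setting is Kenya's
HIV programme reporting (form MOH 731): six programmatic areas — HCT,
PMTCT, CrT, VMMC, PEP and BS with 14, 40, 65, 13, 14 and 3 indicators
respectively — each expecting 12 monthly reports per facility-year.

## The method

Three percentages summarise one facility's annual reporting in one area:

* **RR** (Reporting Rate) = 100 · submitted reports / expected reports
* **RRT** (Reporting Rate on Time) = 100 · on-time reports / expected reports
* **CPC** (Cumulative Percent Completion) = 100 · non-blank indicator
  values / indicators in the area — e.g. 10 values in a 40-indicator
  report is 25% complete.

Every (CPC, RR, RRT) triple is diagnosed into a *situation*: `A` (0,0,0 —
never reported), `B` (0,X,X — empty but submitted), `C` (0,X,0), `D`
(X,0,0 — data without rates), `E`/`F` (rates above 100%, impossible), `G`
(X,X,X — ideal), `H` (X,X,0 — late but substantive), plus `ERRX` for
triples where on-time exceeds submitted.  Treatment runs in ordered
cycles with full accounting: facility-years averaging zero on all three
variables are excluded; records with impossible rates are excluded;
duplicated (facility, county, year) rows are deleted entirely when their
RR/RRT values conflict and deduplicated to one representative when
identical; the survivors fan out into six per-area datasets where only
situations `G` and `H` are retained.  Yearly counts of a chosen situation
across the six areas are then compared with a Friedman analysis of
variance by ranks and pairwise Wilcoxon signed-rank post hoc tests.

A synthetic-data module generates DHIS2-like source files (reporting
extract, indicator extract, facility master list, EMR list) with
injected, labelled anomalies, so the whole pipeline is testable without
access to any national database.

## Worked example

```bash
cat > example.yaml <<'YAML'
generate:
  n_facilities: 150
  seed: 11
  dup_scenario1_rate: 0.005
  dup_scenario2_rate: 0.005
YAML
dhis2clean all --config example.yaml --out demo
```

This generates sources for 150 facilities over 2011–2018 (1,212
facility-records after duplicate injection), cleans them, and writes
`demo/clean/cycles.json`:

```
cycle 1  nonreporting          1212 in   624 removed   588 out
cycle 2  erroneous              588 in     0 removed   588 out
cycle 3  duplicates             588 in    18 removed   570 out
cycle 4  situation_treatment   3420 in  2048 removed  1372 out   (area rows)
```

Cycle 1 removes the facility-years that filed nothing at all (here 51%,
the generator's default non-reporting rate of 0.50 at work).  Cycle 3
resolves the injected duplicate groups.  Cycle 4 operates on 570 × 6 =
3,420 per-area rows and keeps only situations G and H.  The distribution
table in `demo/report.json` (percentages of each area's analysis-dataset
records) comes out as:

```
                      HCT  PMTCT    CrT   VMMC    PEP     BS
A                    2.21   6.29  53.91  92.35  58.50  94.56
B                    2.72   7.31   1.53   2.72  16.16   1.53
...
total_retained_pct  90.31  80.78  39.80   0.85  21.26   0.34
```

Reading it: HCT reporting is largely intact (90% retained), while VMMC
and BS are dominated by area-level non-reporting — few facilities offer
those services — so under 1% of their rows survive.  Empty submissions
(situation B) concentrate in PEP (16.16%), and the Friedman test on
yearly B counts confirms the areas differ (χ² = 30.86, p < 0.001), with
PEP attaining the maximum mean rank of 6.00; the PMTCT–HCT post hoc
Wilcoxon gives Z = −2.536 (p = 0.011), "Higher in PMTCT for 8 years".

Every removal is logged in `demo/clean/audit.jsonl` with its cycle, rule
and reason, and `demo/report.md` renders the same numbers as a readable
report.

## Layout

| module | role |
| --- | --- |
| `dhis2clean.synthetic` | DHIS2-like source generator with labelled anomalies |
| `dhis2clean.ingest` | CSV parsing, facility matching, evaluation-dataset merge |
| `dhis2clean.metrics` | RR, RRT, CPC and facility-year averages |
| `dhis2clean.classify` | situation taxonomy, duplicate detection, screens |
| `dhis2clean.treatment` | cleaning cycles, audit trail, per-area retention |
| `dhis2clean.stats` | distribution table, Friedman and Wilcoxon tests |
| `dhis2clean.cli` | `dhis2clean generate / clean / stats / all` |

See `docs/methods.md` for the modelling and numerical choices.
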