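# Methods

## Data model

The unit of cleaning is the *facility record*: one row per facility per
calendar year holding, for each of the six HIV programmatic areas (HCT,
PMTCT, CrT, VMMC, PEP, BS), the triple

* CPC — Cumulative Percent Completion, 100 · non-blank indicator values /
  indicators in the area (14/40/65/13/14/3 respectively), in [0, 100] by
  construction;
* RR — Reporting Rate, 100 · submitted reports / expected reports;
* RRT — Reporting Rate on Time, 100 · on-time reports / expected reports;

with 12 monthly reports expected per area-year.  RR and RRT measure
submission only; CPC measures content.  An explicit zero is content (the
platform renders unreported zeros as blank cells, which is precisely one
of the data-quality problems the pipeline surfaces); RR/RRT above 100%
are retained through ingestion because they drive diagnosis.  Averages of
the three variables over the six areas are attached to each record, with
missing components treated as zero so that a facility-year absent from
every extract averages to the all-zero non-reporting signature.

## Situation taxonomy

Each triple is diagnosed by a total, pure function evaluated in
precedence order: (RR>100 ∧ RRT>100) → F; RR>100 → E; (RRT>100 ∨
RRT>RR) → ERRX; then the zero/positive patterns A (0,0,0), B (0,+,+),
C (0,+,0), D (+,0,0), G (+,+,+), H (+,+,0).  The nine branches partition
the non-negative octant (verified by property test over 10⁵ random
triples).  `ERRX` is this package's label for triples the eight named
patterns cannot host; since on-time reports are a subset of submitted
reports, RRT exceeding RR (or 100) is as impossible as RR above 100 and
receives the same exclude action.  Out-of-range rates take precedence
over content patterns, so a record with RR>100 is E/F regardless of CPC.

## Cleaning cycles

Default order, each cycle reporting rows in / removed / out and writing
one audit entry per removal:

1. **nonreporting** — drop facility-years with avg CPC = avg RR =
   avg RRT = 0;
2. **erroneous** — drop facility-years containing any E/F/ERRX area (the
   whole record is removed: impossible values discredit the row);
3. **duplicates** — group rows sharing (normalised facility name,
   normalised county, year).  Conflicting groups (any RR/RRT differs;
   compared exactly as parsed, since duplicates stem from one export)
   lose every member; identical groups keep the first row in a stable
   sort by record key.  The record set entering this cycle is the
   *analysis dataset* — the denominator population of the distribution
   table, so that situation rows plus the duplicates row partition each
   area column to exactly 100%;
4. **disaggregation** — fan-out into six per-area datasets (counts
   multiply by six; the cycle reports carry a granularity tag so
   conservation is checkable at both levels);
5. **situation treatment** — per area, keep only G and H, counting every
   label for the distribution table.

The three record-level cycles are configurable in order (`--order`).
Conservation (n_in = n_removed + n_out, consecutive cycles chaining) and
stage-wise idempotence (each stage applied to its own output removes
nothing) are enforced by tests.  Note that CLI-level re-cleaning is not
literally possible — `clean` consumes the four source files and emits
per-area datasets — so idempotence is stated and tested per stage.

Facility matching uses case-folded, whitespace-collapsed name + county;
fuzzy matching is out of scope.  One-sided joins coerce the missing
triple components to zero before classification (indicator data with no
reporting row thereby lands in situation D, data-without-rates), while
`*_missing` flags preserve the raw distinction for audit.  Master-list
rows matching no extract row are dropped with a merge-log entry.

## Rank tests

Yearly counts of a selected situation across the six areas form an
8×6 matrix of related samples.  The Friedman statistic is computed from
within-block ranks ascending in value (largest count → rank 6, so the
most-affected area approaches mean rank 6.00), average ranks for ties,
with the tie-corrected form χ² = (k−1) Σ(R_j − N(k+1)/2)² / (A − C),
A = Σr², C = Nk(k+1)²/4, and p from χ²(k−1).  All-tied blocks give
statistic 0, p 1.  An uncorrected variant is available via
`tie_correction=False`; the corrected form is the default.

Pairwise post hoc comparisons use the Wilcoxon signed-rank test: zero
differences dropped, |d| ranked with average ties, W = min(R⁺, R⁻),
Z = (W − n(n+1)/4) / √(n(n+1)(2n+1)/24 − Σ(t³−t)/48) with no continuity
correction, so Z is negative by construction and |Z| for 8 one-signed
untied differences is 18/√51 = 2.521.  Because n is small, the exact
two-sided tail (2⁻ⁿ sign enumeration, well-defined under ties, n ≤ 16)
is reported alongside the normal approximation; for the one-signed n = 8
case they are 0.0078 vs 0.0117 — a documented discrepancy of the
approximation, not an error.  All 15 area pairs are tested; direction
summaries count the years one area strictly exceeds the other.  No
multiple-testing correction is applied by default (the post hoc p-values
are reported raw); a Bonferroni option exists.

Both tests are implemented from the rank formulas because the analysis
needs mean ranks, the Z sign convention and the exact tail; scipy's
`friedmanchisquare` and `wilcoxon` serve as independent oracles in the
test suite, together with an exhaustive (3!)³ within-block permutation
distribution on 3×3 instances (chi-square approximation agrees with the
exact permutation p to within 0.1 at N = 3, its known coarseness at
that size).

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as a realistic national HIV-reporting profile:

* 8 years (2011–2018), 47 counties, facility levels II–VI with types and
  ownership drawn from fixed catalogues;
* whole-facility non-reporting: with probability 0.50 a facility-year is
  situation A across all six areas at once (about half of facility-years
  in a national extract belong to registered-but-silent facilities);
* per-area situation mixtures: content-rich areas (HCT, PMTCT) dominated
  by G, low-volume services (VMMC, BS) dominated by area-level A, empty
  submissions concentrated in PEP, a trace of E/F (~0.03% of records
  contain an impossible rate) — each area's residual probability mass is
  assigned to area-level A;
* counts first: situations draw submission counts (B/G: 1–12 submitted
  with on-time ≤ submitted; C/H: on-time 0; E/F: 13–24 submitted so RR
  lands in (100, 200] on the count grid), and percentages are always
  100·count/12, keeping counts and percentages coherent;
* blank-rendered zeros: a drawn zero is written as an empty cell with
  probability `blank_zero_rate` (default 1.0, the platform behaviour);
  content situations force at least one positive value so their CPC
  stays above zero;
* duplicates: a fraction of facility-years is copied — verbatim
  (scenario 2) or with one area's counts resampled to force an RR/RRT
  conflict (scenario 1).  Only rows that survive the earlier facility-
  level cycles are eligible (no whole-facility A, no E/F area, at least
  one perturbable area), so injected groups reach the duplicate stage
  intact and recovery is exact.  Rates default to 0.0002 each, the order
  of magnitude of duplicate rows in a national extract;
* randomness: one root seed, child streams per (facility, year, area)
  derived by spawn-key counters, so growing the facility count or year
  range never reshuffles earlier records, and identical configurations
  give byte-identical output files.  Ingest parses floats with Python's
  exact `strtod` so the write→read round trip reproduces every value
  bit-for-bit.

What the generator does **not** emulate: monthly report timestamps
(timeliness exists only as annual counts), true epidemiological indicator
magnitudes (values are arbitrary positive integers), spelling variation
in facility names, areas missing from one extract, and any correlation of
situations across areas within a reporting facility-year beyond the
whole-facility A mechanism — per-area draws are otherwise independent,
which real service-delivery patterns surely violate.  Passing recovery
tests therefore show that the pipeline's rules are implemented exactly,
not that the generator's mixtures match any particular country's data.

## Problem sizes and numerical choices

Recovery and conservation suites run on 250 facilities × 8 years (2,000
facility-years, 12,000 area rows); mixture recovery uses 625 × 8 = 5,000
facility-years per area, with agreement asserted within three binomial
standard errors per (area, situation) cell.  These sizes put sampling
error well below the effects checked while keeping the default test run
fast.  No rounding happens inside metrics or tests; presentation rounds
to two decimals.  Boundary conventions: RR = 100 exactly is in range,
100.01 is flagged; situation comparisons for duplicate scenarios use
exact float equality; the frequency screen flags a facility when its
annual report count in an area exceeds the year-span length
(parameterised, 8 for the default window).

## Known limitations

Duplicate attribution in the distribution table assigns the record-level
duplicate count to every area column equally, since the duplicate key is
record-level; per-area duplicate burden is not modelled.  The pipeline
deletes rather than corrects: no imputation or adjustment for incomplete
reporting is attempted, and the causal origin of situations D, E and F
is out of scope.  Facility matching is exact after normalisation; true
spelling drift between master list and platform requires upstream
linkage.
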