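# Methods

## Scope and design

`oncobudget` is a league-table budget-impact pipeline, not a health-economic
modelling framework: no QALYs, no Markov or partitioned-survival models, no
discounting, no probabilistic sensitivity analysis. It mirrors the kind of
rapid analysis a ministry pharmacoeconomics unit can run with tender prices,
published trial results and expert patient estimates, and makes every
arithmetic step auditable.

The pipeline is: catalog → course cost → life-years gained → cost per
life-year → threshold category → patient numbers → annual cost →
best-option selection → totals and cumulative curve.

## Costing

* Reference patient: adult male, 50 kg, 1.3 m² body surface area. Dose
  rules: flat per administration, per kg, per m². Oral continuous agents
  are encoded as one flat administration per day (cycle length 1 day).
* Unit prices are per mg in LKR (tender prices) or USD; LKR is converted at
  the context's annual average rate (200 LKR/US$ for 2021).
* Curative courses run for the protocol's planned cycles. Palliative
  courses run for the median treatment duration, falling back to median PFS
  (treatment until progression). Months map to cycles as
  `ceil(months × 30.44 / cycle_days)` — a started cycle is dispensed in
  full. The 30.44 is the mean Gregorian month; the ceiling convention is
  this package's choice and is isolated in `cycles_for_exposure`.
* Substitutive regimens subtract the comparator arm's drug cost priced over
  the same exposure; additive regimens do not. A negative net cost is kept
  and flagged, never clamped.
* Vial rounding and wastage are not modelled (continuous dose × unit
  price); administration consumables, staffing and investigations are out
  of scope. Costs are therefore a floor on real acquisition cost.
* Courses under US$1,000 are treated as conventional chemotherapy and
  excluded; the cut is strictly below, so a course at exactly US$1,000
  stays in. For chronic therapies where per-course pricing is meaningless
  (CML tyrosine-kinase inhibitors), `horizon_excess_cost` reports the
  annual-cost difference against a comparator over a fixed horizon instead.

## Effectiveness

* Palliative: life-years = months gained / 12. Basis hierarchy:
  restricted-mean survival gain when reported (robust to long-tailed
  immunotherapy curves), else median OS, else median PFS — which also
  substitutes when control-arm crossover dilutes the OS difference.
* Curative: life-years = Δ(survival proportion at end of follow-up) ×
  residual years, with residual = max(0, LE − mean age at diagnosis −
  follow-up). The rule lives behind a named strategy
  (`RESIDUAL_STRATEGIES`) so an alternative extrapolation (e.g. cancer- and
  age-specific life tables) can be swapped in without touching callers. It
  reproduces the residual multipliers implied by all four curative rows of
  the transcribed tables (20, 9.5, 31.5 and 5 years) from the cataloged
  ages at diagnosis (47, 64.5, 42.5, 62) and the 2021 life expectancy
  of 77.
* No discounting or quality adjustment anywhere; results therefore
  overstate benefit relative to QALY-based thresholds.

## Thresholds and classification

Boundaries are multipliers × per-capita GDP (defaults 1, 3, 4 on
US$3,815 → 3,815 / 11,445 / 15,260). Boundary assignment: the 1× boundary
is exclusive for "highly cost-effective" ("less than per-capita GDP"); the
3× and 4× boundaries belong to the cheaper band ("between 1 and 3 times").
Both conventions are configurable on `ThresholdScheme`; no transcribed row
sits exactly on a boundary, so the choice does not affect the shipped
fixture.

De-escalated options (non-inferior lower dose or shorter duration) are
costed at their own price and divided by the standard option's life-year
gain; both options stay in the catalog as one option group and the cheaper
per life-year wins at selection time.

## Budget impact

Patient numbers are the arithmetic mean of the per-expert estimates,
rounded half-up (Python's banker's rounding is deliberately not used
anywhere a report value is produced; see `round_half_up`). Annual cost is
net course cost × patients. Best-option selection takes the group-wide
minimum cost per life-year jointly across all threshold bands — necessary
because a group's options can land in different printed tables (high-dose
abiraterone pre-docetaxel sits one band above the low-dose option).
Totals are reported raw and in millions to 1 dp. The cumulative curve
ranks selected options by GDP fraction (the league tables' ordering
column, identical to cost-per-life-year order whenever the two columns are
consistent) with deterministic tie-breaks, so it is invariant to input
order and its last ordinate equals the unconstrained total.

## The transcribed-tables fixture

`data/tables_1_2.csv` transcribes the 31 published league-table rows (17
highly cost-effective, 14 cost-effective) with thousands separators
normalised. An arithmetic audit recomputes cost per life-year from each
row's printed course cost and survival gain; a row whose recomputed value,
rounded half-up to whole USD, is more than 1 USD from the printed column is
flagged `inconsistent` — beyond what rounding of the printed inputs
explains. Thirteen rows are flagged; the clearest are transcription or
typesetting errors in the source (a US$504,992 GIST course cost against a
US$35,120 annual cost for 10 patients; a fulvestrant 500 course of US$502
against an implied ≈US$2,049; an erlotinib gain of 8.5 months against an
implied 5.2). Flagged rows are preserved verbatim, excluded from
exact-arithmetic tests, but still classified and totalled by their printed
columns.

The printed footer totals apply best-option selection; the fixture's
`in_printed_total` column transcribes which rows each footer counted. The
Table-1 footer retained erlotinib although gefitinib is cheaper per
life-year; the package's own selection retains gefitinib, so the GDP×1
total computed here (US$5.80 M) sits slightly below the printed
US$6,004,878.24 and is checked at million-level rounding only. The
cost-effective footer (US$7,209,904) reproduces exactly under joint
selection. Totals for the ×4 and unconstrained tiers are supported by the
same operations but have no transcribed inputs, so they are covered by the
monotonicity property (widening the threshold never lowers the total)
rather than numeric reproduction.

## Synthetic catalogs and the oracle

`generate_catalog` draws reproducible catalogs from a seeded
`numpy.random.default_rng`. Defaults emulate the study conditions: 50
indications, three expert estimates per indication with ~30 % relative
dispersion, ~12 % of indications adjuvant/curative (10 of 93 in the source
analysis), unit prices 10–400 LKR/mg, palliative gains 2–24 months,
adjuvant proportion gains 2–15 % over 3/5/10-year follow-up, ages at
diagnosis 40–66, cycle cadences of 7/14/21/28 days, and a mix of additive
and substitutive regimens (comparators share the schedule at 5–50 % of the
price, keeping net costs positive). Five option groups carry a second,
independently priced option.

Every generated catalog ships with a `GroundTruth` computed by a
deliberately naive loop-based oracle inside `synthetic.py` that shares no
code with the pipeline modules (its own dose arithmetic, ceiling, mean,
rounding and threshold chains). Tests require field-level agreement to
1e-9 relative tolerance on 20 independent catalogs.

What the generator does not emulate: multi-component combination regimens
priced jointly, vial sizes, real price–efficacy correlation, dose
reductions and discontinuations, and patient-number uncertainty beyond
i.i.d. expert noise. Passing the oracle equivalence therefore certifies the
arithmetic, not the realism of any particular catalog.

## Numerical conventions and edge cases

* All internal arithmetic is full-precision float; half-up rounding is
  applied only at report time (costs 2 dp, cost/LY whole USD, GDP fraction
  2 dp, patients integer).
* Zero or negative life-year gain raises an explicit "not assessable"
  error and the indication is logged and excluded — never an infinite
  ratio.
* Catalog CSVs are UTF-8, comma-separated, "." decimal mark, no thousands
  separators; floats are written with `repr` and parsed with pandas'
  round-trip parser so generated catalogs survive write/read bit-exactly
  (and `generate` is byte-deterministic per seed).
* Ties in selection and curve ordering break by course cost / annual cost,
  then drug name.

## Problem sizes

The shipped tests and the acceptance script run the fixture (31 rows) and
20 synthetic catalogs of 50 indications + 5 alternatives each; the full
suite completes in a few seconds on one CPU.
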