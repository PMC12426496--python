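# oncobudget

Budget-impact and cost-per-life-year analysis of novel cancer drugs for
resource-limited health systems.

Publicly funded health systems in lower-middle-income countries must decide
which expensive novel cancer drugs to procure from a fixed budget.
`oncobudget` implements a deliberately simple, transparent pipeline for that
decision, built around the league-table analysis performed for Sri Lanka's
state health system: price a full treatment course from regimen dosing rules
and local tender prices, convert pivotal-trial survival evidence into
life-years gained, rank every drug-indication pair by cost per life-year
gained against WHO GDP-multiple thresholds, and aggregate expert
patient-number estimates into per-indication annual budgets and a cumulative
affordability curve.

## The model

For each indication of a novel drug, the cost-effectiveness statistic is the
undiscounted **cost per life-year gained**

```
CLYG = C_net / ΔLY
```

where `C_net` is the direct drug-acquisition cost of one full course for a
reference patient (adult male, 50 kg, 1.3 m² BSA), net of the comparator
arm's drug cost when the novel agent substitutes rather than adds to it, and
`ΔLY` is the survival gain:

* **palliative** — the median (or restricted-mean) OS gain in months / 12;
  PFS gain stands in where control-arm crossover dilutes OS. The course is
  priced over the median treatment duration (median PFS if unreported),
  with a started cycle dispensed in full.
* **curative (adjuvant)** — the absolute gain Δ in the proportion surviving
  (OS, DFS or DSS) at end of follow-up, times the residual years a survivor
  is expected to live: `ΔLY = Δ × max(0, LE − age_dx − follow-up)`.

Each indication is classified against WHO GDP-multiple thresholds
(per-capita GDP × 1 / × 3 / × 4: highly cost-effective, cost-effective,
potentially cost-effective with price reduction, not cost-effective), its
annual budget impact is `C_net ×` (mean of three independent expert patient
estimates), and where several options serve one indication (e.g. low-dose
abiraterone, 6-month trastuzumab, gefitinib vs erlotinib) only the cheapest
per life-year is retained in national totals. Conventional agents with a
course cost under US$1,000 are excluded. De-escalated regimens proven
non-inferior are costed at their own price but divided by the standard
option's life-year gain.

## Worked example

```python
from oncobudget import (RegimenComponent, Regimen, TrialEvidence,
                        IndicationRecord, assess_indication, fixture_context)

ctx = fixture_context()  # Sri Lanka 2021: GDP US$3,815, 200 LKR/US$, LE 77 y

rec = IndicationRecord(
    indication_id="gastric_2l", option_group="gastric_2l", drug_name="novelimab",
    regimen=Regimen(
        components=[RegimenComponent(
            drug_name="novelimab", dose_rule="per_kg", dose_value_mg=6.0,
            administrations_per_cycle=1, cycle_length_days=21.0,
            unit_price=150.0, currency="LKR")],
        setting="palliative", additive=True),
    evidence=TrialEvidence(outcome_measure="OS", gain_value=4.8,
                           median_treatment_duration_months=5.6),
    patient_estimates=[60, 75, 90],
)
a = assess_indication(rec, ctx)
```

which prints, via the obvious f-strings:

```
course cost      US$ 2,025.00
life-years gained 0.40  (basis: median_OS)
cost per LY      US$ 5,062.50
GDP fraction     1.33
category         cost_effective
patients/year    75
annual cost      US$ 151,875.00
```

Reading: 6 mg/kg × 50 kg = 300 mg per administration at 150 LKR/mg
(US$0.75/mg) is US$225 per dose; 5.6 months of three-weekly dosing means 9
started cycles, so the course costs US$2,025. A 4.8-month median OS gain is
0.40 life-years, giving US$5,062.50 per life-year — 1.33× per-capita GDP,
i.e. cost-effective but not highly so — and treating the estimated 75
patients a year would cost US$151,875.

The same pipeline runs from the shell. `oncobudget assess --use-fixture
--out report/` assesses the 31 transcribed published league-table rows and
writes league tables per category, budget totals per threshold, the
cumulative-cost curve TSV and a run log; `oncobudget generate --seed 1
--n 50 --out catalog.csv` writes a reproducible synthetic catalog, and
`oncobudget curve`/`oncobudget fixture` export the curve and the built-in
fixture. The catalog CSV schema is documented in
`src/oncobudget/catalog.py` (`CSV_COLUMNS`).

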