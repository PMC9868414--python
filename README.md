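# pharmsig

Disproportionality signal detection for spontaneous adverse-event
reports, in the style of analyses run against the FDA Adverse Event
Reporting System (FAERS).

Pharmacovigilance teams screen spontaneous-reporting databases for
drug–event pairs that are reported *disproportionately* often. For a
target drug and a target adverse event, the deduplicated reports are
cross-classified into a 2×2 table

|            | event | no event |
|------------|-------|----------|
| drug       | a     | b        |
| no drug    | c     | d        |

where the background is every report not mentioning the drug. The
**proportional reporting ratio**

PRR = [a / (a + b)] / [c / (c + d)]

compares the event's reporting frequency among reports of the drug with
its frequency in the background; PRR = 2 means the event is reported
twice as often with the drug. Together with the Pearson χ² statistic of
the same table (Yates-corrected by default) and the case count N = a,
the classical positive-signal rule is

**PRR ≥ 2 and χ² ≥ 4 and N ≥ 3** (all boundaries inclusive).

A signal is a reporting association, not evidence of causation.

`pharmsig` implements this pipeline end to end for a worked study
system — antihypertensive drugs and the urate-related adverse events
hyperuricaemia, gout, gouty arthritis, gouty tophus and urate
nephropathy (each defined by one MedDRA Preferred Term) — but every
component is generic: vocabularies, event definitions and report tables
are plain user-supplied files.

Components:

- **Report model and I/O** — a three-table CSV layout (`demo.csv`,
  `drug.csv`, `reac.csv`), age normalization to years, and case
  deduplication (highest version per case, ties to the greatest
  report id).
- **Vocabulary** — verbatim drug-name strings resolved to canonical
  drugnames with drug classes by exact lookup after case/whitespace
  normalization; fixed-dose compound preparations are canonical entries
  distinct from their components. Adverse events are named sets of
  Preferred Terms.
- **Disproportionality** — the 2×2 construction, PRR (with optional
  additive continuity correction), χ² (Yates or plain Pearson), and the
  signal classification.
- **Screening** — every (drug, event) pair screened in one pass,
  per-event signal tables grouped by drug class, and the cross-event
  overlap histogram (which drugs are flagged for how many events).
- **Overview** — per-event demographic breakdowns (sex; age bins 0–17,
  18–40, 41–65, >65; reporter country United States/other/unknown) with
  half-up two-decimal percentages.
- **Synthetic generator** — a seeded FAERS-like report simulator with
  planted (drug, event) reporting-rate multipliers and an exact
  `expected_prr`, giving ground truth for end-to-end tests.
- **Packaged data** — an example antihypertensive vocabulary (76 drugs,
  11 classes), the five event definitions, and transcriptions of
  published signal tables for regression-testing the classification,
  counting and overlap logic.

## Worked example

Simulate a database with one planted association (furosemide reports
carry gout at 6× the background rate of 0.01), then screen it:

```
$ pharmsig simulate --config src/pharmsig/data/example_simulation.yaml --out db
INFO pharmsig: wrote 5000 reports to db

$ pharmsig screen --demo db/demo.csv --drug db/drug.csv --reac db/reac.csv \
      --out run --positives-only
INFO pharmsig: read 5000 reports
INFO pharmsig: 5000 reports after case deduplication
INFO pharmsig: event 'gout': 141 cases screened, 1 positive
...

$ head -2 run/signals_gout.csv
drug_class,drug_name,event,N,PRR,chi2,signal
Diuretics,Furosemide,gout,72,4.52,66.83,positive
```

The only positive signal is the planted pair: 72 furosemide–gout cases,
PRR 4.52 (sampling noise around the planted 6; at n = 30 000 the
estimate tightens to ≈ 6), χ² 66.83 — well past the 2 / 4 / 3
thresholds. `run/` also contains `overlap.csv` (drugs by number of
positive events), `overview.csv` (demographics per event) and
`manifest.json` (input hashes and thresholds).

Recompute summaries from the packaged published signal tables:

```
$ pharmsig fixtures
Positive signals per event (recomputed from printed N/PRR/chi2):
  hyperuricaemia: 46
  gout: 64
  gouty arthritis: 27
  gouty tophus: 8
  urate nephropathy: 6
Drugs by number of positive events:
  5 events: 2 drugs
  4 events: 6 drugs
  3 events: 15 drugs
  2 events: 19 drugs
  1 events: 34 drugs
Drugs with positive signals for >=2 events: 42
```

Every printed row satisfies the signal criterion, and 42 drugs are
flagged for two or more of the five events (furosemide and amlodipine
for all five).

## File formats

`demo.csv`: `report_id, case_id, version, sex, age_value, age_unit,
country` — one row per report; `drug.csv`: `report_id, drug_name` — one
row per verbatim mention; `reac.csv`: `report_id, pt`. Vocabulary YAML:
list of `{canonical, class, synonyms[]}`; events YAML: `label: [PTs]`.
Output `signals_<event>.csv`: `drug_class, drug_name, event, N, PRR,
chi2, signal` (PRR/χ² half-up to 2 decimals); `overlap.csv`: `drug,
n_positive_events, events`; `overview.csv`: `event, breakdown, stratum,
count, pct`.

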