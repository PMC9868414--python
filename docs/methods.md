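# Methods

## Statistical model

Each deduplicated spontaneous report either mentions the target drug or
not, and either carries the target adverse event or not, giving the 2×2
table (a, b, c, d) with total n. The background population for a drug
is every report not mentioning it — the standard, unrestricted PRR
background.

**PRR.** PRR = [a/(a+b)] / [c/(c+d)]. Degenerate cells are handled
explicitly rather than smoothed: a = 0 gives PRR = 0; c = 0 with a > 0
gives PRR = +∞ (rendered `inf` in output tables); an empty row
(a+b = 0 or c+d = 0) is an undefined-statistic error. No Haldane 0.5
correction is applied by default because the signal rule's N ≥ 3 and χ²
gates make infinite PRRs safe to classify; `continuity=0.5` (CLI
`--continuity 0.5`) adds the correction to every cell when finite
estimates are preferred.

**χ².** The Pearson statistic n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], with
the Yates continuity correction by default: |ad−bc| is reduced by n/2
and the statistic floored at 0. Yates is the convention of the
classical positive-signal criterion and of the common FAERS query
tools; the uncorrected Pearson form is available via `yates=False`
(CLI `--no-yates`). Any zero marginal is an undefined-statistic error;
during batch screening such pairs are recorded as negatives with a
reason code (`"no cases"`, `"drug not in any report"`, …) instead of
being dropped.

**Classification.** positive ⇔ N ≥ 3 and PRR ≥ 2 and χ² ≥ 4, all
boundaries inclusive ("two or greater", "at least four", "three or
more"). No multiple-testing adjustment is applied across the
drug × event grid — the convention of this screening literature — and
results must be read accordingly: with hundreds of pairs, a handful of
false positives is expected.

## Deduplication and counting rules

A case may be submitted repeatedly as versioned reports. `deduplicate`
keeps, per `case_id`, the record with the highest `version`, breaking
ties by the lexicographically greatest `report_id`; it is idempotent,
and all counting is report-level (a drug mentioned twice in one report
counts once). These rules are documented assumptions about how cleaned
FAERS-style extracts behave, not facts recoverable from any single
published analysis, since public query tools pre-clean the data.

## Vocabulary and events

Drug-name resolution is exact lookup after case-folding and whitespace
collapsing. No fuzzy, substring or spelling-corrected matching: a miss
is an explicit `UNMAPPED`, never a guess, because approximate matching
inflates a and shifts every downstream statistic unpredictably. The
vocabulary invariant — no synonym resolves to two canonical names —
makes the mapping independent of entry order. Compound preparations are
separate canonical entries; a mention of a combination product never
counts toward its components.

Events are sets of MedDRA Preferred Terms matched case-insensitively.
A composite event over k PTs is exactly the OR of the k single-PT
events (property-tested).

## Overview tables

Age is normalized to years at read time (months/12, days/365.25; a
value with a missing unit is taken as years with a logged warning) and
binned as [0,18), [18,41), [41,66), [66,∞), matching the label
semantics "0–17 … >65" — a 65-year-old falls in "41–65". Reporter
country is normalized case-insensitively ({united states, us, usa} →
United States; other non-missing → other). Percentages are
100·count/total rounded half-up at two decimals; half-up (not banker's)
is what published tables use, verified cell-by-cell against the
packaged transcription (e.g. 960/1727 → 55.59%).

One transcribed breakdown (gout, reporter country) sums to more than
its printed total; its percentage cells nonetheless recompute exactly
from the printed counts and total, so the total is treated as
authoritative and the regression tests assert the percentage identity
rather than the sum for that breakdown.

## Synthetic generator

The generator emulates the features the pipeline is sensitive to:
reports with one or more drugs mentioned under verbatim variants
(synonym or case-variant rendering with probability `synonym_noise`),
sparse reaction PT lists, demographic fields with realistic missing
mass, and optionally versioned duplicate cases. Defaults mirror the
urate-AE reporting profile: sex 55/35/10 male/female/unknown, age
concentrated in 41–65 and >65 with 25% missing, US-heavy reporter mix.

Drugs are sampled independently per report with configured marginals;
rows with no drug are rejected and resampled, which renormalizes all
marginals by 1/P(≥1 drug) but — because the event law depends only on
which drugs are present — leaves the population PRR of a single planted
pair untouched; with several planted drugs for one PT the rejection
perturbs their joint presence distribution slightly, a bias
`expected_prr` neglects. Each PT occurs with probability
min(1, background × m), where m is the largest planted multiplier among
drugs present (1 if none). `expected_prr` evaluates the exact
PRR implied by these joint probabilities by enumerating presence
subsets of the planted drugs; for a single planted pair it equals λ
exactly.

Not emulated: co-prescription correlation between drugs (confounding by
co-reporting), reporting-volume trends over time, stimulated reporting,
and real MedDRA coding noise. Passing the synthetic recovery tests
therefore demonstrates the statistical machinery is correct under the
stated sampling model, not that real-world signals are unconfounded.

## Problem sizes and numerical choices

Unit tests run on hundreds of reports; the stochastic recovery test
uses one 50 000-report database with background event probability 0.002
and one pair planted at λ = 5 (≈ 50 exposed cases), checking the
estimated PRR against the 95% interval from the delta-method SD of
log PRR, √(1/a − 1/(a+b) + 1/c − 1/(c+d)), and requiring the λ = 1
pairs to be flagged rarely (≤ 5%). The χ² implementation is verified
against the cell-wise Σ(O−E)²/E form at 1e−9 relative tolerance and
against an independent library implementation for both the corrected
and uncorrected variants.

## Known limitations

- Disproportionality measures reporting, not incidence; no causal or
  dose-response inference is possible.
- Only the unrestricted background is implemented (no comparator-set
  or class-restricted backgrounds).
- Alternative signal statistics (ROR, IC/BCPNN, EBGM) are out of scope.
- The packaged vocabulary is an illustrative fixture, not a complete
  regulatory dictionary; real analyses must supply their own mapping.
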