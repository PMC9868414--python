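"""Batch disproportionality screening and cross-event overlap analysis.

Runs the PRR / chi-squared / Evans-criterion pipeline over every
(drug, event) pair in a vocabulary x event list, producing per-event
signal tables grouped by drug class and a cross-event overlap summary
(which drugs are flagged for how many distinct adverse events).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from pharmsig.models import ReportSet
from pharmsig.vocabulary import (
    DrugVocabulary,
    EventDefinition,
    map_drug_name,
    report_has_event,
    UNMAPPED,
)
from pharmsig.disproportionality import (
    ContingencyTable,
    SignalResult,
    compute_prr,
    compute_chi2,
    classify_signal,
)

PathLike = Union[str, Path]


@dataclass
class ScreenResult:
    """All pairwise signal results plus the positive-signal overlap map."""

    per_event: dict[str, list[SignalResult]]
    overlap: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        overlap: dict[str, set[str]] = {}
        for label, results in self.per_event.items():
            for r in results:
                if r.positive:
                    overlap.setdefault(r.drug, set()).add(label)
        self.overlap = overlap

    @property
    def event_labels(self) -> list[str]:
        return list(self.per_event)


@dataclass(frozen=True)
class OverlapHistogram:
    """Distribution of drugs over their number of positive events."""

    by_count: dict[int, tuple[int, list[str]]]  # k -> (count, sorted drugs)
    total_multi: int  # drugs positive for >= 2 events

    def count_at(self, k: int) -> int:
        return self.by_count.get(k, (0, []))[0]

    def drugs_at(self, k: int) -> list[str]:
        return self.by_count.get(k, (0, []))[1]


def _pair_result(
    drug: str,
    drug_class: str,
    label: str,
    t: ContingencyTable,
    yates: bool,
    continuity: float,
) -> SignalResult:
    """Compute one pair's statistics; degenerate tables become explicit
    negatives with a reason code instead of being dropped."""
    reason = ""
    if t.a + t.b == 0:
        prr, chi2, reason = 0.0, 0.0, "drug not in any report"
    elif t.c + t.d == 0:
        prr, chi2, reason = 0.0, 0.0, "no background reports"
    elif t.a + t.c == 0:
        prr, chi2, reason = 0.0, 0.0, "no cases"
    elif t.b + t.d == 0:
        prr, chi2, reason = 0.0, 0.0, "all reports are cases"
    else:
        prr = compute_prr(t, continuity=continuity)
        chi2 = compute_chi2(t, yates=yates)
    return SignalResult(
        drug=drug,
        event=label,
        n_cases=t.a,
        prr=prr,
        chi2=chi2,
        positive=classify_signal(t.a, prr, chi2),
        drug_class=drug_class,
        reason=reason,
    )


def run_screen(
    reports: ReportSet,
    vocab: DrugVocabulary,
    events: Sequence[EventDefinition],
    yates: bool = True,
    continuity: float = 0.0,
) -> ScreenResult:
    """Screen every (drug, event) pair of the vocabulary x event list.

    ``reports`` must already be deduplicated.  For each pair the 2x2
    table is formed against the background of all reports not
    mentioning the drug, then PRR, chi-squared and the Evans
    classification are computed.  Pairs whose statistics are undefined
    (zero marginals) appear as negatives with a reason code.
    """
    if len(reports) == 0:
        raise ValueError("empty ReportSet: background population undefined")
    if len(vocab) == 0 or len(events) == 0:
        raise ValueError("need at least one drug and one event to screen")

    n_total = len(reports)
    drugs = vocab.canonical_names
    labels = [e.label for e in events]

    # one pass over reports: per-drug totals, per-event totals, and
    # per-(drug, event) joint counts
    n_drug = {d: 0 for d in drugs}
    n_event = {lab: 0 for lab in labels}
    joint = {(d, lab): 0 for d in drugs for lab in labels}
    for rec in reports:
        canon = {
            m for m in (map_drug_name(vocab, v) for v in rec.drug_mentions)
            if m is not UNMAPPED
        }
        flags = [lab for e, lab in zip(events, labels) if report_has_event(e, rec)]
        for d in canon:
            n_drug[d] += 1
            for lab in flags:
                joint[(d, lab)] += 1
        for lab in flags:
            n_event[lab] += 1

    per_event: dict[str, list[SignalResult]] = {lab: [] for lab in labels}
    for lab in labels:
        for d in drugs:
            a = joint[(d, lab)]
            t = ContingencyTable(
                a=a,
                b=n_drug[d] - a,
                c=n_event[lab] - a,
                d=n_total - n_drug[d] - n_event[lab] + a,
            )
            per_event[lab].append(
                _pair_result(d, vocab.drug_class_of(d), lab, t, yates, continuity)
            )
    return ScreenResult(per_event=per_event)


def count_positive(result: ScreenResult, event_label: str) -> int:
    """Number of drugs with a positive signal for one event."""
    if event_label not in result.per_event:
        raise KeyError(f"event {event_label!r} was not screened")
    return sum(r.positive for r in result.per_event[event_label])


def overlap_histogram(result: ScreenResult) -> OverlapHistogram:
    """Distribution of drugs by their number of positive adverse events."""
    by_drug = {drug: len(labels) for drug, labels in result.overlap.items()}
    by_count: dict[int, tuple[int, list[str]]] = {}
    for k in sorted(set(by_drug.values())):
        drugs = sorted(d for d, c in by_drug.items() if c == k)
        by_count[k] = (len(drugs), drugs)
    total_multi = sum(1 for c in by_drug.values() if c >= 2)
    return OverlapHistogram(by_count=by_count, total_multi=total_multi)


def group_by_class(
    result: ScreenResult,
    vocab: DrugVocabulary,
    event_label: str,
    positives_only: bool = True,
) -> list[SignalResult]:
    """Order one event's results by drug class, then vocabulary order.

    The class display order is the order in which classes first appear
    in the vocabulary file (published signal tables list diuretics
    first and compound preparations last); within a class, rows keep
    the vocabulary's drug order.
    """
    if event_label not in result.per_event:
        raise KeyError(f"event {event_label!r} was not screened")
    class_order: dict[str, int] = {}
    drug_order: dict[str, int] = {}
    for i, entry in enumerate(vocab.entries):
        drug_order[entry.canonical] = i
        class_order.setdefault(entry.drug_class, len(class_order))
    rows = result.per_event[event_label]
    if positives_only:
        rows = [r for r in rows if r.positive]
    return sorted(
        rows,
        key=lambda r: (
            class_order.get(r.drug_class, len(class_order)),
            drug_order.get(r.drug, len(drug_order)),
        ),
    )


def results_from_table(
    path: PathLike,
    event_label: str,
    delimiter: str = ",",
) -> list[SignalResult]:
    """Load a published-style signal table and recompute classifications.

    The file must have columns ``drug_class, drug_name, N, PRR, chi2``
    (as printed in disproportionality signal tables).  The Evans
    classification is recomputed from the printed N / PRR / chi2 values
    rather than trusted from the file.
    """
    df = pd.read_csv(path, sep=delimiter)
    required = {"drug_class", "drug_name", "N", "PRR", "chi2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal table {path} missing columns: {sorted(missing)}")
    results = []
    for row in df.itertuples(index=False):
        n, prr, chi2 = int(row.N), float(row.PRR), float(row.chi2)
        results.append(
            SignalResult(
                drug=str(row.drug_name),
                event=event_label,
                n_cases=n,
                prr=prr,
                chi2=chi2,
                positive=classify_signal(n, prr, chi2),
                drug_class=str(row.drug_class),
            )
        )
    return results
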