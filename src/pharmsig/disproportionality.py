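"""2x2 disproportionality statistics: PRR, chi-squared, Evans criterion.

For a target drug and a target adverse event, each deduplicated report
falls into exactly one cell of the 2x2 table

    ============  =======  =========
    .             event    no event
    ============  =======  =========
    drug          a        b
    no drug       c        d
    ============  =======  =========

where the background population is every report not mentioning the
drug.  The proportional reporting ratio is

    PRR = [a / (a + b)] / [c / (c + d)]

— the event's reporting frequency among reports of the drug divided by
its frequency in the background; PRR = 2 means the event is reported
twice as frequently with the drug as without it.  The chi-squared
statistic is the Pearson statistic of the same table, with Yates
continuity correction by default (the convention of the classical
positive-signal criterion).  A pair is a *positive signal* when
PRR >= 2, chi2 >= 4 and there are at least 3 cases, all boundaries
inclusive.  A signal is a reporting association, not causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from pharmsig.models import ReportSet
from pharmsig.vocabulary import (
    DrugVocabulary,
    EventDefinition,
    report_has_drug,
    report_has_event,
)

PRR_THRESHOLD = 2.0
CHI2_THRESHOLD = 4.0
MIN_CASES = 3


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's preconditions (non-zero margins) fail."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a/b/c/d of one (drug, event) query; all cells >= 0."""

    a: int  # drug and event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {cell} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality result for one (drug, event) pair.

    ``positive`` is always the Evans conjunction
    ``n_cases >= 3 and prr >= 2 and chi2 >= 4``.  ``reason`` carries a
    code such as ``"no cases"`` when a statistic's preconditions failed
    and the pair was recorded as negative rather than dropped.
    """

    drug: str
    event: str
    n_cases: int
    prr: float
    chi2: float
    positive: bool
    drug_class: str = ""
    reason: str = ""


def build_contingency(
    reports: ReportSet,
    vocab: DrugVocabulary,
    drug: str,
    event: EventDefinition,
) -> ContingencyTable:
    """Count the 2x2 table for (drug, event) over a deduplicated ReportSet.

    Each report contributes to exactly one cell, via
    ``report_has_drug x report_has_event``.
    """
    if len(reports) == 0:
        raise ValueError("empty ReportSet: background population undefined")
    a = b = c = d = 0
    for rec in reports:
        has_drug = report_has_drug(vocab, rec, drug)
        has_event = report_has_event(event, rec)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_prr(t: ContingencyTable, continuity: float = 0.0) -> float:
    """Proportional reporting ratio of a 2x2 table.

    ``continuity`` (e.g. 0.5, the Haldane correction) is added to every
    cell before forming the ratio; the default applies no correction,
    so PRR is ``+inf`` when c = 0 with a > 0, and 0 when a = 0.

    Raises :class:`UndefinedStatisticError` when a + b = 0 (the drug
    never occurs) or c + d = 0 (no background).
    """
    a = t.a + continuity
    b = t.b + continuity
    c = t.c + continuity
    d = t.d + continuity
    if a + b == 0 or c + d == 0:
        raise UndefinedStatisticError(
            f"PRR undefined for table (a={t.a}, b={t.b}, c={t.c}, d={t.d}): empty row"
        )
    if a == 0:
        return 0.0
    if c == 0:
        return math.inf
    return (a / (a + b)) / (c / (c + d))


def compute_chi2(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-squared statistic of a 2x2 table.

    Without correction: ``n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``.
    With Yates continuity correction (the default), ``|ad - bc|`` is
    reduced by ``n/2`` and floored at zero.

    Raises :class:`UndefinedStatisticError` when any marginal is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise UndefinedStatisticError(
            f"chi-squared undefined for table (a={a}, b={b}, c={c}, d={d}): zero marginal"
        )
    det = a * d - b * c
    if yates:
        adj = abs(det) - n / 2
        if adj <= 0:
            return 0.0
        num = n * adj * adj
    else:
        num = n * det * det
    return num / (row1 * row2 * col1 * col2)


def classify_signal(n_cases: int, prr: float, chi2: float) -> bool:
    """Evans positive-signal criterion, all boundaries inclusive."""
    return n_cases >= MIN_CASES and prr >= PRR_THRESHOLD and chi2 >= CHI2_THRESHOLD
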