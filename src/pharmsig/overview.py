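"""Per-event report overviews: sex, age-bin and country breakdowns.

For each adverse event the overview counts the deduplicated reports
carrying the event and tabulates them by sex (male / female / unknown),
age bin in years (0-17, 18-40, 41-65, >65, unknown) and reporter
country (United States / other / unknown), each with a percentage of
the event's total.  Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pharmsig.io import round_half_up
from pharmsig.models import ReportSet
from pharmsig.vocabulary import EventDefinition, report_has_event

AGE_BIN_LABELS = ("0-17", "18-40", "41-65", ">65", "unknown")
SEX_LABELS = ("male", "female", "unknown")
COUNTRY_LABELS = ("United States", "other", "unknown")

_US_ALIASES = {"united states", "us", "usa", "united states of america"}


def age_bin(age_years: Optional[float]) -> str:
    """Assign an age in years to the overview bins.

    Boundaries are [0, 18), [18, 41), [41, 66), [66, inf), so a
    65-year-old falls in "41-65" and an 18th birthday moves a patient
    into "18-40".  Missing age -> "unknown".
    """
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "0-17"
    if age_years < 41:
        return "18-40"
    if age_years < 66:
        return "41-65"
    return ">65"


def country_group(country: Optional[str]) -> str:
    """Collapse a reporter-country string to United States / other / unknown."""
    if country is None or not country.strip():
        return "unknown"
    if country.strip().casefold() in _US_ALIASES:
        return "United States"
    return "other"


def format_percentage(count: int, total: int) -> str:
    """Render ``100*count/total`` as "NN.NN%", half-up at 2 decimals."""
    if total <= 0:
        raise ValueError("percentage undefined for total <= 0")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return f"{round_half_up(100.0 * count / total, 2):.2f}%"


@dataclass(frozen=True)
class OverviewTable:
    """Counts and percentages of one event's reports by stratum.

    Each breakdown's counts sum to ``total_reports``; each percentage
    is ``100*count/total`` rounded half-up to 2 decimals.
    """

    event: str
    total_reports: int
    sex_counts: dict[str, int]
    age_counts: dict[str, int]
    country_counts: dict[str, int]

    def percentage(self, breakdown: str, stratum: str) -> str:
        counts = getattr(self, f"{breakdown}_counts")
        return format_percentage(counts[stratum], self.total_reports)

    def rows(self) -> list[tuple[str, str, str, int, str]]:
        """Flatten to (event, breakdown, stratum, count, pct) rows."""
        out = []
        for breakdown, labels in (
            ("sex", SEX_LABELS),
            ("age", AGE_BIN_LABELS),
            ("country", COUNTRY_LABELS),
        ):
            counts = getattr(self, f"{breakdown}_counts")
            for lab in labels:
                pct = (
                    format_percentage(counts[lab], self.total_reports)
                    if self.total_reports
                    else ""
                )
                out.append((self.event, breakdown, lab, counts[lab], pct))
        return out


def summarize_event(reports: ReportSet, event: EventDefinition) -> OverviewTable:
    """Tabulate the deduplicated reports carrying ``event`` by stratum."""
    sex_counts = {lab: 0 for lab in SEX_LABELS}
    age_counts = {lab: 0 for lab in AGE_BIN_LABELS}
    country_counts = {lab: 0 for lab in COUNTRY_LABELS}
    total = 0
    for rec in reports:
        if not report_has_event(event, rec):
            continue
        total += 1
        sex_counts[rec.sex if rec.sex in SEX_LABELS else "unknown"] += 1
        age_counts[age_bin(rec.age_years)] += 1
        country_counts[country_group(rec.country)] += 1
    return OverviewTable(
        event=event.label,
        total_reports=total,
        sex_counts=sex_counts,
        age_counts=age_counts,
        country_counts=country_counts,
    )
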