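"""Domain types for spontaneous adverse-event reports.

A *report* is one submission to a spontaneous-reporting system: patient
demographics, the drugs mentioned verbatim by the reporter, and the
adverse events coded as MedDRA Preferred Terms (PTs).  A *case* (one
patient/incident) may be submitted several times as versioned reports;
analyses count one record per case after deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

SEX_VALUES = ("male", "female", "unknown")
AGE_UNITS = ("years", "months", "days")


class ValidationError(ValueError):
    """Raised when a report or report set violates a structural invariant."""


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous adverse-event report.

    Parameters
    ----------
    report_id
        Opaque unique identifier of this submission.
    case_id
        Identifier of the underlying case; several report versions may
        share a case_id.
    version
        Report version within the case, ``>= 1``.
    sex
        ``"male"``, ``"female"`` or ``"unknown"``.
    age_years
        Age normalized to years, or ``None`` when missing.
    country
        Reporter country string, or ``None`` when missing.
    drug_mentions
        Verbatim drug-name strings as reported; at least one.
    reaction_pts
        Preferred Term strings; may be empty.
    """

    report_id: str
    case_id: str
    version: int
    sex: str = "unknown"
    age_years: Optional[float] = None
    country: Optional[str] = None
    drug_mentions: tuple[str, ...] = ()
    reaction_pts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be a non-empty string")
        if self.version < 1:
            raise ValidationError(
                f"report {self.report_id!r}: version must be >= 1, got {self.version}"
            )
        if self.sex not in SEX_VALUES:
            raise ValidationError(
                f"report {self.report_id!r}: sex must be one of {SEX_VALUES}, got {self.sex!r}"
            )
        if not self.drug_mentions:
            raise ValidationError(
                f"report {self.report_id!r} has zero drug mentions"
            )
        if any(not m or not m.strip() for m in self.drug_mentions):
            raise ValidationError(
                f"report {self.report_id!r} has an empty drug mention"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(
                f"report {self.report_id!r}: negative age {self.age_years}"
            )
        # normalize list inputs to tuples so records are hashable
        object.__setattr__(self, "drug_mentions", tuple(self.drug_mentions))
        object.__setattr__(self, "reaction_pts", tuple(self.reaction_pts))


@dataclass
class ReportSet:
    """An ordered collection of :class:`ReportRecord` with unique ids.

    The only invariant enforced on construction is ``report_id``
    uniqueness.  Raw extracts may carry several versions of one case —
    even colliding (case_id, version) pairs; resolving them to one
    record per ``case_id`` is a separate, explicit step
    (:func:`pharmsig.io.deduplicate`).
    """

    records: list[ReportRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        for rec in self.records:
            if rec.report_id in seen_ids:
                raise ValidationError(f"duplicate report_id {rec.report_id!r}")
            seen_ids.add(rec.report_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ReportRecord:
        return self.records[i]
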