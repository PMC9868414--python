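"""Readers and writers for the delimited three-table report layout.

Reports are exchanged as three CSV tables mirroring the structure of
spontaneous-reporting extracts:

``demo.csv``
    one row per report: ``report_id, case_id, version, sex, age_value,
    age_unit, country``
``drug.csv``
    one row per drug mention: ``report_id, drug_name``
``reac.csv``
    one row per reaction: ``report_id, pt``

Files are comma-separated UTF-8 with a header row; a tab delimiter is
accepted through the ``delimiter`` argument.  Ages are normalized to
years at read time (months / 12, days / 365.25); a value with a missing
unit is treated as years with a warning.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import math
import pandas as pd

from pharmsig.models import ReportRecord, ReportSet, ValidationError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEMO_COLUMNS = ("report_id", "case_id", "version", "sex", "age_value", "age_unit", "country")
DRUG_COLUMNS = ("report_id", "drug_name")
REAC_COLUMNS = ("report_id", "pt")

_DAYS_PER_YEAR = 365.25


class FormatError(ValueError):
    """Raised when an input table is malformed (e.g. missing a column)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties away from zero.

    Python's builtin ``round`` uses banker's rounding; published
    pharmacovigilance tables round halves up, so 5.445 renders "5.45".
    """
    x = float(x)
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{table} table is missing required column(s): {', '.join(missing)}"
        )


def _norm_sex(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    return "unknown"


def age_to_years(value: Optional[float], unit: Optional[str], report_id: str = "?") -> Optional[float]:
    """Normalize an (age_value, age_unit) pair to years.

    Missing value -> ``None``.  Missing unit with a present value is
    treated as years, with a warning logged.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    value = float(value)
    if unit is None or (isinstance(unit, float) and math.isnan(unit)) or str(unit).strip() == "":
        logger.warning(
            "report %s: age value %s has no unit; assuming years", report_id, value
        )
        return value
    u = str(unit).strip().lower()
    if u in ("year", "years", "yr", "y"):
        return value
    if u in ("month", "months", "mon", "mo"):
        return value / 12.0
    if u in ("day", "days", "d"):
        return value / _DAYS_PER_YEAR
    raise FormatError(f"report {report_id}: unrecognized age unit {unit!r}")


def read_report_tables(
    demo_path: PathLike,
    drug_path: PathLike,
    reac_path: PathLike,
    delimiter: str = ",",
    provenance: str = "",
) -> ReportSet:
    """Read the three-table layout into a :class:`ReportSet`.

    Every demo row becomes one record carrying its joined drug mentions
    and reaction PTs.  Drug/reaction rows whose ``report_id`` does not
    appear in the demo table are a referential-integrity error, as is a
    report with zero drug mentions.
    """
    demo = pd.read_csv(demo_path, sep=delimiter, dtype=str, keep_default_na=False)
    drug = pd.read_csv(drug_path, sep=delimiter, dtype=str, keep_default_na=False)
    reac = pd.read_csv(reac_path, sep=delimiter, dtype=str, keep_default_na=False)

    _require_columns(demo, DEMO_COLUMNS, "demo")
    _require_columns(drug, DRUG_COLUMNS, "drug")
    _require_columns(reac, REAC_COLUMNS, "reac")

    known_ids = set(demo["report_id"])
    for table_name, df in (("drug", drug), ("reac", reac)):
        orphans = sorted(set(df["report_id"]) - known_ids)
        if orphans:
            raise FormatError(
                f"{table_name} table references unknown report_id(s): "
                + ", ".join(orphans[:10])
            )

    mentions: dict[str, list[str]] = {rid: [] for rid in known_ids}
    for rid, name in zip(drug["report_id"], drug["drug_name"]):
        mentions[rid].append(name)
    pts: dict[str, list[str]] = {rid: [] for rid in known_ids}
    for rid, pt in zip(reac["report_id"], reac["pt"]):
        pts[rid].append(pt)

    no_drugs = [rid for rid in demo["report_id"] if not mentions[rid]]
    if no_drugs:
        raise ValidationError(
            "report(s) with zero drug mentions: " + ", ".join(sorted(no_drugs)[:10])
        )

    records = []
    for row in demo.itertuples(index=False):
        age_value = float(row.age_value) if row.age_value != "" else None
        rec = ReportRecord(
            report_id=row.report_id,
            case_id=row.case_id,
            version=int(row.version),
            sex=_norm_sex(row.sex),
            age_years=age_to_years(age_value, row.age_unit or None, row.report_id),
            country=row.country or None,
            drug_mentions=tuple(mentions[row.report_id]),
            reaction_pts=tuple(pts[row.report_id]),
        )
        records.append(rec)
    return ReportSet(records=records, provenance=provenance)


def write_report_tables(
    reports: ReportSet,
    demo_path: PathLike,
    drug_path: PathLike,
    reac_path: PathLike,
    delimiter: str = ",",
) -> None:
    """Write a :class:`ReportSet` back to the three-table layout.

    Ages are written in years (unit column ``years``), so
    read -> write -> read round-trips the in-memory representation.
    """
    demo_rows = []
    drug_rows = []
    reac_rows = []
    for rec in reports:
        demo_rows.append(
            {
                "report_id": rec.report_id,
                "case_id": rec.case_id,
                "version": rec.version,
                "sex": rec.sex,
                "age_value": "" if rec.age_years is None else repr(float(rec.age_years)),
                "age_unit": "" if rec.age_years is None else "years",
                "country": rec.country or "",
            }
        )
        for m in rec.drug_mentions:
            drug_rows.append({"report_id": rec.report_id, "drug_name": m})
        for pt in rec.reaction_pts:
            reac_rows.append({"report_id": rec.report_id, "pt": pt})

    pd.DataFrame(demo_rows, columns=list(DEMO_COLUMNS)).to_csv(
        demo_path, sep=delimiter, index=False
    )
    pd.DataFrame(drug_rows, columns=list(DRUG_COLUMNS)).to_csv(
        drug_path, sep=delimiter, index=False
    )
    pd.DataFrame(reac_rows, columns=list(REAC_COLUMNS)).to_csv(
        reac_path, sep=delimiter, index=False
    )


def deduplicate(reports: ReportSet) -> ReportSet:
    """Collapse versioned reports to one record per case.

    For each ``case_id`` the record with the highest ``version`` wins;
    a version tie is broken by the lexicographically greatest
    ``report_id``.  Idempotent.
    """
    best: dict[str, ReportRecord] = {}
    for rec in reports:
        cur = best.get(rec.case_id)
        if cur is None or (rec.version, rec.report_id) > (cur.version, cur.report_id):
            best[rec.case_id] = rec
    # preserve first-appearance order of cases
    order: list[str] = []
    seen: set[str] = set()
    for rec in reports:
        if rec.case_id not in seen:
            seen.add(rec.case_id)
            order.append(rec.case_id)
    return ReportSet(
        records=[best[cid] for cid in order],
        provenance=reports.provenance,
    )


def write_signal_table(results, out_path: PathLike, delimiter: str = ",") -> None:
    """Serialize screening results to a delimited signal table.

    Columns: ``drug_class, drug_name, event, N, PRR, chi2, signal``.
    PRR and chi2 are rendered to 2 decimals, half-up; an infinite PRR is
    rendered ``inf``.  ``results`` is an iterable of
    :class:`pharmsig.disproportionality.SignalResult`.
    """

    def fmt(x: float) -> str:
        if math.isinf(x):
            return "inf"
        return f"{round_half_up(x, 2):.2f}"

    rows = [
        {
            "drug_class": r.drug_class,
            "drug_name": r.drug,
            "event": r.event,
            "N": r.n_cases,
            "PRR": fmt(r.prr),
            "chi2": fmt(r.chi2),
            "signal": "positive" if r.positive else "negative",
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["drug_class", "drug_name", "event", "N", "PRR", "chi2", "signal"]
    ).to_csv(out_path, sep=delimiter, index=False)
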