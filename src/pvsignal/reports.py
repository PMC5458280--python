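"""Data model and I/O for spontaneous adverse-event safety reports.

A :class:`SafetyReport` is the unit of analysis: one spontaneous report
carrying the drugs the patient received, the indications they were treated
for, and the adverse-reaction preferred terms that were observed.  Term
matching throughout the package is exact equality on *normalized* strings
(uppercase, whitespace-collapsed), mirroring how spontaneous-report
databases index fixed vocabulary terms; substring matching would silently
inflate counts (e.g. "ANAEMIA" occurs inside "HAEMOLYTIC ANAEMIA").

Two input dialects are supported:

``openfda``
    JSON lines, one report per line::

        {"safetyreportid": "1001", "receiptdate": "20090315",
         "patient": {
            "drug": [{"generic_name": "CARBOPLATIN",
                      "drugindication": "NON-SMALL CELL LUNG CANCER"}],
            "reaction": [{"reactionmeddrapt": "ANAEMIA"}]}}

    Per-drug records may carry ``generic_name`` (string or list, also
    accepted nested under an ``openfda`` sub-object) or fall back to
    ``medicinalproduct``; the receipt year is the first four digits of the
    8-digit ``receiptdate``.

``csv``
    Flat CSV with columns ``report_id, receipt_date, drugs, indications,
    reactions``; multi-valued cells are delimited by ``|``.

Reports sharing a ``report_id`` are deduplicated keeping the *last*
occurrence in stream order (spontaneous-reporting systems supersede earlier
case versions); records whose receipt year cannot be parsed are dropped and
counted, never imputed, because year is the stratification key downstream.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SafetyReport",
    "CohortSpec",
    "LoadSummary",
    "normalize_term",
    "read_reports",
    "write_reports_jsonl",
    "write_reports_csv",
    "select_cohort",
    "classify",
]

_WS = re.compile(r"\s+")

DIALECTS = ("openfda", "csv")


def normalize_term(raw: str) -> str:
    """Normalize a vocabulary term: uppercase, trim, collapse whitespace.

    Idempotent; the empty string maps to itself.
    """
    return _WS.sub(" ", raw.strip()).upper()


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous adverse-event report."""

    report_id: str
    year: int
    drugs: frozenset[str]
    indications: frozenset[str]
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        for name in ("drugs", "indications", "reactions"):
            terms = getattr(self, name)
            object.__setattr__(self, name, frozenset(normalize_term(t) for t in terms))


@dataclass(frozen=True)
class CohortSpec:
    """The three index terms and year window defining one signal analysis.

    ``indication_term`` selects the cohort, ``drug_term`` splits it into
    exposed/unexposed, ``event_term`` splits it into event/no-event.
    """

    indication_term: str
    drug_term: str
    event_term: str
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        for name in ("indication_term", "drug_term", "event_term"):
            val = getattr(self, name)
            if not val:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, normalize_term(val))
        years = tuple(int(y) for y in self.years)
        if not years:
            raise ValueError("years must be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)


@dataclass
class LoadSummary:
    """Bookkeeping from one :func:`read_reports` call."""

    n_read: int = 0
    n_deduplicated: int = 0
    n_dropped_year: int = 0
    dropped_lines: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_deduplicated": self.n_deduplicated,
            "n_dropped_year": self.n_dropped_year,
            "dropped_lines": list(self.dropped_lines),
        }


def _parse_year(receipt_date: object) -> int | None:
    s = str(receipt_date) if receipt_date is not None else ""
    if len(s) >= 4 and s[:4].isdigit():
        return int(s[:4])
    return None


def _terms(value: object) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value] if value else []
    if isinstance(value, (list, tuple)):
        out: list[str] = []
        for v in value:
            out.extend(_terms(v))
        return out
    return [str(value)]


def _from_openfda(obj: dict) -> tuple[str, object, list[str], list[str], list[str]]:
    patient = obj.get("patient") or {}
    drugs: list[str] = []
    indications: list[str] = []
    for drec in patient.get("drug") or []:
        names = _terms(drec.get("generic_name"))
        if not names:
            names = _terms((drec.get("openfda") or {}).get("generic_name"))
        if not names:
            names = _terms(drec.get("medicinalproduct"))
        drugs.extend(names)
        indications.extend(_terms(drec.get("drugindication")))
    reactions = [
        r for rrec in patient.get("reaction") or [] for r in _terms(rrec.get("reactionmeddrapt"))
    ]
    return str(obj.get("safetyreportid", "")), obj.get("receiptdate"), drugs, indications, reactions


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_reports(source, dialect: str = "openfda") -> tuple[list[SafetyReport], LoadSummary]:
    """Read safety reports from a path or line iterable.

    Returns the deduplicated, normalized reports (last occurrence of each
    ``report_id`` wins, at its first-seen position) and a :class:`LoadSummary`.

    Raises
    ------
    ValueError
        On an unknown dialect, or on a malformed line/row (the message
        names the 1-based line number).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    summary = LoadSummary()
    raw: list[tuple[str, object, list[str], list[str], list[str]]] = []
    if dialect == "openfda":
        for lineno, line in enumerate(_iter_lines(source), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON on line {lineno}: {exc}") from exc
            raw.append(_from_openfda(obj))
    else:
        text = source
        if isinstance(source, (str, Path)):
            text = open(source, "r", encoding="utf-8", newline="")
        elif not hasattr(source, "read"):
            text = io.StringIO("\n".join(source))
        reader = csv.DictReader(text)
        required = {"report_id", "receipt_date", "drugs", "indications", "reactions"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"CSV header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in required):
                raise ValueError(f"malformed CSV row on line {lineno}")
            raw.append(
                (
                    row["report_id"],
                    row["receipt_date"],
                    [t for t in row["drugs"].split("|") if t],
                    [t for t in row["indications"].split("|") if t],
                    [t for t in row["reactions"].split("|") if t],
                )
            )
        if isinstance(text, io.TextIOWrapper):
            text.close()

    # Dedup keeping the last occurrence per report_id, stable in first-seen order.
    best: dict[str, tuple[object, list[str], list[str], list[str]]] = {}
    order: list[str] = []
    for rid, rdate, drugs, inds, reacts in raw:
        summary.n_read += 1
        if rid in best:
            summary.n_deduplicated += 1
        else:
            order.append(rid)
        best[rid] = (rdate, drugs, inds, reacts)

    reports: list[SafetyReport] = []
    for rid in order:
        rdate, drugs, inds, reacts = best[rid]
        year = _parse_year(rdate)
        if year is None:
            summary.n_dropped_year += 1
            continue
        reports.append(
            SafetyReport(
                report_id=rid,
                year=year,
                drugs=frozenset(drugs),
                indications=frozenset(inds),
                reactions=frozenset(reacts),
            )
        )
    return reports, summary


def _receiptdate(report: SafetyReport) -> str:
    return f"{report.year:04d}0101"


def write_reports_jsonl(reports: Sequence[SafetyReport], path) -> None:
    """Write reports as openFDA-dialect JSON lines (deterministic byte output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            indications = sorted(r.indications)
            obj = {
                "safetyreportid": r.report_id,
                "receiptdate": _receiptdate(r),
                "patient": {
                    "drug": [
                        {"generic_name": d, "drugindication": indications[0] if indications else ""}
                        for d in sorted(r.drugs)
                    ],
                    "reaction": [{"reactionmeddrapt": t} for t in sorted(r.reactions)],
                },
            }
            fh.write(json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n")


def write_reports_csv(reports: Sequence[SafetyReport], path) -> None:
    """Canonical CSV dump of normalized reports (terms sorted, ``|``-joined)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "receipt_date", "drugs", "indications", "reactions"])
        for r in reports:
            writer.writerow(
                [
                    r.report_id,
                    _receiptdate(r),
                    "|".join(sorted(r.drugs)),
                    "|".join(sorted(r.indications)),
                    "|".join(sorted(r.reactions)),
                ]
            )


def select_cohort(
    reports: Iterable[SafetyReport], indication_term: str, years: Sequence[int]
) -> list[SafetyReport]:
    """Reports whose indication set contains the exact term, within the year window.

    Matching is exact equality on normalized strings (never substring);
    input order is preserved.
    """
    if not years:
        raise ValueError("years must be non-empty")
    term = normalize_term(indication_term)
    window = set(int(y) for y in years)
    return [r for r in reports if term in r.indications and r.year in window]


def classify(report: SafetyReport, term: str, field: str) -> bool:
    """True iff ``term`` is an element of the report's ``drugs`` or ``reactions`` set.

    Exposure is ``classify(r, drug_term, "drugs")``; the event is
    ``classify(r, event_term, "reactions")``.
    """
    if field not in ("drugs", "reactions"):
        raise ValueError(f"unknown field {field!r}; expected 'drugs' or 'reactions'")
    return normalize_term(term) in getattr(report, field)
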