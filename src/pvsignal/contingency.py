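"""Per-year 2x2 exposure-by-event tables and the zero-cell rule.

Each calendar year of a cohort yields one table::

                 event   no event
    exposed        a        b
    unexposed      c        d

The Haldane–Anscombe continuity correction (add 0.5 to every cell when any
cell is zero) keeps the log odds ratio and its Woolf variance finite.
Strata with no exposed (a+b=0) or no unexposed (c+d=0) reports are excluded
from pooling: their corrected estimate would be pure artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .reports import CohortSpec, SafetyReport, classify

__all__ = ["StratumTable", "build_yearly_tables", "continuity_correct", "exclude_degenerate"]


@dataclass(frozen=True)
class StratumTable:
    """One stratum's 2x2 exposure-by-event counts."""

    stratum: str
    a: float  # exposed, event reported
    b: float  # exposed, event not reported
    c: float  # unexposed, event reported
    d: float  # unexposed, event not reported
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if not self.corrected:
            for cell in (self.a, self.b, self.c, self.d):
                if cell != int(cell):
                    raise ValueError("uncorrected cells must be integers")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def swap_exposure(self) -> "StratumTable":
        """Exchange the exposure labels: (a,b) <-> (c,d)."""
        return replace(self, a=self.c, b=self.d, c=self.a, d=self.b)


def build_yearly_tables(
    cohort: Iterable[SafetyReport], spec: CohortSpec
) -> list[StratumTable]:
    """One table per year of ``spec.years``, in order; empty years give all-zero tables.

    The cohort is assumed already restricted to the indication; reports
    outside ``spec.years`` are ignored.
    """
    cells: dict[int, list[int]] = {int(y): [0, 0, 0, 0] for y in spec.years}
    for r in cohort:
        if r.year not in cells:
            continue
        exposed = classify(r, spec.drug_term, "drugs")
        event = classify(r, spec.event_term, "reactions")
        idx = (0 if event else 1) if exposed else (2 if event else 3)
        cells[r.year][idx] += 1
    return [
        StratumTable(stratum=str(y), a=cells[int(y)][0], b=cells[int(y)][1],
                     c=cells[int(y)][2], d=cells[int(y)][3])
        for y in spec.years
    ]


def continuity_correct(table: StratumTable) -> StratumTable:
    """Add 0.5 to all four cells when any cell is zero; otherwise return unchanged."""
    if table.corrected:
        raise ValueError("table already corrected")
    if min(table.a, table.b, table.c, table.d) > 0:
        return table
    return replace(
        table, a=table.a + 0.5, b=table.b + 0.5, c=table.c + 0.5, d=table.d + 0.5,
        corrected=True,
    )


def exclude_degenerate(
    tables: Sequence[StratumTable],
) -> tuple[list[StratumTable], list[str]]:
    """Drop raw strata with an empty exposure margin (a+b=0 or c+d=0).

    Returns the kept tables and the labels of excluded strata, for the run log.
    """
    kept, excluded = [], []
    for t in tables:
        if t.a + t.b == 0 or t.c + t.d == 0:
            excluded.append(t.stratum)
        else:
            kept.append(t)
    return kept, excluded
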