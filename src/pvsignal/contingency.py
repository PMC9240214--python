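"""Fourfold (2x2) tables for drug-set x event pairs over a report database.

Disproportionality statistics are computed from the classic pharmacovigilance
fourfold table over a deduplicated report database:

====================  ============  ===============
                      target event  all other events
====================  ============  ===============
suspect drug in set        a               b
all other reports          c               d
====================  ============  ===============

The counting unit is the report: a report carrying both target events (e.g.
MDS and AML PTs) contributes to ``a`` for both event definitions.  For a
single-agent drug set, reports for sibling drugs of the same class stay in
the comparator cells (c, d) — the background is the full database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .report_io import CaseReport, EventDefinition

__all__ = ["FourfoldTable", "DrugSet", "build_table", "build_table_grid", "grid_to_frame"]


@dataclass(frozen=True)
class FourfoldTable:
    """Counts a, b, c, d of one drug-set x event fourfold table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("fourfold counts must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        """Reports whose primary suspect is in the drug set (a+b)."""
        return self.a + self.b

    @property
    def event_total(self) -> int:
        """Reports mentioning the target event (a+c)."""
        return self.a + self.c

    def transpose(self) -> "FourfoldTable":
        return FourfoldTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class DrugSet:
    """A labelled set of generic drug names (one agent or a whole class)."""

    label: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError("DrugSet.members must be non-empty")

    @classmethod
    def of(cls, label: str, *members: str) -> "DrugSet":
        return cls(label, frozenset(members))


def build_table(reports: Sequence[CaseReport], drugs: DrugSet, event: EventDefinition) -> FourfoldTable:
    """Count the fourfold table for one drug set and one event definition.

    Expects an already-deduplicated report list; each report lands in exactly
    one cell.  An empty report list yields the all-zero table (valid input
    for downstream estimators, which flag it undefined).
    """
    a = b = c = d = 0
    for rep in reports:
        has_drug = rep.primary_suspect_drug in drugs.members
        has_event = event.matches_report(rep)
        if has_drug:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return FourfoldTable(a, b, c, d)


def build_table_grid(
    reports: Sequence[CaseReport],
    drug_sets: Sequence[DrugSet],
    events: Sequence[EventDefinition],
) -> list:
    """Fourfold tables for every drug set x event pair in one pass.

    Element ``[i][j]`` equals ``build_table(reports, drug_sets[i], events[j])``.
    """
    n_ds, n_ev = len(drug_sets), len(events)
    a = [[0] * n_ev for _ in range(n_ds)]
    drug_totals = [0] * n_ds
    event_totals = [0] * n_ev
    n = 0
    for rep in reports:
        n += 1
        in_set = [rep.primary_suspect_drug in ds.members for ds in drug_sets]
        has_ev = [ev.matches_report(rep) for ev in events]
        for i, flag in enumerate(in_set):
            if flag:
                drug_totals[i] += 1
        for j, flag in enumerate(has_ev):
            if flag:
                event_totals[j] += 1
        for i, di in enumerate(in_set):
            if not di:
                continue
            for j, ej in enumerate(has_ev):
                if ej:
                    a[i][j] += 1
    grid = []
    for i in range(n_ds):
        row = []
        for j in range(n_ev):
            aa = a[i][j]
            bb = drug_totals[i] - aa
            cc = event_totals[j] - aa
            dd = n - aa - bb - cc
            row.append(FourfoldTable(aa, bb, cc, dd))
        grid.append(row)
    return grid


def grid_to_frame(grid, drug_sets: Sequence[DrugSet], events: Sequence[EventDefinition]) -> pd.DataFrame:
    """Long-format export: one row per (drug_label, event_label) table."""
    rows = []
    for i, ds in enumerate(drug_sets):
        for j, ev in enumerate(events):
            t = grid[i][j]
            rows.append({
                "drug_label": ds.label, "event_label": ev.label,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.N,
            })
    return pd.DataFrame(rows)
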