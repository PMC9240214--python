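"""Reading, validation, deduplication and filtering of spontaneous case reports.

Spontaneous reporting systems (FAERS, EudraVigilance) distribute individual
case safety reports as delimited line listings, one row per case, with
multi-valued cells for adverse-event preferred terms (PTs), concomitant
drugs and seriousness outcomes.  This module parses such listings into
:class:`CaseReport` records, resolves duplicate case versions, removes
aberrant reports (event onset before therapy start) and applies the study
inclusion filters (primary-suspect drug, receipt-date window).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SEXES",
    "REGIONS",
    "DATABASES",
    "OUTCOMES",
    "BRAND_TO_GENERIC",
    "CaseReport",
    "StudyWindow",
    "EventDefinition",
    "Dialect",
    "RejectedRow",
    "ReadResult",
    "normalize_drug",
    "read_reports",
    "write_reports",
    "reports_to_frame",
    "deduplicate",
    "remove_aberrant",
    "filter_primary_suspect",
    "filter_window",
]

SEXES = ("female", "male", "missing")
REGIONS = ("EEA", "non-EEA", "missing")
DATABASES = ("FAERS", "EV", "OTHER")
OUTCOMES = ("death", "life_threatening", "hospitalization_prolonged", "disability", "other")

#: Default brand-name synonym table for the four marketed PARP inhibitors.
BRAND_TO_GENERIC: Mapping[str, str] = {
    "lynparza": "olaparib",
    "zejula": "niraparib",
    "rubraca": "rucaparib",
    "talzenna": "talazoparib",
}

_WS = re.compile(r"\s+")


def normalize_drug(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Lower-case, collapse whitespace and map brand names to generics."""
    norm = _WS.sub(" ", name.strip().lower())
    table = BRAND_TO_GENERIC if synonyms is None else synonyms
    return table.get(norm, norm)


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous adverse-event case report.

    ``event_pts`` is a frozenset of ``(pt_name, pt_code)`` pairs; the PT code
    is ``None`` when the source listing carries names only.  An empty
    ``outcomes`` set means "outcome data unavailable", not "no serious
    outcome".
    """

    report_id: str
    primary_suspect_drug: str
    event_pts: frozenset  # of (str, int | None)
    database: str = "OTHER"
    receipt_date: Optional[dt.date] = None
    concomitant_drugs: tuple = ()
    sex: str = "missing"
    age_years: Optional[float] = None
    region: str = "missing"
    indication: Optional[str] = None
    outcomes: frozenset = frozenset()
    therapy_start_date: Optional[dt.date] = None
    event_onset_date: Optional[dt.date] = None
    version_seq: int = 0

    def __post_init__(self):
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.event_pts:
            raise ValueError("event_pts must be non-empty")
        if self.age_years is not None and not (0 <= self.age_years <= 130):
            raise ValueError(f"age_years out of range: {self.age_years}")
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex: {self.sex!r}")
        if self.region not in REGIONS:
            raise ValueError(f"invalid region: {self.region!r}")
        if self.database not in DATABASES:
            raise ValueError(f"invalid database: {self.database!r}")
        if not set(self.outcomes) <= set(OUTCOMES):
            raise ValueError(f"invalid outcomes: {set(self.outcomes) - set(OUTCOMES)}")
        if self.version_seq < 0:
            raise ValueError("version_seq must be >= 0")


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive receipt-date window for report inclusion."""

    start_date: dt.date
    end_date: dt.date

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")

    def __contains__(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclass(frozen=True)
class EventDefinition:
    """A target adverse event defined by MedDRA PT codes and/or names.

    Matching is exact on the PT code when the report PT carries one and the
    definition lists codes; otherwise case-insensitive on the PT name.  No
    MedDRA hierarchy expansion is performed (PTs are opaque labels here).
    """

    label: str
    pt_codes: frozenset = frozenset()
    pt_names: frozenset = frozenset()

    def __post_init__(self):
        if not self.pt_codes and not self.pt_names:
            raise ValueError("EventDefinition needs at least one PT code or name")
        object.__setattr__(self, "_names_cf", frozenset(n.casefold() for n in self.pt_names))

    def matches_pt(self, pt_name: str, pt_code: Optional[int]) -> bool:
        if pt_code is not None and pt_code in self.pt_codes:
            return True
        return pt_name.casefold() in self._names_cf

    def matches_report(self, report: CaseReport) -> bool:
        return any(self.matches_pt(n, c) for n, c in report.event_pts)


# ---------------------------------------------------------------------------
# Delimited-text dialect

_CANONICAL_COLUMNS = (
    "report_id",
    "database",
    "receipt_date",
    "primary_suspect_drug",
    "concomitant_drugs",
    "event_pts",
    "sex",
    "age_years",
    "region",
    "indication",
    "outcomes",
    "therapy_start_date",
    "event_onset_date",
    "version_seq",
)

_SEX_TOKENS = {"f": "female", "female": "female", "m": "male", "male": "male"}
_REGION_TOKENS = {"eea": "EEA", "european economic area": "EEA",
                  "non-eea": "non-EEA", "non-european economic area": "non-EEA"}
_OUTCOME_TOKENS = {
    "death": "death", "died": "death",
    "life_threatening": "life_threatening", "life-threatening": "life_threatening",
    "hospitalization_prolonged": "hospitalization_prolonged",
    "hospitalization": "hospitalization_prolonged",
    "hospital prolonged": "hospitalization_prolonged",
    "disability": "disability", "disabling": "disability",
    "other": "other",
}


@dataclass
class Dialect:
    """Format configuration mapping a delimited listing onto canonical fields.

    ``columns`` maps canonical field names to the column names found in the
    file; unmapped canonical fields fall back to their own name.  Multi-valued
    cells (events, concomitants, outcomes) are split on ``intra_sep``; a PT
    cell entry is ``name`` or ``name<code_sep>code``.
    """

    delimiter: str = "\t"
    intra_sep: str = ";"
    code_sep: str = "|"
    date_format: str = "%Y-%m-%d"
    columns: Mapping[str, str] = field(default_factory=dict)
    outcome_tokens: Mapping[str, str] = field(default_factory=lambda: dict(_OUTCOME_TOKENS))
    drug_synonyms: Mapping[str, str] = field(default_factory=lambda: dict(BRAND_TO_GENERIC))

    def column_for(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def parse_date(self, token: str) -> dt.date:
        return dt.datetime.strptime(token, self.date_format).date()

    def format_date(self, d: dt.date) -> str:
        return d.strftime(self.date_format)


@dataclass(frozen=True)
class RejectedRow:
    """A row (0-based, excluding header) that failed validation.

    ``fatal`` rows produced no CaseReport; non-fatal entries are advisory
    (e.g. a parseable report lacking a receipt date, which is retained but
    excluded from windowed analyses).
    """

    row: int
    reason: str
    fatal: bool = True


@dataclass
class ReadResult:
    reports: list
    rejects: list

    def reject_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.row, r.reason, r.fatal) for r in self.rejects],
            columns=["row", "reason", "fatal"],
        )


def _parse_events(cell: str, dialect: Dialect) -> frozenset:
    pts = set()
    for token in cell.split(dialect.intra_sep):
        token = token.strip()
        if not token:
            continue
        if dialect.code_sep in token:
            name, code_s = token.rsplit(dialect.code_sep, 1)
            code = int(code_s) if code_s.strip() else None
            pts.add((name.strip(), code))
        else:
            pts.add((token, None))
    return frozenset(pts)


def _parse_row(row: pd.Series, dialect: Dialect) -> CaseReport:
    def cell(canonical: str) -> str:
        v = row.get(dialect.column_for(canonical))
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v).strip()

    report_id = cell("report_id")
    if not report_id:
        raise ValueError("missing report_id")
    drug = cell("primary_suspect_drug")
    if not drug:
        raise ValueError("missing primary_suspect_drug")
    events = _parse_events(cell("event_pts"), dialect)
    if not events:
        raise ValueError("missing event term")

    def opt_date(canonical: str) -> Optional[dt.date]:
        tok = cell(canonical)
        return dialect.parse_date(tok) if tok else None

    age_tok = cell("age_years")
    outcomes = frozenset(
        dialect.outcome_tokens.get(t.strip().lower(), "other")
        for t in cell("outcomes").split(dialect.intra_sep)
        if t.strip()
    )
    db = cell("database").upper() or "OTHER"
    return CaseReport(
        report_id=report_id,
        primary_suspect_drug=normalize_drug(drug, dialect.drug_synonyms),
        event_pts=events,
        database=db if db in DATABASES else "OTHER",
        receipt_date=opt_date("receipt_date"),
        concomitant_drugs=tuple(
            normalize_drug(t, dialect.drug_synonyms)
            for t in cell("concomitant_drugs").split(dialect.intra_sep)
            if t.strip()
        ),
        sex=_SEX_TOKENS.get(cell("sex").lower(), "missing"),
        age_years=float(age_tok) if age_tok else None,
        region=_REGION_TOKENS.get(cell("region").lower(), "missing"),
        indication=cell("indication").lower() or None,
        outcomes=outcomes,
        therapy_start_date=opt_date("therapy_start_date"),
        event_onset_date=opt_date("event_onset_date"),
        version_seq=int(cell("version_seq") or 0),
    )


def read_reports(path, dialect: Dialect | None = None) -> ReadResult:
    """Read a delimited case listing into :class:`CaseReport` records.

    Rows whose mandatory fields (report_id, primary suspect drug, at least
    one event term) cannot be parsed are collected into ``rejects`` with a
    reason, never silently dropped.  Reports lacking a receipt date are kept
    but flagged with a non-fatal reject entry, since they cannot enter
    windowed analyses.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = {dialect.column_for(c) for c in ("report_id", "primary_suspect_drug", "event_pts")}
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise ValueError(f"no mappable header: missing columns {missing_cols}")

    reports, rejects = [], []
    for i, row in df.iterrows():
        try:
            rep = _parse_row(row, dialect)
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(row=int(i), reason=str(exc)))
            continue
        if rep.receipt_date is None:
            rejects.append(RejectedRow(row=int(i), reason="missing receipt_date", fatal=False))
        reports.append(rep)
    return ReadResult(reports=reports, rejects=rejects)


def _format_events(pts: frozenset, dialect: Dialect) -> str:
    parts = []
    for name, code in sorted(pts):
        parts.append(f"{name}{dialect.code_sep}{code}" if code is not None else name)
    return dialect.intra_sep.join(parts)


def reports_to_frame(reports: Iterable[CaseReport], dialect: Dialect | None = None) -> pd.DataFrame:
    """Serialize reports to the canonical delimited-table layout."""
    dialect = dialect or Dialect()
    rows = []
    for r in reports:
        rows.append({
            "report_id": r.report_id,
            "database": r.database,
            "receipt_date": dialect.format_date(r.receipt_date) if r.receipt_date else "",
            "primary_suspect_drug": r.primary_suspect_drug,
            "concomitant_drugs": dialect.intra_sep.join(r.concomitant_drugs),
            "event_pts": _format_events(r.event_pts, dialect),
            "sex": r.sex,
            "age_years": "" if r.age_years is None else repr(float(r.age_years)),
            "region": r.region,
            "indication": r.indication or "",
            "outcomes": dialect.intra_sep.join(sorted(r.outcomes)),
            "therapy_start_date": dialect.format_date(r.therapy_start_date) if r.therapy_start_date else "",
            "event_onset_date": dialect.format_date(r.event_onset_date) if r.event_onset_date else "",
            "version_seq": str(r.version_seq),
        })
    return pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))


def write_reports(reports: Iterable[CaseReport], path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    reports_to_frame(reports, dialect).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Filters

def deduplicate(reports: Sequence[CaseReport]) -> list:
    """Keep one record per report_id: the regulatory case-versioning winner.

    Highest ``version_seq`` wins; ties resolved by latest receipt date, then
    by latest input position.  Output is sorted by report_id so repeated runs
    are deterministic.  Idempotent.
    """
    best: dict = {}
    for idx, rep in enumerate(reports):
        key = (rep.version_seq, rep.receipt_date or dt.date.min, idx)
        prev = best.get(rep.report_id)
        if prev is None or key > prev[0]:
            best[rep.report_id] = (key, rep)
    return [best[rid][1] for rid in sorted(best)]


def remove_aberrant(reports: Sequence[CaseReport]):
    """Partition reports into (kept, removed) by date plausibility.

    A report is aberrant iff both therapy start and event onset are recorded
    and onset precedes start; same-day onset is plausible and kept, as are
    reports with either date missing.
    """
    kept, removed = [], []
    for rep in reports:
        if (rep.therapy_start_date is not None and rep.event_onset_date is not None
                and rep.event_onset_date < rep.therapy_start_date):
            removed.append(rep)
        else:
            kept.append(rep)
    return kept, removed


def filter_primary_suspect(reports: Sequence[CaseReport], drugs) -> list:
    """Keep reports whose *primary suspect* drug is in ``drugs``.

    Concomitant-only mentions of a study drug do not qualify a report.
    """
    drugs = set(drugs)
    if not drugs:
        raise ValueError("drugs must be non-empty")
    return [r for r in reports if r.primary_suspect_drug in drugs]


def filter_window(reports: Sequence[CaseReport], window: StudyWindow) -> list:
    """Keep reports received inside the inclusive study window.

    Reports without a receipt date are excluded (they cannot be placed in
    the window; read_reports flags them on ingestion).
    """
    return [r for r in reports if r.receipt_date is not None and r.receipt_date in window]
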