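"""Descriptive surfaces: demographics, seriousness outcomes, time to onset.

All percentages follow the "data available" convention of spontaneous-report
tabulations: the denominator is the number of reports with a non-missing
value for that particular field, never the total case count.  Seriousness
outcomes are multi-valued per report, so outcome counts may sum to more
than their denominator.  Time-to-onset summaries with fewer than four
computable latencies are suppressed (small-cell rule), mirroring how public
dashboards withhold sparse latency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dispro import round_half_away
from .report_io import CaseReport

__all__ = [
    "AGE_BANDS",
    "INDICATION_BUCKETS",
    "CategoryBreakdown",
    "OutcomeSummary",
    "TTOSummary",
    "age_band",
    "normalize_indication",
    "breakdown",
    "outcome_summary",
    "time_to_onset",
    "top_concomitants",
]

#: Age bands of the demographic tables: [0,18), [18,65), [65,86), [86, inf).
AGE_BANDS = (
    ("<18 y", 0.0, 18.0),
    ("18-64 y", 18.0, 65.0),
    ("65-85 y", 65.0, 86.0),
    (">85 y", 86.0, float("inf")),
)

#: Free-text indications are mapped into the five buckets used by the
#: characteristics tables.  Anything unmapped falls into the "other" bucket.
INDICATION_BUCKETS = ("ovarian cancer", "breast cancer", "pancreatic carcinoma",
                      "prostate cancer", "other malignant neoplasm")

_INDICATION_SYNONYMS: Mapping[str, str] = {
    "ovarian cancer": "ovarian cancer",
    "ovarian carcinoma": "ovarian cancer",
    "fallopian tube cancer": "ovarian cancer",
    "peritoneal cancer": "ovarian cancer",
    "breast cancer": "breast cancer",
    "breast carcinoma": "breast cancer",
    "pancreatic carcinoma": "pancreatic carcinoma",
    "pancreatic cancer": "pancreatic carcinoma",
    "prostate cancer": "prostate cancer",
    "prostate carcinoma": "prostate cancer",
}


def age_band(age_years: float) -> str:
    for label, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return label
    raise ValueError(f"age out of range: {age_years}")


def normalize_indication(text: str, synonyms: Mapping[str, str] | None = None) -> str:
    table = _INDICATION_SYNONYMS if synonyms is None else synonyms
    return table.get(text.strip().lower(), "other malignant neoplasm")


@dataclass(frozen=True)
class CategoryBreakdown:
    """Counts and data-available percentages for one categorical field."""

    field: str
    category_counts: Mapping[str, int]
    data_available: int
    percentages: Mapping[str, float]

    @classmethod
    def from_counts(cls, field: str, counts: Mapping[str, int]) -> "CategoryBreakdown":
        available = sum(counts.values())
        pct = {
            k: round_half_away(100.0 * v / available, 2)
            for k, v in counts.items()
        } if available else {}
        return cls(field, dict(counts), available, pct)


@dataclass(frozen=True)
class OutcomeSummary:
    """Serious-outcome counts over reports with at least one recorded outcome."""

    counts: Mapping[str, int]
    data_available: int
    percentages: Mapping[str, float]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], data_available: int) -> "OutcomeSummary":
        pct = {
            k: round_half_away(100.0 * v / data_available, 2)
            for k, v in counts.items()
        } if data_available else {}
        return cls(dict(counts), data_available, pct)


@dataclass(frozen=True)
class TTOSummary:
    """Median/IQR of therapy-start-to-onset latency, with small-n suppression."""

    n: int
    median_days: Optional[float]
    q1_days: Optional[float]
    q3_days: Optional[float]

    @property
    def suppressed(self) -> bool:
        return self.n < 4


def breakdown(reports: Iterable[CaseReport], field: str,
              indication_synonyms: Mapping[str, str] | None = None) -> CategoryBreakdown:
    """Tabulate one of sex / age_band / region / indication.

    Reports with a missing value for the field are excluded from the
    denominator (the "data available" convention).
    """
    counts: dict = {}
    for rep in reports:
        if field == "sex":
            cat = None if rep.sex == "missing" else rep.sex
        elif field == "age_band":
            cat = None if rep.age_years is None else age_band(rep.age_years)
        elif field == "region":
            cat = None if rep.region == "missing" else rep.region
        elif field == "indication":
            cat = None if rep.indication is None else normalize_indication(
                rep.indication, indication_synonyms)
        else:
            raise ValueError(f"unknown breakdown field: {field}")
        if cat is not None:
            counts[cat] = counts.get(cat, 0) + 1
    return CategoryBreakdown.from_counts(field, counts)


def outcome_summary(reports: Iterable[CaseReport]) -> OutcomeSummary:
    """Tally serious outcomes; a report increments every outcome it carries."""
    counts = {k: 0 for k in ("death", "life_threatening", "hospitalization_prolonged", "disability")}
    available = 0
    for rep in reports:
        if not rep.outcomes:
            continue
        available += 1
        for out in rep.outcomes:
            if out in counts:
                counts[out] += 1
    return OutcomeSummary.from_counts(counts, available)


def latencies_days(reports: Iterable[CaseReport]) -> list:
    """Whole-day onset latencies for reports with both dates and latency >= 0."""
    out = []
    for rep in reports:
        if rep.therapy_start_date is None or rep.event_onset_date is None:
            continue
        days = (rep.event_onset_date - rep.therapy_start_date).days
        if days >= 0:
            out.append(days)
    return out


def time_to_onset(reports: Iterable[CaseReport]) -> TTOSummary:
    """Median and IQR of onset latency with the small-cell suppression rule.

    Quantiles use linear interpolation (the common 'type 7' default), so
    fractional values such as 93.5 days are representable.  Fewer than four
    computable latencies yields a suppressed summary with no quantiles.
    """
    lat = latencies_days(reports)
    n = len(lat)
    if n < 4:
        return TTOSummary(n, None, None, None)
    q1, med, q3 = np.percentile(lat, [25, 50, 75])
    return TTOSummary(n, float(med), float(q1), float(q3))


def top_concomitants(reports: Iterable[CaseReport], k: int = 3) -> list:
    """Top-k concomitant drugs by report frequency, alphabetical tie-break."""
    counts: dict = {}
    for rep in reports:
        for drug in set(rep.concomitant_drugs):
            counts[drug] = counts.get(drug, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Table exports

def characteristics_frame(reports: Sequence[CaseReport], label: str = "") -> pd.DataFrame:
    """Long-format characteristics table (field, category, count, pct, available)."""
    rows = []
    for field in ("sex", "age_band", "region", "indication"):
        bd = breakdown(reports, field)
        for cat, cnt in sorted(bd.category_counts.items()):
            rows.append({
                "label": label, "field": field, "category": cat,
                "count": cnt, "percent": bd.percentages[cat],
                "data_available": bd.data_available,
            })
    return pd.DataFrame(rows, columns=["label", "field", "category", "count", "percent", "data_available"])


def outcomes_frame(reports: Sequence[CaseReport], label: str = "") -> pd.DataFrame:
    summ = outcome_summary(reports)
    rows = [{
        "label": label, "outcome": out, "count": summ.counts[out],
        "percent": summ.percentages.get(out, float("nan")),
        "data_available": summ.data_available,
    } for out in summ.counts]
    return pd.DataFrame(rows)


def tto_record(reports: Sequence[CaseReport], label: str = "") -> dict:
    summ = time_to_onset(reports)
    return {
        "label": label, "n": summ.n, "suppressed": summ.suppressed,
        "median_days": summ.median_days, "q1_days": summ.q1_days, "q3_days": summ.q3_days,
    }
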