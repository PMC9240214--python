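"""Published FAERS/EudraVigilance summary counts for PARP-inhibitor MDS/AML.

Fixtures encoding the printed results of a postmarketing surveillance
analysis of the four PARP inhibitors (olaparib, niraparib, rucaparib,
talazoparib) and the target events myelodysplastic syndrome (MDS) and acute
myeloid leukaemia (AML), covering receipt dates 2014-10-01 to 2021-09-30.
The source tabulations print per-drug report totals, target-case counts,
demographic and outcome counts with their "data available" denominators,
and per-pair ROR/PRR/IC estimates — but not the database background cells
(c, d).  :func:`reference_fixture` therefore back-solves integer backgrounds
from the printed ROR/PRR values via
:func:`pvsignal.dispro.consistency_check`, giving complete fourfold tables
that reproduce the printed estimates to their printed precision.

These fixtures let the estimators and descriptive summaries be exercised
against real published numbers without access to the raw databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from .contingency import FourfoldTable
from .dispro import BackSolveResult, consistency_check

__all__ = [
    "DRUGS", "FAERS_DRUG_TOTALS", "EV_DRUG_TOTALS",
    "FAERS_CASES", "EV_CASES", "GENDER_COUNTS", "OUTCOME_COUNTS",
    "PRINTED_DISPRO", "TTO_PUBLISHED", "ReferenceFixture", "reference_fixture",
]

DRUGS = ("olaparib", "niraparib", "rucaparib", "talazoparib")

#: All-cause report totals per drug over the study window.
FAERS_DRUG_TOTALS: Mapping[str, int] = {
    "olaparib": 5670, "niraparib": 8211, "rucaparib": 2475, "talazoparib": 354,
}
EV_DRUG_TOTALS: Mapping[str, int] = {
    "olaparib": 5493, "niraparib": 4854, "rucaparib": 1428, "talazoparib": 198,
}

#: Target-event case counts per drug: {event: {drug: a}}.
FAERS_CASES: Mapping[str, Mapping[str, int]] = {
    "MDS": {"olaparib": 147, "niraparib": 29, "rucaparib": 7, "talazoparib": 4},
    "AML": {"olaparib": 110, "niraparib": 30, "rucaparib": 4, "talazoparib": 1},
}
EV_CASES: Mapping[str, Mapping[str, int]] = {
    "MDS": {"olaparib": 179, "niraparib": 32, "rucaparib": 10, "talazoparib": 1},
    "AML": {"olaparib": 103, "niraparib": 19, "rucaparib": 5, "talazoparib": 0},
}

#: Gender counts per (database, event): per-drug female/male counts in drug
#: order; the data-available denominator is their sum.
GENDER_COUNTS: Mapping[tuple, Mapping[str, tuple]] = {
    ("FAERS", "MDS"): {"female": (136, 21, 3, 3), "male": (1, 1, 1, 1)},
    ("FAERS", "AML"): {"female": (94, 23, 4, 1), "male": (9, 2, 0, 0)},
    ("EV", "MDS"): {"female": (177, 31, 9, 1), "male": (1, 1, 1, 0)},
    ("EV", "AML"): {"female": (95, 12, 5, 0), "male": (7, 2, 0, 0)},
}

#: Serious-outcome counts per (database, event): per-drug counts in drug
#: order plus the per-drug data-available denominators.  Multiple outcomes
#: can be reported for the same report, so columns may sum past the
#: denominator.
OUTCOME_COUNTS: Mapping[tuple, Mapping[str, tuple]] = {
    ("FAERS", "MDS"): {
        "death": (36, 10, 3, 2), "life_threatening": (26, 11, 1, 1),
        "hospitalization_prolonged": (23, 7, 3, 3), "disability": (2, 2, 0, 0),
        "data_available": (87, 30, 7, 6),
    },
    ("FAERS", "AML"): {
        "death": (50, 16, 2, 1), "life_threatening": (27, 19, 1, 1),
        "hospitalization_prolonged": (25, 5, 2, 1), "disability": (1, 1, 0, 0),
        "data_available": (103, 41, 5, 3),
    },
    ("EV", "MDS"): {
        "death": (27, 4, 1, 0), "life_threatening": (25, 7, 0, 0),
        "hospitalization_prolonged": (18, 9, 2, 1), "disability": (4, 1, 0, 0),
        "data_available": (74, 21, 3, 1),
    },
    ("EV", "AML"): {
        "death": (24, 5, 0, 0), "life_threatening": (21, 4, 0, 0),
        "hospitalization_prolonged": (22, 5, 0, 0), "disability": (2, 0, 0, 0),
        "data_available": (69, 14, 0, 0),
    },
}

#: Printed FAERS disproportionality estimates per (drug-set label, event):
#: (ror, ror_lo, ror_hi, prr, prr_lo, prr_hi, ic, ic_lo, ic_hi), with the
#: per-value decimal precision of the ROR tuple used for back-solving.
PRINTED_DISPRO: Mapping[tuple, dict] = {
    ("PARP class", "MDS"): {
        "ror": (16.94, 14.66, 19.57), "prr": (16.76, 14.52, 19.34),
        "ic": (4.06, 3.51, 4.69), "decimals": (2, 2, 2, 2),
    },
    ("PARP class", "AML"): {
        "ror": (12.85, 10.91, 15.14), "prr": (12.75, 10.84, 14.99),
        "ic": (3.66, 3.11, 4.32), "decimals": (2, 2, 2, 2),
    },
    ("olaparib", "MDS"): {
        "ror": (40.49, 34.3, 47.78), "prr": (39.46, 33.58, 46.38),
        "ic": (5.27, 4.54, 6.12), "decimals": (2, 1, 2, 2),
    },
    ("olaparib", "AML"): {
        "ror": (29.39, 24.29, 35.55), "prr": (28.84, 23.93, 34.76),
        "ic": (4.83, 4.15, 5.6), "decimals": (2, 2, 2, 2),
    },
    ("rucaparib", "MDS"): {
        "ror": (4.22, 2.01, 8.86), "prr": (4.21, 2.01, 8.82),
        "ic": (2.07, 1.64, 2.62), "decimals": (2, 2, 2, 2),
    },
}

#: Published EV time-to-onset summaries (days): median and IQR, class level.
TTO_PUBLISHED: Mapping[str, dict] = {
    "MDS": {"median": 211.0, "q1": 93.5, "q3": 491.25},
    "AML": {"median": 355.0, "q1": 72.0, "q3": 483.5},
}


@dataclass(frozen=True)
class ReferenceFixture:
    """Published counts plus back-solved fourfold tables."""

    faers_total: int
    ev_total: int
    faers_class_cases: Mapping[str, int]
    ev_class_cases: Mapping[str, int]
    tables: Mapping[tuple, FourfoldTable]
    backsolve: Mapping[tuple, BackSolveResult]

    def table(self, drug_label: str, event: str) -> FourfoldTable:
        return self.tables[(drug_label, event)]


def _drug_total(label: str) -> int:
    if label == "PARP class":
        return sum(FAERS_DRUG_TOTALS.values())
    return FAERS_DRUG_TOTALS[label]


def _case_count(label: str, event: str) -> int:
    if label == "PARP class":
        return sum(FAERS_CASES[event].values())
    return FAERS_CASES[event][label]


@lru_cache(maxsize=1)
def reference_fixture() -> ReferenceFixture:
    """Build the full fixture, back-solving FAERS backgrounds on first use.

    Each back-solve searches integer comparator cells (c, d) that reproduce
    the printed ROR point estimate, its 95% bounds and the PRR point
    estimate at their printed precision; feasibility of this search is
    itself a correctness check of the estimator implementations against the
    published analysis.
    """
    tables = {}
    solved = {}
    for (label, event), printed in PRINTED_DISPRO.items():
        a = _case_count(label, event)
        total = _drug_total(label)
        ror_t = printed["ror"]
        target = (ror_t[0], ror_t[1], ror_t[2], printed["prr"][0])
        res = consistency_check(a, total, target, decimals=printed["decimals"])
        solved[(label, event)] = res
        if res.ok:
            tables[(label, event)] = FourfoldTable(a, total - a, res.c, res.d)
    return ReferenceFixture(
        faers_total=sum(FAERS_DRUG_TOTALS.values()),
        ev_total=sum(EV_DRUG_TOTALS.values()),
        faers_class_cases={ev: sum(FAERS_CASES[ev].values()) for ev in FAERS_CASES},
        ev_class_cases={ev: sum(EV_CASES[ev].values()) for ev in EV_CASES},
        tables=tables,
        backsolve=solved,
    )


def gender_breakdown_counts(database: str, event: str) -> Mapping[str, int]:
    """Pooled female/male counts across the four drugs for one table."""
    counts = GENDER_COUNTS[(database, event)]
    return {sex: sum(vals) for sex, vals in counts.items()}


def outcome_summary_counts(database: str, event: str):
    """Pooled outcome counts and the pooled data-available denominator."""
    tab = OUTCOME_COUNTS[(database, event)]
    counts = {k: sum(v) for k, v in tab.items() if k != "data_available"}
    return counts, sum(tab["data_available"])
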