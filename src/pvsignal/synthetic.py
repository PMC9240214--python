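"""Seeded synthetic spontaneous-report databases with known ground truth.

The generator emulates the statistical structure a disproportionality
analysis assumes: a database of case reports where each report names one
primary-suspect drug, carries one or more adverse-event PTs drawn with
drug-independent baseline probabilities, and selected drug-event pairs have
their event probability multiplied by an injected relative reporting
strength RR — the generative counterpart of the reporting-ratio estimand.
Demographics, serious outcomes, onset latencies, missingness, duplicate
case versions and aberrant date pairs are layered on top so every pipeline
stage can be exercised and checked against the recorded ground truth.

Randomness is organised as counter-based per-field streams derived from one
global seed (``SeedSequence([seed, field_id])``), so adding or removing a
configured field never reshuffles the draws of unrelated fields.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .report_io import CaseReport, StudyWindow

__all__ = ["SyntheticConfig", "GroundTruth", "default_config", "generate",
           "MDS_PT", "AML_PT", "MDS_PT_CODE", "AML_PT_CODE"]

MDS_PT = "Myelodysplastic syndrome"
AML_PT = "Acute myeloid leukaemia"
MDS_PT_CODE = 10028533
AML_PT_CODE = 10000846

_STUDY_WINDOW = StudyWindow(dt.date(2014, 10, 1), dt.date(2021, 9, 30))

# Stable per-field stream ids (counter-based substreams of the global seed).
_STREAMS = {
    "drug": 0, "events": 1, "receipt": 2, "therapy": 3, "latency": 4,
    "sex": 5, "age": 6, "region": 7, "indication": 8, "outcomes": 9,
    "missing": 10, "duplicates": 11, "aberrant": 12, "concomitant": 13,
}


def _rng(seed: int, stream: str, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream], sub]))


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic report database.

    ``injected_signals`` maps (drug, PT) to the relative reporting strength
    RR >= 1 multiplying the PT's baseline probability for reports whose
    primary suspect is that drug.  ``outcome_model`` and ``latency_model``
    are keyed by PT name (or a (drug, PT) tuple for latencies) with a
    ``"__default__"`` fallback; latency entries are (median_days, sigma) of
    a log-normal.  ``missingness`` holds per-field missing probabilities.
    """

    n_reports: int
    drug_vocabulary: Mapping[str, float]
    event_vocabulary: Mapping[str, float]
    pt_codes: Mapping[str, int] = field(default_factory=dict)
    injected_signals: Mapping[tuple, float] = field(default_factory=dict)
    outcome_model: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"__default__": {
            "death": 0.02, "life_threatening": 0.02,
            "hospitalization_prolonged": 0.04, "disability": 0.005}})
    latency_model: Mapping = field(default_factory=lambda: {"__default__": (120.0, 1.0)})
    concomitant_vocabulary: Mapping[str, float] = field(default_factory=dict)
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.93, "male": 0.07})
    age_mean: float = 62.0
    age_sd: float = 11.0
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {"EEA": 0.48, "non-EEA": 0.52})
    indication_probs: Mapping[str, float] = field(
        default_factory=lambda: {"ovarian cancer": 0.85, "breast cancer": 0.05,
                                 "pancreatic carcinoma": 0.01, "prostate cancer": 0.02,
                                 "other malignant neoplasm": 0.07})
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.40, "sex": 0.10, "region": 0.0,
                                 "indication": 0.15, "therapy_start_date": 0.35,
                                 "event_onset_date": 0.30, "outcomes": 0.30})
    duplicate_rate: float = 0.02
    aberrant_rate: float = 0.01
    window: StudyWindow = _STUDY_WINDOW
    database: str = "OTHER"
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for name, probs in (("drug_vocabulary", self.drug_vocabulary),
                            ("event_vocabulary", self.event_vocabulary)):
            if not probs:
                raise ValueError(f"{name} must be non-empty")
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k!r}] out of [0, 1]: {p}")
        for pair, rr in self.injected_signals.items():
            if rr < 1.0:
                raise ValueError(f"injected RR must be >= 1 ({pair}: {rr})")
        for f, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{f!r}] out of [0, 1]: {p}")
        for rate in (self.duplicate_rate, self.aberrant_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("duplicate/aberrant rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to verify the pipeline against the generator.

    ``expected_a`` is the exact expected target-cell count per (drug, PT)
    pair under the generative model, including the conditioning introduced
    by the guaranteed-at-least-one-event redraw; ``realized_a`` counts the
    emitted base reports (before duplication).
    """

    injected: dict
    expected_a: dict
    realized_a: dict
    expected_drug_total: dict
    duplicates: list
    aberrant: list
    warnings: list


def default_config(seed: int = 0, n_reports: int = 20_000) -> SyntheticConfig:
    """Study-scale default conditions.

    Four PARP inhibitors share 5% of the database with within-class shares
    matching their observed report volumes; rare target events (MDS, AML)
    ride on a bed of common background PTs; injected RRs mirror the
    magnitudes reported for the class (strong MDS signals, olaparib
    strongest, weak-to-null rucaparib/talazoparib AML).
    """
    parp_share = 0.05
    within = {"olaparib": 0.34, "niraparib": 0.49, "rucaparib": 0.148, "talazoparib": 0.022}
    drugs = {d: parp_share * w for d, w in within.items()}
    n_comparators = 8
    rest = (1.0 - parp_share) / n_comparators
    for i in range(n_comparators):
        drugs[f"comparator-{i:02d}"] = rest
    events = {
        MDS_PT: 0.0008, AML_PT: 0.0006,
        "Nausea": 0.12, "Fatigue": 0.10, "Anaemia": 0.06, "Vomiting": 0.05,
        "Diarrhoea": 0.05, "Headache": 0.04, "Thrombocytopenia": 0.03,
        "Neutropenia": 0.03,
    }
    injected = {
        ("olaparib", MDS_PT): 39.0, ("olaparib", AML_PT): 29.0,
        ("niraparib", MDS_PT): 9.0, ("niraparib", AML_PT): 12.0,
        ("rucaparib", MDS_PT): 4.2,
        ("talazoparib", MDS_PT): 12.0,
    }
    outcome_model = {
        "__default__": {"death": 0.02, "life_threatening": 0.02,
                        "hospitalization_prolonged": 0.04, "disability": 0.005},
        MDS_PT: {"death": 0.39, "life_threatening": 0.30,
                 "hospitalization_prolonged": 0.28, "disability": 0.03},
        AML_PT: {"death": 0.45, "life_threatening": 0.32,
                 "hospitalization_prolonged": 0.22, "disability": 0.01},
    }
    latency_model = {
        "__default__": (120.0, 1.0),
        MDS_PT: (211.0, 1.23),  # IQR ratio ~5.25 of the published latency spread
        AML_PT: (355.0, 1.41),
    }
    concomitants = {"carboplatin": 0.30, "paclitaxel": 0.25, "bevacizumab": 0.10,
                    "doxorubicin": 0.08, "cisplatin": 0.05}
    return SyntheticConfig(
        n_reports=n_reports,
        drug_vocabulary=drugs,
        event_vocabulary=events,
        pt_codes={MDS_PT: MDS_PT_CODE, AML_PT: AML_PT_CODE},
        injected_signals=injected,
        outcome_model=outcome_model,
        latency_model=latency_model,
        concomitant_vocabulary=concomitants,
        seed=seed,
    )


def _choice(rng, categories, probs, n):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(len(categories), size=n, p=p)


def generate(config: SyntheticConfig):
    """Generate (reports, truth), fully deterministic given ``config.seed``.

    Per report: draw the primary suspect from the drug vocabulary, draw each
    PT independently with probability baseline * RR(drug, PT) capped at 1
    (redrawing until at least one event is present), then demographics,
    outcomes and dates, then apply missingness; finally emit duplicate case
    versions and aberrant date corruptions, all recorded in the truth.
    """
    seed = config.seed
    n = config.n_reports
    drug_names = list(config.drug_vocabulary)
    drug_probs = np.array([config.drug_vocabulary[d] for d in drug_names], dtype=float)
    pt_names = list(config.event_vocabulary)
    base_p = np.array([config.event_vocabulary[p] for p in pt_names], dtype=float)
    warnings: list = []

    # per-(drug, PT) event probability matrix with injected RR, capped at 1
    p_matrix = np.tile(base_p, (len(drug_names), 1))
    for (drug, pt), rr in config.injected_signals.items():
        if drug not in config.drug_vocabulary or pt not in config.event_vocabulary:
            raise ValueError(f"injected signal references unknown pair {(drug, pt)}")
        i, j = drug_names.index(drug), pt_names.index(pt)
        raw = base_p[j] * rr
        if raw > 1.0:
            warnings.append(f"capped event probability for {(drug, pt)}: {raw:.3f} -> 1.0")
        p_matrix[i, j] = min(raw, 1.0)

    drug_idx = _choice(_rng(seed, "drug"), drug_names, drug_probs, n)

    # events: independent Bernoulli per PT, conditioned on >= 1 via redraw
    ev_rng = _rng(seed, "events")
    p_rows = p_matrix[drug_idx]
    events = ev_rng.random((n, len(pt_names))) < p_rows
    pending = ~events.any(axis=1)
    tries = 0
    while pending.any():
        tries += 1
        if tries > 1000:  # numerically unreachable for sane configs
            events[pending, np.argmax(p_rows[pending], axis=1)] = True
            break
        idx = np.flatnonzero(pending)
        events[idx] = ev_rng.random((idx.size, len(pt_names))) < p_rows[idx]
        pending[idx] = ~events[idx].any(axis=1)

    # dates
    span = (config.window.end_date - config.window.start_date).days
    receipt_off = _rng(seed, "receipt").integers(0, span + 1, n)
    start_off = _rng(seed, "therapy").integers(0, span + 1, n)

    # one latency per report, keyed by its most specific configured event
    lat_rng = _rng(seed, "latency")
    z = lat_rng.standard_normal(n)
    med = np.empty(n)
    sig = np.empty(n)
    default_med, default_sig = config.latency_model.get("__default__", (120.0, 1.0))
    pt_lookup = {}
    for key, val in config.latency_model.items():
        if key != "__default__":
            pt_lookup[key] = val
    for i in range(n):
        m, s = default_med, default_sig
        drug = drug_names[drug_idx[i]]
        for j in np.flatnonzero(events[i]):
            pt = pt_names[j]
            if (drug, pt) in pt_lookup:
                m, s = pt_lookup[(drug, pt)]
                break
            if pt in pt_lookup:
                m, s = pt_lookup[pt]
                break
        med[i], sig[i] = m, s
    latency = np.rint(np.exp(np.log(med) + sig * z)).astype(int)

    # demographics
    sex_cats = list(config.sex_probs)
    sex_idx = _choice(_rng(seed, "sex"), sex_cats, [config.sex_probs[c] for c in sex_cats], n)
    age = np.clip(_rng(seed, "age").normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    region_cats = list(config.region_probs)
    region_idx = _choice(_rng(seed, "region"), region_cats,
                         [config.region_probs[c] for c in region_cats], n)
    ind_cats = list(config.indication_probs)
    ind_idx = _choice(_rng(seed, "indication"), ind_cats,
                      [config.indication_probs[c] for c in ind_cats], n)

    # outcomes: per-report probabilities from the most severe matching model
    outcome_names = ("death", "life_threatening", "hospitalization_prolonged", "disability")
    default_out = config.outcome_model.get("__default__", {})
    out_p = np.zeros((n, len(outcome_names)))
    pt_out = {pt: mod for pt, mod in config.outcome_model.items() if pt != "__default__"}
    pt_out_idx = {pt_names.index(pt): mod for pt, mod in pt_out.items() if pt in pt_names}
    base_out = np.array([default_out.get(o, 0.0) for o in outcome_names])
    out_p[:] = base_out
    for j, mod in pt_out_idx.items():
        vec = np.array([mod.get(o, 0.0) for o in outcome_names])
        rows = events[:, j]
        out_p[rows] = np.maximum(out_p[rows], vec)
    out_draw = _rng(seed, "outcomes").random((n, len(outcome_names))) < out_p

    # concomitant medications
    con_names = list(config.concomitant_vocabulary)
    if con_names:
        con_p = np.array([config.concomitant_vocabulary[c] for c in con_names])
        con_draw = _rng(seed, "concomitant").random((n, len(con_names))) < con_p
    else:
        con_draw = np.zeros((n, 0), dtype=bool)

    # missingness, one substream per field
    def missing_mask(fname: str, sub: int) -> np.ndarray:
        p = config.missingness.get(fname, 0.0)
        if p <= 0:
            return np.zeros(n, dtype=bool)
        return _rng(seed, "missing", sub).random(n) < p

    miss_age = missing_mask("age", 0)
    miss_sex = missing_mask("sex", 1)
    miss_region = missing_mask("region", 2)
    miss_ind = missing_mask("indication", 3)
    miss_start = missing_mask("therapy_start_date", 4)
    miss_onset = missing_mask("event_onset_date", 5)
    miss_out = missing_mask("outcomes", 6)

    # aberrant corruption: only date-complete reports, so removal is exact
    date_complete = ~(miss_start | miss_onset)
    n_aberrant = int(math.floor(config.aberrant_rate * n))
    candidates = np.flatnonzero(date_complete)
    ab_rng = _rng(seed, "aberrant")
    aberrant_idx = ab_rng.choice(candidates, size=min(n_aberrant, candidates.size), replace=False)
    aberrant_back = ab_rng.integers(1, 181, aberrant_idx.size)

    n_dup = int(math.floor(config.duplicate_rate * n))
    dup_idx = _rng(seed, "duplicates").choice(n, size=n_dup, replace=False)

    start_date = config.window.start_date
    reports = []
    id_width = max(6, len(str(n)))
    pt_code = dict(config.pt_codes)
    aberrant_ids, duplicate_ids = [], []
    realized_a: dict = {}
    for i in range(n):
        rid = f"{i:0{id_width}d}"
        drug = drug_names[drug_idx[i]]
        evs = frozenset((pt_names[j], pt_code.get(pt_names[j]))
                        for j in np.flatnonzero(events[i]))
        for j in np.flatnonzero(events[i]):
            key = (drug, pt_names[j])
            realized_a[key] = realized_a.get(key, 0) + 1
        therapy = None if miss_start[i] else start_date + dt.timedelta(days=int(start_off[i]))
        onset = None
        if not miss_onset[i]:
            base = start_date + dt.timedelta(days=int(start_off[i]))
            onset = base + dt.timedelta(days=int(latency[i]))
        reports.append(CaseReport(
            report_id=rid,
            primary_suspect_drug=drug,
            event_pts=evs,
            database=config.database,
            receipt_date=start_date + dt.timedelta(days=int(receipt_off[i])),
            concomitant_drugs=tuple(con_names[j] for j in np.flatnonzero(con_draw[i])),
            sex="missing" if miss_sex[i] else sex_cats[sex_idx[i]],
            age_years=None if miss_age[i] else float(np.round(age[i], 1)),
            region="missing" if miss_region[i] else region_cats[region_idx[i]],
            indication=None if miss_ind[i] else ind_cats[ind_idx[i]],
            outcomes=frozenset() if miss_out[i] else frozenset(
                outcome_names[j] for j in np.flatnonzero(out_draw[i])),
            therapy_start_date=therapy,
            event_onset_date=onset,
            version_seq=1,
        ))

    # apply aberrant corruption (onset strictly before therapy start)
    for k, i in enumerate(aberrant_idx):
        rep = reports[i]
        new_onset = rep.therapy_start_date - dt.timedelta(days=int(aberrant_back[k]))
        reports[i] = replace(rep, event_onset_date=new_onset)
        aberrant_ids.append(rep.report_id)

    # duplicate case versions: an earlier version_seq appended at the end
    for i in dup_idx:
        rep = reports[i]
        older_receipt = max(start_date, rep.receipt_date - dt.timedelta(days=30))
        reports.append(replace(rep, version_seq=0, receipt_date=older_receipt))
        duplicate_ids.append(rep.report_id)

    # exact expected target-cell counts under the >= 1-event conditioning
    probs_norm = drug_probs / drug_probs.sum()
    expected_a: dict = {}
    expected_drug_total: dict = {}
    for i, drug in enumerate(drug_names):
        p_row = p_matrix[i]
        p_any = 1.0 - np.prod(1.0 - p_row)
        expected_drug_total[drug] = n * probs_norm[i]
        for j, pt in enumerate(pt_names):
            expected_a[(drug, pt)] = n * probs_norm[i] * p_row[j] / p_any

    truth = GroundTruth(
        injected=dict(config.injected_signals),
        expected_a=expected_a,
        realized_a=realized_a,
        expected_drug_total=expected_drug_total,
        duplicates=sorted(duplicate_ids),
        aberrant=sorted(aberrant_ids),
        warnings=warnings,
    )
    return reports, truth
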