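"""Calibration and recovery experiments for the consensus signal pipeline.

These seeded simulation studies quantify the operating characteristics of
the end-to-end pipeline on synthetic databases:

* :func:`null_flag_rate` — type-I behaviour: how often the consensus rule
  flags any drug-event pair in databases generated with no injected
  associations (conjunction of three tests plus a case floor should be
  conservative).
* :func:`signal_recovery_rate` — power: how often injected associations of
  known strength are recovered after the full filter chain, and how often
  non-injected pairs are (wrongly) flagged.
* :func:`tto_recovery_rate` — how often the time-to-onset median estimator
  recovers a configured latency median within a relative tolerance at a
  given case count.

All experiments derive replicate seeds from one base seed and are fully
reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .contingency import DrugSet, build_table_grid
from .descriptive import time_to_onset
from .dispro import BCPNNPriors, SignalCriteria, evaluate_signal
from .report_io import EventDefinition, deduplicate, remove_aberrant
from .synthetic import (AML_PT, AML_PT_CODE, MDS_PT, MDS_PT_CODE,
                        default_config, generate)

__all__ = [
    "parp_drug_sets", "target_events",
    "null_flag_rate", "signal_recovery_rate", "tto_recovery_rate",
]

_PARP = ("olaparib", "niraparib", "rucaparib", "talazoparib")


def parp_drug_sets() -> list:
    return [DrugSet.of("PARP class", *_PARP)] + [DrugSet.of(d, d) for d in _PARP]


def target_events() -> list:
    return [
        EventDefinition("MDS", pt_codes=frozenset([MDS_PT_CODE]),
                        pt_names=frozenset([MDS_PT])),
        EventDefinition("AML", pt_codes=frozenset([AML_PT_CODE]),
                        pt_names=frozenset([AML_PT])),
    ]


def _replicate_seed(base_seed: int, i: int) -> int:
    return (base_seed * 1_000_003 + i) % (2**31 - 1)


def _evaluate_pairs(reports, drug_sets, events, criteria, priors):
    grid = build_table_grid(reports, drug_sets, events)
    results = {}
    for i, ds in enumerate(drug_sets):
        for j, ev in enumerate(events):
            results[(ds.label, ev.label)] = evaluate_signal(grid[i][j], criteria, priors)
    return results


def null_flag_rate(n_replicates: int = 200, n_reports: int = 10_000,
                   base_seed: int = 0) -> float:
    """Fraction of null databases where any drug-event pair signals.

    Databases are generated from the default study-scale configuration with
    every injected association removed (RR = 1 everywhere), then pushed
    through deduplication, aberrant removal and the signal grid.
    """
    drug_sets, events = parp_drug_sets(), target_events()
    criteria, priors = SignalCriteria(), BCPNNPriors()
    flagged = 0
    for i in range(n_replicates):
        cfg = dataclasses.replace(
            default_config(seed=_replicate_seed(base_seed, i), n_reports=n_reports),
            injected_signals={})
        reports, _ = generate(cfg)
        reports, _ = remove_aberrant(deduplicate(reports))
        results = _evaluate_pairs(reports, drug_sets, events, criteria, priors)
        if any(r.signal for r in results.values()):
            flagged += 1
    return flagged / n_replicates


def signal_recovery_rate(n_replicates: int = 200, n_reports: int = 20_000,
                         base_seed: int = 0, rr_min: float = 10.0,
                         expected_a_min: float = 20.0):
    """(recovery rate, false-flag rate) over seeded default-condition replicates.

    A replicate counts as recovered when every *qualifying* injected pair —
    injected RR >= ``rr_min`` and expected target-cell count >=
    ``expected_a_min`` under the generative model — raises a consensus
    signal after the full filter chain.  The false-flag rate is the
    fraction of non-injected pairs flagged, pooled over replicates.
    """
    drug_sets, events = parp_drug_sets(), target_events()
    label_of_pt = {MDS_PT: "MDS", AML_PT: "AML"}
    criteria, priors = SignalCriteria(), BCPNNPriors()
    recovered = 0
    false_flags = 0
    null_pairs = 0
    n_qualifying = None
    for i in range(n_replicates):
        cfg = default_config(seed=_replicate_seed(base_seed, i), n_reports=n_reports)
        reports, truth = generate(cfg)
        reports, _ = remove_aberrant(deduplicate(reports))
        results = _evaluate_pairs(reports, drug_sets, events, criteria, priors)
        qualifying = [
            (drug, label_of_pt[pt])
            for (drug, pt), rr in truth.injected.items()
            if pt in label_of_pt and rr >= rr_min
            and truth.expected_a[(drug, pt)] >= expected_a_min
        ]
        n_qualifying = len(qualifying)
        injected_labels = {(d, label_of_pt[p]) for (d, p) in truth.injected if p in label_of_pt}
        if qualifying and all(results[pair].signal for pair in qualifying):
            recovered += 1
        for pair, res in results.items():
            if pair not in injected_labels and pair[0] != "PARP class":
                null_pairs += 1
                if res.signal:
                    false_flags += 1
    if not n_qualifying:
        raise RuntimeError("no injected pair qualifies at these settings")
    return recovered / n_replicates, false_flags / max(null_pairs, 1)


def tto_recovery_rate(n_seeds: int = 100, n_cases: int = 222,
                      median_days: float = 211.0, sigma: float = 1.229,
                      rel_tol: float = 0.15, base_seed: int = 0) -> float:
    """Fraction of seeds where the recovered latency median is within
    ``rel_tol`` of the configured median at the given case count.

    Each replicate generates a database whose every report carries the MDS
    PT with the configured log-normal latency and fully observed dates,
    then recovers the median via :func:`pvsignal.descriptive.time_to_onset`.
    """
    hits = 0
    for i in range(n_seeds):
        cfg = dataclasses.replace(
            default_config(seed=_replicate_seed(base_seed, i), n_reports=n_cases),
            event_vocabulary={MDS_PT: 1.0},
            injected_signals={},
            latency_model={"__default__": (median_days, sigma)},
            missingness={"therapy_start_date": 0.0, "event_onset_date": 0.0},
            duplicate_rate=0.0, aberrant_rate=0.0)
        reports, _ = generate(cfg)
        summ = time_to_onset(reports)
        assert summ.n == n_cases
        if abs(summ.median_days - median_days) / median_days <= rel_tol:
            hits += 1
    return hits / n_seeds
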