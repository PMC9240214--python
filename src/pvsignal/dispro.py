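"""Disproportionality estimators and the consensus signal rule.

Three classical pharmacovigilance measures are computed from a fourfold
table (a, b, c, d; N = a+b+c+d):

* **ROR** (reporting odds ratio) ``a*d / (b*c)`` with a Wald 95% interval on
  the log scale, ``exp(ln ROR +- z*sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]`` with
  ``exp(ln PRR +- z*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``, plus the
  companion Pearson chi-square.
* **IC** (BCPNN information component)
  ``log2[ P(drug, event) / (P(drug) P(event)) ]`` under the conjugate
  Beta-Bernoulli model of Bate-style Bayesian screening: independent Beta
  posteriors for the joint probability p11 ~ Beta(a + g11, N - a + g - g11)
  and the margins p1 ~ Beta(a+b+alpha1, c+d+alpha-alpha1),
  p2 ~ Beta(a+c+beta1, b+d+beta-beta1), with the joint prior total g chosen
  per table so the prior expectation sits at independence.  The point
  estimate and variance are the exact posterior mean and variance of IC
  (digamma/trigamma moments of log-Beta variables); the interval is
  ``ic +- z*sd``.  The prior shrinks small-count tables toward IC = 0, so IC
  is defined even with zero cells.

A drug-event pair is a **consensus signal** only when all three measures
are positive (ROR and PRR lower 95% bound > 1, IC lower bound > 0) and at
least ``min_cases`` target cases are reported.  Conjunction of the three
tests plus the case floor is deliberately conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma, psi

from .contingency import FourfoldTable

__all__ = [
    "Estimate",
    "SignalCriteria",
    "BCPNNPriors",
    "DisproResult",
    "round_half_away",
    "ror_estimate",
    "prr_estimate",
    "chi_square",
    "ic_estimate",
    "ic_mc",
    "evaluate_signal",
    "consistency_check",
    "BackSolveResult",
    "results_frame",
    "forest_frame",
]

_LN2 = math.log(2.0)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (display convention for printed estimates)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its 95% interval, or an undefined marker.

    Undefined is a value, not an exception: zero cells make ROR/PRR
    incalculable and the reason is carried along for reporting.
    """

    value: Optional[float]
    lo: Optional[float]
    hi: Optional[float]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    @classmethod
    def undefined(cls, reason: str) -> "Estimate":
        return cls(None, None, None, reason)


@dataclass(frozen=True)
class SignalCriteria:
    """Positivity rules for the three algorithms and the consensus gate.

    The default rule set is interval-based: ROR and PRR are positive when
    the lower 95% bound exceeds 1, IC when its lower bound exceeds 0, and a
    pair can only signal with at least ``min_cases`` reported cases.  The
    classical Evans rule (PRR >= 2 and chi-square >= 4) is available via
    ``classical_prr_rule``.
    """

    min_cases: int = 3
    z: float = 1.96
    classical_prr_rule: bool = False
    yates_correction: bool = False

    def __post_init__(self):
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be > 0")


@dataclass(frozen=True)
class BCPNNPriors:
    """Prior weights of the BCPNN Beta-Bernoulli model.

    Defaults (alpha1 = beta1 = gamma11 = 1, alpha = beta = 2) put a uniform
    Beta(1, 1) prior on each margin.  The joint prior total ``gamma`` is
    recomputed per table so that the prior mean of p11 equals the product of
    the posterior margin means, i.e. the prior is centred on independence.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha", "beta", "gamma11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def gamma(self, t: FourfoldTable) -> float:
        n = t.N
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1)))


@dataclass(frozen=True)
class DisproResult:
    """All three estimators, per-algorithm flags and the consensus verdict."""

    table: FourfoldTable
    ror: Estimate
    prr: Estimate
    chi2: Optional[float]
    ic: Estimate
    flags: dict = field(default_factory=dict)
    signal: bool = False


def ror_estimate(t: FourfoldTable, z: float = 1.96) -> Estimate:
    """Reporting odds ratio with Wald log-scale CI; undefined on zero cells."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return Estimate.undefined("zero cell")
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return Estimate(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def prr_estimate(t: FourfoldTable, z: float = 1.96) -> Estimate:
    """Proportional reporting ratio with Wald log-scale CI.

    Defined iff a > 0 and c > 0 (finite, non-zero proportions in both rows).
    """
    if t.a == 0 or t.c == 0:
        return Estimate.undefined("zero target-event cell")
    prr = (t.a / t.drug_total) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / t.drug_total + 1 / t.c - 1 / (t.c + t.d))
    return Estimate(prr, prr * math.exp(-z * se), prr * math.exp(z * se))


def chi_square(t: FourfoldTable, yates: bool = False) -> Optional[float]:
    """Pearson chi-square of the fourfold table (no continuity correction by
    default; Yates behind the flag).  ``None`` when any marginal is zero."""
    if min(t.drug_total, t.event_total, t.c + t.d, t.b + t.d) == 0:
        return None
    chi2, _, _, _ = stats.chi2_contingency(
        np.array([[t.a, t.b], [t.c, t.d]]), correction=yates
    )
    return float(chi2)


def _ic_moments(t: FourfoldTable, priors: BCPNNPriors):
    g = priors.gamma(t)
    n = t.N
    # E[ln X], Var[ln X] for X ~ Beta(p, q): psi(p) - psi(p+q), psi'(p) - psi'(p+q)
    terms = (
        (t.a + priors.gamma11, n + g, +1),            # joint p11
        (t.drug_total + priors.alpha1, n + priors.alpha, -1),   # margin p1
        (t.event_total + priors.beta1, n + priors.beta, -1),    # margin p2
    )
    mean = 0.0
    var = 0.0
    for p, tot, sign in terms:
        mean += sign * (psi(p) - psi(tot))
        var += float(polygamma(1, p) - polygamma(1, tot))
    return mean / _LN2, var / _LN2 ** 2


def ic_estimate(t: FourfoldTable, priors: BCPNNPriors | None = None, z: float = 1.96) -> Estimate:
    """Posterior mean and +-z*sd interval of the information component (bits).

    Always defined: the independence-centred prior regularises zero cells.
    """
    if t.N <= 0:
        raise ValueError("ic_estimate requires N > 0")
    priors = priors or BCPNNPriors()
    ic, var = _ic_moments(t, priors)
    sd = math.sqrt(var)
    return Estimate(ic, ic - z * sd, ic + z * sd)


def ic_mc(t: FourfoldTable, priors: BCPNNPriors | None = None,
          n_samples: int = 10_000, seed: int = 0):
    """Monte-Carlo oracle for :func:`ic_estimate`.

    Samples the factorised conjugate posterior of the BCPNN model — the
    independent Beta laws of the joint probability and the two margins —
    computes IC per draw and returns ``(mean, q2.5, q97.5)``.  Seeded and
    reproducible; the mean converges to the closed-form posterior mean.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    priors = priors or BCPNNPriors()
    g = priors.gamma(t)
    n = t.N
    rng = np.random.default_rng(seed)
    p11 = rng.beta(t.a + priors.gamma11, n - t.a + g - priors.gamma11, n_samples)
    p1 = rng.beta(t.drug_total + priors.alpha1, n - t.drug_total + priors.alpha - priors.alpha1, n_samples)
    p2 = rng.beta(t.event_total + priors.beta1, n - t.event_total + priors.beta - priors.beta1, n_samples)
    ic = np.log2(p11 / (p1 * p2))
    lo, hi = np.percentile(ic, [2.5, 97.5])
    return float(ic.mean()), float(lo), float(hi)


def evaluate_signal(t: FourfoldTable, criteria: SignalCriteria | None = None,
                    priors: BCPNNPriors | None = None) -> DisproResult:
    """Compute all three estimators and apply the consensus rule.

    An undefined estimator counts as not positive; fewer than ``min_cases``
    target cases forces ``signal = False`` regardless of the estimates.
    """
    criteria = criteria or SignalCriteria()
    priors = priors or BCPNNPriors()
    ror = ror_estimate(t, criteria.z)
    prr = prr_estimate(t, criteria.z)
    chi2 = chi_square(t, yates=criteria.yates_correction)
    ic = ic_estimate(t, priors, criteria.z)

    ror_pos = ror.defined and ror.lo > 1.0
    if criteria.classical_prr_rule:
        prr_pos = prr.defined and chi2 is not None and prr.value >= 2.0 and chi2 >= 4.0
    else:
        prr_pos = prr.defined and prr.lo > 1.0
    ic_pos = ic.lo > 0.0
    min_cases_met = t.a >= criteria.min_cases
    flags = {
        "ror_positive": ror_pos,
        "prr_positive": prr_pos,
        "ic_positive": ic_pos,
        "min_cases_met": min_cases_met,
    }
    return DisproResult(
        table=t, ror=ror, prr=prr, chi2=chi2, ic=ic, flags=flags,
        signal=ror_pos and prr_pos and ic_pos and min_cases_met,
    )


# ---------------------------------------------------------------------------
# Back-solving printed estimates for comparator cells

@dataclass(frozen=True)
class BackSolveResult:
    """Outcome of the integer background search for printed estimates."""

    ok: bool
    c: Optional[int]
    d: Optional[int]
    achieved: dict
    message: str


def _rounds_to(values: np.ndarray, target: float, decimals: int) -> np.ndarray:
    factor = 10.0 ** decimals
    rounded = np.floor(values * factor + 0.5) / factor
    return np.abs(rounded - target) < 0.5 / factor * 1e-6 + 1e-12


def consistency_check(
    a: int,
    drug_total: int,
    printed,
    decimals=(2, 2, 2, 2),
    z: float = 1.96,
    c_max: int = 200_000,
) -> BackSolveResult:
    """Search integer comparator cells (c, d) reproducing printed estimates.

    Published disproportionality tables print a, the drug total and the
    ROR/PRR estimates, but not the database background cells.  Given
    ``printed = (ror, ror_lo, ror_hi, prr)`` at the per-value ``decimals``,
    this searches c in [1, c_max] (d follows from the ROR point estimate)
    for a background that reproduces every printed value at its printed
    precision.  Returns the feasible pair with smallest c, or a failure
    carrying the closest achievable values.
    """
    b = drug_total - a
    if b <= 0 or a <= 0:
        raise ValueError("need 0 < a < drug_total")
    ror_t, lo_t, hi_t, prr_t = printed
    half = [0.5 * 10.0 ** -dec for dec in decimals]

    def score_and_check(cc: np.ndarray, dd: np.ndarray):
        ror = a * dd / (b * cc)
        se = np.sqrt(1 / a + 1 / b + 1 / cc + 1 / dd)
        lo = ror * np.exp(-z * se)
        hi = ror * np.exp(z * se)
        prr = (a / drug_total) / (cc / (cc + dd))
        ok = (
            _rounds_to(ror, ror_t, decimals[0])
            & _rounds_to(lo, lo_t, decimals[1])
            & _rounds_to(hi, hi_t, decimals[2])
            & _rounds_to(prr, prr_t, decimals[3])
        )
        score = (
            np.abs(ror - ror_t) / 10.0 ** -decimals[0]
            + np.abs(lo - lo_t) / 10.0 ** -decimals[1]
            + np.abs(hi - hi_t) / 10.0 ** -decimals[2]
            + np.abs(prr - prr_t) / 10.0 ** -decimals[3]
        )
        return ok, score

    # Rounding windows for the printed values constrain the table three ways:
    #   ROR window:  d/c in [R1, R2] * b/a
    #   PRR window:  d/c in [P/p_a - 1] window, p_a = a/(a+b)
    #   CI  window:  1/c + 1/d = (ln(hi/ror)/z)^2 - 1/a - 1/b, bracketed
    # The d/c windows intersect to a narrow band; the CI window brackets c.
    eps = 1e-9
    R1, R2 = ror_t - half[0], ror_t + half[0]
    L1, L2 = max(lo_t - half[1], eps), lo_t + half[1]
    H1, H2 = max(hi_t - half[2], eps), hi_t + half[2]
    P1, P2 = prr_t - half[3], prr_t + half[3]
    p_a = a / drug_total
    r_min = max(R1 * b / a, P1 / p_a - 1.0, eps)
    r_max = min(R2 * b / a, P2 / p_a - 1.0)
    zse_lo = max(math.log(max(H1 / R2, 1.0)), math.log(max(R1 / L2, 1.0)))
    zse_hi = min(math.log(H2 / max(R1, eps)), math.log(R2 / L1))
    K = 1.0 / a + 1.0 / b

    feasible = None  # (c, d) with smallest c
    closest = None
    closest_score = np.inf
    if r_min <= r_max and zse_hi > 0:
        S1 = max((zse_lo / z) ** 2 - K, 0.0)  # bounds on 1/c + 1/d
        S2 = (zse_hi / z) ** 2 - K
        if S2 > 0:
            c_lo = max(1, int(1.0 / S2) - 1)
            c_hi = c_max if S1 <= 0 else min(c_max, int((1.0 + 1.0 / r_min) / S1) + 2)
            for cval in range(c_lo, c_hi + 1):
                d0 = max(1, int(math.floor(r_min * cval)) - 1)
                d1 = int(math.ceil(r_max * cval)) + 1
                dd = np.arange(d0, d1 + 1, dtype=float)
                cc = np.full_like(dd, float(cval))
                ok, score = score_and_check(cc, dd)
                if ok.any():
                    i = int(np.argmax(ok))
                    feasible = (cval, int(dd[i]))
                    break
                j = int(np.argmin(score))
                if score[j] < closest_score:
                    closest_score = float(score[j])
                    closest = (cval, int(dd[j]))

    if feasible is None and closest is None:
        # incompatible windows: scan the ROR centre line for a diagnostic
        c = np.arange(1.0, float(c_max) + 1.0)
        d = np.maximum(np.floor(ror_t * b * c / a + 0.5), 1.0)
        _, score = score_and_check(c, d)
        j = int(np.argmin(score))
        closest = (int(c[j]), int(d[j]))

    cb, db = feasible if feasible is not None else closest
    t = FourfoldTable(a, b, cb, db)
    r, p = ror_estimate(t, z), prr_estimate(t, z)
    achieved = {"ror": r.value, "ror_lo": r.lo, "ror_hi": r.hi, "prr": p.value}
    if feasible is not None:
        return BackSolveResult(True, cb, db, achieved, "feasible background found")
    return BackSolveResult(False, None, None, achieved,
                           "no integer background reproduces the printed values")


# ---------------------------------------------------------------------------
# Exports

def results_frame(results, labels) -> pd.DataFrame:
    """Long-format results export: one row per (drug_label, event_label)."""
    rows = []
    for (drug_label, event_label), res in zip(labels, results):
        rows.append({
            "drug_label": drug_label,
            "event_label": event_label,
            "a": res.table.a, "b": res.table.b, "c": res.table.c, "d": res.table.d,
            "ror": res.ror.value, "ror_lo": res.ror.lo, "ror_hi": res.ror.hi,
            "prr": res.prr.value, "prr_lo": res.prr.lo, "prr_hi": res.prr.hi,
            "chi2": res.chi2,
            "ic": res.ic.value, "ic_lo": res.ic.lo, "ic_hi": res.ic.hi,
            "ror_positive": res.flags["ror_positive"],
            "prr_positive": res.flags["prr_positive"],
            "ic_positive": res.flags["ic_positive"],
            "min_cases_met": res.flags["min_cases_met"],
            "signal": res.signal,
        })
    return pd.DataFrame(rows)


def forest_frame(results, labels) -> pd.DataFrame:
    """Forest-plot-ready rows: one (estimate, lo, hi, label) per measure."""
    rows = []
    for (drug_label, event_label), res in zip(labels, results):
        for name, est in (("ROR", res.ror), ("PRR", res.prr), ("IC", res.ic)):
            rows.append({
                "row_label": f"{drug_label} / {event_label} / {name}",
                "measure": name,
                "estimate": est.value, "lo": est.lo, "hi": est.hi,
            })
    return pd.DataFrame(rows)
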