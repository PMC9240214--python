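# Methods

## Scope and data model

The package operates on individual case safety reports from spontaneous
reporting systems (FAERS, EudraVigilance). A report carries one
primary-suspect drug, a non-empty set of MedDRA preferred terms (PTs,
treated as opaque code/name labels — no hierarchy traversal), demographics,
seriousness outcomes, and therapy-start/event-onset dates. The counting
unit everywhere is the report: a report listing both MDS and AML PTs
counts as a case of each event, and no drug–event-mention expansion is
performed.

Cleaning follows regulatory case-versioning practice:

- **Deduplication** keeps, per report identifier, the record with the
  highest version sequence, breaking ties by latest receipt date and then
  latest input position; output is sorted by identifier, so the operation
  is deterministic and idempotent.
- **Aberrant reports** are those whose event onset strictly precedes
  therapy start; same-day onset is kept, as are reports missing either
  date.
- The **study window** (default 2014-10-01 to 2021-09-30, inclusive)
  filters on the receipt date, the date quarterly regulatory files are
  organised by; reports without a receipt date are excluded from windowed
  analyses and surfaced in the rejects log.
- The **primary-suspect criterion** identifies target cases only.
  Comparator reports are never dropped from the analysis database: for a
  single agent, reports for sibling drugs of the same class remain in the
  background cells, matching the full-database comparator that class-level
  published analyses imply.

## Disproportionality estimators

From the fourfold table (a, b, c, d; N):

- ROR = ad/(bc); 95% CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96.
  Defined only when all four cells are positive; zero cells yield an
  explicit undefined value rather than a Haldane–Anscombe correction,
  because continuity corrections change printed-value reproduction and the
  minimum-case gate already handles sparse pairs.
- PRR = [a/(a+b)]/[c/(c+d)]; 95% CI
  exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))); defined when a > 0 and
  c > 0. The companion Pearson χ² (no continuity correction by default,
  Yates behind a flag) is computed via `scipy.stats.chi2_contingency`.
- IC: the BCPNN information component log₂[p₁₁/(p₁p₂)] under conjugate
  Beta laws — p₁₁ ~ Beta(a+γ₁₁, N−a+γ−γ₁₁) jointly with margin posteriors
  p₁ ~ Beta(a+b+α₁, c+d+α−α₁) and p₂ ~ Beta(a+c+β₁, b+d+β−β₁), priors
  α₁ = β₁ = γ₁₁ = 1, α = β = 2, and the joint prior total
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) recomputed per table so the prior
  sits at independence. The point estimate and variance are the *exact*
  posterior moments of IC (digamma/trigamma moments of log-Beta
  variables). The classical closed form log₂ of the ratio of posterior
  means differs from the exact mean by ≈ 1/(2a·ln2) bits, which is
  invisible for a ≳ 50 but breaks agreement with the Monte-Carlo posterior
  oracle at small a; the exact moments are consistent with the oracle at
  every count. The interval is ic ± z·sd (a symmetric presentation;
  percentile intervals are available from `ic_mc`, which samples the same
  factorised posterior).

The IC prior pulls small-count and even large-count tables toward 0: with
the per-table γ the joint probability carries a prior weight of order
N²/((a+b)(a+c)), so e.g. a 147-case pair in a ~9M-report background is
shrunk by ~0.3 bits relative to the plug-in log₂ observed/expected.
Published IC values computed with other BCPNN variants can therefore
differ by a few tenths of a bit; comparisons against printed ICs use a
0.3-bit tolerance.

**Consensus rule.** A pair signals when the ROR and PRR lower 95% bounds
exceed 1, the IC lower bound exceeds 0, and a ≥ 3. An undefined estimator
is not positive. The classical Evans rule (PRR ≥ 2 and χ² ≥ 4) is
available behind a flag; the interval-based rules are the default because
the published negative-signal reasoning cites exactly those conditions.

## Back-solving published backgrounds

Published tables print a, the drug report total and rounded ROR/PRR
values, but not (c, d). `consistency_check` searches integer backgrounds
reproducing every printed value at its printed precision. The printed
rounding windows constrain the table three ways — the ROR and PRR windows
each pin d/c to a narrow band, and the CI width pins 1/c + 1/d — so the
search enumerates the small integer intersection exactly and returns the
feasible pair with smallest c (or the closest achievable values on
failure). Feasibility itself is a check of the estimator implementations
against the published analysis; all five published rows (class and
olaparib for both events, rucaparib–MDS) are feasible. Representatives
with small c give slightly smaller backgrounds than FAERS plausibly had;
this affects nothing that depends only on the printed precision, and
shifts IC by well under the variant tolerance across the feasible range.

## Descriptive surfaces

Every percentage uses the field-specific "data available" denominator
(reports with a non-missing value for that field), never the total case
count. Display rounding is half-away-from-zero at 2 decimals. Age bands
are [0,18), [18,65), [65,86), [86,∞); free-text indications map to five
buckets (ovarian, breast, pancreatic, prostate, other malignant neoplasm)
via a configurable synonym table. Outcomes are multi-valued per report, so
outcome counts may jointly exceed their denominator. Time-to-onset
latencies are whole days from therapy start to event onset (0 is valid,
negative excluded); quantiles use linear interpolation (type 7, the common
default, chosen because the published fractional quartiles like 93.5 are
representable under it); summaries with fewer than 4 latencies are
suppressed without quantiles. Top-k concomitant medication lists break
frequency ties alphabetically.

## Synthetic databases

The generator emulates the structure the analysis assumes, with defaults
at study scale: 20,000 reports; the four PARP inhibitors sharing 5% of the
database with within-class shares proportional to their observed report
volumes; rare target events (MDS 8×10⁻⁴, AML 6×10⁻⁴ baseline per report)
over a bed of common background PTs; injected relative reporting strengths
mirroring the published magnitudes (olaparib strongest, rucaparib MDS
weak, rucaparib/talazoparib AML absent). Events are independent Bernoulli
draws per PT with the injected multiplier applied to the suspect drug's
reports (capped at 1 with a recorded warning), redrawn until each report
has ≥ 1 event; the recorded ground truth uses the exact conditional
expectation this redraw induces. Onset latencies are log-normal per event:
MDS median 211 d with σ = 1.229 and AML median 355 d with σ = 1.41, the
dispersions implied by the published interquartile ranges (σ =
ln(q3/q1)/(2·0.6745)). Receipt and therapy-start dates are uniform over
the study window; duplicates are re-emitted earlier case versions;
aberrant corruption moves onset before start on date-complete reports so
ground-truth removal lists are exact. Randomness uses counter-based
per-field streams derived from one seed, so adding a field never
reshuffles unrelated draws.

What the generator does **not** emulate: reporting-delay dynamics,
stimulated reporting, masking/competition between signals, drug-correlated
demographics, record-linkage-level duplicates (only shared identifiers),
or realistic background-PT correlation structure. Passing recovery tests
therefore shows the estimators and pipeline are correct under the assumed
generative structure, not that real databases satisfy it.

## Operating characteristics

Measured by `pvsignal.experiments` (and recomputed by the acceptance
script) at the generator's default conditions:

- **Null calibration**: 200 seeded replicates of 10,000-report databases
  with no injected associations; the fraction of replicates where any of
  the 10 drug-event pairs raises a consensus signal is ≈ 0–1%, well under
  the 5% bar — the conjunction of three tests plus the case floor is
  conservative.
- **Signal recovery**: 200 seeded replicates at 20,000 reports; every
  injected pair with RR ≥ 10 and expected target count ≥ 20 is recovered
  in ≥ 95% of replicates (observed 100%), with non-injected pairs flagged
  at ≈ 0%.
- **Latency-median recovery**: at the published MDS conditions (n = 222
  cases, median 211 d, σ = 1.229), the sample median lands within ±15% of
  the configured median in only ~85% of seeds — the asymptotic standard
  error of the median, σ·m·√(π/2n), is ≈ 22 d, so the ±15% (≈ 31.6 d) band
  has ≈ 1.45-sigma coverage. A 90% recovery bar is unattainable at these
  faithful conditions (it would need σ ≤ ~1.08 or n ≥ ~350); the
  corresponding acceptance test is expected to fail and is intentionally
  left failing rather than relaxing the dispersion the published IQR
  implies. The practical reading: a published 211-day median from 222
  cases carries roughly ±16% sampling uncertainty.

## Problem sizes and numerics

Simulation studies run at 10⁴–2×10⁴ reports per replicate and 100–200
replicates, sizes at which every estimator operates far from numerical
limits; the background back-solve enumerates integers exactly rather than
optimising, so it cannot converge to a near-miss. Replicate seeds derive
from one base seed by affine hashing below 2³¹. Degenerate inputs are
contracts, not errors: empty databases give all-zero tables, zero cells
give undefined ROR/PRR flags, and empty category blocks give zero
denominators with no percentages.

## Known limitations

No MedDRA hierarchy or SMQ expansion; no stratified or adjusted tables;
no EBGM/MGPS; no multiple-comparison control across the grid (none is
applied in the published analyses this mirrors); no record-linkage
duplicate detection; live FAERS/EudraVigilance extraction is out of scope
— published counts enter as fixtures and everything else is synthetic.
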