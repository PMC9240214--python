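# pvsignal

Disproportionality signal detection for spontaneous adverse-event report
databases, built around the postmarketing safety question of whether PARP
inhibitors (olaparib, niraparib, rucaparib, talazoparib) are
disproportionately reported with myelodysplastic syndrome (MDS) and acute
myeloid leukaemia (AML) in FAERS and EudraVigilance.

## Who this is for

Pharmacovigilance analysts and methods researchers who need a tested,
scriptable implementation of the classical signal-detection stack — report
cleaning, fourfold tables, ROR/PRR/BCPNN estimators, consensus rules,
descriptive surfaces — plus a synthetic report-database generator with
known injected signals so every stage can be validated without access to
the raw regulatory databases.

## The statistics

For a drug set D and event E over a deduplicated report database, the
fourfold table counts a (D and E), b (D, other events), c (other drugs, E)
and d (neither), N = a+b+c+d. The package computes:

- **Reporting odds ratio** ROR = ad/(bc), with the Wald interval
  exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)); undefined on zero cells.
- **Proportional reporting ratio** PRR = [a/(a+b)] / [c/(c+d)], with
  exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), plus the Pearson χ².
- **Information component** IC = log₂[P(D,E) / (P(D)P(E))] under the
  conjugate Beta model of Bayesian confidence propagation neural network
  (BCPNN) screening, reported as the exact posterior mean with a ± z·sd
  interval; shrinkage toward IC = 0 keeps it defined on zero cells.
- **Consensus signal**: a pair signals only when the ROR and PRR lower 95%
  bounds exceed 1, the IC lower bound exceeds 0, and at least 3 target
  cases are reported.

Because published analyses print a, the drug totals and the estimates but
not the background cells, `consistency_check` back-solves integer (c, d)
that reproduce printed ROR/PRR values and intervals to their printed
precision — turning published tables into complete, checkable fixtures.

## Worked example

Reconstruct the published olaparib–MDS FAERS row (147 cases among 5,670
olaparib reports; printed ROR 40.49, PRR 39.46) and evaluate the signal:

```python
from pvsignal import reference_fixture, ror_estimate, prr_estimate, ic_estimate, evaluate_signal

fix = reference_fixture()              # back-solves backgrounds on first use
t = fix.table("olaparib", "MDS")
print((t.a, t.b, t.c, t.d))            # (147, 5523, 5877, 8939383)
print(ror_estimate(t).value)           # 40.485...  -> prints as 40.49
print(prr_estimate(t).value)           # 39.461...  -> prints as 39.46
print(ic_estimate(t).value)            # 4.94 bits (BCPNN-shrunk)
print(evaluate_signal(t).signal)       # True
```

Simulate a 20,000-report database with the default injected associations
and run the pipeline from the shell:

```bash
pvsignal simulate -o sim --seed 42 --n-reports 20000
pvsignal signal -i sim/reports.tsv -o sig
```

```
6 consensus signal(s) across 10 drug-event pairs
```

The grid in `sig/dispro.tsv` shows the expected structure — strong class
and olaparib signals, a weak rucaparib–MDS association that fails the
consensus rule, and undefined ROR/PRR with negative IC for the pairs with
no injected association:

```
 drug_label event_label  a   ror  ror_lo   prr    ic  ic_lo  signal
 PARP class         MDS 38 19.96   12.67 19.22  3.01   2.45    True
   olaparib         MDS 23 25.90   15.69 24.26  3.33   2.65    True
  rucaparib         MDS  3  5.92    1.84  5.81  1.20  -0.36   False
talazoparib         AML  0   NaN     NaN   NaN -0.91  -4.60   False
```

`pvsignal describe` writes the demographic/outcome/time-to-onset tables
(with "data available" denominators and the <4-case suppression rule), and
`pvsignal fixture` exports the reference tables.

## Layout

- `pvsignal.report_io` — case-report parsing, deduplication, filters
- `pvsignal.contingency` — fourfold tables at drug and class level
- `pvsignal.dispro` — ROR/PRR/χ²/IC, consensus rule, background back-solve
- `pvsignal.descriptive` — demographics, outcomes, time to onset
- `pvsignal.synthetic` — seeded report-database generator with ground truth
- `pvsignal.reference` — published-count fixtures
- `pvsignal.experiments` — calibration/recovery simulation studies
- `pvsignal.cli` — `pvsignal simulate | signal | describe | fixture`

See `docs/methods.md` for the model variants, defaults and known limits.
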