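# pvsignals

Disproportionality-based signal detection for spontaneous adverse-event
reporting databases, built around the case study of tramadol-related
acute central respiratory depression (ACRD) in a worldwide
pharmacovigilance database.

Spontaneous-report databases (VigiBase, FAERS, EudraVigilance) collect
individual case safety reports (ICSRs): one report lists demographics,
one or more drugs with a reporter-assigned role (suspected, interacting,
concomitant) and one or more adverse events coded as MedDRA preferred
terms (PTs). Because there is no denominator of exposed patients,
hypothesis generation relies on *disproportionality*: comparing how often
a drug–event pair is reported against its expectation under independence
within the database. `pvsignals` implements that workflow end to end for
analysts and methodologists who want a scriptable, testable pipeline:

* an ICSR domain model with a deterministic TSV line-listing format;
* SMQ-based event grouping (the 19 narrow-scope ACRD PTs are built in),
  ATC-prefix opioid scoping (N02A, N01AH) and drug-class membership;
* 2×2 contingency tables per drug–event pair under a configurable
  comparator scope (full database, or opioid reports only) with the three
  classical indices

  ```
  PRR = [A/(A+B)] / [C/(C+D)]
  ROR = (A/B) / (C/D)
  IC  = log2 (N_obs + 0.5) / (N_exp + 0.5),   N_exp = N_drug·N_effect / N_total
  ```

  and the composite signal rule *N_obs ≥ 3 and PRR ≥ 2 and ROR ≥ 2 and
  IC025 ≥ 0*, plus age-stratified runs;
* 2×k factor analysis of case status against demographics, concomitant
  drug classes (CYP2D6 inhibitors, opioids, benzodiazepines,
  antidepressants), abuse co-reporting and death — Pearson chi-square with
  adjusted-standardised-residual post hoc;
* a synthetic report generator with injected drug–event relative risks,
  so every stage is testable without access to a restricted database.

## Worked example

Generate a reduced-scale synthetic analogue of the tramadol study
database (100,000 reports, tramadol on ~0.6 % of them, the five ACRD
signal terms injected at elevated relative risks) and run signal
detection:

```python
from pvsignals import (
    tramadol_study_preset, generate, detect_signals, builtin_acrd_smq,
)

config = tramadol_study_preset(n_reports=100_000)
db, ledger = generate(config, seed=11)
results = detect_signals(db, "tramadol", builtin_acrd_smq())
for r in results[:6]:
    print(f"{r.table.event:<28} {r.table.a:>3} {r.prr.value:>6.2f} "
          f"{r.ror.value:>6.2f} {r.ic025:>6.2f}  {r.signal}")
```

```
Bradypnoea                    25  16.33  17.04   2.89  True
Respiratory depression        14  10.33  10.57   2.01  True
Respiratory arrest            12  10.76  10.97   1.92  True
Hypoventilation                5   5.36   5.39   0.35  True
Respiratory rate decreased     4   5.53   5.57   0.09  True
Respiratory failure            3   1.83   1.83  -1.36  False
```

Each row is one preferred term: `n` is the number of reports carrying
both tramadol (suspected/interacting) and the term, PRR/ROR measure the
reporting disproportion against all other reports, and `IC025` is the
lower 95 % credibility bound of the information component. The five
injected terms — and only those — satisfy the composite rule, so the
pipeline recovers exactly the association structure the generator put in.
Running the same detection with `scope="opioids"` compares tramadol
against other opioid reports instead and yields no signal, reflecting the
stronger respiratory-depression risks injected for the full agonists.

The same workflow is available from the shell:

```bash
pvsignals simulate --n-reports 100000 --seed 11 --out listing.tsv
pvsignals signals --listing listing.tsv --drug tramadol --smq acrd --out table.tsv
pvsignals report --preset --seed 11 --out bundle/
```

`report` writes the full bundle: demographics table, per-term signal
tables per drug × scope, an under-18 stratified table, factor tables with
chi-square and post-hoc flags, and a machine-readable `summary.json`.
Identical config and seed always produce byte-identical bundles.

## Layout

```
src/pvsignals/
  icsr.py                 ICSR domain types, line-listing I/O, report filtering
  terminology.py          SMQs, ATC scoping, drug classes
  simulate.py             synthetic database generator + study preset
  disproportionality.py   2x2 tables, PRR/ROR/IC, signal rule, stratification
  factors.py              2xk factor tables, chi-square, post hoc, ratios
  reporting.py            pipeline orchestration and table rendering
  cli.py                  command-line interface
  reference.py            published summary counts (demographics, per-term
                          statistics, factor tables)
docs/methods.md           model, assumptions, parameter choices, limitations
```
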