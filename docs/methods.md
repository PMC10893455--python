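# Methods

## Setting and data model

The unit of analysis is the individual case safety report (ICSR). A
report carries demographics (sex; seven reporting age bands ≤11, 12–17,
18–44, 45–64, 65–74, ≥75, unknown; region; reporter type; year), a
three-valued seriousness token, a death flag, at least one drug entry
(name, optional ATC code, role ∈ {suspected, interacting, concomitant})
and at least one adverse event coded as a MedDRA preferred term (PT).
`death = true` is only admitted when seriousness is true or unknown,
because death is itself a seriousness criterion. The on-disk format is a
long-grain TSV (one row per report–drug–event triple) merged to report
grain at read time; demographics that disagree across rows of one
report_id are a hard error rather than a silent pick. All counting
downstream is at report level: a report contributes at most once to any
cell no matter how many qualifying entries it carries.

Drug-name matching is case-insensitive exact matching after whitespace
normalisation; combination products are distinct names ("tramadol/
paracetamol" is not "tramadol"), mirroring how combination formulations
are analysed separately in pharmacovigilance practice.

## Event grouping and scoping

Respiratory depression is operationalised as the narrow scope of the
"Acute central respiratory depression" Standardised MedDRA Query: 19
preferred terms, shipped verbatim in `builtin_acrd_smq` with
case-insensitive membership. A report with several SMQ terms is one
case. The "drug abuse and dependence" grouping is a configurable term
file; MedDRA SMQ contents are licensed, so the shipped default covers the
common abuse/dependence/misuse/overdose PTs and is explicitly
user-replaceable. Opioid comparator membership is decided purely on ATC
prefixes (N02A, N01AH) of the coded drug entries — bit-exact and
testable, at the cost of requiring coded data. Drug-class lists
(CYP2D6 inhibitors per the FDA interaction examples, opioids,
benzodiazepines, antidepressants) are configuration files with defaults
covering the common members; before factor analysis a class is restricted
to members co-reported with the index drug in strictly more than
`min_cases` (default 20) reports.

## Disproportionality

For a drug of interest and an event definition, reports cross-classify
as A (drug and event), B (drug, no event), C (event, no drug) and D
(neither), where the drug's reports are those listing it as suspected or
interacting, and C/D run over the comparator scope: the whole database,
or reports carrying another opioid. The index drug's own reports are
excluded from the opioid comparator (its ATC code does not re-qualify
them), which is standard case/non-case practice. Three indices are
computed in full precision:

* PRR = [A/(A+B)] / [C/(C+D)], 95 % CI by the log-scale Wald interval
  with SE = √(1/A − 1/(A+B) + 1/C − 1/(C+D)); undefined when C = 0.
* ROR = (A/B)/(C/D), Wald SE = √(1/A + 1/B + 1/C + 1/D); when any cell
  is zero the CI uses the Haldane–Anscombe +0.5 correction and the point
  estimate is reported missing when B·C·D = 0.
* IC = log2 (A + 0.5)/(N_exp + 0.5) with N_exp = (A+B)(A+C)/N. The +0.5
  offsets keep the IC finite for every table including A = 0. The lower
  95 % credibility bound defaults to the closed-form approximation
  IC − 3.3 (A+0.5)^−1/2 − 2.0 (A+0.5)^−3/2; a Gamma(A+0.5, rate N_exp+0.5)
  quantile bound is selectable via `ic_method="gamma"`. On reconstructed
  large-database tables the two differ by at most ~0.03 bits, with the
  gamma bound tracking published values slightly more closely.

A pair is a signal only if all of: A ≥ 3, PRR ≥ 2, ROR ≥ 2, IC025 ≥ 0.
Pairs with fewer than three reports are reported but never flagged. A
missing PRR or ROR fails its criterion. Age-stratified runs repeat the
identical computation on the sub-database of the requested age bands;
unknown-age reports belong to no stratum, and an empty stratum yields an
empty result with a warning rather than an error.

Published per-term tables print only (n, PRR, ROR, IC025); the full 2×2
is recovered by back-solving C from the PRR formula given the drug's
report total and the database size, rounding to the nearest report
(`reconstruct_table`). On these tables the recomputed PRR and ROR agree
with the printed values to ±0.01 after two-decimal half-up rounding and
the closed-form IC025 to within 0.06 bits (the worst case across all 19
ACRD terms for both index drugs), and the composite rule reproduces the
published signal sets exactly.

## Factor analysis

Within the index drug's suspected/interacting reports, ACRD cases are
cross-tabulated against: sex; age collapsed to ≤17 / 18–64 / ≥65;
region; reporter; concomitant use of each drug class; abuse co-reporting
(an abuse-SMQ term on the same report — the data model has no patient
linkage, so cross-report abuse history is out of reach); and death.
Unknown categories are excluded before testing and their count retained.
Association is tested with Pearson's chi-square without continuity
correction (expected counts from the margins; a zero margin is a
degenerate table). For factors with k ≥ 3 categories, a post-hoc pass
computes adjusted standardised residuals (O−E)/√(E(1−row/n)(1−col/n)) and
flags categories two-sided against a Bonferroni-corrected level α/(2k);
in a 2×k table the two residuals of a column are equal and opposite, so
one flag per category (case-row sign) is reported. Per-category
proportions use the case and non-case totals after unknown exclusion as
denominators; the case/non-case proportion ratio and, for binary
factors, the odds ratio with a Wald CI summarise effect size. The
published source table is internally inconsistent on one point (its
non-case reporter percentages use the pre-exclusion total); this package
applies the post-exclusion convention uniformly.

## Synthetic database generator

The generator emulates the structure of a spontaneous-reporting extract,
not its full complexity. Reports are independent. Demographics are
sampled from categorical marginals; drug exposures from per-drug
Bernoulli prevalences, optionally correlated through co-medication rules
P(co-drug | index drug); events from per-PT Bernoulli draws whose
probability is multiplied by an injected relative risk when the paired
drug is present (optionally boosted further in chosen age groups), capped
at 1. Death is a baseline probability scaled by per-PT multipliers, so
fatal-outcome associations are recoverable; a sampled death forces
seriousness away from "false". Reports where no catalogue drug (or
event) fired receive a dedicated filler entry ("unspecified medication" /
"Drug ineffective") instead of a redraw — this keeps every configured
marginal and injected relative risk exact, which the calibration
properties test (goodness-of-fit on demographic marginals; empirical RR
within 10 % of the configured value at expected cell counts ≥ 200).
Generation is a pure function of (config, seed) through one seeded
numpy generator consumed in a fixed order, so identical inputs give
byte-identical line listings; this single-stream design was chosen over
per-report substreams because the fully vectorised sampler makes
substreams unnecessary for reproducibility.

Alongside the database, a ledger records the model-implied expected count
for every injected pair, realised co-report counts, and co-report counts
per co-medication index drug — an independent oracle for recovery and
concomitant-eligibility tests.

`tramadol_study_preset` is a reduced-scale analogue of the study
database: 100,000 reports by default; sex, age-band, reporter, region and
year marginals equal to the published stratum proportions of the tramadol
series (the published consumer-reporter count is corrected to match its
own percentage and column total, and seriousness is a free marginal —
40 % true / 50 % false / 10 % unknown — because the published seriousness
percentage is not internally consistent); tramadol on ~0.6 % of reports
and the combination product on ~0.22 %, their shares of the source
database. The five full-database ACRD signal terms carry injected RRs of
3–9 for tramadol with a 3× extra boost under 18; bradypnoea alone is
injected for the combination product; abuse-related terms are injected
for tramadol; comparator opioids (full agonists) carry ACRD RRs of 8–12
so that the opioid-scope analysis yields no tramadol signal, mirroring
the weak-agonist pharmacology; and co-medication rules in the few-percent
range create the four concomitant drug-class structures. ACRD event base
rates are set in the 10⁻⁴–10⁻³ range so that injected pairs reach
detectable counts at the reduced scale; they are deliberately larger than
the source database's per-term shares, which would need millions of
reports to exercise the signal rule.

What the generator does *not* emulate: duplicate reports,
reporting-delay dynamics, within-report event correlation beyond the
injections, patient-level linkage, and drug–demographic dependence beyond
the configured conditionals. Passing tests therefore demonstrate that
the counting and statistics are correct and calibrated under the stated
generative model — not that the pipeline is robust to duplication or
coding noise in real extracts.

## Numerical and design choices

* 95 % intervals use z = 1.959963984540054; computation is full
  precision, display rounds half-up (two decimals for ratios, one for
  percentages; p-values floored at "<0.0001").
* Chi-square uses `scipy.stats.chi2_contingency(correction=False)`; the
  test suite pins it against an explicit Σ(O−E)²/E computation.
* "More than 20 cases" for concomitant eligibility is a strict
  inequality. A drug listed under several roles counts once if any role
  qualifies.
* Degenerate inputs: an empty drug row makes PRR/ROR a hard error; a
  factor with fewer than two non-empty categories is an error; a factor
  table whose case row is all zeros is reported without a test statistic.
* Problem sizes in the test-suite calibration runs (20 synthetic
  databases of 1,500–10,000 reports; 200 null tables of n = 2,000; five
  50,000-report runs for marginal goodness-of-fit) were chosen to give
  the stochastic assertions comfortable power while keeping the default
  suite fast.

## Known limitations

Disproportionality is hypothesis generation, not causal inference: no
shrinkage (EBGM/MGPS), no duplicate adjustment, no masking correction,
and no multivariable modelling of the factors (the factor battery is
univariate by design). ATC scoping misses uncoded drug entries. The
abuse flag requires same-report co-reporting. Dose, formulation and
genotype are outside the data model entirely.
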