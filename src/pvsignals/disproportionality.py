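"""2x2 contingency tables and disproportionality statistics.

For a drug of interest and an event definition (one preferred term or a
pooled SMQ), reports are cross-classified as

===================  ============  =============
\\                    event         no event
===================  ============  =============
drug of interest     A             B
comparator           C             D
===================  ============  =============

where the drug's reports are those listing it as suspected or interacting
and the comparator is every other in-scope report (the full database, or
reports carrying an opioid by ATC code).  Three classical indices are
computed on the table:

* proportional reporting ratio  PRR = [A/(A+B)] / [C/(C+D)]
* reporting odds ratio          ROR = (A/B) / (C/D)
* information component         IC  = log2 (N_obs + 0.5)/(N_exp + 0.5),
  with N_exp = N_drug * N_effect / N_total.

The composite signal rule requires at least ``min_reports`` co-reports,
PRR >= 2, ROR >= 2 and a lower 95% IC credibility bound >= 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from scipy import stats

from pvsignals.icsr import Database, _canon
from pvsignals.terminology import SMQDefinition, is_opioid_report

logger = logging.getLogger(__name__)

SCOPES = ("full_database", "opioids")

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class Estimate(NamedTuple):
    """A point estimate with a 95% confidence interval (NaN when undefined)."""

    value: float
    ci_low: float
    ci_high: float


class ICEstimate(NamedTuple):
    """Information component (bits) and its lower 95% credibility bound."""

    ic: float
    ic025: float


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-event pair within a comparator scope."""

    a: int
    b: int
    c: int
    d: int
    scope: str = "full_database"
    drug: str = ""
    event: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be >= 0")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_effect(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_expected(self) -> float:
        if self.n_total == 0:
            return 0.0
        return self.n_drug * self.n_effect / self.n_total


@dataclass(frozen=True)
class SignalCriteria:
    """Composite positive-signal thresholds (all must hold)."""

    min_reports: int = 3
    prr_min: float = 2.0
    ror_min: float = 2.0
    ic025_min: float = 0.0

    def __post_init__(self) -> None:
        if self.min_reports < 0 or self.prr_min < 0 or self.ror_min < 0:
            raise ValueError("criteria thresholds must be >= 0")


@dataclass(frozen=True)
class DisproportionalityResult:
    table: ContingencyTable
    prr: Estimate
    ror: Estimate
    ic: float
    ic025: float
    signal: bool

    @property
    def n_observed(self) -> int:
        return self.table.a

    @property
    def n_expected(self) -> float:
        return self.table.n_expected


def build_table(
    db: Database,
    drug: str,
    event_terms: Iterable[str] | SMQDefinition,
    scope: str = "full_database",
    exclude_index_from_comparator: bool = True,
) -> ContingencyTable:
    """Cross-classify reports for one drug against an event-term set.

    The drug's own reports (rows A+B) are those listing it as suspected or
    interacting.  Under ``scope="opioids"`` the comparator (C+D) is
    restricted to reports carrying a drug with ATC code N02A*/N01AH*; by
    default the index drug itself does not qualify a report for the
    comparator (standard practice, so the comparator is "other opioids").
    Event presence means at least one report PT in ``event_terms``; a
    report with several matching PTs still counts once.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if isinstance(event_terms, SMQDefinition):
        term_keys = event_terms.term_keys
        event_label = event_terms.name
    else:
        terms = tuple(event_terms)
        if not terms:
            raise ValueError("event_terms must be non-empty")
        term_keys = frozenset(_canon(t) for t in terms)
        event_label = terms[0] if len(terms) == 1 else f"{len(terms)} terms"
    index_roles = frozenset(("suspected", "interacting"))
    exclude = drug if exclude_index_from_comparator else None
    a = b = c = d = 0
    for report in db:
        has_event = not report.pt_keys().isdisjoint(term_keys)
        if report.has_drug(drug, index_roles):
            if has_event:
                a += 1
            else:
                b += 1
        else:
            if scope == "opioids" and not is_opioid_report(report, exclude_drug=exclude):
                continue
            if has_event:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d, scope=scope, drug=drug, event=event_label)


def prr(t: ContingencyTable) -> Estimate:
    """Proportional reporting ratio with a log-scale Wald 95% CI.

    Undefined (NaN) when the comparator has no event reports (C = 0); an
    empty drug row (A + B = 0) is a hard error because the drug's reporting
    proportion does not exist.
    """
    if t.n_drug == 0:
        raise ValueError("PRR undefined: no reports for the drug (a+b=0)")
    if t.c == 0 or t.c + t.d == 0:
        return Estimate(math.nan, math.nan, math.nan)
    est = (t.a / t.n_drug) / (t.c / (t.c + t.d))
    if t.a == 0:
        return Estimate(0.0, math.nan, math.nan)
    se = math.sqrt(1 / t.a - 1 / t.n_drug + 1 / t.c - 1 / (t.c + t.d))
    log_est = math.log(est)
    return Estimate(est, math.exp(log_est - _Z95 * se), math.exp(log_est + _Z95 * se))


def ror(t: ContingencyTable) -> Estimate:
    """Reporting odds ratio with a log-scale Wald 95% CI.

    When any cell is zero the CI uses the Haldane-Anscombe +0.5 correction
    on all four cells; the point estimate is reported as NaN when B, C or D
    is zero (the odds ratio is then infinite or indeterminate).
    """
    if t.n_drug == 0:
        raise ValueError("ROR undefined: no reports for the drug (a+b=0)")
    if t.b * t.c * t.d == 0:
        est = 0.0 if (t.a == 0 and t.b > 0 and t.c > 0) else math.nan
    else:
        est = (t.a / t.b) / (t.c / t.d)
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = map(float, cells)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_ci_centre = math.log((aa / bb) / (cc / dd))
    return Estimate(
        est,
        math.exp(log_ci_centre - _Z95 * se),
        math.exp(log_ci_centre + _Z95 * se),
    )


def ic(t: ContingencyTable, method: str = "noren") -> ICEstimate:
    """Information component (bits) and its lower 95% credibility bound.

    The +0.5 offsets keep the IC finite for every table including A = 0.
    ``method="noren"`` uses the closed-form approximation of the lower
    bound, IC - 3.3 (A+0.5)^(-1/2) - 2.0 (A+0.5)^(-3/2); ``method="gamma"``
    uses the 2.5% quantile of the Gamma(A+0.5, rate = N_exp+0.5) posterior
    on the observed-to-expected ratio.
    """
    value = math.log2((t.a + 0.5) / (t.n_expected + 0.5))
    if method == "noren":
        shift = 3.3 * (t.a + 0.5) ** -0.5 + 2.0 * (t.a + 0.5) ** -1.5
        lower = value - shift
    elif method == "gamma":
        q = stats.gamma.ppf(0.025, t.a + 0.5, scale=1.0 / (t.n_expected + 0.5))
        lower = math.log2(q) if q > 0 else -math.inf
    else:
        raise ValueError(f"unknown IC interval method {method!r}")
    return ICEstimate(value, lower)


def evaluate_table(
    t: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    ic_method: str = "noren",
) -> DisproportionalityResult:
    """Compute all three indices on one table and apply the signal rule.

    The composite verdict is a conjunction: a pair with fewer than
    ``min_reports`` co-reports is reported but can never be a signal, and a
    missing PRR or ROR fails its criterion.
    """
    prr_est = prr(t)
    ror_est = ror(t)
    ic_est = ic(t, method=ic_method)
    signal = (
        t.a >= criteria.min_reports
        and math.isfinite(prr_est.value)
        and prr_est.value >= criteria.prr_min
        and math.isfinite(ror_est.value)
        and ror_est.value >= criteria.ror_min
        and ic_est.ic025 >= criteria.ic025_min
    )
    return DisproportionalityResult(
        table=t, prr=prr_est, ror=ror_est, ic=ic_est.ic, ic025=ic_est.ic025, signal=signal
    )


def detect_signals(
    db: Database,
    drug: str,
    terms: Iterable[str] | SMQDefinition,
    scope: str = "full_database",
    criteria: SignalCriteria = SignalCriteria(),
    include_smq_aggregate: bool = False,
    ic_method: str = "noren",
) -> list[DisproportionalityResult]:
    """One disproportionality result per preferred term, most-reported first.

    With ``include_smq_aggregate`` a pooled table over the whole term set is
    appended; the pooled table deduplicates reports, so its A cell is at
    most the sum of the per-term A cells.
    """
    term_list = tuple(terms.terms) if isinstance(terms, SMQDefinition) else tuple(terms)
    tables = _per_term_tables(db, drug, term_list, scope, include_smq_aggregate)
    pooled = tables.pop() if include_smq_aggregate else None
    results = [evaluate_table(t, criteria, ic_method=ic_method) for t in tables]
    results.sort(key=lambda r: (-r.table.a, r.table.event))
    if pooled is not None:
        if isinstance(terms, SMQDefinition):
            pooled = ContingencyTable(
                pooled.a, pooled.b, pooled.c, pooled.d,
                scope=scope, drug=drug, event=terms.name,
            )
        results.append(evaluate_table(pooled, criteria, ic_method=ic_method))
    return results


def _per_term_tables(
    db: Database,
    drug: str,
    term_list: tuple[str, ...],
    scope: str,
    with_pooled: bool,
) -> list[ContingencyTable]:
    """All per-term tables (plus optionally the pooled one) in one pass.

    Equivalent to calling :func:`build_table` per term, but scans the
    database once; the per-pair brute-force tests pin the equivalence.
    """
    keys = [_canon(t) for t in term_list]
    key_index = {k: i for i, k in enumerate(keys)}
    all_keys = frozenset(keys)
    index_roles = frozenset(("suspected", "interacting"))
    n_terms = len(term_list)
    a = [0] * n_terms
    c = [0] * n_terms
    pooled_a = pooled_c = 0
    n_drug = n_comp = 0
    for report in db:
        in_drug = report.has_drug(drug, index_roles)
        if not in_drug and scope == "opioids" and not is_opioid_report(report, exclude_drug=drug):
            continue
        present = report.pt_keys() & all_keys
        if in_drug:
            n_drug += 1
            for key in present:
                a[key_index[key]] += 1
            pooled_a += bool(present)
        else:
            n_comp += 1
            for key in present:
                c[key_index[key]] += 1
            pooled_c += bool(present)
    tables = [
        ContingencyTable(
            a[i], n_drug - a[i], c[i], n_comp - c[i],
            scope=scope, drug=drug, event=term_list[i],
        )
        for i in range(n_terms)
    ]
    if with_pooled:
        tables.append(
            ContingencyTable(
                pooled_a, n_drug - pooled_a, pooled_c, n_comp - pooled_c,
                scope=scope, drug=drug, event=f"{n_terms} terms",
            )
        )
    return tables


def stratified_signals(
    db: Database,
    drug: str,
    terms: Iterable[str] | SMQDefinition,
    age_groups: Iterable[str],
    scope: str = "full_database",
    criteria: SignalCriteria = SignalCriteria(),
    **kwargs,
) -> list[DisproportionalityResult]:
    """Run signal detection on the sub-database of an age stratum.

    Reports with unknown age are never part of a stratum.  An empty stratum
    yields an empty result list (with a logged warning) rather than an error.
    """
    wanted = frozenset(age_groups) - {"unknown"}
    sub = Database(tuple(r for r in db if r.age_group in wanted))
    if sub.n_total == 0:
        logger.warning(
            "age stratum %s contains no reports; no signals computed", sorted(wanted)
        )
        return []
    return detect_signals(sub, drug, terms, scope=scope, criteria=criteria, **kwargs)


def reconstruct_table(
    n_reports: int,
    printed_prr: float,
    n_drug: int,
    n_total: int,
    drug: str = "",
    event: str = "",
) -> ContingencyTable:
    """Back-solve a full-database 2x2 table from published (n, PRR) values.

    Published disproportionality tables print the drug-event report count
    and the PRR but not the comparator cells; given the drug's total report
    count and the database size, the comparator event count C is recovered
    from the PRR formula, C = [(A/(A+B)) / PRR] * (C+D), rounded to the
    nearest report.
    """
    if printed_prr <= 0:
        raise ValueError("printed PRR must be positive")
    comparator = n_total - n_drug
    c = round((n_reports / n_drug) / printed_prr * comparator)
    return ContingencyTable(
        a=n_reports,
        b=n_drug - n_reports,
        c=c,
        d=comparator - c,
        scope="full_database",
        drug=drug,
        event=event,
    )
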