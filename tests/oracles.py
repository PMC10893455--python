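"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, with plain loops over
report fields, deliberately avoiding the package's counting helpers so
that agreement is meaningful.
"""

from __future__ import annotations


def _canon(s: str) -> str:
    return " ".join(s.split()).casefold()


def report_has_drug(report, drug_name, roles) -> bool:
    key = _canon(drug_name)
    return any(_canon(d.drug_name) == key and d.role in roles for d in report.drugs)


def report_has_opioid(report, exclude=None) -> bool:
    ex = _canon(exclude) if exclude else None
    for d in report.drugs:
        if ex is not None and _canon(d.drug_name) == ex:
            continue
        code = d.atc_code.upper()
        if code.startswith("N02A") or code.startswith("N01AH"):
            return True
    return False


def report_has_any_term(report, terms) -> bool:
    keys = {_canon(t) for t in terms}
    return any(_canon(e.pt) in keys for e in report.events)


def contingency_cells(db, drug, terms, scope="full_database", exclude_index=True):
    """A/B/C/D by nested per-report scans."""
    si = ("suspected", "interacting")
    a = b = c = d = 0
    for report in db:
        has_event = report_has_any_term(report, terms)
        if report_has_drug(report, drug, si):
            if has_event:
                a += 1
            else:
                b += 1
        else:
            if scope == "opioids" and not report_has_opioid(
                report, exclude=drug if exclude_index else None
            ):
                continue
            if has_event:
                c += 1
            else:
                d += 1
    return a, b, c, d


def case_count(db, terms) -> int:
    return sum(1 for report in db if report_has_any_term(report, terms))


def pearson_chi2(counts) -> float:
    """Sum of (O-E)^2/E with explicit margin arithmetic."""
    rows = len(counts)
    cols = len(counts[0])
    row_sums = [sum(counts[i]) for i in range(rows)]
    col_sums = [sum(counts[i][j] for i in range(rows)) for j in range(cols)]
    total = sum(row_sums)
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (counts[i][j] - expected) ** 2 / expected
    return stat
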