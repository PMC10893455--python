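"""Cross-tabulation of case status against candidate risk cofactors.

Within the index drug's reports, ACRD cases (reports carrying at least one
SMQ term) are compared with non-cases on demographics (sex, collapsed age,
region, reporter), concomitant drug-class exposure, abuse co-reporting and
death.  Each factor yields a 2xk table tested with Pearson's chi-square;
for k >= 3 categories a post-hoc pass flags the categories driving the
association using adjusted standardised residuals with a Bonferroni
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np
from scipy import stats

from pvsignals.icsr import Database
from pvsignals.terminology import DrugClassList, SMQDefinition, is_case, is_class_user

#: Collapse of the reporting age bands used for factor analysis.
AGE3_MAP = {
    "le11": "le17",
    "a12_17": "le17",
    "a18_44": "a18_64",
    "a45_64": "a18_64",
    "a65_74": "ge65",
    "ge75": "ge65",
}
AGE3_ORDER = ("le17", "a18_64", "ge65")


class DegenerateTableError(ValueError):
    """Raised when a factor table cannot support a chi-square test."""


@dataclass(frozen=True)
class DemographicFactor:
    """A demographic factor: one of sex, age3, region, reporter.

    Reports with the unknown token are excluded (and counted) before
    testing; ``age3`` collapses the reporting bands to <=17 / 18-64 / >=65.
    """

    field_name: str

    def __post_init__(self) -> None:
        if self.field_name not in ("sex", "age3", "region", "reporter"):
            raise ValueError(f"unsupported demographic factor {self.field_name!r}")


@dataclass(frozen=True)
class ClassUserFactor:
    """Concomitant use of any member of a drug class (vs none)."""

    drug_class: DrugClassList


@dataclass(frozen=True)
class AbuseFactor:
    """Co-reporting of an abuse/dependence SMQ term on the same report."""

    smq: SMQDefinition


@dataclass(frozen=True)
class DeathFactor:
    """Fatal outcome of the report."""


FactorSpec = Union[DemographicFactor, ClassUserFactor, AbuseFactor, DeathFactor]


class PosthocCell(NamedTuple):
    category: str
    residual: float  # adjusted standardised residual, case row (+ = over-represented in cases)
    significant: bool


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int
    p_value: float


@dataclass
class FactorTable:
    """2xk cross-tabulation of case status against one factor.

    ``counts[0]`` is the case row, ``counts[1]`` the non-case row, in the
    order of ``categories``.  ``posthoc`` is None for k < 3 (not
    applicable) and otherwise holds one flag per category.
    """

    factor_name: str
    categories: tuple[str, ...]
    counts: np.ndarray
    excluded_unknown: int = 0
    chi2: float = math.nan
    df: int = 0
    p_value: float = math.nan
    posthoc: list[PosthocCell] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, len(self.categories)):
            raise ValueError("counts must be a 2 x k matrix matching categories")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def n_cases(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_noncases(self) -> int:
        return int(self.counts[1].sum())


def _category_of(report, factor: FactorSpec, index_drug: str) -> str | None:
    """Category label for one report, or None to exclude it."""
    if isinstance(factor, DemographicFactor):
        if factor.field_name == "age3":
            return AGE3_MAP.get(report.age_group)
        value = getattr(report, factor.field_name)
        return None if value == "unknown" else value
    if isinstance(factor, ClassUserFactor):
        return "user" if is_class_user(report, factor.drug_class, index_drug) else "non_user"
    if isinstance(factor, AbuseFactor):
        return "abuser" if is_case(report, factor.smq) else "non_abuser"
    if isinstance(factor, DeathFactor):
        return "death" if report.death else "survival"
    raise TypeError(f"unknown factor spec {factor!r}")


def _factor_name(factor: FactorSpec) -> str:
    if isinstance(factor, DemographicFactor):
        return factor.field_name
    if isinstance(factor, ClassUserFactor):
        return factor.drug_class.class_name
    if isinstance(factor, AbuseFactor):
        return "abuse"
    return "death"


def _category_order(factor: FactorSpec, seen: list[str]) -> tuple[str, ...]:
    fixed = {
        "age3": AGE3_ORDER,
        "sex": ("male", "female"),
        "region": ("americas", "europe", "asia", "oceania", "africa"),
        "reporter": ("physician", "pharmacist", "other_hcp", "consumer", "lawyer"),
    }
    if isinstance(factor, DemographicFactor):
        order = fixed[factor.field_name]
        return tuple(c for c in order if c in seen)
    if isinstance(factor, ClassUserFactor):
        return tuple(c for c in ("user", "non_user") if c in seen)
    if isinstance(factor, AbuseFactor):
        return tuple(c for c in ("abuser", "non_abuser") if c in seen)
    return tuple(c for c in ("death", "survival") if c in seen)


def build_factor_table(
    db: Database,
    index_drug: str,
    smq: SMQDefinition,
    factor: FactorSpec,
    run_tests: bool = True,
) -> FactorTable:
    """Cross-tabulate ACRD status against one factor for the index drug.

    Only reports listing the index drug as suspected or interacting enter
    the table; unknown demographic categories are excluded (their count is
    kept in ``excluded_unknown``).  The chi-square test and, for k >= 3,
    the post-hoc residual pass are run unless ``run_tests`` is False.
    """
    seen: list[str] = []
    tallies: dict[str, list[int]] = {}
    excluded = 0
    for report in db:
        if not report.has_drug(index_drug, ("suspected", "interacting")):
            continue
        category = _category_of(report, factor, index_drug)
        if category is None:
            excluded += 1
            continue
        if category not in tallies:
            tallies[category] = [0, 0]
            seen.append(category)
        tallies[category][0 if is_case(report, smq) else 1] += 1
    categories = _category_order(factor, seen)
    nonempty = [c for c in categories if sum(tallies[c]) > 0]
    if len(nonempty) < 2:
        raise DegenerateTableError(
            f"factor {_factor_name(factor)!r} has fewer than 2 non-empty categories"
        )
    counts = np.array([[tallies[c][0] for c in nonempty], [tallies[c][1] for c in nonempty]])
    table = FactorTable(
        factor_name=_factor_name(factor),
        categories=tuple(nonempty),
        counts=counts,
        excluded_unknown=excluded,
    )
    if run_tests:
        try:
            table.chi2, table.df, table.p_value = chi_square(table)
            if len(table.categories) >= 3:
                table.posthoc = posthoc(table)
        except DegenerateTableError as exc:
            # e.g. no cases at all among the index drug's reports: the table
            # is still reportable, but no test statistic exists
            import logging

            logging.getLogger(__name__).warning(
                "chi-square unavailable for factor %s: %s", table.factor_name, exc
            )
    return table


def chi_square(t: FactorTable) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    Expected counts come from the row/column margins; a zero margin (hence
    a zero expected cell) is a degenerate table and a hard error.
    """
    counts = t.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise DegenerateTableError("zero expected cell")
    return ChiSquareResult(float(chi2), int(df), float(p))


def posthoc(t: FactorTable, alpha: float = 0.05) -> list[PosthocCell]:
    """Adjusted standardised Pearson residuals with Bonferroni correction.

    Each cell residual (O-E)/sqrt(E (1 - row/n)(1 - col/n)) is an
    approximate standard normal under independence; categories are flagged
    two-sided at level alpha divided by the 2k cells of the table.  In a
    2xk table the two residuals of a column have equal magnitude and
    opposite sign, so one flag per category (case-row sign) suffices.
    """
    counts = t.counts.astype(float)
    n = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    if (expected <= 0).any():
        raise DegenerateTableError("zero expected cell")
    denom = np.sqrt(expected * (1 - rows / n) * (1 - cols / n))
    residuals = (counts - expected) / denom
    n_cells = counts.size
    threshold = stats.norm.isf((alpha / n_cells) / 2)
    return [
        PosthocCell(cat, float(residuals[0, j]), bool(abs(residuals[0, j]) > threshold))
        for j, cat in enumerate(t.categories)
    ]


@dataclass(frozen=True)
class FactorSummary:
    """Per-category proportions and case/non-case proportion ratios.

    Proportions use the case and non-case totals of the table as
    denominators.  For 2-level factors the odds ratio of the first category
    (with a log-scale Wald 95% CI) is also reported.
    """

    factor_name: str
    categories: tuple[str, ...]
    proportion_case: tuple[float, ...]
    proportion_noncase: tuple[float, ...]
    proportion_ratio: tuple[float, ...]
    odds_ratio: float | None = None
    odds_ratio_ci: tuple[float, float] | None = None


def summarize_factor(t: FactorTable) -> FactorSummary:
    n_case = t.n_cases
    n_non = t.n_noncases
    p_case = tuple(t.counts[0, j] / n_case if n_case else math.nan for j in range(len(t.categories)))
    p_non = tuple(t.counts[1, j] / n_non if n_non else math.nan for j in range(len(t.categories)))
    ratios = tuple(
        pc / pn if pn and not math.isnan(pn) else math.nan for pc, pn in zip(p_case, p_non)
    )
    odds_ratio = None
    odds_ci = None
    if len(t.categories) == 2:
        a, b = (float(x) for x in t.counts[0])
        c, d = (float(x) for x in t.counts[1])
        if b * c * d > 0 and a > 0:
            odds_ratio = (a / b) / (c / d)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            odds_ci = (
                math.exp(math.log(odds_ratio) - 1.959963984540054 * se),
                math.exp(math.log(odds_ratio) + 1.959963984540054 * se),
            )
    return FactorSummary(
        factor_name=t.factor_name,
        categories=t.categories,
        proportion_case=p_case,
        proportion_noncase=p_non,
        proportion_ratio=ratios,
        odds_ratio=odds_ratio,
        odds_ratio_ci=odds_ci,
    )
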