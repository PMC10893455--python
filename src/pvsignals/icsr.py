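"""Domain types for individual case safety reports and line-listing I/O.

The on-disk format is a long-grain UTF-8 TSV with one row per
report-drug-event triple, the natural shape of a spontaneous-report
extract.  Reading merges rows that share a ``report_id`` into a single
:class:`ICSRReport`; demographics must agree across the merged rows.
The unit of counting everywhere downstream is the report, never the row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

ROLES = ("suspected", "interacting", "concomitant")
SEXES = ("male", "female", "unknown")
AGE_GROUPS = ("le11", "a12_17", "a18_44", "a45_64", "a65_74", "ge75", "unknown")
REGIONS = ("americas", "europe", "asia", "oceania", "africa", "unknown")
REPORTERS = ("consumer", "physician", "other_hcp", "pharmacist", "lawyer", "unknown")
SERIOUS_TOKENS = ("true", "false", "unknown")

#: Column order of the line-listing TSV.
COLUMNS = (
    "report_id",
    "sex",
    "age_group",
    "region",
    "reporter",
    "year",
    "serious",
    "death",
    "drug_name",
    "atc_code",
    "role",
    "pt",
)


class LineListingError(ValueError):
    """Raised for malformed line-listing files (bad header, enum, conflict)."""


def _canon(s: str) -> str:
    """Whitespace-normalised, case-folded canonical form for matching."""
    return " ".join(s.split()).casefold()


@dataclass(frozen=True, order=True)
class DrugEntry:
    """One drug on a report, with its reporter-assigned causality role."""

    drug_name: str
    atc_code: str = ""
    role: str = "suspected"

    def __post_init__(self) -> None:
        if not self.drug_name.strip():
            raise ValueError("drug_name must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def name_key(self) -> str:
        return _canon(self.drug_name)


@dataclass(frozen=True, order=True)
class EventEntry:
    """One adverse event on a report, coded as a MedDRA preferred term."""

    pt: str

    def __post_init__(self) -> None:
        normalised = " ".join(self.pt.split())
        if not normalised:
            raise ValueError("pt must be non-empty after whitespace normalisation")
        object.__setattr__(self, "pt", normalised)

    @property
    def pt_key(self) -> str:
        return self.pt.casefold()


@dataclass
class ICSRReport:
    """One individual case safety report.

    ``serious`` is a three-valued token ("true"/"false"/"unknown") because
    seriousness is frequently unreported; ``death`` is a hard outcome flag
    and is only permitted when the report is serious or of unknown
    seriousness (death is itself a seriousness criterion).
    """

    report_id: str
    sex: str = "unknown"
    age_group: str = "unknown"
    region: str = "unknown"
    reporter: str = "unknown"
    year: int | None = None
    serious: str = "unknown"
    death: bool = False
    drugs: tuple[DrugEntry, ...] = ()
    events: tuple[EventEntry, ...] = ()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"invalid age_group {self.age_group!r}")
        if self.region not in REGIONS:
            raise ValueError(f"invalid region {self.region!r}")
        if self.reporter not in REPORTERS:
            raise ValueError(f"invalid reporter {self.reporter!r}")
        if self.serious not in SERIOUS_TOKENS:
            raise ValueError(f"invalid serious token {self.serious!r}")
        if self.death and self.serious == "false":
            raise ValueError(
                f"report {self.report_id}: death=true requires serious true or unknown"
            )
        self.drugs = tuple(self.drugs)
        self.events = tuple(self.events)
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: at least one drug required")
        if not self.events:
            raise ValueError(f"report {self.report_id}: at least one event required")

    # Entry order carries no meaning; compare as sets.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ICSRReport):
            return NotImplemented
        return (
            self.report_id == other.report_id
            and self.sex == other.sex
            and self.age_group == other.age_group
            and self.region == other.region
            and self.reporter == other.reporter
            and self.year == other.year
            and self.serious == other.serious
            and self.death == other.death
            and frozenset(self.drugs) == frozenset(other.drugs)
            and frozenset(self.events) == frozenset(other.events)
        )

    def has_drug(self, drug_name: str, roles: Iterable[str] = ROLES) -> bool:
        """True if the report lists ``drug_name`` under any of ``roles``."""
        role_map = self._drug_roles()
        found = role_map.get(_canon(drug_name))
        return bool(found) and not found.isdisjoint(roles)

    # Entries are treated as immutable after construction, so the derived
    # lookup structures are computed once per report.
    def _drug_roles(self) -> dict[str, set[str]]:
        cache = self.__dict__.get("_drug_roles_cache")
        if cache is None:
            cache = {}
            for d in self.drugs:
                cache.setdefault(d.name_key, set()).add(d.role)
            self.__dict__["_drug_roles_cache"] = cache
        return cache

    def pt_keys(self) -> frozenset[str]:
        cache = self.__dict__.get("_pt_keys_cache")
        if cache is None:
            cache = frozenset(e.pt_key for e in self.events)
            self.__dict__["_pt_keys_cache"] = cache
        return cache


@dataclass
class Database:
    """A collection of reports with unique report identifiers."""

    reports: tuple[ICSRReport, ...] = ()

    def __post_init__(self) -> None:
        self.reports = tuple(self.reports)
        ids = [r.report_id for r in self.reports]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate report_id {dup!r}")

    @property
    def n_total(self) -> int:
        return len(self.reports)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Database):
            return NotImplemented
        mine = {r.report_id: r for r in self.reports}
        theirs = {r.report_id: r for r in other.reports}
        return mine == theirs


def _parse_row(row: dict[str, str], lineno: int) -> tuple[dict, DrugEntry, EventEntry]:
    def bad(msg: str) -> LineListingError:
        return LineListingError(f"line {lineno}: {msg}")

    for col, allowed in (
        ("sex", SEXES),
        ("age_group", AGE_GROUPS),
        ("region", REGIONS),
        ("reporter", REPORTERS),
        ("serious", SERIOUS_TOKENS),
        ("role", ROLES),
    ):
        if row[col] not in allowed:
            raise bad(f"unknown {col} token {row[col]!r}")
    if row["death"] not in ("true", "false"):
        raise bad(f"unknown death token {row['death']!r}")
    year_tok = row["year"]
    if year_tok == "NA":
        year: int | None = None
    else:
        try:
            year = int(year_tok)
        except ValueError:
            raise bad(f"unparseable year {year_tok!r}") from None
    demo = dict(
        report_id=row["report_id"],
        sex=row["sex"],
        age_group=row["age_group"],
        region=row["region"],
        reporter=row["reporter"],
        year=year,
        serious=row["serious"],
        death=row["death"] == "true",
    )
    try:
        drug = DrugEntry(row["drug_name"], row["atc_code"], row["role"])
        event = EventEntry(row["pt"])
    except ValueError as exc:
        raise bad(str(exc)) from None
    return demo, drug, event


def read_line_listing(path: str | Path) -> Database:
    """Read a long-grain TSV line listing and merge rows to report grain.

    Rows sharing a ``report_id`` are merged into one report holding the
    union of drug and event entries; demographics that disagree between
    rows of one report are a hard error naming the report_id.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(frame.columns) != COLUMNS:
        raise LineListingError(
            f"bad header: expected {list(COLUMNS)}, got {list(frame.columns)}"
        )
    demo_by_id: dict[str, dict] = {}
    drugs_by_id: dict[str, set[DrugEntry]] = {}
    events_by_id: dict[str, set[EventEntry]] = {}
    order: list[str] = []
    for i, row in enumerate(frame.to_dict("records")):
        demo, drug, event = _parse_row(row, i + 2)  # +2: header is line 1
        rid = demo["report_id"]
        if rid not in demo_by_id:
            demo_by_id[rid] = demo
            drugs_by_id[rid] = set()
            events_by_id[rid] = set()
            order.append(rid)
        elif demo_by_id[rid] != demo:
            raise LineListingError(
                f"conflicting demographics for report_id {rid!r}"
            )
        drugs_by_id[rid].add(drug)
        events_by_id[rid].add(event)
    reports = [
        ICSRReport(
            drugs=tuple(sorted(drugs_by_id[rid])),
            events=tuple(sorted(events_by_id[rid])),
            **demo_by_id[rid],
        )
        for rid in sorted(order)
    ]
    return Database(tuple(reports))


def write_line_listing(db: Database, path: str | Path) -> None:
    """Write ``db`` as a long-grain TSV; one row per drug x event pair.

    Rows are sorted by (report_id, drug_name, atc, role, pt) so identical
    databases always serialise to identical bytes.
    """
    buf = io.StringIO()
    buf.write("\t".join(COLUMNS) + "\n")
    for report in sorted(db.reports, key=lambda r: r.report_id):
        year_tok = "NA" if report.year is None else str(report.year)
        for drug in sorted(report.drugs):
            for event in sorted(report.events):
                buf.write(
                    "\t".join(
                        (
                            report.report_id,
                            report.sex,
                            report.age_group,
                            report.region,
                            report.reporter,
                            year_tok,
                            report.serious,
                            "true" if report.death else "false",
                            drug.drug_name,
                            drug.atc_code,
                            drug.role,
                            event.pt,
                        )
                    )
                    + "\n"
                )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def filter_reports(
    db: Database, drug_name: str, roles: Iterable[str] = ("suspected", "interacting")
) -> Database:
    """Reports containing ``drug_name`` under any role in ``roles``.

    A report counts once however many matching drug entries it carries.
    """
    roleset = frozenset(roles)
    if not roleset:
        raise ValueError("roles must be non-empty")
    unknown = roleset - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles {sorted(unknown)}")
    return Database(tuple(r for r in db if r.has_drug(drug_name, roleset)))
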