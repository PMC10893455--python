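"""SMQ term sets, ATC-based drug scoping and drug-class membership.

Case flags (acute central respiratory depression, drug abuse), opioid
comparator membership and concomitant drug-class exposure are all decided
here so that the counting modules never touch raw vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from pvsignals.icsr import Database, ICSRReport, _canon

#: Narrow-scope preferred terms of the "Acute central respiratory
#: depression" Standardised MedDRA Query (19 terms).
ACRD_NARROW_TERMS: tuple[str, ...] = (
    "Acute respiratory distress syndrome",
    "Acute respiratory failure",
    "Apnoea",
    "Apnoeic attack",
    "Apparent life threatening event",
    "Bradypnoea",
    "Breath holding",
    "Breath sounds abnormal",
    "Hypopnoea",
    "Hypoventilation",
    "Infantile apnoea",
    "Neonatal respiratory arrest",
    "Neonatal respiratory depression",
    "Respiratory arrest",
    "Respiratory depression",
    "Respiratory depth decreased",
    "Respiratory failure",
    "Respiratory paralysis",
    "Respiratory rate decreased",
)

#: ATC prefixes defining the opioid comparator scope: opioid analgesics
#: (N02A) and opioid anaesthetics (N01AH).
OPIOID_ATC_PREFIXES = ("N02A", "N01AH")

DRUG_CLASS_NAMES = ("cyp2d6_inhibitors", "opioids", "benzodiazepines", "antidepressants")


@dataclass(frozen=True)
class SMQDefinition:
    """A named, validated set of MedDRA preferred terms.

    Membership tests are case-insensitive and whitespace-normalised.
    """

    name: str
    scope: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scope not in ("narrow", "broad"):
            raise ValueError(f"scope must be narrow or broad, got {self.scope!r}")
        if not self.terms:
            raise ValueError("terms must be non-empty")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def term_keys(self) -> frozenset[str]:
        return frozenset(_canon(t) for t in self.terms)

    def __contains__(self, pt: str) -> bool:
        return _canon(pt) in self.term_keys

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class DrugClassList:
    """A named set of drug names used as a concomitant-exposure factor."""

    class_name: str
    members: tuple[str, ...]

    @property
    def member_keys(self) -> frozenset[str]:
        return frozenset(_canon(m) for m in self.members)

    def __contains__(self, drug_name: str) -> bool:
        return _canon(drug_name) in self.member_keys


def builtin_acrd_smq() -> SMQDefinition:
    """The built-in narrow-scope acute central respiratory depression SMQ."""
    return SMQDefinition("acute_central_respiratory_depression", "narrow", ACRD_NARROW_TERMS)


def default_abuse_smq() -> SMQDefinition:
    """A default "drug abuse and dependence" term set.

    MedDRA SMQ contents are licensed, so this ships a documented default
    covering the common abuse/dependence/overdose preferred terms; replace
    it with a licensed term file via :func:`load_smq` for production use.
    """
    with resources.files("pvsignals.data").joinpath("abuse_smq_default.txt").open(
        "r", encoding="utf-8"
    ) as fh:
        terms = _read_term_lines(fh)
    return SMQDefinition("drug_abuse_and_dependence", "narrow", tuple(terms))


def _read_term_lines(fh: Iterable[str]) -> list[str]:
    terms = []
    for line in fh:
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line)
    return terms


def load_smq(path: str | Path, name: str, scope: str = "narrow") -> SMQDefinition:
    """Load an SMQ from a term file: one PT per line, ``#`` comments allowed."""
    with open(path, "r", encoding="utf-8") as fh:
        terms = _read_term_lines(fh)
    return SMQDefinition(name, scope, tuple(terms))


def load_drug_classes(path: str | Path) -> dict[str, DrugClassList]:
    """Load drug classes from a TSV with columns ``class_name`` and ``drug_name``."""
    members: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["class_name", "drug_name"]:
            raise ValueError(f"bad drug-class header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            class_name, drug_name = line.split("\t")
            members.setdefault(class_name, []).append(drug_name)
    return {
        cls: DrugClassList(cls, tuple(names)) for cls, names in sorted(members.items())
    }


def default_drug_classes() -> dict[str, DrugClassList]:
    """Built-in drug-class lists (CYP2D6 inhibitors per the FDA interaction
    examples; common opioids, benzodiazepines and antidepressants)."""
    with resources.as_file(
        resources.files("pvsignals.data").joinpath("drug_classes.tsv")
    ) as p:
        return load_drug_classes(p)


def load_atc_map(path: str | Path) -> dict[str, str]:
    """Load an optional ``drug_name\tatc_code`` TSV used to back-fill codes."""
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["drug_name", "atc_code"]:
            raise ValueError(f"bad ATC map header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            drug_name, atc = line.split("\t")
            mapping[_canon(drug_name)] = atc
    return mapping


def backfill_atc(db: Database, mapping: dict[str, str]) -> Database:
    """Return a database with empty ATC codes filled from ``mapping``."""
    from dataclasses import replace

    new_reports = []
    for report in db:
        drugs = tuple(
            replace(d, atc_code=mapping.get(d.name_key, ""))
            if not d.atc_code and d.name_key in mapping
            else d
            for d in report.drugs
        )
        new_reports.append(replace(report, drugs=drugs))
    return Database(tuple(new_reports))


def is_case(report: ICSRReport, smq: SMQDefinition) -> bool:
    """True iff at least one event PT of the report is in the SMQ.

    A report carrying several SMQ terms is still a single case; counting is
    always at case level.
    """
    return not report.pt_keys().isdisjoint(smq.term_keys)


def is_opioid_report(report: ICSRReport, exclude_drug: str | None = None) -> bool:
    """True iff the report carries a drug with an opioid ATC code.

    ``exclude_drug`` removes entries for that drug name (any role) before
    the test, so the index drug's own opioid code does not qualify its
    reports for the comparator.
    """
    exclude_key = _canon(exclude_drug) if exclude_drug else None
    for d in report.drugs:
        if exclude_key is not None and d.name_key == exclude_key:
            continue
        if d.atc_code.upper().startswith(OPIOID_ATC_PREFIXES):
            return True
    return False


def is_class_user(report: ICSRReport, cls: DrugClassList, index_drug: str) -> bool:
    """True iff the report carries a class member other than the index drug.

    Any role qualifies: concomitant exposure is what the factor measures.
    """
    if not cls.members:
        raise ValueError(f"class {cls.class_name!r} has no members")
    index_key = _canon(index_drug)
    return any(
        d.name_key != index_key and d.name_key in cls.member_keys for d in report.drugs
    )


def eligible_concomitants(
    db: Database,
    index_drug: str,
    min_cases: int = 20,
    index_roles: Iterable[str] = ("suspected", "interacting"),
) -> frozenset[str]:
    """Drugs co-reported with the index drug in strictly more than
    ``min_cases`` reports.

    The index drug's report set is defined by ``index_roles`` (suspected or
    interacting by default, matching the case definition); co-medication
    counts any role.  Used to restrict drug-class lists to medications with
    enough co-exposure before factor analysis.
    """
    if min_cases < 0:
        raise ValueError("min_cases must be >= 0")
    index_key = _canon(index_drug)
    counts: dict[str, int] = {}
    names: dict[str, str] = {}
    for report in db:
        if not report.has_drug(index_drug, index_roles):
            continue
        seen = set()
        for d in report.drugs:
            if d.name_key == index_key or d.name_key in seen:
                continue
            seen.add(d.name_key)
            counts[d.name_key] = counts.get(d.name_key, 0) + 1
            names.setdefault(d.name_key, d.drug_name)
    return frozenset(names[k] for k, n in counts.items() if n > min_cases)
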