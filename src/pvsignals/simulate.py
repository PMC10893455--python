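"""Synthetic spontaneous-report database generator.

Reports are drawn independently.  Each report receives demographics from
configurable categorical marginals, drug exposures from per-drug Bernoulli
prevalences (optionally correlated through co-medication rules), and
events from per-PT Bernoulli prevalences.  A drug-event association is
injected by multiplying the event's probability by a relative risk on
reports carrying the drug (optionally boosted further in chosen age
groups), capped at 1.  Death is sampled from a baseline probability scaled
by per-PT multipliers so that fatal-outcome associations are recoverable.
Reports where no catalogue drug (or event) fired receive a dedicated
filler entry rather than a redraw, so every configured marginal — and
every injected relative risk — is realised exactly.

Generation is a pure function of (config, seed): the same inputs always
produce a byte-identical line listing.  Alongside the database the
generator returns a :class:`GenerationLedger` of model-implied expected
counts and realised bookkeeping counts, which downstream tests use as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path


import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from pvsignals.icsr import (
    AGE_GROUPS,
    REGIONS,
    REPORTERS,
    ROLES,
    SERIOUS_TOKENS,
    SEXES,
    Database,
    DrugEntry,
    EventEntry,
    ICSRReport,
)

_DEMOGRAPHIC_TOKENS = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "region": REGIONS,
    "reporter": REPORTERS,
    "serious": SERIOUS_TOKENS,
}
_SUM_TOL = 1e-9


class DrugSpec(BaseModel):
    """A drug in the catalogue with its marginal exposure probability."""

    name: str
    atc_code: str = ""
    prevalence: float = Field(ge=0.0, le=1.0)

    @field_validator("name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("drug name must be non-empty")
        return v


class EventSpec(BaseModel):
    """A preferred term with its marginal per-report probability."""

    pt: str
    prevalence: float = Field(ge=0.0, le=1.0)

    @field_validator("pt")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("pt must be non-empty")
        return v


class Injection(BaseModel):
    """Multiply one event's probability by ``rr`` on reports with ``drug``.

    ``age_rr_multipliers`` applies an extra factor on top of ``rr`` for
    reports in the named age groups (used to enrich a stratum).
    """

    drug: str
    pt: str
    rr: float = Field(ge=0.0)
    age_rr_multipliers: dict[str, float] = Field(default_factory=dict)

    @field_validator("age_rr_multipliers")
    @classmethod
    def _valid_ages(cls, v: dict[str, float]) -> dict[str, float]:
        for age, mult in v.items():
            if age not in AGE_GROUPS:
                raise ValueError(f"unknown age group {age!r}")
            if mult < 0:
                raise ValueError("age multipliers must be >= 0")
        return v


class CoMedicationRule(BaseModel):
    """P(co_drug present | index_drug present) is raised to at least ``probability``."""

    index_drug: str
    co_drug: str
    probability: float = Field(ge=0.0, le=1.0)


class DeathModel(BaseModel):
    """Baseline death probability scaled by per-PT multipliers (capped at 1)."""

    baseline: float = Field(default=0.01, ge=0.0, le=1.0)
    pt_multipliers: dict[str, float] = Field(default_factory=dict)

    @field_validator("pt_multipliers")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        if any(m < 0 for m in v.values()):
            raise ValueError("death multipliers must be >= 0")
        return v


def _default_demographics() -> dict[str, dict[str, float]]:
    return {
        "sex": {"unknown": 1.0},
        "age_group": {"unknown": 1.0},
        "region": {"unknown": 1.0},
        "reporter": {"unknown": 1.0},
        "year": {"NA": 1.0},
        "serious": {"unknown": 1.0},
    }


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic spontaneous-report database."""

    n_reports: int = Field(ge=1)
    seed: int = 0
    drugs: list[DrugSpec] = Field(min_length=1)
    events: list[EventSpec] = Field(min_length=1)
    injections: list[Injection] = Field(default_factory=list)
    demographics: dict[str, dict[str, float]] = Field(default_factory=_default_demographics)
    co_medication: list[CoMedicationRule] = Field(default_factory=list)
    death: DeathModel = Field(default_factory=DeathModel)
    #: per-drug (suspected, interacting, concomitant) probabilities;
    #: the "default" key applies to drugs without their own entry.
    role_probabilities: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {"default": (0.7, 0.05, 0.25)}
    )
    #: Reports where no catalogue drug/event fired receive these filler
    #: entries instead of a redraw, so configured marginals stay exact.
    filler_drug: DrugSpec = Field(
        default_factory=lambda: DrugSpec(name="unspecified medication", atc_code="", prevalence=0.0)
    )
    filler_event_pt: str = "Drug ineffective"

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        drug_names = {d.name for d in self.drugs}
        if len(drug_names) != len(self.drugs):
            raise ValueError("duplicate drug names in catalogue")
        pts = {e.pt for e in self.events}
        if len(pts) != len(self.events):
            raise ValueError("duplicate PTs in catalogue")
        demographics = dict(_default_demographics())
        demographics.update(self.demographics)
        for field_name, dist in demographics.items():
            if field_name not in (*_DEMOGRAPHIC_TOKENS, "year"):
                raise ValueError(f"unknown demographic field {field_name!r}")
            if abs(sum(dist.values()) - 1.0) > _SUM_TOL:
                raise ValueError(f"{field_name} marginal must sum to 1")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError(f"{field_name} probabilities must lie in [0, 1]")
            if field_name != "year":
                bad = set(dist) - set(_DEMOGRAPHIC_TOKENS[field_name])
                if bad:
                    raise ValueError(f"unknown {field_name} tokens {sorted(bad)}")
            else:
                for token in dist:
                    if token != "NA":
                        int(token)  # raises on non-numeric year
        object.__setattr__(self, "demographics", demographics)
        for inj in self.injections:
            if inj.drug not in drug_names:
                raise ValueError(f"injection drug {inj.drug!r} not in catalogue")
            if inj.pt not in pts:
                raise ValueError(f"injection pt {inj.pt!r} not in catalogue")
        for rule in self.co_medication:
            for name in (rule.index_drug, rule.co_drug):
                if name not in drug_names:
                    raise ValueError(f"co-medication drug {name!r} not in catalogue")
            if rule.index_drug == rule.co_drug:
                raise ValueError("co-medication index and co drug must differ")
        for mult in self.death.pt_multipliers:
            if mult not in pts:
                raise ValueError(f"death multiplier PT {mult!r} not in catalogue")
        for name, probs in self.role_probabilities.items():
            if name != "default" and name not in drug_names:
                raise ValueError(f"role probabilities for unknown drug {name!r}")
            if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > _SUM_TOL:
                raise ValueError(f"role probabilities for {name!r} must be 3 values summing to 1")
        if "default" not in self.role_probabilities:
            raise ValueError('role_probabilities must include a "default" entry')
        if self.filler_drug.name in drug_names:
            raise ValueError("filler drug name collides with the catalogue")
        if self.filler_event_pt in pts:
            raise ValueError("filler event PT collides with the catalogue")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


@dataclass
class GenerationLedger:
    """Bookkeeping emitted with every generated database.

    ``expected_counts`` holds, for every injected (drug, pt) pair, the
    expected number of co-reports implied by the configured marginals (age
    mixture included); filler entries never collide with the catalogue, so
    the value is exact.  ``realized_counts`` counts actual co-reports (any
    drug role).
    ``co_report_counts`` counts, per co-medication index drug, reports
    where the index drug is suspected/interacting and the other drug is
    present in any role.  ``drug_exposure`` keeps the latent per-report
    exposure flags of injected and index drugs for oracle tests.
    """

    expected_counts: dict[tuple[str, str], float] = dataclass_field(default_factory=dict)
    realized_counts: dict[tuple[str, str], int] = dataclass_field(default_factory=dict)
    co_report_counts: dict[str, dict[str, int]] = dataclass_field(default_factory=dict)
    drug_exposure: dict[str, np.ndarray] = dataclass_field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "drug": drug,
                "pt": pt,
                "expected_count": expected,
                "realized_count": self.realized_counts.get((drug, pt), 0),
            }
            for (drug, pt), expected in sorted(self.expected_counts.items())
        ]
        return pd.DataFrame(rows, columns=["drug", "pt", "expected_count", "realized_count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sample_categorical(
    rng: np.random.Generator, dist: dict[str, float], n: int
) -> np.ndarray:
    cats = sorted(dist)
    probs = np.array([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.array(cats, dtype=object)[idx]


def generate(config: GeneratorConfig, seed: int | None = None) -> tuple[Database, GenerationLedger]:
    """Draw a synthetic database and its bookkeeping ledger.

    ``seed`` overrides ``config.seed`` when given.  Identical (config,
    seed) yields an identical database, hence a byte-identical line
    listing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drugs = config.drugs
    events = config.events
    drug_index = {d.name: j for j, d in enumerate(drugs)}
    pt_index = {e.pt: j for j, e in enumerate(events)}

    # --- demographics ------------------------------------------------------
    demo = {
        field_name: _sample_categorical(rng, config.demographics[field_name], n)
        for field_name in ("sex", "age_group", "region", "reporter", "year", "serious")
    }
    age = demo["age_group"]

    # --- drug exposure -----------------------------------------------------
    exposure = np.zeros((n, len(drugs)), dtype=bool)
    for j, d in enumerate(drugs):
        exposure[:, j] = rng.random(n) < d.prevalence
    for rule in config.co_medication:
        idx = drug_index[rule.index_drug]
        co = drug_index[rule.co_drug]
        mask = exposure[:, idx]
        exposure[:, co] |= mask & (rng.random(n) < rule.probability)
    needs_filler_drug = ~exposure.any(axis=1)

    # --- events ------------------------------------------------------------
    base = np.array([e.prevalence for e in events], dtype=float)
    probs = np.tile(base, (n, 1))
    for inj in config.injections:
        if inj.rr == 1.0 and not inj.age_rr_multipliers:
            continue  # identity: no effect on any probability
        j = pt_index[inj.pt]
        mask = exposure[:, drug_index[inj.drug]]
        rr_vec = np.full(n, inj.rr)
        for age_group, mult in inj.age_rr_multipliers.items():
            rr_vec[age == age_group] *= mult
        probs[mask, j] = probs[mask, j] * rr_vec[mask]
    np.clip(probs, 0.0, 1.0, out=probs)
    has_event = rng.random((n, len(events))) < probs
    needs_filler_event = ~has_event.any(axis=1)

    # --- roles -------------------------------------------------------------
    default_roles = np.array(config.role_probabilities["default"], dtype=float)
    roles = np.zeros((n, len(drugs)), dtype=np.int8)
    for j, d in enumerate(drugs):
        probs_j = np.array(config.role_probabilities.get(d.name, default_roles), dtype=float)
        rows = np.flatnonzero(exposure[:, j])
        if rows.size:
            roles[rows, j] = rng.choice(3, size=rows.size, p=probs_j / probs_j.sum())

    # --- death and seriousness --------------------------------------------
    p_death = np.full(n, config.death.baseline)
    for pt, mult in config.death.pt_multipliers.items():
        p_death[has_event[:, pt_index[pt]]] *= mult
    np.clip(p_death, 0.0, 1.0, out=p_death)
    death = rng.random(n) < p_death
    serious = demo["serious"].copy()
    serious[death & (serious == "false")] = "true"  # death is itself a seriousness criterion

    # --- assemble reports --------------------------------------------------
    width = max(7, len(str(n)))
    filler_drug_entry = DrugEntry(
        config.filler_drug.name, config.filler_drug.atc_code, "suspected"
    )
    filler_event_entry = EventEntry(config.filler_event_pt)
    reports = []
    for i in range(n):
        if needs_filler_drug[i]:
            drug_entries: tuple[DrugEntry, ...] = (filler_drug_entry,)
        else:
            drug_entries = tuple(
                sorted(
                    DrugEntry(drugs[j].name, drugs[j].atc_code, ROLES[roles[i, j]])
                    for j in np.flatnonzero(exposure[i])
                )
            )
        if needs_filler_event[i]:
            event_entries: tuple[EventEntry, ...] = (filler_event_entry,)
        else:
            event_entries = tuple(
                sorted(EventEntry(events[j].pt) for j in np.flatnonzero(has_event[i]))
            )
        year_tok = demo["year"][i]
        reports.append(
            ICSRReport(
                report_id=f"R{i:0{width}d}",
                sex=demo["sex"][i],
                age_group=age[i],
                region=demo["region"][i],
                reporter=demo["reporter"][i],
                year=None if year_tok == "NA" else int(year_tok),
                serious=serious[i],
                death=bool(death[i]),
                drugs=drug_entries,
                events=event_entries,
            )
        )
    db = Database(tuple(reports))

    ledger = _build_ledger(config, exposure, roles, has_event, drug_index, pt_index)
    return db, ledger


def _effective_prevalence(config: GeneratorConfig, drug_name: str) -> float:
    """Marginal exposure probability of a drug including co-medication boosts."""
    spec = next(d for d in config.drugs if d.name == drug_name)
    p_absent = 1.0 - spec.prevalence
    for rule in config.co_medication:
        if rule.co_drug == drug_name:
            index_prev = next(d for d in config.drugs if d.name == rule.index_drug).prevalence
            p_absent *= 1.0 - index_prev * rule.probability
    return 1.0 - p_absent


def _build_ledger(
    config: GeneratorConfig,
    exposure: np.ndarray,
    roles: np.ndarray,
    has_event: np.ndarray,
    drug_index: dict[str, int],
    pt_index: dict[str, int],
) -> GenerationLedger:
    ledger = GenerationLedger()
    age_dist = config.demographics["age_group"]
    for inj in config.injections:
        base = next(e.prevalence for e in config.events if e.pt == inj.pt)
        p_drug = _effective_prevalence(config, inj.drug)
        p_event_given_drug = sum(
            share * min(base * inj.rr * inj.age_rr_multipliers.get(age_group, 1.0), 1.0)
            for age_group, share in age_dist.items()
        )
        ledger.expected_counts[(inj.drug, inj.pt)] = (
            config.n_reports * p_drug * p_event_given_drug
        )
        mask = exposure[:, drug_index[inj.drug]]
        ledger.realized_counts[(inj.drug, inj.pt)] = int(
            (mask & has_event[:, pt_index[inj.pt]]).sum()
        )
        ledger.drug_exposure.setdefault(inj.drug, mask.copy())
    for rule in config.co_medication:
        idx = drug_index[rule.index_drug]
        index_si = exposure[:, idx] & (roles[:, idx] <= 1)  # suspected or interacting
        ledger.drug_exposure.setdefault(rule.index_drug, exposure[:, idx].copy())
        per_index = ledger.co_report_counts.setdefault(rule.index_drug, {})
        for name, j in drug_index.items():
            if name == rule.index_drug:
                continue
            per_index[name] = int((index_si & exposure[:, j]).sum())
    return ledger


# ---------------------------------------------------------------------------
# Study preset
# ---------------------------------------------------------------------------

_PRESET_ACRD_BASE = {
    "Respiratory arrest": 0.0020,
    "Respiratory depression": 0.0020,
    "Respiratory failure": 0.0030,
    "Bradypnoea": 0.0020,
    "Apnoea": 0.0015,
    "Hypoventilation": 0.0015,
    "Respiratory rate decreased": 0.0012,
    "Acute respiratory failure": 0.0010,
    "Hypopnoea": 0.0008,
    "Acute respiratory distress syndrome": 0.0008,
    "Apnoeic attack": 0.0003,
    "Breath holding": 0.0003,
    "Infantile apnoea": 0.0002,
    "Breath sounds abnormal": 0.0004,
    "Neonatal respiratory depression": 0.0002,
    "Apparent life threatening event": 0.0002,
    "Neonatal respiratory arrest": 0.0001,
    "Respiratory depth decreased": 0.0001,
    "Respiratory paralysis": 0.0001,
}

_PRESET_BACKGROUND_EVENTS = {
    "Nausea": 0.060,
    "Vomiting": 0.045,
    "Dizziness": 0.050,
    "Headache": 0.040,
    "Rash": 0.030,
    "Pruritus": 0.020,
    "Somnolence": 0.025,
    "Constipation": 0.020,
    "Dry mouth": 0.015,
    "Fatigue": 0.030,
    "Hyperhidrosis": 0.010,
    "Seizure": 0.008,
    "Serotonin syndrome": 0.002,
    "Drug abuse": 0.004,
    "Drug dependence": 0.003,
    "Intentional product misuse": 0.002,
    "Overdose": 0.005,
    "Drug withdrawal syndrome": 0.003,
}

#: Injected relative risks for the five full-database ACRD signal terms.
_PRESET_SIGNAL_RR = {
    "Respiratory arrest": 3.0,
    "Respiratory depression": 5.5,
    "Bradypnoea": 9.0,
    "Hypoventilation": 3.0,
    "Respiratory rate decreased": 3.0,
}

#: Comparator opioids carry stronger ACRD risks than tramadol (a weak
#: mu-agonist), so the opioid-scope analysis yields no tramadol signal.
_PRESET_OPIOID_ACRD_RR = {
    "Respiratory depression": 12.0,
    "Respiratory arrest": 10.0,
    "Apnoea": 8.0,
    "Bradypnoea": 10.0,
    "Hypoventilation": 8.0,
    "Respiratory rate decreased": 8.0,
}
_PRESET_COMPARATOR_OPIOIDS = (
    "morphine", "oxycodone", "fentanyl", "hydromorphone",
    "buprenorphine", "sufentanil", "methadone",
)

_PRESET_DRUGS = [
    # (name, atc_code, prevalence)
    ("tramadol", "N02AX02", 0.006),
    ("tramadol/paracetamol", "N02AJ13", 0.0022),
    ("morphine", "N02AA01", 0.004),
    ("oxycodone", "N02AA05", 0.004),
    ("fentanyl", "N02AB03", 0.005),
    ("hydromorphone", "N02AA03", 0.002),
    ("buprenorphine", "N02AE01", 0.002),
    ("sufentanil", "N01AH03", 0.001),
    ("methadone", "N07BC02", 0.002),
    ("diazepam", "N05BA01", 0.006),
    ("alprazolam", "N05BA12", 0.005),
    ("lorazepam", "N05BA06", 0.004),
    ("clonazepam", "N03AE01", 0.003),
    ("fluoxetine", "N06AB03", 0.006),
    ("paroxetine", "N06AB05", 0.004),
    ("sertraline", "N06AB06", 0.005),
    ("venlafaxine", "N06AX16", 0.004),
    ("amitriptyline", "N06AA09", 0.003),
    ("duloxetine", "N06AX21", 0.003),
    ("bupropion", "N06AX12", 0.003),
    ("quinidine", "C01BA01", 0.001),
    ("terbinafine", "D01BA02", 0.002),
    ("paracetamol", "N02BE01", 0.030),
    ("ibuprofen", "M01AE01", 0.025),
    ("acetylsalicylic acid", "N02BA01", 0.020),
    ("metformin", "A10BA02", 0.020),
    ("amoxicillin", "J01CA04", 0.015),
    ("omeprazole", "A02BC01", 0.020),
    ("atorvastatin", "C10AA05", 0.020),
    ("lisinopril", "C09AA03", 0.015),
    ("amlodipine", "C08CA01", 0.015),
    ("salbutamol", "R03AC02", 0.010),
    ("prednisolone", "H02AB06", 0.010),
    ("warfarin", "B01AA03", 0.008),
    ("gabapentin", "N03AX12", 0.010),
    ("ondansetron", "A04AA01", 0.008),
]

_PRESET_CO_MEDICATION = [
    # P(co-drug | tramadol): opioid / benzodiazepine / antidepressant /
    # CYP2D6-inhibitor co-exposure rates in the few-percent range.
    ("tramadol", "morphine", 0.030),
    ("tramadol", "oxycodone", 0.030),
    ("tramadol", "fentanyl", 0.020),
    ("tramadol", "diazepam", 0.015),
    ("tramadol", "alprazolam", 0.010),
    ("tramadol", "lorazepam", 0.008),
    ("tramadol", "fluoxetine", 0.015),
    ("tramadol", "paroxetine", 0.010),
    ("tramadol", "sertraline", 0.012),
    ("tramadol", "venlafaxine", 0.008),
    ("tramadol", "duloxetine", 0.005),
    ("tramadol", "amitriptyline", 0.005),
    ("tramadol", "bupropion", 0.004),
    ("tramadol", "quinidine", 0.002),
    ("tramadol", "terbinafine", 0.003),
    ("tramadol", "paracetamol", 0.100),
    ("tramadol/paracetamol", "diazepam", 0.010),
    ("tramadol/paracetamol", "fluoxetine", 0.010),
]

_PRESET_YEAR_MAP = {
    "le2013": "2013",
    "y2014": "2014",
    "y2015": "2015",
    "y2016": "2016",
    "y2017": "2017",
    "y2018": "2018",
    "y2019": "2019",
    "ge2020": "2020",
}


def tramadol_study_preset(n_reports: int = 100_000, seed: int = 0) -> GeneratorConfig:
    """A reduced-scale synthetic analogue of the tramadol study database.

    Demographic marginals mirror the published stratum proportions of the
    tramadol report series (sex, age bands, reporter, region, year);
    seriousness is a free marginal because the published seriousness
    percentage is not internally consistent.  Tramadol exposure is ~0.6%
    of reports (its share of the source database); the five ACRD preferred
    terms that were full-database signals carry injected relative risks
    >= 3 with an extra under-18 boost, bradypnoea alone is injected for
    tramadol/paracetamol, abuse-related terms are injected for tramadol,
    and co-medication rules create the four concomitant drug-class factor
    structures.
    """
    from pvsignals import reference

    demo = reference.demographics_summary()
    totals = demo[demo["block"] == "total"].iloc[0]
    n_tramadol = int(totals["tramadol_all"])

    def block_marginal(block: str, rename: dict[str, str] | None = None) -> dict[str, float]:
        rows = demo[demo["block"] == block]
        out = {}
        for _, row in rows.iterrows():
            token = rename.get(row["category"], row["category"]) if rename else row["category"]
            out[token] = int(row["tramadol_all"]) / n_tramadol
        return out

    demographics = {
        "sex": block_marginal("sex"),
        "age_group": block_marginal("age"),
        "reporter": block_marginal("reporter"),
        "region": block_marginal("region"),
        "year": block_marginal("year", rename=_PRESET_YEAR_MAP),
        "serious": {"true": 0.40, "false": 0.50, "unknown": 0.10},
    }

    events = [
        EventSpec(pt=pt, prevalence=p)
        for pt, p in {**_PRESET_ACRD_BASE, **_PRESET_BACKGROUND_EVENTS}.items()
    ]
    under18_boost = {"le11": 3.0, "a12_17": 3.0}
    injections = [
        Injection(drug="tramadol", pt=pt, rr=rr, age_rr_multipliers=under18_boost)
        for pt, rr in _PRESET_SIGNAL_RR.items()
    ]
    injections.append(Injection(drug="tramadol/paracetamol", pt="Bradypnoea", rr=3.2))
    injections += [
        Injection(drug=opioid, pt=pt, rr=rr)
        for opioid in _PRESET_COMPARATOR_OPIOIDS
        for pt, rr in _PRESET_OPIOID_ACRD_RR.items()
    ]
    injections += [
        Injection(drug="tramadol", pt="Drug abuse", rr=4.0),
        Injection(drug="tramadol", pt="Drug dependence", rr=3.0),
        Injection(drug="tramadol", pt="Overdose", rr=3.0),
    ]

    role_probabilities: dict[str, tuple[float, float, float]] = {
        "default": (0.60, 0.05, 0.35),
        "tramadol": (0.85, 0.05, 0.10),
        "tramadol/paracetamol": (0.85, 0.05, 0.10),
    }
    # CNS co-medications are mostly reported as concomitant.
    for name in (
        "morphine", "oxycodone", "fentanyl", "diazepam", "alprazolam", "lorazepam",
        "fluoxetine", "paroxetine", "sertraline", "venlafaxine", "duloxetine",
        "amitriptyline", "bupropion", "paracetamol",
    ):
        role_probabilities[name] = (0.30, 0.05, 0.65)

    death = DeathModel(
        baseline=0.008,
        pt_multipliers={
            "Respiratory arrest": 25.0,
            "Neonatal respiratory arrest": 25.0,
            "Respiratory depression": 8.0,
            "Respiratory failure": 10.0,
            "Acute respiratory failure": 10.0,
            "Apnoea": 5.0,
            "Hypoventilation": 5.0,
            "Overdose": 6.0,
        },
    )

    return GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        drugs=[DrugSpec(name=n, atc_code=a, prevalence=p) for n, a, p in _PRESET_DRUGS],
        events=events,
        injections=injections,
        demographics=demographics,
        co_medication=[
            CoMedicationRule(index_drug=i, co_drug=c, probability=p)
            for i, c, p in _PRESET_CO_MEDICATION
        ],
        death=death,
        role_probabilities=role_probabilities,
    )
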