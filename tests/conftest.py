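from __future__ import annotations

import pytest

from pvsignals.icsr import Database, DrugEntry, EventEntry, ICSRReport
from pvsignals.simulate import (
    DrugSpec,
    EventSpec,
    GeneratorConfig,
    Injection,
    generate,
    tramadol_study_preset,
)


def make_report(
    report_id: str,
    drugs: list[tuple[str, str, str]] | list[str],
    events: list[str],
    **demo,
) -> ICSRReport:
    """Compact report builder: drugs as names or (name, atc, role) triples."""
    drug_entries = tuple(
        DrugEntry(*d) if isinstance(d, tuple) else DrugEntry(d) for d in drugs
    )
    return ICSRReport(
        report_id=report_id,
        drugs=drug_entries,
        events=tuple(EventEntry(e) for e in events),
        **demo,
    )


def small_config(
    seed: int = 0,
    n_reports: int = 2000,
    injections: list[Injection] | None = None,
    **overrides,
) -> GeneratorConfig:
    """A compact mixed catalogue used by oracle and property tests."""
    kwargs = dict(
        n_reports=n_reports,
        seed=seed,
        drugs=[
            DrugSpec(name="tramadol", atc_code="N02AX02", prevalence=0.05),
            DrugSpec(name="morphine", atc_code="N02AA01", prevalence=0.03),
            DrugSpec(name="sufentanil", atc_code="N01AH03", prevalence=0.01),
            DrugSpec(name="diazepam", atc_code="N05BA01", prevalence=0.04),
            DrugSpec(name="fluoxetine", atc_code="N06AB03", prevalence=0.04),
            DrugSpec(name="paracetamol", atc_code="N02BE01", prevalence=0.10),
        ],
        events=[
            EventSpec(pt="Respiratory depression", prevalence=0.01),
            EventSpec(pt="Respiratory arrest", prevalence=0.008),
            EventSpec(pt="Bradypnoea", prevalence=0.006),
            EventSpec(pt="Nausea", prevalence=0.08),
            EventSpec(pt="Dizziness", prevalence=0.06),
            EventSpec(pt="Drug abuse", prevalence=0.01),
        ],
        injections=injections or [],
        demographics={
            "sex": {"male": 0.4, "female": 0.55, "unknown": 0.05},
            "age_group": {
                "le11": 0.05,
                "a12_17": 0.05,
                "a18_44": 0.35,
                "a45_64": 0.3,
                "a65_74": 0.1,
                "ge75": 0.1,
                "unknown": 0.05,
            },
            "region": {"americas": 0.3, "europe": 0.3, "asia": 0.35, "oceania": 0.03, "africa": 0.02},
            "reporter": {"consumer": 0.3, "physician": 0.4, "other_hcp": 0.2, "pharmacist": 0.1},
            "year": {"2019": 0.5, "2020": 0.4, "NA": 0.1},
            "serious": {"true": 0.4, "false": 0.5, "unknown": 0.1},
        },
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def preset_db():
    """One reduced-scale study-preset database shared across the session."""
    config = tramadol_study_preset(n_reports=100_000)
    db, ledger = generate(config, seed=11)
    return config, db, ledger


@pytest.fixture()
def toy_db() -> Database:
    """Four reports exercising the 2x2 cells for tramadol x Respiratory arrest."""
    return Database(
        (
            make_report("r1", [("tramadol", "N02AX02", "suspected")], ["Respiratory arrest"]),
            make_report("r2", [("tramadol", "N02AX02", "suspected")], ["Nausea"]),
            make_report("r3", [("morphine", "N02AA01", "suspected")], ["Respiratory arrest"]),
            make_report("r4", [("paracetamol", "N02BE01", "suspected")], ["Headache"]),
        )
    )
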