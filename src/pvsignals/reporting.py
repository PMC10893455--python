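"""Pipeline orchestration and deterministic table rendering.

``run_pipeline`` chains the full workflow — load or simulate a line
listing, flag SMQ cases, run per-term and age-stratified disproportionality
for each index drug and comparator scope, cross-tabulate the risk
cofactors — and writes a bundle of schema-versioned TSV tables plus a
machine-readable JSON summary.  Identical inputs and seed always produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from pvsignals import factors as factors_mod
from pvsignals.disproportionality import (
    SignalCriteria,
    detect_signals,
    stratified_signals,
)
from pvsignals.icsr import Database, read_line_listing, write_line_listing
from pvsignals.simulate import GeneratorConfig, generate
from pvsignals.terminology import (
    SMQDefinition,
    builtin_acrd_smq,
    default_abuse_smq,
    default_drug_classes,
    eligible_concomitants,
    is_case,
)

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "#pvsignals-tables v1"

UNDER_18 = ("le11", "a12_17")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (display convention for percentages/ratios)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    listing_path: str | None = None
    generator: GeneratorConfig | None = None
    index_drugs: tuple[str, ...] = ("tramadol", "tramadol/paracetamol")
    smq: SMQDefinition = field(default_factory=builtin_acrd_smq)
    abuse_smq: SMQDefinition = field(default_factory=default_abuse_smq)
    scopes: tuple[str, ...] = ("full_database", "opioids")
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    min_concomitant_cases: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.index_drugs:
            raise ValueError("at least one index drug required")
        if (self.listing_path is None) == (self.generator is None):
            raise ValueError("exactly one of listing_path or generator must be set")


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def render_demographics(db: Database, index_drug: str, smq: SMQDefinition) -> pd.DataFrame:
    """Stratum counts and half-up one-decimal percentages, for all reports
    of the index drug and for its SMQ cases."""
    from pvsignals.icsr import AGE_GROUPS, REGIONS, REPORTERS, SEXES, filter_reports

    sub = filter_reports(db, index_drug)
    cases = [r for r in sub if is_case(r, smq)]
    n_all, n_case = len(sub), len(cases)
    years = sorted({r.year for r in sub if r.year is not None})
    blocks: list[tuple[str, str, object]] = (
        [("sex", s, lambda r, s=s: r.sex == s) for s in SEXES]
        + [("age", a, lambda r, a=a: r.age_group == a) for a in AGE_GROUPS]
        + [("reporter", rep, lambda r, rep=rep: r.reporter == rep) for rep in REPORTERS]
        + [("serious", "serious", lambda r: r.serious == "true")]
        + [("region", reg, lambda r, reg=reg: r.region == reg) for reg in REGIONS]
        + [("year", str(y), lambda r, y=y: r.year == y) for y in years]
        + [("year", "NA", lambda r: r.year is None)]
    )
    rows = []
    for block, category, pred in blocks:
        c_all = sum(1 for r in sub if pred(r))
        c_case = sum(1 for r in cases if pred(r))
        rows.append(
            {
                "block": block,
                "category": category,
                "n_all": c_all,
                "pct_all": round_half_up(100 * c_all / n_all, 1) if n_all else 0.0,
                "n_case": c_case,
                "pct_case": round_half_up(100 * c_case / n_case, 1) if n_case else 0.0,
            }
        )
    frame = pd.DataFrame(rows, columns=["block", "category", "n_all", "pct_all", "n_case", "pct_case"])
    frame.attrs["n_all"] = n_all
    frame.attrs["n_case"] = n_case
    return frame


def signals_frame(results) -> pd.DataFrame:
    """Flatten disproportionality results into the Table-2-style layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.table.event,
                "n": r.table.a,
                "prr": r.prr.value,
                "prr_ci_low": r.prr.ci_low,
                "prr_ci_high": r.prr.ci_high,
                "ror": r.ror.value,
                "ror_ci_low": r.ror.ci_low,
                "ror_ci_high": r.ror.ci_high,
                "ic": r.ic,
                "ic025": r.ic025,
                "signal": r.signal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "n", "prr", "prr_ci_low", "prr_ci_high",
            "ror", "ror_ci_low", "ror_ci_high", "ic", "ic025", "signal",
        ],
    ).round(6)


def factors_frame(tables, summaries) -> pd.DataFrame:
    rows = []
    for t, s in zip(tables, summaries):
        ph = {p.category: p for p in (t.posthoc or [])}
        for j, cat in enumerate(t.categories):
            rows.append(
                {
                    "factor": t.factor_name,
                    "category": cat,
                    "n_case": int(t.counts[0, j]),
                    "pct_case": round_half_up(100 * s.proportion_case[j], 1),
                    "n_noncase": int(t.counts[1, j]),
                    "pct_noncase": round_half_up(100 * s.proportion_noncase[j], 1),
                    "proportion_ratio": round(s.proportion_ratio[j], 4)
                    if math.isfinite(s.proportion_ratio[j])
                    else float("nan"),
                    "chi2": round(t.chi2, 4),
                    "df": t.df,
                    "p_value": "<0.0001" if t.p_value < 0.0001 else f"{t.p_value:.4f}",
                    "posthoc_residual": round(ph[cat].residual, 4) if cat in ph else float("nan"),
                    "posthoc_significant": ph[cat].significant if cat in ph else "",
                    "excluded_unknown": t.excluded_unknown,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "factor", "category", "n_case", "pct_case", "n_noncase", "pct_noncase",
            "proportion_ratio", "chi2", "df", "p_value",
            "posthoc_residual", "posthoc_significant", "excluded_unknown",
        ],
    )


def default_factor_specs(db: Database, index_drug: str, abuse_smq: SMQDefinition,
                         min_concomitant_cases: int = 20):
    """The study's factor battery: demographics, the four drug classes
    (restricted to sufficiently co-reported members), abuse and death."""
    specs: list[factors_mod.FactorSpec] = [
        factors_mod.DemographicFactor("sex"),
        factors_mod.DemographicFactor("age3"),
        factors_mod.DemographicFactor("region"),
        factors_mod.DemographicFactor("reporter"),
    ]
    eligible = eligible_concomitants(db, index_drug, min_concomitant_cases)
    eligible_keys = {e.casefold() for e in eligible}
    for class_name, cls in default_drug_classes().items():
        members = tuple(m for m in cls.members if m.casefold() in eligible_keys)
        if members:
            specs.append(factors_mod.ClassUserFactor(type(cls)(class_name, members)))
        else:
            logger.warning(
                "drug class %s has no member co-reported in >%d cases with %s; skipped",
                class_name, min_concomitant_cases, index_drug,
            )
    specs.append(factors_mod.AbuseFactor(abuse_smq))
    specs.append(factors_mod.DeathFactor())
    return specs


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and write the report bundle to ``outdir``.

    Returns the machine-readable summary (also written as summary.json).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"index_drugs": list(cfg.index_drugs), "tables": []}

    if cfg.generator is not None:
        logger.info("stage=simulate seed=%s n=%d", cfg.seed, cfg.generator.n_reports)
        db, ledger = generate(cfg.generator, seed=cfg.seed)
        write_line_listing(db, out / "listing.tsv")
        ledger.write(out / "ledger.tsv")
        summary["n_reports"] = db.n_total
    else:
        logger.info("stage=load listing=%s", cfg.listing_path)
        db = read_line_listing(cfg.listing_path)
        summary["n_reports"] = db.n_total

    if db.n_total == 0:
        logger.warning("empty database: writing empty bundle, skipping factor stage")

    for drug in cfg.index_drugs:
        slug = _slug(drug)
        demo = render_demographics(db, drug, cfg.smq)
        _write_table(demo, out / f"demographics_{slug}.tsv")
        summary["tables"].append(f"demographics_{slug}.tsv")
        summary.setdefault("drug_report_counts", {})[drug] = int(demo.attrs["n_all"])
        summary.setdefault("case_counts", {})[drug] = int(demo.attrs["n_case"])

        drug_signals: list[str] = []
        for scope in cfg.scopes:
            if db.n_total == 0:
                results = []
            else:
                results = detect_signals(
                    db, drug, cfg.smq, scope=scope, criteria=cfg.criteria
                )
            frame = signals_frame(results)
            name = f"signals_{slug}_{scope}.tsv"
            _write_table(frame, out / name)
            summary["tables"].append(name)
            if scope == "full_database":
                drug_signals = [r.table.event for r in results if r.signal]
        summary.setdefault("signals", {})[drug] = drug_signals

        if db.n_total > 0:
            under18 = stratified_signals(
                db, drug, cfg.smq, UNDER_18, criteria=cfg.criteria
            )
            frame = signals_frame(under18)
            name = f"signals_{slug}_full_database_under18.tsv"
            _write_table(frame, out / name)
            summary["tables"].append(name)
            summary.setdefault("signals_under18", {})[drug] = [
                r.table.event for r in under18 if r.signal
            ]

        if db.n_total == 0 or summary["case_counts"][drug] == 0:
            logger.warning("factor stage skipped for %s: no cases", drug)
            continue
        tables, summaries = [], []
        for spec in default_factor_specs(db, drug, cfg.abuse_smq, cfg.min_concomitant_cases):
            try:
                t = factors_mod.build_factor_table(db, drug, cfg.smq, spec)
            except factors_mod.DegenerateTableError as exc:
                logger.warning("factor stage: %s", exc)
                continue
            tables.append(t)
            summaries.append(factors_mod.summarize_factor(t))
        name = f"factors_{slug}.tsv"
        _write_table(factors_frame(tables, summaries), out / name)
        summary["tables"].append(name)
        summary.setdefault("factor_ratios", {})[drug] = {
            t.factor_name: {
                cat: (round(s.proportion_ratio[j], 4) if math.isfinite(s.proportion_ratio[j]) else None)
                for j, cat in enumerate(t.categories)
            }
            for t, s in zip(tables, summaries)
        }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
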