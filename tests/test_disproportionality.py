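"""Contingency construction, PRR/ROR/IC values, signal rule, stratification."""

from __future__ import annotations

import math

import pytest

from pvsignals.disproportionality import (
    ContingencyTable,
    SignalCriteria,
    build_table,
    detect_signals,
    evaluate_table,
    ic,
    prr,
    reconstruct_table,
    ror,
    stratified_signals,
)
from pvsignals.icsr import Database
from pvsignals.reference import (
    N_COMBINATION,
    N_DATABASE,
    N_TRAMADOL,
    disproportionality_summary,
)
from pvsignals.simulate import Injection, generate
from pvsignals.terminology import builtin_acrd_smq

from conftest import make_report, small_config

FIVE_SIGNAL_TERMS = {
    "Respiratory arrest",
    "Respiratory depression",
    "Bradypnoea",
    "Hypoventilation",
    "Respiratory rate decreased",
}


class TestBuildTable:
    def test_four_report_toy_database(self, toy_db):
        t = build_table(toy_db, "tramadol", ("Respiratory arrest",))
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_report_with_two_smq_terms_counts_once_in_pooled_table(self):
        db = Database(
            (
                make_report(
                    "r1",
                    [("tramadol", "", "suspected")],
                    ["Respiratory arrest", "Bradypnoea"],
                ),
                make_report("r2", [("morphine", "", "suspected")], ["Nausea"]),
            )
        )
        t = build_table(db, "tramadol", builtin_acrd_smq())
        assert t.a == 1

    def test_absent_drug_gives_empty_drug_row(self, toy_db):
        t = build_table(toy_db, "codeine", ("Nausea",))
        assert t.a == 0 and t.b == 0

    def test_opioid_scope_excludes_non_opioid_comparators(self):
        db = Database(
            (
                make_report("r1", [("tramadol", "N02AX02", "suspected")], ["Apnoea"]),
                make_report("r2", [("morphine", "N02AA01", "suspected")], ["Apnoea"]),
                make_report("r3", [("paracetamol", "N02BE01", "suspected")], ["Apnoea"]),
            )
        )
        t = build_table(db, "tramadol", ("Apnoea",), scope="opioids")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 0)  # paracetamol report dropped

    def test_cells_match_brute_force_on_synthetic_databases(self):
        import oracles

        rng_pairs = [
            ("tramadol", ("Respiratory depression",)),
            ("tramadol", ("Bradypnoea",)),
            ("morphine", ("Nausea",)),
            ("diazepam", ("Drug abuse",)),
            ("tramadol", builtin_acrd_smq().terms),
        ]
        for seed in (0, 1, 2):
            db, _ = generate(small_config(seed=seed, n_reports=1200))
            for drug, terms in rng_pairs:
                for scope in ("full_database", "opioids"):
                    t = build_table(db, drug, terms, scope=scope)
                    assert (t.a, t.b, t.c, t.d) == oracles.contingency_cells(
                        db, drug, terms, scope=scope
                    ), (seed, drug, scope)

    def test_cell_conservation(self):
        db, _ = generate(small_config(seed=5, n_reports=800))
        t_full = build_table(db, "tramadol", ("Nausea",))
        assert t_full.n_total == db.n_total
        t_op = build_table(db, "tramadol", ("Nausea",), scope="opioids")
        assert t_op.n_total <= db.n_total


class TestPrr:
    def test_hand_computed_example(self):
        t = ContingencyTable(10, 90, 10, 890)
        est = prr(t)
        assert est.value == pytest.approx(9.0)
        assert est.ci_low < 9.0 < est.ci_high

    def test_equal_proportions_give_one(self):
        assert prr(ContingencyTable(10, 90, 100, 900)).value == pytest.approx(1.0)

    def test_zero_comparator_events_is_missing(self):
        assert math.isnan(prr(ContingencyTable(5, 5, 0, 10)).value)

    def test_empty_drug_row_is_an_error(self):
        with pytest.raises(ValueError):
            prr(ContingencyTable(0, 0, 5, 5))

    def test_respiratory_arrest_reconstruction_rounds_to_published(self):
        t = reconstruct_table(358, 2.91, N_TRAMADOL, N_DATABASE)
        assert round(prr(t).value, 2) == pytest.approx(2.91, abs=0.011)


class TestRor:
    def test_hand_computed_example(self):
        t = ContingencyTable(10, 90, 10, 890)
        assert ror(t).value == pytest.approx(8900 / 900)

    def test_balanced_table_gives_one(self):
        assert ror(ContingencyTable(20, 20, 50, 50)).value == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_ci_and_missing_point(self):
        est = ror(ContingencyTable(5, 5, 0, 10))
        assert math.isnan(est.value)
        assert est.ci_low > 0 and math.isfinite(est.ci_high)

    def test_ror_close_to_prr_in_large_sparse_tables(self):
        # in a sparse database the drug's and event's shares are tiny, so
        # odds ratios and proportion ratios coincide to the display precision
        frame = disproportionality_summary("tramadol")
        for _, row in frame.iterrows():
            t = reconstruct_table(int(row["n"]), row["prr"], N_TRAMADOL, N_DATABASE)
            assert abs(ror(t).value - prr(t).value) < 0.02


class TestIc:
    def test_empty_table_is_zero(self):
        assert ic(ContingencyTable(0, 0, 0, 0)).ic == pytest.approx(0.0)

    def test_monotone_in_observed_count_at_fixed_expected(self):
        values = [
            math.log2((a + 0.5) / (10 + 0.5)) for a in range(0, 50, 5)
        ]
        computed = [ic(ContingencyTable(a, 100 - a, 0, 0)).ic for a in range(0, 50, 5)]
        assert computed == sorted(computed)
        assert values == sorted(values)

    def test_respiratory_arrest_reconstruction(self):
        t = reconstruct_table(358, 2.91, N_TRAMADOL, N_DATABASE)
        assert t.n_expected == pytest.approx(124.41, abs=0.01)
        est = ic(t)
        assert est.ic == pytest.approx(1.521, abs=0.001)
        assert est.ic025 == pytest.approx(1.346, abs=0.001)
        # published lower bound is 1.37
        assert abs(est.ic025 - 1.37) < 0.06

    def test_gamma_method_close_to_closed_form(self):
        t = reconstruct_table(358, 2.91, N_TRAMADOL, N_DATABASE)
        noren = ic(t, method="noren").ic025
        gamma = ic(t, method="gamma").ic025
        assert abs(noren - gamma) < 0.05

    def test_prr_ror_scale_invariant_but_ic_is_not(self):
        t1 = ContingencyTable(10, 90, 10, 890)
        t2 = ContingencyTable(30, 270, 30, 2670)
        assert prr(t1).value == pytest.approx(prr(t2).value)
        assert ror(t1).value == pytest.approx(ror(t2).value)
        assert ic(t1).ic != pytest.approx(ic(t2).ic)


class TestSignalRule:
    def test_fewer_than_three_reports_is_never_a_signal(self):
        t = ContingencyTable(2, 8, 10, 5000)
        result = evaluate_table(t)
        assert prr(t).value > 50
        assert not result.signal

    def test_all_criteria_must_hold(self):
        # strong PRR/ROR but IC lower bound below zero
        t = ContingencyTable(3, 7, 30, 700)
        result = evaluate_table(t)
        assert result.prr.value >= 2 and result.ror.value >= 2
        assert result.ic025 < 0
        assert not result.signal

    def test_reconstructed_tramadol_tables_flag_exactly_the_five_terms(self):
        frame = disproportionality_summary("tramadol")
        signals = set()
        for _, row in frame.iterrows():
            t = reconstruct_table(
                int(row["n"]), row["prr"], N_TRAMADOL, N_DATABASE, event=row["term"]
            )
            if evaluate_table(t).signal:
                signals.add(row["term"])
        assert signals == FIVE_SIGNAL_TERMS

    def test_reconstructed_combination_tables_flag_only_bradypnoea(self):
        frame = disproportionality_summary("tramadol/paracetamol")
        signals = set()
        for _, row in frame.iterrows():
            if int(row["n"]) == 0 or not math.isfinite(row["prr"]):
                continue
            t = reconstruct_table(
                int(row["n"]), row["prr"], N_COMBINATION, N_DATABASE, event=row["term"]
            )
            if evaluate_table(t).signal:
                signals.add(row["term"])
        assert signals == {"Bradypnoea"}

    def test_detect_signals_orders_by_report_count(self):
        db, _ = generate(small_config(seed=2, n_reports=1500))
        results = detect_signals(db, "tramadol", builtin_acrd_smq())
        counts = [r.table.a for r in results]
        assert counts == sorted(counts, reverse=True)
        assert len(results) == 19

    def test_pooled_smq_count_bounded_by_per_term_sum(self):
        db, _ = generate(small_config(seed=2, n_reports=1500))
        results = detect_signals(
            db, "tramadol", builtin_acrd_smq(), include_smq_aggregate=True
        )
        pooled = results[-1]
        assert pooled.table.event == "acute_central_respiratory_depression"
        assert pooled.table.a <= sum(r.table.a for r in results[:-1])


class TestStratification:
    def test_all_age_groups_equals_full_database(self):
        db, _ = generate(small_config(seed=4, n_reports=1000))
        # exclude unknown-age reports to mirror the stratum rule
        known = Database(tuple(r for r in db if r.age_group != "unknown"))
        all_ages = (
            "le11", "a12_17", "a18_44", "a45_64", "a65_74", "ge75",
        )
        strat = stratified_signals(db, "tramadol", ("Nausea",), all_ages)
        full = detect_signals(known, "tramadol", ("Nausea",))
        assert [(r.table.a, r.table.b, r.table.c, r.table.d) for r in strat] == [
            (r.table.a, r.table.b, r.table.c, r.table.d) for r in full
        ]

    def test_empty_stratum_returns_empty_list(self, toy_db):
        assert stratified_signals(toy_db, "tramadol", ("Nausea",), ("le11",)) == []

    def test_under18_enrichment_recovers_stratum_signal(self):
        config = small_config(
            seed=10,
            n_reports=30_000,
            injections=[
                Injection(
                    drug="tramadol",
                    pt="Bradypnoea",
                    rr=5.0,
                    age_rr_multipliers={"le11": 4.0, "a12_17": 4.0},
                )
            ],
        )
        config = config.model_copy(
            update={
                "role_probabilities": {"default": (1.0, 0.0, 0.0)},
            }
        )
        db, ledger = generate(config)
        assert ledger.expected_counts[("tramadol", "Bradypnoea")] > 50
        under18 = stratified_signals(db, "tramadol", ("Bradypnoea",), ("le11", "a12_17"))
        full = detect_signals(db, "tramadol", ("Bradypnoea",))
        assert under18[0].signal
        assert full[0].signal  # enrichment strengthens, not replaces, the signal
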