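"""Factor cross-tabulation, chi-square, post hoc and proportion ratios."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pvsignals.factors import (
    AbuseFactor,
    ClassUserFactor,
    DeathFactor,
    DegenerateTableError,
    DemographicFactor,
    FactorTable,
    build_factor_table,
    chi_square,
    posthoc,
    summarize_factor,
)
from pvsignals.icsr import Database
from pvsignals.reference import factor_summary
from pvsignals.simulate import generate
from pvsignals.terminology import DrugClassList, builtin_acrd_smq, default_abuse_smq

from conftest import make_report, small_config


def _published_table(factor: str) -> FactorTable:
    frame = factor_summary(factor)
    return FactorTable(
        factor_name=factor,
        categories=tuple(frame["category"]),
        counts=np.array([frame["acrd"].to_numpy(), frame["non_acrd"].to_numpy()]),
    )


class TestBuildFactorTable:
    def test_toy_death_table(self):
        smq = builtin_acrd_smq()
        reports = [
            make_report("c1", [("tramadol", "", "suspected")], ["Apnoea"], serious="true", death=True),
            make_report("c2", [("tramadol", "", "suspected")], ["Apnoea"]),
        ] + [
            make_report(f"n{i}", [("tramadol", "", "suspected")], ["Nausea"])
            for i in range(8)
        ]
        table = build_factor_table(Database(tuple(reports)), "tramadol", smq, DeathFactor())
        assert table.categories == ("death", "survival")
        assert table.counts.tolist() == [[1, 1], [0, 8]]

    def test_unknown_sex_reports_are_excluded_and_counted(self):
        smq = builtin_acrd_smq()
        reports = (
            make_report("r1", [("tramadol", "", "suspected")], ["Apnoea"], sex="male"),
            make_report("r2", [("tramadol", "", "suspected")], ["Nausea"], sex="female"),
            make_report("r3", [("tramadol", "", "suspected")], ["Nausea"], sex="unknown"),
            make_report("r4", [("tramadol", "", "suspected")], ["Nausea"], sex="male"),
        )
        table = build_factor_table(Database(reports), "tramadol", smq, DemographicFactor("sex"))
        assert table.excluded_unknown == 1
        assert table.counts.sum() == 3

    def test_counts_match_brute_force_scan(self):
        import oracles

        smq = builtin_acrd_smq()
        db, _ = generate(small_config(seed=12, n_reports=2000))
        table = build_factor_table(db, "tramadol", smq, DemographicFactor("sex"))
        si = ("suspected", "interacting")
        for j, sex in enumerate(table.categories):
            for i, case in enumerate((True, False)):
                expected = sum(
                    1
                    for r in db
                    if oracles.report_has_drug(r, "tramadol", si)
                    and r.sex == sex
                    and oracles.report_has_any_term(r, smq.terms) is case
                )
                assert table.counts[i, j] == expected

    def test_age_bands_collapse_to_three_levels(self):
        smq = builtin_acrd_smq()
        db, _ = generate(small_config(seed=13, n_reports=2000))
        table = build_factor_table(db, "tramadol", smq, DemographicFactor("age3"))
        assert table.categories == ("le17", "a18_64", "ge65")

    def test_class_and_abuse_factors_use_terminology_predicates(self):
        smq = builtin_acrd_smq()
        db, _ = generate(small_config(seed=14, n_reports=8000))
        benzos = DrugClassList("benzodiazepines", ("diazepam",))
        t_benzo = build_factor_table(db, "tramadol", smq, ClassUserFactor(benzos))
        assert t_benzo.factor_name == "benzodiazepines"
        t_abuse = build_factor_table(db, "tramadol", smq, AbuseFactor(default_abuse_smq()))
        assert set(t_abuse.categories) <= {"abuser", "non_abuser"}

    def test_single_category_factor_is_degenerate(self):
        smq = builtin_acrd_smq()
        db = Database(
            (
                make_report("r1", [("tramadol", "", "suspected")], ["Apnoea"], sex="male"),
                make_report("r2", [("tramadol", "", "suspected")], ["Nausea"], sex="male"),
            )
        )
        with pytest.raises(DegenerateTableError):
            build_factor_table(db, "tramadol", smq, DemographicFactor("sex"))


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        result = chi_square(FactorTable("x", ("a", "b"), np.array([[10, 10], [10, 10]])))
        assert result.chi2 == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_perfectly_associated_table(self):
        result = chi_square(FactorTable("x", ("a", "b"), np.array([[20, 0], [0, 20]])))
        assert result.chi2 == pytest.approx(40.0)
        assert result.df == 1

    def test_published_death_table_is_overwhelmingly_significant(self):
        result = chi_square(_published_table("death"))
        assert result.p_value < 0.0001

    def test_matches_brute_force_on_random_tables(self):
        import oracles

        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = rng.integers(1, 200, size=(2, rng.integers(2, 6)))
            ours = chi_square(FactorTable("x", tuple(map(str, range(counts.shape[1]))), counts))
            assert ours.chi2 == pytest.approx(oracles.pearson_chi2(counts.tolist()), abs=1e-9)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square(FactorTable("x", ("a", "b"), np.array([[0, 0], [5, 5]])))


class TestPosthoc:
    def test_proportional_table_flags_nothing(self):
        cells = posthoc(FactorTable("x", ("a", "b", "c"), np.array([[10, 20, 30], [100, 200, 300]])))
        assert not any(c.significant for c in cells)

    def test_single_inflated_category_is_flagged(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            # independent base counts, then inflate category 0 of the case row
            base = rng.multinomial(4000, [1 / 4] * 4, size=2)
            base[0, 0] += 600
            cells = posthoc(FactorTable("x", ("a", "b", "c", "d"), base))
            flagged = {c.category for c in cells if c.significant and c.residual > 0}
            hits += flagged == {"a"}
        assert hits >= 19

    def test_published_region_table_flags_americas_and_asia_oppositely(self):
        cells = {c.category: c for c in posthoc(_published_table("region"))}
        assert cells["americas"].significant and cells["americas"].residual > 0
        assert cells["asia"].significant and cells["asia"].residual < 0


class TestSummaries:
    def test_death_proportion_ratio_rounds_to_published(self):
        from pvsignals.reporting import round_half_up

        s = summarize_factor(_published_table("death"))
        ratio = s.proportion_ratio[0]
        assert ratio == pytest.approx((233 / 1126) / (3377 / 139595))
        assert round_half_up(ratio, 1) == 8.6

    def test_opioid_user_share(self):
        s = summarize_factor(_published_table("opioids"))
        assert 100 * s.proportion_case[0] == pytest.approx(31.1, abs=0.05)

    def test_equal_proportions_give_ratio_one(self):
        s = summarize_factor(FactorTable("x", ("a", "b"), np.array([[10, 90], [20, 180]])))
        assert s.proportion_ratio[0] == pytest.approx(1.0)

    def test_two_level_factor_reports_odds_ratio_with_ci(self):
        s = summarize_factor(_published_table("death"))
        assert s.odds_ratio == pytest.approx((233 / 893) / (3377 / 136218))
        low, high = s.odds_ratio_ci
        assert low < s.odds_ratio < high

    def test_ratios_invariant_to_scaling_rows(self):
        t1 = FactorTable("x", ("a", "b"), np.array([[10, 30], [50, 150]]))
        t2 = FactorTable("x", ("a", "b"), np.array([[30, 90], [100, 300]]))
        assert summarize_factor(t1).proportion_ratio == pytest.approx(
            summarize_factor(t2).proportion_ratio
        )

    def test_published_percentages_recompute_within_a_tenth(self):
        # Published convention: percentages against the column totals after
        # unknown exclusion -- except the non-case reporter column, which the
        # source table computed against the pre-exclusion total.
        from pvsignals.reporting import round_half_up

        printed = {
            ("sex", "male"): (42.7, 36.8),
            ("sex", "female"): (57.4, 63.2),
            ("age3", "le17"): (11.7, 3.0),
            ("age3", "a18_64"): (65.8, 67.7),
            ("age3", "ge65"): (22.5, 29.3),
            ("region", "americas"): (50.4, 17.6),
            ("region", "asia"): (7.6, 61.7),
            ("opioids", "user"): (31.1, 6.7),
            ("benzodiazepines", "user"): (19.8, 2.8),
            ("antidepressants", "user"): (20.1, 4.6),
            ("cyp2d6_inhibitors", "user"): (12.1, 3.6),
            ("abuse", "abuser"): (12.6, 2.3),
            ("death", "death"): (20.7, 2.4),
        }
        for factor in {f for f, _ in printed}:
            s = summarize_factor(_published_table(factor))
            for j, cat in enumerate(s.categories):
                if (factor, cat) not in printed:
                    continue
                case_pct, non_pct = printed[(factor, cat)]
                assert abs(round_half_up(100 * s.proportion_case[j], 1) - case_pct) <= 0.1 + 1e-9
                assert abs(round_half_up(100 * s.proportion_noncase[j], 1) - non_pct) <= 0.1 + 1e-9

    def test_reporter_noncase_percentages_use_preexclusion_denominator(self):
        frame = factor_summary("reporter")
        n_noncase_full = 139_595
        printed = {"physician": 26.0, "pharmacist": 10.3, "other_hcp": 22.6,
                   "consumer": 30.3, "lawyer": 0.5}
        for _, row in frame.iterrows():
            pct = 100 * row["non_acrd"] / n_noncase_full
            assert abs(pct - printed[row["category"]]) <= 0.1 + 1e-9
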