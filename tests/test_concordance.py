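"""Tests for binarization, the reuse window, the concordance tables, and the
nine-way discordance classifier."""

from datetime import date

import pytest

from varconcord.acmg import Classification, assessment, combine_criteria
from varconcord.concordance import (
    DiscordanceCategory,
    Flags,
    VariantComparisonRecord,
    binarize,
    categorize_discordance,
    per_case_table,
    per_variant_table,
    reuse_policy,
    round_pct,
    tabulate_categories,
)
from varconcord.exceptions import ValidationError
from varconcord.reporting import render_report


def record(key, manual, auto, count=1, manual_criteria=(), auto_criteria=(), flags=Flags()):
    return VariantComparisonRecord(
        variant_key=key,
        consensus_binary=binarize(manual),
        manual_class=manual,
        automated_class=auto,
        case_count=count,
        manual_criteria=frozenset(manual_criteria),
        automated_criteria=frozenset(auto_criteria),
        flags=flags,
    )


class TestBinarize:
    @pytest.mark.parametrize(
        "cls, expected",
        [
            (Classification.P, "positive"),
            (Classification.LP, "positive"),
            (Classification.VUS, "negative"),
            (Classification.LB, "negative"),
            (Classification.B, "negative"),
        ],
    )
    def test_reporting_dichotomy(self, cls, expected):
        assert binarize(cls) == expected


class TestReusePolicy:
    @pytest.mark.parametrize(
        "manual, analysis, expected",
        [
            (date(2020, 1, 15), date(2020, 6, 15), "reuse"),      # 5 months
            (date(2020, 1, 15), date(2020, 8, 15), "re_review"),  # 7 months
            (date(2020, 1, 15), date(2020, 7, 15), "re_review"),  # exactly 6 months
            (date(2020, 1, 15), date(2020, 7, 14), "reuse"),      # one day short
            (date(2020, 8, 31), date(2021, 2, 28), "re_review"),  # month-end clamping
        ],
    )
    def test_six_month_window(self, manual, analysis, expected):
        assert reuse_policy(manual, analysis) == expected

    def test_manual_date_after_analysis_rejected(self):
        with pytest.raises(ValidationError):
            reuse_policy(date(2021, 1, 1), date(2020, 1, 1))


class TestConfusionTables:
    def test_amplification_by_case_count(self):
        records = [
            record("a", Classification.P, Classification.VUS, count=100),  # discordant
            record("b", Classification.P, Classification.P, count=10),     # concordant
        ]
        assert per_variant_table(records).overall_concordance_pct() == 50.0
        per_case = per_case_table(records)
        assert per_case.grand_total == 110
        assert per_case.overall_concordance_pct() == 9.1  # 10/110

    def test_unit_counts_degenerate_to_per_variant(self):
        records = [
            record("a", Classification.P, Classification.P),
            record("b", Classification.VUS, Classification.P),
            record("c", Classification.B, Classification.B),
        ]
        assert per_case_table(records) == per_variant_table(records)

    def test_weighting_equals_expansion(self):
        records = [
            record("a", Classification.P, Classification.VUS, count=7),
            record("b", Classification.LB, Classification.LB, count=3),
            record("c", Classification.LP, Classification.P, count=5),
        ]
        expanded = [
            record(f"{r.variant_key}_{i}", r.manual_class, r.automated_class)
            for r in records
            for i in range(r.case_count)
        ]
        assert per_case_table(records) == per_variant_table(expanded)

    def test_column_percentages_sum_to_100(self):
        records = [
            record("a", Classification.P, Classification.P, count=13),
            record("b", Classification.P, Classification.B, count=29),
            record("c", Classification.VUS, Classification.P, count=7),
            record("d", Classification.B, Classification.B, count=111),
        ]
        for table in (per_variant_table(records), per_case_table(records)):
            assert abs(sum(table.manual_positive_pcts()) - 100.0) <= 0.1
            assert abs(sum(table.manual_negative_pcts()) - 100.0) <= 0.1
            assert table.grand_total == sum(table.cells())

    def test_all_discordant_gives_zero_concordance(self):
        table = per_variant_table([record("a", Classification.P, Classification.VUS)])
        assert table.overall_concordance_pct() == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="no analyzable"):
            per_variant_table([])

    def test_round_half_up(self):
        assert round_pct(1, 8) == 12.5
        assert round_pct(125, 1000) == 12.5
        assert round_pct(1245, 10000) == 12.5  # half rounds up, not to even
        assert round_pct(1244, 10000) == 12.4


def _disc(manual_codes, auto_codes, flags=Flags(), manual_sources=None):
    manual = frozenset(
        assessment(c, (manual_sources or {}).get(c)) for c in manual_codes
    )
    auto = frozenset(assessment(c) for c in auto_codes)
    return record(
        "v", combine_criteria(manual), combine_criteria(auto),
        manual_criteria=manual, auto_criteria=auto, flags=flags,
    )


class TestCategorizeDiscordance:
    def test_literature_case_criteria_missed_by_automation(self):
        r = _disc({"PM3", "PP1", "PS3"}, {"PS3"})
        assert categorize_discordance(r) is DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED

    def test_subpopulation_frequency_on_positive_variant(self):
        r = _disc({"PS1", "PM2"}, {"PS1", "PM2", "BS1"}, flags=Flags(subpop_freq_elevated=True))
        assert categorize_discordance(r) is DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC

    def test_late_null_takes_priority_over_everything(self):
        r = _disc({}, {"PVS1", "PM2"}, flags=Flags(late_null=True, phenotype_mismatch=True))
        assert categorize_discordance(r) is DiscordanceCategory.LATE_NULL_VARIANT

    def test_missed_clinvar_entry(self):
        r = _disc({"PS1", "PP5", "PP2"}, {"PS1", "PP2"}, flags=Flags(clinvar_entry_missed=True))
        assert categorize_discordance(r) is DiscordanceCategory.CLINVAR_ENTRY_NOT_IDENTIFIED

    def test_atypical_phenotype_beats_case_criteria(self):
        # automation wrongly invokes case codes on the wrong phenotype
        r = _disc({}, {"PM3", "PM6", "PM2"}, flags=Flags(phenotype_mismatch=True))
        assert categorize_discordance(r) is DiscordanceCategory.ATYPICAL_PHENOTYPE

    def test_variable_penetrance_via_healthy_individuals(self):
        r = _disc({"PS1", "PM2"}, {"PS1", "PM2", "BS2"}, flags=Flags(healthy_in_popdb=True))
        assert categorize_discordance(r) is DiscordanceCategory.VARIABLE_PENETRANCE

    def test_functional_study_criteria_missed(self):
        r = _disc({"PS3", "PM2"}, {"PM2"})
        assert categorize_discordance(r) is DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED

    def test_prediction_only_difference(self):
        r = _disc({"PS1", "PM2"}, {"PS1", "PM2", "BP4"})
        assert categorize_discordance(r) is DiscordanceCategory.FUNCTIONAL_PREDICTION

    def test_fallback_is_expert_decision(self):
        r = _disc({"PS1", "PM2"}, {"PM2"})
        assert categorize_discordance(r) is DiscordanceCategory.EXPERT_DECISION

    def test_case_criteria_requires_literature_source(self):
        # the same manual-only PM3 sourced from allelic data is not a missed
        # literature case; it falls through to expert decision
        r = _disc({"PM3", "PP2", "PS1"}, {"PP2", "PS1"},
                  manual_sources={"PM3": "allelic_data"})
        assert categorize_discordance(r) is DiscordanceCategory.EXPERT_DECISION

    def test_concordant_record_rejected(self):
        r = record("v", Classification.P, Classification.LP)
        with pytest.raises(ValidationError, match="concordant"):
            categorize_discordance(r)


class TestTabulateCategories:
    def test_single_record_is_100_percent(self):
        tab = tabulate_categories([_disc({"PS3", "PM2"}, {"PM2"})])
        assert tab.total == 1
        assert tab.percentages() == (100.0,)

    def test_two_categories_split_evenly(self):
        tab = tabulate_categories([
            _disc({"PS3", "PM2"}, {"PM2"}),
            _disc({"PS1", "PM2"}, {"PM2"}),
        ])
        assert tab.percentages() == (50.0, 50.0)

    def test_empty_tabulation(self):
        tab = tabulate_categories([])
        assert tab.total == 0
        assert tab.counts == ()

    def test_precomputed_labels_must_match_length(self):
        with pytest.raises(ValidationError):
            tabulate_categories([_disc({"PS3", "PM2"}, {"PM2"})], categories=[])


class TestRenderReport:
    def _records(self):
        return [
            record("a", Classification.P, Classification.P, count=5),
            record("b", Classification.P, Classification.VUS, count=2,
                   manual_criteria={assessment("PS3"), assessment("PM2")},
                   auto_criteria={assessment("PM2")}),
            record("c", Classification.B, Classification.B, count=9),
        ]

    def test_byte_identical_across_runs(self):
        records = self._records()
        discordant = [r for r in records if r.is_discordant]
        bundles = [
            render_report(per_variant_table(records), per_case_table(records),
                          tabulate_categories(discordant))
            for _ in range(2)
        ]
        assert bundles[0].text == bundles[1].text
        assert "Per-variant concordance" in bundles[0].text

    def test_empty_discordance_section(self):
        records = [record("a", Classification.P, Classification.P)]
        bundle = render_report(per_variant_table(records), per_case_table(records),
                               tabulate_categories([]))
        assert "no discordant records" in bundle.text
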