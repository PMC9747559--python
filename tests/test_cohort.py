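"""Tests for the synthetic cohort generator: injection round-trips, case-count
amplification, determinism, and recovery of configured parameters."""

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from varconcord.acmg import Classification, assessment, combine_criteria
from varconcord.cohort import (
    CaseCountModel,
    CohortConfig,
    MECHANISM_STRATUM,
    generate_cohort,
    inject_discordance,
    sample_case_counts,
    study_shaped_config,
)
from varconcord.concordance import (
    DiscordanceCategory,
    VariantComparisonRecord,
    binarize,
    categorize_discordance,
    per_case_table,
    per_variant_table,
)
from varconcord.consensus import consensus_pipeline, funnel_report
from varconcord.exceptions import ValidationError


def concordant_record(codes, key="v"):
    criteria = frozenset(assessment(c) for c in codes)
    cls = combine_criteria(criteria)
    return VariantComparisonRecord(
        variant_key=key,
        consensus_binary=binarize(cls),
        manual_class=cls,
        automated_class=cls,
        case_count=1,
        manual_criteria=criteria,
        automated_criteria=criteria,
    )


class TestConfigValidation:
    def test_rates_must_stay_within_stratum_budget(self):
        with pytest.raises(ValidationError, match="sum"):
            CohortConfig(
                n_variants=10, seed=0,
                mechanism_rates={
                    DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED: 0.7,
                    DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC: 0.5,
                },
            )

    def test_fraction_bounds_checked(self):
        with pytest.raises(ValidationError):
            CohortConfig(n_variants=10, seed=0, positive_fraction=1.5)
        with pytest.raises(ValidationError):
            CaseCountModel(family="zipf", exponent=0.9)
        with pytest.raises(ValidationError):
            CaseCountModel(amplification=0.5)


class TestSampleCaseCounts:
    def test_degenerate_lognormal_is_point_mass_at_one(self):
        counts = sample_case_counts(
            50, CaseCountModel(family="lognormal", mu=0.0, sigma=0.0),
            [False] * 50, np.random.default_rng(0),
        )
        assert (counts == 1).all()

    def test_counts_are_positive_integers(self):
        model = CaseCountModel(family="zipf", exponent=2.5, amplification=3.0)
        mask = [True, False] * 500
        counts = sample_case_counts(1000, model, mask, np.random.default_rng(1))
        assert counts.dtype.kind == "i" and (counts >= 1).all()

    def test_amplification_scales_the_masked_mean(self):
        n = 20_000
        mask = np.arange(n) < n // 2
        model = CaseCountModel(family="lognormal", mu=1.0, sigma=0.5, amplification=20.0)
        counts = sample_case_counts(n, model, mask, np.random.default_rng(2))
        ratio = counts[mask].mean() / counts[~mask].mean()
        assert 16.0 < ratio < 24.0

    def test_no_amplification_means_equal_means(self):
        n = 10_000
        mask = np.arange(n) < n // 2
        model = CaseCountModel(family="lognormal", mu=1.0, sigma=0.5, amplification=1.0)
        counts = sample_case_counts(n, model, mask, np.random.default_rng(3))
        ratio = counts[mask].mean() / counts[~mask].mean()
        assert 0.95 < ratio < 1.05


class TestInjectDiscordance:
    @pytest.mark.parametrize("mechanism", list(DiscordanceCategory))
    def test_round_trip_recovers_mechanism(self, mechanism):
        rng = np.random.default_rng(5)
        if mechanism is DiscordanceCategory.EXPERT_DECISION:
            base = concordant_record({"PS1", "PM2"})
        elif MECHANISM_STRATUM[mechanism] == "positive":
            base = concordant_record({"PS3", "PM3", "PP1", "PP5"})
        else:
            base = concordant_record({"PM2", "PP2"})
        injected = inject_discordance(base, mechanism, rng)
        assert injected.is_discordant
        assert categorize_discordance(injected) is mechanism

    def test_flip_is_real_class_flip(self):
        rng = np.random.default_rng(6)
        base = concordant_record({"PS3", "PM3"})
        injected = inject_discordance(
            base, DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC, rng
        )
        assert combine_criteria(injected.automated_criteria) == injected.automated_class
        assert binarize(injected.automated_class) == "negative"
        assert injected.manual_class == base.manual_class  # manual view untouched

    def test_spec_example_removing_case_codes(self):
        base = concordant_record({"PS3", "PM3"})
        injected = inject_discordance(
            base, DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED, np.random.default_rng(7)
        )
        assert {a.code.code_id for a in injected.automated_criteria} == {"PS3"}
        assert injected.automated_class == Classification.VUS

    def test_wrong_stratum_rejected(self):
        negative = concordant_record({"PM2"})
        with pytest.raises(ValidationError):
            inject_discordance(
                negative, DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC,
                np.random.default_rng(8),
            )

    def test_concordance_precondition(self):
        base = concordant_record({"PS1", "PM2"})
        injected = inject_discordance(
            base, DiscordanceCategory.EXPERT_DECISION, np.random.default_rng(9)
        )
        with pytest.raises(ValidationError):
            inject_discordance(injected, DiscordanceCategory.EXPERT_DECISION,
                               np.random.default_rng(9))


@pytest.fixture(scope="module")
def small_cohort():
    config = replace(
        study_shaped_config(scale=0.1, seed=42),
        n_variants=2_000,
        high_confidence_fraction=1.0,
        lab_conflict_rate=0.0,
    )
    return generate_cohort(config)


class TestGenerateCohort:
    def test_byte_identical_for_same_seed(self):
        config = study_shaped_config(scale=0.01, seed=3)
        a = generate_cohort(config)
        b = generate_cohort(config)
        assert a.submissions == b.submissions
        assert a.comparisons == b.comparisons
        assert a.mechanism_truth == b.mechanism_truth

    def test_zero_mechanism_rates_mean_full_concordance(self):
        config = CohortConfig(
            n_variants=800, seed=4, high_confidence_fraction=1.0,
            lab_conflict_rate=0.0, mechanism_rates={},
        )
        cohort = generate_cohort(config)
        assert per_variant_table(cohort.comparisons).overall_concordance_pct() == 100.0

    def test_mechanism_round_trip_on_cohort(self, small_cohort):
        for r in small_cohort.comparisons:
            if r.is_discordant:
                assert categorize_discordance(r) is small_cohort.mechanism_truth[r.variant_key]
        truth_keys = set(small_cohort.mechanism_truth)
        disc_keys = {r.variant_key for r in small_cohort.comparisons if r.is_discordant}
        assert truth_keys == disc_keys

    def test_consensus_invariant_of_comparison_records(self, small_cohort):
        for r in small_cohort.comparisons:
            assert binarize(r.manual_class) == r.consensus_binary

    def test_positive_fraction_within_binomial_bound(self):
        config = CohortConfig(
            n_variants=10_000, seed=12, high_confidence_fraction=1.0,
            lab_conflict_rate=0.0, positive_fraction=0.235,
        )
        cohort = generate_cohort(config)
        frac = np.mean([r.consensus_binary == "positive" for r in cohort.comparisons])
        half_width = 2.576 * np.sqrt(0.235 * 0.765 / 10_000)  # 99% binomial interval
        assert abs(frac - 0.235) < half_width

    def test_funnel_fractions_recovered_by_consensus_builder(self):
        config = study_shaped_config(scale=0.1, seed=21)
        cohort = generate_cohort(config)
        results = consensus_pipeline(
            list(cohort.submissions), config.submitters.qualifying,
            config.cutoff_date, cohort.internal_labels,
        )
        funnel = funnel_report(results)
        assert funnel.total == config.n_variants
        expected_hc = config.high_confidence_fraction * config.n_variants
        sd = np.sqrt(expected_hc * (1 - config.high_confidence_fraction))
        assert abs(funnel.high_confidence - expected_hc) < 3 * sd + 1
        assert funnel.retained == funnel.high_confidence - funnel.lab_conflict

    def test_amplification_drives_per_case_discordance(self, small_cohort):
        pv = per_variant_table(small_cohort.comparisons)
        pc = per_case_table(small_cohort.comparisons)
        pv_fn = pv.auto_neg_manual_pos / pv.manual_positive_total
        pc_fn = pc.auto_neg_manual_pos / pc.manual_positive_total
        assert pc_fn > pv_fn
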