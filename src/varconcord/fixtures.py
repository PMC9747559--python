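"""Study-shaped fixtures built programmatically from the published marginal counts.

These expand the printed summary tables of the source study into record-level
inputs: a per-variant comparison set whose confusion-table cells match the
published per-variant and per-case tables, a 359-record discordance set whose
mechanistic categories match the published discordance tabulation, and a
consensus-result set reproducing the inclusion funnel (116,721 observed
variants, 5,548 high-confidence, 17 laboratory conflicts, 5,531 retained with
a 1,299/4,232 positive/negative split).
"""

from __future__ import annotations

from datetime import date

from .acmg import Classification, assessment, combine_criteria
from .concordance import (
    NEGATIVE,
    POSITIVE,
    DiscordanceCategory,
    Flags,
    VariantComparisonRecord,
    binarize,
)
from .consensus import (
    DISCORDANT,
    HIGH_CONFIDENCE,
    INSUFFICIENT,
    LAB_CONFLICT,
    ConsensusResult,
)

__all__ = [
    "TABLE1_CELLS",
    "TABLE3_CELLS",
    "TABLE2_COUNTS",
    "FUNNEL_COUNTS",
    "study_comparison_records",
    "study_discordance_records",
    "study_consensus_results",
]

#: Per-variant confusion cells: (auto+/manual+, auto-/manual+, auto+/manual-, auto-/manual-).
TABLE1_CELLS = (1_004, 295, 73, 4_159)
#: Per-case confusion cells in the same order.
TABLE3_CELLS = (5_083, 8_789, 1_244, 1_989_157)
#: Published discordance counts per mechanism.
TABLE2_COUNTS: dict[DiscordanceCategory, int] = {
    DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED: 167,
    DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC: 57,
    DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED: 37,
    DiscordanceCategory.ATYPICAL_PHENOTYPE: 35,
    DiscordanceCategory.EXPERT_DECISION: 24,
    DiscordanceCategory.FUNCTIONAL_PREDICTION: 21,
    DiscordanceCategory.VARIABLE_PENETRANCE: 12,
    DiscordanceCategory.CLINVAR_ENTRY_NOT_IDENTIFIED: 5,
    DiscordanceCategory.LATE_NULL_VARIANT: 1,
}
#: (total observed, high confidence, lab conflicts, retained positive, retained negative)
FUNNEL_COUNTS = (116_721, 5_548, 17, 1_299, 4_232)

_FIXTURE_DATE = date(2020, 11, 3)


def _spread(total_cases: int, n_variants: int) -> list[int]:
    """Distribute a case total over variants as evenly as integers allow."""
    base, rem = divmod(total_cases, n_variants)
    return [base + 1 if i < rem else base for i in range(n_variants)]


def study_comparison_records() -> list[VariantComparisonRecord]:
    """5,531 comparison records matching the published per-variant cells, with
    case counts distributed so the per-case cells match as well."""
    specs = [
        ("tp", Classification.P, Classification.P, TABLE1_CELLS[0], TABLE3_CELLS[0]),
        ("fn", Classification.P, Classification.VUS, TABLE1_CELLS[1], TABLE3_CELLS[1]),
        ("fp", Classification.VUS, Classification.P, TABLE1_CELLS[2], TABLE3_CELLS[2]),
        ("tn", Classification.VUS, Classification.VUS, TABLE1_CELLS[3], TABLE3_CELLS[3]),
    ]
    records = []
    for tag, manual, auto, n, cases in specs:
        counts = _spread(cases, n)
        for i, c in enumerate(counts):
            records.append(
                VariantComparisonRecord(
                    variant_key=f"{tag}_{i + 1:06d}",
                    consensus_binary=binarize(manual),
                    manual_class=manual,
                    automated_class=auto,
                    case_count=c,
                    manual_date=_FIXTURE_DATE,
                )
            )
    return records


def _discordance_template(category: DiscordanceCategory, key: str) -> VariantComparisonRecord:
    """One record whose evidence sets and flags realize the given mechanism."""
    C = DiscordanceCategory
    if category is C.CASE_CRITERIA_NOT_INVOKED:
        manual = frozenset({assessment("PS3"), assessment("PM3"), assessment("PP1")})
        auto = frozenset({assessment("PS3")})
        flags = Flags(literature_identified=True)
    elif category is C.HIGH_FREQUENCY_PATHOGENIC:
        manual = frozenset({assessment("PS1"), assessment("PM2")})
        auto = frozenset(manual | {assessment("BS1")})
        flags = Flags(subpop_freq_elevated=True)
    elif category is C.FUNCTIONAL_CRITERIA_NOT_INVOKED:
        manual = frozenset({assessment("PS3"), assessment("PM2")})
        auto = frozenset({assessment("PM2")})
        flags = Flags()
    elif category is C.ATYPICAL_PHENOTYPE:
        manual = frozenset()
        auto = frozenset({assessment("PM3"), assessment("PM6"), assessment("PM2")})
        flags = Flags(phenotype_mismatch=True)
    elif category is C.EXPERT_DECISION:
        manual = frozenset({assessment("PS1"), assessment("PM2")})
        auto = frozenset({assessment("PM2")})
        flags = Flags(expert_reviewed=True)
    elif category is C.FUNCTIONAL_PREDICTION:
        manual = frozenset({assessment("PS1"), assessment("PM2")})
        auto = frozenset(manual | {assessment("BP4")})
        flags = Flags()
    elif category is C.VARIABLE_PENETRANCE:
        manual = frozenset({assessment("PS1"), assessment("PM2")})
        auto = frozenset(manual | {assessment("BS2", "population_frequency")})
        flags = Flags(healthy_in_popdb=True)
    elif category is C.CLINVAR_ENTRY_NOT_IDENTIFIED:
        manual = frozenset({assessment("PS1"), assessment("PP5"), assessment("PP2")})
        auto = frozenset({assessment("PS1"), assessment("PP2")})
        flags = Flags(clinvar_entry_missed=True)
    elif category is C.LATE_NULL_VARIANT:
        manual = frozenset()
        auto = frozenset({assessment("PVS1"), assessment("PM2")})
        flags = Flags(late_null=True)
    else:  # pragma: no cover
        raise ValueError(category)
    manual_class = combine_criteria(manual)
    return VariantComparisonRecord(
        variant_key=key,
        consensus_binary=binarize(manual_class),
        manual_class=manual_class,
        automated_class=combine_criteria(auto),
        case_count=1,
        manual_criteria=manual,
        automated_criteria=auto,
        flags=flags,
        manual_date=_FIXTURE_DATE,
    )


def study_discordance_records() -> list[VariantComparisonRecord]:
    """359 discordant records realizing the published mechanism counts."""
    records = []
    for category, n in TABLE2_COUNTS.items():
        for i in range(n):
            records.append(
                _discordance_template(category, f"{category.value}_{i + 1:03d}")
            )
    return records


def study_consensus_results() -> list[ConsensusResult]:
    """116,721 consensus results reproducing the published inclusion funnel."""
    total, high_conf, conflicts, pos, neg = FUNNEL_COUNTS
    remainder = total - high_conf
    n_insufficient = round(remainder * 0.8)
    n_discordant = remainder - n_insufficient
    results: list[ConsensusResult] = []
    idx = 0

    def key() -> str:
        nonlocal idx
        idx += 1
        return f"cv_{idx:06d}"

    for _ in range(pos):
        results.append(ConsensusResult(key(), HIGH_CONFIDENCE, POSITIVE, 2))
    for _ in range(neg):
        results.append(ConsensusResult(key(), HIGH_CONFIDENCE, NEGATIVE, 2))
    for _ in range(conflicts):
        results.append(ConsensusResult(key(), LAB_CONFLICT, POSITIVE, 2))
    for _ in range(n_insufficient):
        results.append(ConsensusResult(key(), INSUFFICIENT, None, 1))
    for _ in range(n_discordant):
        results.append(ConsensusResult(key(), DISCORDANT, None, 2))
    return results
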