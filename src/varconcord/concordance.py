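"""Per-variant and per-case concordance between automated and manual interpretation.

Interpretations are binarized for carrier-screening reporting: P and LP are
"positive" (clinically actionable), VUS, LB and B are "negative".  Concordance
is tabulated twice — once per unique variant and once weighted by the number
of cases in which the variant was observed — and every discordant variant is
assigned exactly one of nine mechanistic discordance categories.
"""

from __future__ import annotations

import calendar
import enum
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .acmg import Classification, EvidenceAssessment
from .exceptions import ValidationError

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "binarize",
    "reuse_policy",
    "Flags",
    "VariantComparisonRecord",
    "ConfusionTable",
    "DiscordanceCategory",
    "CategoryTabulation",
    "per_variant_table",
    "per_case_table",
    "categorize_discordance",
    "tabulate_categories",
    "round_pct",
]

POSITIVE = "positive"
NEGATIVE = "negative"


def binarize(c: Classification) -> str:
    """Map the five-level class to the reporting dichotomy: P/LP positive, else negative."""
    return POSITIVE if c >= Classification.LP else NEGATIVE


def _add_months(d: date, months: int) -> date:
    year, month0 = divmod(d.month - 1 + months, 12)
    year += d.year
    month = month0 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def reuse_policy(manual_date: date, analysis_date: date) -> str:
    """Decide whether a prior manual interpretation is still current.

    Interpretations are current for six calendar months: strictly less than
    six months elapsed -> ``"reuse"``; six months or more -> ``"re_review"``.
    """
    if manual_date > analysis_date:
        raise ValidationError(
            f"manual date {manual_date} is after analysis date {analysis_date}"
        )
    return "reuse" if analysis_date < _add_months(manual_date, 6) else "re_review"


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, round half up (the convention of the report tables)."""
    if denominator == 0:
        raise ValidationError("percentage of an empty total is undefined")
    pct = Decimal(numerator) / Decimal(denominator) * Decimal(100)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Flags:
    """Annotation flags attached to a variant comparison record."""

    late_null: bool = False
    phenotype_mismatch: bool = False
    subpop_freq_elevated: bool = False
    healthy_in_popdb: bool = False
    clinvar_entry_missed: bool = False
    literature_identified: bool = False
    expert_reviewed: bool = False

    FLAG_NAMES = (
        "late_null",
        "phenotype_mismatch",
        "subpop_freq_elevated",
        "healthy_in_popdb",
        "clinvar_entry_missed",
        "literature_identified",
        "expert_reviewed",
    )

    def active(self) -> tuple[str, ...]:
        return tuple(n for n in self.FLAG_NAMES if getattr(self, n))


@dataclass(frozen=True)
class VariantComparisonRecord:
    """Paired manual/automated interpretation of one variant, with its case count."""

    variant_key: str
    consensus_binary: str
    manual_class: Classification
    automated_class: Classification
    case_count: int
    manual_criteria: frozenset[EvidenceAssessment] = frozenset()
    automated_criteria: frozenset[EvidenceAssessment] = frozenset()
    flags: Flags = field(default_factory=Flags)
    manual_date: date = date(2020, 11, 3)

    def __post_init__(self) -> None:
        if not self.variant_key:
            raise ValidationError("variant_key must be non-empty")
        if self.consensus_binary not in (POSITIVE, NEGATIVE):
            raise ValidationError(
                f"consensus_binary must be positive|negative, got {self.consensus_binary!r}"
            )
        if self.case_count < 1:
            raise ValidationError(f"case_count must be >= 1, got {self.case_count}")
        if binarize(self.manual_class) != self.consensus_binary:
            raise ValidationError(
                f"{self.variant_key}: manual class {self.manual_class.token} is "
                f"{binarize(self.manual_class)} but consensus_binary is "
                f"{self.consensus_binary}"
            )

    @property
    def automated_binary(self) -> str:
        return binarize(self.automated_class)

    @property
    def is_discordant(self) -> bool:
        return self.automated_binary != self.consensus_binary


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of automated calls against manual consensus.

    Cells are counts (unweighted variants, or cases when weighted by case
    count).  Percentages are computed within each manual column at one
    decimal, round half up.
    """

    auto_pos_manual_pos: int
    auto_neg_manual_pos: int
    auto_pos_manual_neg: int
    auto_neg_manual_neg: int

    def __post_init__(self) -> None:
        for cell in self.cells():
            if cell < 0:
                raise ValidationError("confusion table cells must be non-negative")

    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.auto_pos_manual_pos,
            self.auto_neg_manual_pos,
            self.auto_pos_manual_neg,
            self.auto_neg_manual_neg,
        )

    @property
    def manual_positive_total(self) -> int:
        return self.auto_pos_manual_pos + self.auto_neg_manual_pos

    @property
    def manual_negative_total(self) -> int:
        return self.auto_pos_manual_neg + self.auto_neg_manual_neg

    @property
    def automated_positive_total(self) -> int:
        return self.auto_pos_manual_pos + self.auto_pos_manual_neg

    @property
    def automated_negative_total(self) -> int:
        return self.auto_neg_manual_pos + self.auto_neg_manual_neg

    @property
    def grand_total(self) -> int:
        return sum(self.cells())

    @property
    def concordant_total(self) -> int:
        return self.auto_pos_manual_pos + self.auto_neg_manual_neg

    def manual_positive_pcts(self) -> tuple[float, float]:
        """(automated positive %, automated negative %) within the manual-positive column."""
        t = self.manual_positive_total
        return round_pct(self.auto_pos_manual_pos, t), round_pct(self.auto_neg_manual_pos, t)

    def manual_negative_pcts(self) -> tuple[float, float]:
        """(automated positive %, automated negative %) within the manual-negative column."""
        t = self.manual_negative_total
        return round_pct(self.auto_pos_manual_neg, t), round_pct(self.auto_neg_manual_neg, t)

    def overall_concordance_pct(self) -> float:
        return round_pct(self.concordant_total, self.grand_total)

    def to_dataframe(self) -> pd.DataFrame:
        """Render the table with counts and column percentages, report style."""
        pos_pcts = self.manual_positive_pcts() if self.manual_positive_total else ("-", "-")
        neg_pcts = self.manual_negative_pcts() if self.manual_negative_total else ("-", "-")
        return pd.DataFrame(
            {
                "manual_positive": [
                    f"{self.auto_pos_manual_pos} ({pos_pcts[0]})",
                    f"{self.auto_neg_manual_pos} ({pos_pcts[1]})",
                    str(self.manual_positive_total),
                ],
                "manual_negative": [
                    f"{self.auto_pos_manual_neg} ({neg_pcts[0]})",
                    f"{self.auto_neg_manual_neg} ({neg_pcts[1]})",
                    str(self.manual_negative_total),
                ],
                "total": ["", "", str(self.grand_total)],
            },
            index=["automated_positive", "automated_negative", "total"],
        )


def _tabulate(records: Sequence[VariantComparisonRecord], weighted: bool) -> ConfusionTable:
    if not records:
        raise ValidationError("no analyzable records")
    cells = {(POSITIVE, POSITIVE): 0, (NEGATIVE, POSITIVE): 0,
             (POSITIVE, NEGATIVE): 0, (NEGATIVE, NEGATIVE): 0}
    for r in records:
        cells[(r.automated_binary, r.consensus_binary)] += r.case_count if weighted else 1
    return ConfusionTable(
        auto_pos_manual_pos=cells[(POSITIVE, POSITIVE)],
        auto_neg_manual_pos=cells[(NEGATIVE, POSITIVE)],
        auto_pos_manual_neg=cells[(POSITIVE, NEGATIVE)],
        auto_neg_manual_neg=cells[(NEGATIVE, NEGATIVE)],
    )


def per_variant_table(records: Sequence[VariantComparisonRecord]) -> ConfusionTable:
    """Cross-tabulate automated against manual calls, one unit per unique variant."""
    return _tabulate(records, weighted=False)


def per_case_table(records: Sequence[VariantComparisonRecord]) -> ConfusionTable:
    """Cross-tabulate weighted by case count, so common variants dominate.

    The grand total equals the number of observations in the cohort; a
    discordant high-frequency variant is amplified accordingly.
    """
    return _tabulate(records, weighted=True)


class DiscordanceCategory(enum.Enum):
    """The nine mechanistic reasons a discordance can arise."""

    CASE_CRITERIA_NOT_INVOKED = "case_criteria_not_invoked"
    HIGH_FREQUENCY_PATHOGENIC = "high_frequency_pathogenic"
    FUNCTIONAL_CRITERIA_NOT_INVOKED = "functional_criteria_not_invoked"
    ATYPICAL_PHENOTYPE = "atypical_phenotype"
    EXPERT_DECISION = "expert_decision"
    FUNCTIONAL_PREDICTION = "functional_prediction"
    VARIABLE_PENETRANCE = "variable_penetrance"
    CLINVAR_ENTRY_NOT_IDENTIFIED = "clinvar_entry_not_identified"
    LATE_NULL_VARIANT = "late_null_variant"


#: Human-readable labels used in rendered reports.
CATEGORY_LABELS: dict[DiscordanceCategory, str] = {
    DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED: "Case criteria not invoked by automation",
    DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC: "High-frequency pathogenic variant",
    DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED: "Functional criteria not invoked by automation",
    DiscordanceCategory.ATYPICAL_PHENOTYPE: "Atypical, subclinical, or somatic phenotype",
    DiscordanceCategory.EXPERT_DECISION: "Expert decision",
    DiscordanceCategory.FUNCTIONAL_PREDICTION: "Functional prediction discordance",
    DiscordanceCategory.VARIABLE_PENETRANCE: "Variable penetrance",
    DiscordanceCategory.CLINVAR_ENTRY_NOT_IDENTIFIED: "ClinVar entry not identified by automated program",
    DiscordanceCategory.LATE_NULL_VARIANT: "Late null variant",
}

_CASE_CODES = frozenset({"PM3", "PP1", "BS2", "BP2"})
_FUNCTIONAL_CODES = frozenset({"PS3", "BS3"})
_PREDICTION_CODES = frozenset({"PM1", "PP3", "BP4"})
_REPUTABLE_SOURCE_CODES = frozenset({"PP5", "BP6"})


def categorize_discordance(r: VariantComparisonRecord) -> DiscordanceCategory:
    """Assign one mechanistic category to a discordant record.

    Rules are applied in a fixed priority order so every discordance maps to
    exactly one category; specific mechanisms (late null, missed ClinVar
    entry, atypical phenotype, sub-population frequency, variable penetrance)
    are tested before the generic literature-case / functional-study /
    in-silico categories, with expert decision as the fallback.
    """
    if not r.is_discordant:
        raise ValidationError(
            f"{r.variant_key}: record is concordant; no discordance category applies"
        )
    manual_ids = {a.code.code_id for a in r.manual_criteria}
    auto_ids = {a.code.code_id for a in r.automated_criteria}
    auto_only = auto_ids - manual_ids
    manual_only = manual_ids - auto_ids
    sym_diff = auto_only | manual_only

    if "PVS1" in auto_only and r.flags.late_null:
        return DiscordanceCategory.LATE_NULL_VARIANT
    if r.flags.clinvar_entry_missed and manual_only & _REPUTABLE_SOURCE_CODES:
        return DiscordanceCategory.CLINVAR_ENTRY_NOT_IDENTIFIED
    if r.flags.phenotype_mismatch and auto_only & _CASE_CODES:
        return DiscordanceCategory.ATYPICAL_PHENOTYPE
    if r.flags.subpop_freq_elevated and "BS1" in auto_only and r.consensus_binary == POSITIVE:
        return DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC
    if r.flags.healthy_in_popdb and "BS2" in auto_only and r.consensus_binary == POSITIVE:
        return DiscordanceCategory.VARIABLE_PENETRANCE
    if any(
        a.code.code_id in manual_only
        and a.code.code_id in _CASE_CODES
        and a.source == "literature_case"
        for a in r.manual_criteria
    ):
        return DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED
    if manual_only & _FUNCTIONAL_CODES:
        return DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED
    if sym_diff and sym_diff <= _PREDICTION_CODES:
        return DiscordanceCategory.FUNCTIONAL_PREDICTION
    return DiscordanceCategory.EXPERT_DECISION


@dataclass(frozen=True)
class CategoryTabulation:
    """Per-category discordance counts with percentages of the discordant total."""

    counts: tuple[tuple[DiscordanceCategory, int], ...]  # descending by count

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def percentages(self) -> tuple[float, ...]:
        return tuple(round_pct(n, self.total) for _, n in self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.counts:
            return pd.DataFrame(columns=["reason", "variant_count", "percent"])
        pcts = self.percentages()
        return pd.DataFrame(
            {
                "reason": [CATEGORY_LABELS[c] for c, _ in self.counts],
                "variant_count": [n for _, n in self.counts],
                "percent": list(pcts),
            }
        )


def tabulate_categories(
    records: Iterable[VariantComparisonRecord],
    categories: Optional[Sequence[DiscordanceCategory]] = None,
) -> CategoryTabulation:
    """Count discordant records per category, sorted by descending count.

    Categories are derived with :func:`categorize_discordance` unless
    precomputed labels are supplied.  Empty input yields an empty tabulation
    with total 0.
    """
    records = list(records)
    if categories is None:
        categories = [categorize_discordance(r) for r in records]
    else:
        categories = list(categories)
        if len(categories) != len(records):
            raise ValidationError("one category per record required")
    tally: dict[DiscordanceCategory, int] = {}
    for c in categories:
        tally[c] = tally.get(c, 0) + 1
    order = list(DiscordanceCategory)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], order.index(kv[0])))
    return CategoryTabulation(counts=tuple(ranked))
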