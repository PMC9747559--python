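"""Synthetic cohorts with the statistical structure of a carrier-screening study.

The generator produces, from a seeded configuration, (a) multi-submitter
archive submissions whose consensus funnel matches configured fractions,
(b) paired manual/automated comparison records in which discordance is
*injected* through one of the nine mechanistic categories, with the ground
truth retained, and (c) heavy-tailed per-variant case counts in which
discordant positive variants are amplified — the feature that makes per-case
discordance exceed per-variant discordance.

Every discordance is constructed so that the category classifier recovers the
injected mechanism exactly, and so that the automated classification really
does fall on the other side of the positive/negative divide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .acmg import (
    CODES,
    Classification,
    EvidenceAssessment,
    assessment,
    combine_criteria,
    sample_criteria_for_class,
)
from .concordance import (
    NEGATIVE,
    POSITIVE,
    DiscordanceCategory,
    Flags,
    VariantComparisonRecord,
    binarize,
    categorize_discordance,
)
from .consensus import SubmissionRecord
from .exceptions import SamplingError, ValidationError

__all__ = [
    "CaseCountModel",
    "SubmitterPool",
    "CohortConfig",
    "SyntheticCohort",
    "study_shaped_config",
    "generate_cohort",
    "inject_discordance",
    "sample_case_counts",
    "MECHANISM_STRATUM",
    "STUDY_MECHANISM_COUNTS",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class CaseCountModel:
    """Heavy-tailed case-count family with a discordant-positive amplifier.

    ``family`` is ``"zipf"`` (discrete power law, parameter ``exponent`` > 1)
    or ``"lognormal"`` (parameters ``mu``/``sigma`` on the log scale, rounded
    to integers with a floor of 1).  ``amplification`` (>= 1) multiplies the
    expected count of records flagged as discordant positives.
    """

    family: str = "lognormal"
    exponent: float = 2.5
    mu: float = 0.0
    sigma: float = 0.0
    amplification: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("zipf", "lognormal"):
            raise ValidationError(f"unknown case-count family {self.family!r}")
        if self.family == "zipf" and self.exponent <= 1.0:
            raise ValidationError("zipf exponent must be > 1")
        if self.sigma < 0:
            raise ValidationError("lognormal sigma must be >= 0")
        if self.amplification < 1.0:
            raise ValidationError("amplification must be >= 1")


@dataclass(frozen=True)
class SubmitterPool:
    """Submitter identifiers; only the qualifying subset feeds the consensus."""

    qualifying: tuple[str, ...] = tuple(f"lab_{i:02d}" for i in range(1, 7))
    other: tuple[str, ...] = tuple(f"lab_{i:02d}" for i in range(7, 11))

    def __post_init__(self) -> None:
        if len(self.qualifying) < 5:
            raise ValidationError("need at least 5 qualifying submitters")
        if set(self.qualifying) & set(self.other):
            raise ValidationError("qualifying and other submitter sets overlap")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; the seed is mandatory."""

    n_variants: int
    seed: int
    high_confidence_fraction: float = 5_548 / 116_721
    lab_conflict_rate: float = 17 / 5_548
    positive_fraction: float = 0.235
    mechanism_rates: dict[DiscordanceCategory, float] = field(default_factory=dict)
    case_counts: CaseCountModel = field(default_factory=CaseCountModel)
    submitters: SubmitterPool = field(default_factory=SubmitterPool)
    cutoff_date: date = date(2020, 11, 4)

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValidationError("n_variants must be positive")
        for name in ("high_confidence_fraction", "lab_conflict_rate", "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for mech, rate in self.mechanism_rates.items():
            if not isinstance(mech, DiscordanceCategory):
                raise ValidationError(f"unknown mechanism {mech!r}")
            if rate < 0:
                raise ValidationError(f"negative rate for {mech.value}")
        for stratum in (POSITIVE, NEGATIVE):
            s = sum(
                rate
                for mech, rate in self.mechanism_rates.items()
                if MECHANISM_STRATUM[mech] == stratum
            )
            if s > 1.0 + 1e-12:
                raise ValidationError(
                    f"mechanism rates for the {stratum} stratum sum to {s} > 1"
                )

    def stratum_rates(self, stratum: str) -> list[tuple[DiscordanceCategory, float]]:
        return [
            (mech, rate)
            for mech, rate in self.mechanism_rates.items()
            if MECHANISM_STRATUM[mech] == stratum and rate > 0
        ]


#: Consensus stratum on which each mechanism operates in this generator.
#: False-negative mechanisms act on consensus-positive variants (automation
#: calls them negative); false-positive mechanisms act on consensus-negative
#: variants.
MECHANISM_STRATUM: dict[DiscordanceCategory, str] = {
    DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED: POSITIVE,
    DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC: POSITIVE,
    DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED: POSITIVE,
    DiscordanceCategory.EXPERT_DECISION: POSITIVE,
    DiscordanceCategory.VARIABLE_PENETRANCE: POSITIVE,
    DiscordanceCategory.CLINVAR_ENTRY_NOT_IDENTIFIED: POSITIVE,
    DiscordanceCategory.ATYPICAL_PHENOTYPE: NEGATIVE,
    DiscordanceCategory.FUNCTIONAL_PREDICTION: NEGATIVE,
    DiscordanceCategory.LATE_NULL_VARIANT: NEGATIVE,
}

#: Published per-mechanism discordance counts used by the study-shaped preset.
STUDY_MECHANISM_COUNTS: dict[DiscordanceCategory, int] = {
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

_STUDY_POSITIVE_RETAINED = 1_299
_STUDY_NEGATIVE_RETAINED = 4_232


def study_shaped_config(scale: float = 0.1, seed: int = 0) -> CohortConfig:
    """Preset emulating the study cohort's marginal structure.

    At the default 1/10 scale the cohort holds ~11,672 variants funnelling to
    ~553 retained high-confidence variants with a 23.5%/76.5% positive/negative
    split, the published mechanism mix in expectation, and lognormal case
    counts whose mean (~362 cases per retained variant) reproduces roughly two
    million observations at full scale, amplified six-fold on discordant
    positives.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    rates = {}
    for mech, count in STUDY_MECHANISM_COUNTS.items():
        denom = (
            _STUDY_POSITIVE_RETAINED
            if MECHANISM_STRATUM[mech] == POSITIVE
            else _STUDY_NEGATIVE_RETAINED
        )
        rates[mech] = count / denom
    # lognormal mean exp(mu + sigma^2/2) ~= 362 cases/variant, sigma 1.5
    sigma = 1.5
    mu = math.log(2_004_273 / 5_531) - sigma**2 / 2
    return CohortConfig(
        n_variants=max(1, round(116_721 * scale)),
        seed=seed,
        positive_fraction=_STUDY_POSITIVE_RETAINED
        / (_STUDY_POSITIVE_RETAINED + _STUDY_NEGATIVE_RETAINED),
        mechanism_rates=rates,
        case_counts=CaseCountModel(
            family="lognormal", mu=mu, sigma=sigma, amplification=6.0
        ),
    )


# ---------------------------------------------------------------------------
# Case counts


def sample_case_counts(
    n: int,
    model: CaseCountModel,
    discordant_positive_mask: Sequence[bool],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` heavy-tailed case counts (integers >= 1).

    Records flagged in ``discordant_positive_mask`` get the model's
    amplification: for the lognormal family the log-mean is shifted by
    ``log(amplification)``; for the Zipf family the count is a sum of
    ``floor(A) + Bernoulli(frac(A))`` independent draws.  Either construction
    scales the expected count by exactly the amplification factor.
    """
    mask = np.asarray(discordant_positive_mask, dtype=bool)
    if mask.shape != (n,):
        raise ValidationError("mask length must equal n")
    a = model.amplification
    if model.family == "lognormal":
        mu = np.where(mask, model.mu + math.log(a), model.mu)
        raw = rng.lognormal(mean=0.0, sigma=model.sigma, size=n) * np.exp(mu)
        counts = np.maximum(1, np.rint(raw)).astype(np.int64)
    else:
        counts = rng.zipf(model.exponent, size=n).astype(np.int64)
        if a > 1.0:
            extra_n = int(math.floor(a)) - 1
            frac = a - math.floor(a)
            for i in np.nonzero(mask)[0]:
                k = extra_n + (1 if rng.random() < frac else 0)
                if k > 0:
                    counts[i] += int(rng.zipf(model.exponent, size=k).sum())
    return counts


# ---------------------------------------------------------------------------
# Discordance injection


class _Retry(Exception):
    """Internal: the sampled manual view is incompatible with the mechanism."""


#: Mechanisms whose defining rule only makes sense on one consensus stratum.
_SINGLE_STRATUM_MECHANISMS: dict[DiscordanceCategory, str] = {
    DiscordanceCategory.CASE_CRITERIA_NOT_INVOKED: POSITIVE,
    DiscordanceCategory.HIGH_FREQUENCY_PATHOGENIC: POSITIVE,
    DiscordanceCategory.FUNCTIONAL_CRITERIA_NOT_INVOKED: POSITIVE,
    DiscordanceCategory.VARIABLE_PENETRANCE: POSITIVE,
    DiscordanceCategory.LATE_NULL_VARIANT: NEGATIVE,
}


_CASE_CODES = ("PM3", "PP1", "BS2", "BP2")
_STRENGTH_ORDER = ("supporting", "moderate", "strong", "very_strong", "stand_alone")


def _ids(assessments: Iterable[EvidenceAssessment]) -> set[str]:
    return {a.code.code_id for a in assessments}


def _without(
    assessments: frozenset[EvidenceAssessment], code_ids: Iterable[str]
) -> frozenset[EvidenceAssessment]:
    drop = set(code_ids)
    return frozenset(a for a in assessments if a.code.code_id not in drop)


def _benign_part(assessments: frozenset[EvidenceAssessment]) -> set[str]:
    return {a.code.code_id for a in assessments if a.code.direction == "benign"}


def _strip_until_negative(
    auto: frozenset[EvidenceAssessment], protected: set[str]
) -> frozenset[EvidenceAssessment]:
    """Remove unprotected pathogenic codes, weakest first, until the class is negative."""
    while binarize(combine_criteria(auto)) == POSITIVE:
        removable = sorted(
            (
                a
                for a in auto
                if a.code.direction == "pathogenic" and a.code.code_id not in protected
            ),
            key=lambda a: (_STRENGTH_ORDER.index(a.code.strength), a.code.code_id),
        )
        if not removable:
            raise _Retry
        auto = frozenset(auto - {removable[0]})
    return auto


def _add_until_positive(
    auto: frozenset[EvidenceAssessment], fillers: Sequence[str]
) -> frozenset[EvidenceAssessment]:
    """Add filler pathogenic codes (skipping ones already present) until positive."""
    present = _ids(auto)
    for cid in fillers:
        if binarize(combine_criteria(auto)) == POSITIVE:
            return auto
        if cid in present:
            continue
        auto = frozenset(auto | {assessment(cid)})
        present.add(cid)
    if binarize(combine_criteria(auto)) == POSITIVE:
        return auto
    raise _Retry


def _inject_once(
    manual: frozenset[EvidenceAssessment],
    consensus: str,
    mechanism: DiscordanceCategory,
    rng: np.random.Generator,
) -> tuple[frozenset[EvidenceAssessment], Flags]:
    """One attempt at building the automated view; raises _Retry when the
    manual set cannot express the mechanism."""
    mids = _ids(manual)
    C = DiscordanceCategory

    if mechanism is C.CASE_CRITERIA_NOT_INVOKED:
        lit_case = {
            a.code.code_id
            for a in manual
            if a.code.code_id in ("PM3", "PP1") and a.source == "literature_case"
        }
        if not lit_case:
            raise _Retry
        auto = _without(manual, lit_case)
        auto = _strip_until_negative(auto, protected=set(_CASE_CODES) | {"PVS1"})
        return auto, Flags(literature_identified=True)

    if mechanism is C.HIGH_FREQUENCY_PATHOGENIC:
        if "BS1" in mids:
            raise _Retry
        auto = frozenset(manual | {assessment("BS1", "population_frequency")})
        return auto, Flags(subpop_freq_elevated=True)

    if mechanism is C.FUNCTIONAL_CRITERIA_NOT_INVOKED:
        if "PS3" not in mids and "BS3" not in mids:
            raise _Retry
        auto = _without(manual, ("PS3", "BS3"))
        auto = _strip_until_negative(auto, protected=set(_CASE_CODES))
        return auto, Flags()

    if mechanism is C.VARIABLE_PENETRANCE:
        if "BS2" in mids:
            raise _Retry
        auto = frozenset(manual | {assessment("BS2", "population_frequency")})
        return auto, Flags(healthy_in_popdb=True)

    if mechanism is C.CLINVAR_ENTRY_NOT_IDENTIFIED:
        if consensus == POSITIVE:
            if "PP5" not in mids:
                raise _Retry
            auto = _without(manual, ("PP5", "BP6"))
            auto = _strip_until_negative(auto, protected=set())
            return auto, Flags(clinvar_entry_missed=True)
        if "BP6" not in mids:
            raise _Retry
        auto = _without(manual, _benign_part(manual))
        auto = _add_until_positive(auto, ("PM2", "PM4", "PS1"))
        return auto, Flags(clinvar_entry_missed=True)

    if mechanism is C.EXPERT_DECISION:
        protected = set(_CASE_CODES) | {"PS3", "BS3", "PM1", "PP3", "BP4"}
        if consensus == POSITIVE:
            auto = _strip_until_negative(manual, protected=protected)
            if _ids(manual) == _ids(auto):
                raise _Retry
            return auto, Flags()
        if mids & {"BS2", "BP2", "BS3"}:
            raise _Retry
        auto = _without(manual, _benign_part(manual))
        auto = _add_until_positive(auto, ("PS4", "PM6", "PM5"))
        return auto, Flags()

    if mechanism is C.FUNCTIONAL_PREDICTION:
        edits: list[tuple[set[str], set[str]]] = [  # (add, remove)
            ({"BP4"}, set()),
            (set(), {"PP3"}),
            (set(), {"PM1"}),
            (set(), {"PM1", "PP3"}),
            ({"PM1", "PP3"}, set()),
            ({"PM1"}, set()),
            ({"PP3"}, set()),
            (set(), {"BP4"}),
            ({"PM1", "PP3"}, {"BP4"}),
        ]
        want = NEGATIVE if consensus == POSITIVE else POSITIVE
        for add, remove in edits:
            if not remove <= mids or add & mids:
                continue
            auto = _without(manual, remove)
            auto = frozenset(auto | {assessment(cid, "in_silico") for cid in add})
            if binarize(combine_criteria(auto)) == want:
                return auto, Flags()
        raise _Retry

    if mechanism is C.ATYPICAL_PHENOTYPE:
        if consensus == POSITIVE:
            addable = [c for c in ("BS2", "BP2") if c not in mids]
            if not addable:
                raise _Retry
            auto = frozenset(manual | {assessment(addable[0], "literature_case")})
            return auto, Flags(phenotype_mismatch=True)
        auto = _without(manual, _benign_part(manual))
        case_add = [c for c in ("PM3", "PP1") if c not in mids]
        if not case_add:
            raise _Retry
        auto = frozenset(auto | {assessment(case_add[0], "literature_case")})
        auto = _add_until_positive(auto, ("PM6", "PM2", "PM4", "PS4"))
        return auto, Flags(phenotype_mismatch=True)

    if mechanism is C.LATE_NULL_VARIANT:
        if consensus != NEGATIVE:
            raise ValidationError("late_null_variant applies to consensus-negative variants")
        if "PVS1" in mids:
            raise _Retry
        auto = _without(manual, _benign_part(manual))
        auto = frozenset(auto | {assessment("PVS1")})
        auto = _add_until_positive(auto, ("PM2", "PM4"))
        return auto, Flags(late_null=True)

    raise ValidationError(f"unknown mechanism {mechanism!r}")


def inject_discordance(
    record: VariantComparisonRecord,
    mechanism: DiscordanceCategory,
    rng: np.random.Generator,
    max_attempts: int = 1,
) -> VariantComparisonRecord:
    """Edit a concordant record's automated view so it becomes discordant via
    ``mechanism``.

    The returned record satisfies the round-trip contract: its automated
    binary call differs from the consensus, and
    :func:`~varconcord.concordance.categorize_discordance` recovers exactly
    the injected mechanism.  When the record's manual criteria cannot express
    the mechanism a :class:`SamplingError` is raised so the caller can
    resample the manual view.
    """
    if binarize(record.automated_class) != record.consensus_binary:
        raise ValidationError("inject_discordance expects a concordant record")
    if mechanism in _SINGLE_STRATUM_MECHANISMS:
        required = _SINGLE_STRATUM_MECHANISMS[mechanism]
        if record.consensus_binary != required:
            raise ValidationError(
                f"{mechanism.value} applies to {required}-consensus variants"
            )
    last_error: Optional[BaseException] = None
    for _ in range(max_attempts):
        try:
            auto, flags = _inject_once(
                record.manual_criteria, record.consensus_binary, mechanism, rng
            )
        except _Retry as exc:
            last_error = exc
            continue
        candidate = replace(
            record,
            automated_criteria=auto,
            automated_class=combine_criteria(auto),
            flags=flags,
        )
        if not candidate.is_discordant:
            last_error = _Retry()
            continue
        recovered = categorize_discordance(candidate)
        if recovered is not mechanism:  # pragma: no cover - construction guarantees
            raise SamplingError(
                f"injection produced category {recovered.value}, wanted {mechanism.value}"
            )
        return candidate
    raise SamplingError(
        f"manual criteria {sorted(_ids(record.manual_criteria))} cannot express "
        f"mechanism {mechanism.value}"
    ) from last_error


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: submissions, comparison records, and ground truth."""

    config: CohortConfig
    submissions: tuple[SubmissionRecord, ...]
    comparisons: tuple[VariantComparisonRecord, ...]
    mechanism_truth: dict[str, DiscordanceCategory]
    internal_labels: dict[str, str]


_POSITIVE_CLASSES = (Classification.LP, Classification.P)
_POSITIVE_CLASS_P = (0.55, 0.45)
_NEGATIVE_CLASSES = (Classification.VUS, Classification.LB, Classification.B)
_NEGATIVE_CLASS_P = (0.60, 0.25, 0.15)


def _draw_class(stratum: str, rng: np.random.Generator) -> Classification:
    if stratum == POSITIVE:
        return _POSITIVE_CLASSES[rng.choice(2, p=_POSITIVE_CLASS_P)]
    return _NEGATIVE_CLASSES[rng.choice(3, p=_NEGATIVE_CLASS_P)]


def _jitter_class(stratum: str, rng: np.random.Generator) -> Classification:
    """A submission-level class within the stratum (P<->LP, VUS/LB/B jitter)."""
    return _draw_class(stratum, rng)


def _submission_date(cutoff: date, rng: np.random.Generator) -> date:
    return cutoff - timedelta(days=int(rng.integers(1, 366)))


def _make_submissions(
    key: str,
    stratum: str,
    pool: SubmitterPool,
    cutoff: date,
    rng: np.random.Generator,
    k: int,
) -> list[SubmissionRecord]:
    labs = rng.choice(len(pool.qualifying), size=k, replace=False)
    return [
        SubmissionRecord(
            variant_key=key,
            submitter_id=pool.qualifying[i],
            classification=_jitter_class(stratum, rng),
            assertion_criteria_met=True,
            submission_date=_submission_date(cutoff, rng),
        )
        for i in labs
    ]


def generate_cohort(config: CohortConfig, max_manual_resamples: int = 200) -> SyntheticCohort:
    """Generate a cohort; identical config and seed give identical output.

    Each variant first receives a funnel fate (high confidence vs
    insufficient/discordant archive data); high-confidence variants receive a
    consensus stratum, a manual class and criteria set, optionally an injected
    discordance mechanism, qualifying submissions consistent with the
    consensus, and a heavy-tailed case count with amplification for discordant
    positives.  Lab-conflict variants receive an internal label on the
    opposite side of their archive consensus and produce no comparison record.
    """
    rng = np.random.default_rng(config.seed)
    submissions: list[SubmissionRecord] = []
    pending: list[dict] = []
    mechanism_truth: dict[str, DiscordanceCategory] = {}
    internal_labels: dict[str, str] = {}
    pos_rates = config.stratum_rates(POSITIVE)
    neg_rates = config.stratum_rates(NEGATIVE)

    for i in range(config.n_variants):
        key = f"var_{i + 1:06d}"
        if rng.random() >= config.high_confidence_fraction:
            # Insufficient archive data or discordant submitters, 50/50.
            stratum = POSITIVE if rng.random() < config.positive_fraction else NEGATIVE
            if rng.random() < 0.5:
                submissions.extend(
                    _make_submissions(key, stratum, config.submitters, config.cutoff_date, rng, 1)
                )
            else:
                labs = rng.choice(len(config.submitters.qualifying), size=2, replace=False)
                for lab_idx, sub_stratum in zip(labs, (POSITIVE, NEGATIVE)):
                    submissions.append(
                        SubmissionRecord(
                            variant_key=key,
                            submitter_id=config.submitters.qualifying[lab_idx],
                            classification=_jitter_class(sub_stratum, rng),
                            assertion_criteria_met=True,
                            submission_date=_submission_date(config.cutoff_date, rng),
                        )
                    )
            continue

        consensus = POSITIVE if rng.random() < config.positive_fraction else NEGATIVE
        n_subs = int(rng.integers(2, 6))
        submissions.extend(
            _make_submissions(key, consensus, config.submitters, config.cutoff_date, rng, n_subs)
        )

        if rng.random() < config.lab_conflict_rate:
            internal = NEGATIVE if consensus == POSITIVE else POSITIVE
            internal_labels[key] = internal
            continue
        internal_labels[key] = consensus

        rates = pos_rates if consensus == POSITIVE else neg_rates
        total_rate = sum(r for _, r in rates)
        mechanism: Optional[DiscordanceCategory] = None
        if rates and rng.random() < total_rate:
            u = rng.random() * total_rate
            acc = 0.0
            for mech, r in rates:
                acc += r
                if u <= acc:
                    mechanism = mech
                    break
            else:  # pragma: no cover - float guard
                mechanism = rates[-1][0]

        manual_date = config.cutoff_date - timedelta(days=int(rng.integers(1, 181)))
        record = None
        for _ in range(max_manual_resamples):
            manual_class = _draw_class(consensus, rng)
            manual = sample_criteria_for_class(manual_class, rng)
            base = VariantComparisonRecord(
                variant_key=key,
                consensus_binary=consensus,
                manual_class=manual_class,
                automated_class=manual_class,
                case_count=1,
                manual_criteria=manual,
                automated_criteria=manual,
                manual_date=manual_date,
            )
            if mechanism is None:
                record = base
                break
            try:
                record = inject_discordance(base, mechanism, rng)
                break
            except SamplingError:
                continue
        if record is None:
            raise SamplingError(
                f"could not realize mechanism {mechanism.value} for {key} within "
                f"{max_manual_resamples} manual resamples"
            )
        if mechanism is not None:
            mechanism_truth[key] = mechanism
        pending.append({"record": record})

    mask = [p["record"].is_discordant and p["record"].consensus_binary == POSITIVE
            for p in pending]
    counts = sample_case_counts(len(pending), config.case_counts, mask, rng)
    comparisons = tuple(
        replace(p["record"], case_count=int(c)) for p, c in zip(pending, counts)
    )
    return SyntheticCohort(
        config=config,
        submissions=tuple(submissions),
        comparisons=comparisons,
        mechanism_truth=mechanism_truth,
        internal_labels=internal_labels,
    )
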