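"""High-confidence consensus from multi-submitter ClinVar-style assertions.

A variant's archive entry is "high confidence" when at least two qualifying
submissions (whitelisted submitter, assertion criteria provided, dated
strictly before the snapshot cutoff) agree at the positive/negative level.
Sub-type disagreement within a stratum (P vs LP, B vs LB) is tolerated.
Variants with fewer than two qualifying submissions are insufficient; mixed
strata are discordant; and a high-confidence consensus that contradicts the
analysing laboratory's own manual interpretation is flagged as a lab conflict
and excluded downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from .acmg import Classification
from .concordance import NEGATIVE, POSITIVE, binarize, round_pct
from .exceptions import ValidationError

__all__ = [
    "SubmissionRecord",
    "ConsensusResult",
    "FunnelCounts",
    "filter_qualifying",
    "build_consensus",
    "apply_lab_conflict_filter",
    "funnel_report",
    "consensus_pipeline",
    "HIGH_CONFIDENCE",
    "INSUFFICIENT",
    "DISCORDANT",
    "LAB_CONFLICT",
]

HIGH_CONFIDENCE = "high_confidence"
INSUFFICIENT = "insufficient"
DISCORDANT = "discordant"
LAB_CONFLICT = "lab_conflict"

_STATUSES = (HIGH_CONFIDENCE, INSUFFICIENT, DISCORDANT, LAB_CONFLICT)


@dataclass(frozen=True)
class SubmissionRecord:
    """One submitter's assertion for one variant."""

    variant_key: str
    submitter_id: str
    classification: Classification
    assertion_criteria_met: bool
    submission_date: date

    def __post_init__(self) -> None:
        if not self.variant_key:
            raise ValidationError("variant_key must be non-empty")
        if not self.submitter_id:
            raise ValidationError("submitter_id must be non-empty")


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus status and binary label for one variant."""

    variant_key: str
    status: str
    consensus_binary: Optional[str]  # positive | negative | None
    n_qualifying_submissions: int

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValidationError(f"unknown consensus status {self.status!r}")
        if self.n_qualifying_submissions < 0:
            raise ValidationError("n_qualifying_submissions must be >= 0")
        has_label = self.consensus_binary is not None
        needs_label = self.status in (HIGH_CONFIDENCE, LAB_CONFLICT)
        if has_label != needs_label:
            raise ValidationError(
                f"{self.variant_key}: consensus_binary must be set exactly for "
                f"high_confidence/lab_conflict status (status={self.status}, "
                f"binary={self.consensus_binary})"
            )
        if has_label and self.consensus_binary not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"invalid consensus binary {self.consensus_binary!r}")


def filter_qualifying(
    submissions: Sequence[SubmissionRecord],
    qualifying_submitters: Iterable[str],
    cutoff_date: date,
) -> list[SubmissionRecord]:
    """Keep submissions from whitelisted labs, with assertion criteria, dated
    strictly before the cutoff; input order is preserved."""
    whitelist = set(qualifying_submitters)
    return [
        s
        for s in submissions
        if s.submitter_id in whitelist
        and s.assertion_criteria_met
        and s.submission_date < cutoff_date
    ]


def build_consensus(submissions: Sequence[SubmissionRecord]) -> ConsensusResult:
    """Reduce one variant's qualifying submissions to a consensus result.

    Fewer than two submissions -> insufficient; mixed positive/negative
    strata -> discordant; otherwise high confidence with the shared binary
    label (sub-type disagreement within a stratum is allowed).
    """
    if not submissions:
        raise ValidationError("cannot build a consensus from zero submissions")
    keys = {s.variant_key for s in submissions}
    if len(keys) != 1:
        raise ValidationError(f"submissions span multiple variants: {sorted(keys)}")
    key = keys.pop()
    n = len(submissions)
    if n < 2:
        return ConsensusResult(key, INSUFFICIENT, None, n)
    strata = {binarize(s.classification) for s in submissions}
    if len(strata) > 1:
        return ConsensusResult(key, DISCORDANT, None, n)
    return ConsensusResult(key, HIGH_CONFIDENCE, strata.pop(), n)


def apply_lab_conflict_filter(
    consensus: ConsensusResult, internal_manual_binary: str
) -> ConsensusResult:
    """Demote a high-confidence consensus that contradicts the laboratory's own
    manual interpretation to lab_conflict (excluded downstream)."""
    if consensus.status != HIGH_CONFIDENCE:
        raise ValidationError(
            f"lab-conflict filter applies to high-confidence results only, "
            f"got status {consensus.status!r}"
        )
    if internal_manual_binary not in (POSITIVE, NEGATIVE):
        raise ValidationError(f"invalid internal label {internal_manual_binary!r}")
    if internal_manual_binary != consensus.consensus_binary:
        return replace(consensus, status=LAB_CONFLICT)
    return consensus


@dataclass(frozen=True)
class FunnelCounts:
    """Inclusion/exclusion accounting from all variants to the retained set."""

    total: int
    high_confidence: int  # two or more concordant qualifying submissions
    insufficient_or_discordant: int
    lab_conflict: int
    retained: int

    @property
    def lab_conflict_pct(self) -> float:
        return round_pct(self.lab_conflict, self.high_confidence)


def funnel_report(results: Iterable[ConsensusResult]) -> FunnelCounts:
    """Tally consensus statuses into the study funnel.

    ``high_confidence`` counts every variant that met the two-concordant-
    submission bar (including those later demoted to lab_conflict);
    ``retained`` = high_confidence - lab_conflict.
    """
    tally = {s: 0 for s in _STATUSES}
    total = 0
    for r in results:
        tally[r.status] += 1
        total += 1
    high_conf = tally[HIGH_CONFIDENCE] + tally[LAB_CONFLICT]
    return FunnelCounts(
        total=total,
        high_confidence=high_conf,
        insufficient_or_discordant=tally[INSUFFICIENT] + tally[DISCORDANT],
        lab_conflict=tally[LAB_CONFLICT],
        retained=high_conf - tally[LAB_CONFLICT],
    )


def consensus_pipeline(
    submissions: Sequence[SubmissionRecord],
    qualifying_submitters: Iterable[str],
    cutoff_date: date,
    internal_labels: Optional[Mapping[str, str]] = None,
) -> list[ConsensusResult]:
    """Filter, group by variant, build consensus, and apply the lab-conflict filter.

    ``internal_labels`` maps variant_key to the laboratory's own binary call;
    variants absent from the mapping skip the conflict filter.  Results are
    ordered by first appearance of each variant in the input.
    """
    qualifying = filter_qualifying(submissions, qualifying_submitters, cutoff_date)
    order: list[str] = []
    seen: set[str] = set()
    for s in submissions:
        if s.variant_key not in seen:
            seen.add(s.variant_key)
            order.append(s.variant_key)
    grouped: dict[str, list[SubmissionRecord]] = defaultdict(list)
    for s in qualifying:
        grouped[s.variant_key].append(s)
    results = []
    for key in order:
        subs = grouped.get(key, [])
        if not subs:
            results.append(ConsensusResult(key, INSUFFICIENT, None, 0))
            continue
        res = build_consensus(subs)
        if res.status == HIGH_CONFIDENCE and internal_labels and key in internal_labels:
            res = apply_lab_conflict_filter(res, internal_labels[key])
        results.append(res)
    return results
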