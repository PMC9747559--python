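"""ACMG/AMP evidence codes and the rules that combine them into a classification.

The engine models the 28 evidence codes of the ACMG/AMP sequence-variant
guideline (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7), each with a fixed
direction (pathogenic or benign) and strength (stand-alone, very strong,
strong, moderate, supporting), and combines an invoked set of codes into one
of the five classes B < LB < VUS < LP < P.

Beyond the core combining rules it implements three refinements used in
carrier-screening interpretation practice:

* a PVS1 exception for null variants that escape nonsense-mediated decay
  (last exon, or final 50 bp of the penultimate exon), which is only waived
  when clinical cases with LP/P variants downstream of the variant exist;
* an in-silico consensus rule for PP3/BP4 (majority of missense predictors
  for nonsynonymous variants; both splicing predictors concordant for
  synonymous/intronic variants);
* BS1 allele-frequency evidence evaluated either against the maximum
  sub-population frequency (mimicking fully automated tools) or against the
  global frequency (mimicking manual review).

Conflicting evidence is resolved conservatively: whenever a pathogenic
combination fires while any benign-direction evidence is present (or the
converse), the classification defaults to VUS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .exceptions import SamplingError, ValidationError

__all__ = [
    "Classification",
    "EvidenceCode",
    "EvidenceAssessment",
    "TranscriptModel",
    "InSilicoPanel",
    "FrequencyProfile",
    "CODES",
    "CODE_IDS",
    "EVIDENCE_SOURCES",
    "assessment",
    "combine_criteria",
    "check_nmd_escape",
    "apply_pvs1",
    "insilico_consensus",
    "evaluate_bs1",
    "sample_criteria_for_class",
]


class Classification(enum.IntEnum):
    """Five-level variant classification, totally ordered B < LB < VUS < LP < P."""

    B = 0
    LB = 1
    VUS = 2
    LP = 3
    P = 4

    @classmethod
    def from_token(cls, token: str) -> "Classification":
        try:
            return cls[token.strip()]
        except KeyError:
            raise ValidationError(
                f"unknown classification token {token!r}; expected one of "
                f"{', '.join(c.name for c in cls)}"
            ) from None

    @property
    def token(self) -> str:
        return self.name


@dataclass(frozen=True)
class EvidenceCode:
    """One ACMG/AMP evidence code; direction and strength follow from its prefix."""

    code_id: str
    direction: str  # "pathogenic" | "benign"
    strength: str  # "stand_alone" | "very_strong" | "strong" | "moderate" | "supporting"


_PREFIX_TABLE = {
    "PVS": ("pathogenic", "very_strong"),
    "PS": ("pathogenic", "strong"),
    "PM": ("pathogenic", "moderate"),
    "PP": ("pathogenic", "supporting"),
    "BA": ("benign", "stand_alone"),
    "BS": ("benign", "strong"),
    "BP": ("benign", "supporting"),
}

CODE_IDS: tuple[str, ...] = (
    ("PVS1",)
    + tuple(f"PS{i}" for i in range(1, 5))
    + tuple(f"PM{i}" for i in range(1, 7))
    + tuple(f"PP{i}" for i in range(1, 6))
    + ("BA1",)
    + tuple(f"BS{i}" for i in range(1, 5))
    + tuple(f"BP{i}" for i in range(1, 8))
)
assert len(CODE_IDS) == 28


def _make_code(code_id: str) -> EvidenceCode:
    prefix = code_id.rstrip("0123456789")
    direction, strength = _PREFIX_TABLE[prefix]
    return EvidenceCode(code_id=code_id, direction=direction, strength=strength)


CODES: dict[str, EvidenceCode] = {cid: _make_code(cid) for cid in CODE_IDS}

EVIDENCE_SOURCES: tuple[str, ...] = (
    "literature_case",
    "functional_study",
    "population_frequency",
    "in_silico",
    "clinvar_entry",
    "allelic_data",
    "other",
)

# Default provenance for each code family, used when a caller does not say
# where an invoked criterion came from.
_DEFAULT_SOURCES: dict[str, str] = {
    "PM3": "literature_case",
    "PP1": "literature_case",
    "BS2": "literature_case",
    "BP2": "literature_case",
    "PS4": "literature_case",
    "PS3": "functional_study",
    "BS3": "functional_study",
    "BA1": "population_frequency",
    "BS1": "population_frequency",
    "PM2": "population_frequency",
    "PP3": "in_silico",
    "BP4": "in_silico",
    "PP5": "clinvar_entry",
    "BP6": "clinvar_entry",
}


@dataclass(frozen=True)
class EvidenceAssessment:
    """One invoked criterion together with the kind of evidence that supports it."""

    code: EvidenceCode
    source: str = "other"

    def __post_init__(self) -> None:
        if self.code.code_id not in CODES:
            raise ValidationError(f"unknown evidence code {self.code.code_id!r}")
        if self.source not in EVIDENCE_SOURCES:
            raise ValidationError(
                f"unknown evidence source {self.source!r}; expected one of "
                f"{', '.join(EVIDENCE_SOURCES)}"
            )


def assessment(code_id: str, source: Optional[str] = None) -> EvidenceAssessment:
    """Build an :class:`EvidenceAssessment` from a code identifier.

    When ``source`` is omitted, a code-family default is used (e.g. PM3 is a
    literature case criterion, PS3 a functional study, BS1 population
    frequency).
    """
    try:
        code = CODES[code_id]
    except KeyError:
        raise ValidationError(f"unknown evidence code {code_id!r}") from None
    return EvidenceAssessment(code=code, source=source or _DEFAULT_SOURCES.get(code_id, "other"))


def _strength_counts(assessments: Iterable[EvidenceAssessment]):
    """Validate uniqueness per code and tally codes by direction/strength."""
    seen: set[str] = set()
    counts = {
        "pvs": 0, "ps": 0, "pm": 0, "pp": 0,
        "ba": 0, "bs": 0, "bp": 0,
    }
    for a in assessments:
        cid = a.code.code_id
        if cid in seen:
            raise ValidationError(f"duplicate evidence code {cid} in assessment set")
        seen.add(cid)
        key = {
            ("pathogenic", "very_strong"): "pvs",
            ("pathogenic", "strong"): "ps",
            ("pathogenic", "moderate"): "pm",
            ("pathogenic", "supporting"): "pp",
            ("benign", "stand_alone"): "ba",
            ("benign", "strong"): "bs",
            ("benign", "supporting"): "bp",
        }[(a.code.direction, a.code.strength)]
        counts[key] += 1
    return counts


def combine_criteria(assessments: Iterable[EvidenceAssessment]) -> Classification:
    """Combine a set of invoked criteria into a five-level classification.

    Pathogenic combinations
        P:  PVS1 + (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP); or >=2 PS;
            or 1 PS + (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP)
        LP: PVS1 + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM;
            2 PM + >=2 PP; 1 PM + >=4 PP
    Benign combinations
        B:  BA1, or >=2 BS
        LB: 1 BS + 1 BP, or >=2 BP

    If a pathogenic combination fires while any benign-direction assessment is
    present (or a benign combination fires alongside pathogenic-direction
    evidence) the evidence is conflicting and the result is VUS.  When no
    combination fires the result is VUS.

    The result is deterministic and independent of iteration order; a
    duplicate code in the input raises :class:`ValidationError`.
    """
    c = _strength_counts(assessments)
    pvs, ps, pm, pp = c["pvs"], c["ps"], c["pm"], c["pp"]
    ba, bs, bp = c["ba"], c["bs"], c["bp"]

    pathogenic = bool(pvs) and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2)
    pathogenic = pathogenic or ps >= 2
    pathogenic = pathogenic or (
        ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4))
    )
    likely_pathogenic = (
        (bool(pvs) and pm >= 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = bool(ba) or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_level = Classification.P if pathogenic else (
        Classification.LP if likely_pathogenic else None
    )
    benign_level = Classification.B if benign else (
        Classification.LB if likely_benign else None
    )

    has_path_evidence = (pvs + ps + pm + pp) > 0
    has_benign_evidence = (ba + bs + bp) > 0

    if path_level is not None and has_benign_evidence:
        return Classification.VUS
    if benign_level is not None and has_path_evidence:
        return Classification.VUS
    if path_level is not None:
        return path_level
    if benign_level is not None:
        return benign_level
    return Classification.VUS


# ---------------------------------------------------------------------------
# PVS1 / nonsense-mediated decay


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a transcript in transcript coordinates, 5'->3'."""

    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 1:
            raise ValidationError("a transcript needs at least one exon")
        if any(int(x) <= 0 for x in self.exon_lengths):
            raise ValidationError("exon lengths must be positive integers")

    @property
    def exon_count(self) -> int:
        return len(self.exon_lengths)


#: NMD is predicted to be escaped within the final 50 bp of the penultimate
#: exon (inclusive) or anywhere in the last exon.
NMD_ESCAPE_WINDOW_BP = 50


def check_nmd_escape(
    model: TranscriptModel, variant_exon: int, offset_from_exon_end: int
) -> bool:
    """Return True when a truncating variant is predicted to escape NMD.

    ``variant_exon`` is 1-based; ``offset_from_exon_end`` counts bases from the
    3' end of that exon (0 = last base).  Escape applies in the last exon at
    any offset, or in the penultimate exon within the final 50 bp (inclusive).
    Single-exon transcripts always escape.
    """
    if not 1 <= variant_exon <= model.exon_count:
        raise ValidationError(
            f"exon index {variant_exon} out of range for a "
            f"{model.exon_count}-exon transcript"
        )
    if offset_from_exon_end < 0 or offset_from_exon_end >= model.exon_lengths[variant_exon - 1]:
        raise ValidationError(
            f"offset {offset_from_exon_end} invalid for exon of length "
            f"{model.exon_lengths[variant_exon - 1]}"
        )
    if variant_exon == model.exon_count:
        return True
    if variant_exon == model.exon_count - 1:
        return offset_from_exon_end <= NMD_ESCAPE_WINDOW_BP
    return False


def apply_pvs1(
    is_null_variant: bool, nmd_escape: bool, downstream_lp_p_cases_exist: bool
) -> Optional[EvidenceAssessment]:
    """Decide whether PVS1 applies to a putative null variant.

    PVS1 is invoked for null variants subject to NMD.  A variant predicted to
    escape NMD only keeps PVS1 when clinical cases with LP/P variants 3' of it
    exist; otherwise the criterion is withheld.
    """
    if not is_null_variant:
        return None
    if nmd_escape and not downstream_lp_p_cases_exist:
        return None
    return assessment("PVS1", source="other")


# ---------------------------------------------------------------------------
# In-silico consensus (PP3 / BP4)

_CALL_VALUES = ("deleterious", "benign", "no_call")
MISSENSE_TOOLS = ("cadd", "polyphen", "sift", "mutation_taster")
SPLICING_TOOLS = ("maxentscan", "genesplicer")


@dataclass(frozen=True)
class InSilicoPanel:
    """Per-tool calls from the prediction-tool panel.

    Missense tools (CADD, PolyPhen, SIFT, MutationTaster) drive PP3/BP4 for
    nonsynonymous variants; the splicing tools (MaxEntScan, GeneSplicer) drive
    them for synonymous or intronic variants.
    """

    variant_class: str  # "nonsynonymous" | "synonymous_or_intronic"
    cadd: str = "no_call"
    polyphen: str = "no_call"
    sift: str = "no_call"
    mutation_taster: str = "no_call"
    maxentscan: str = "no_call"
    genesplicer: str = "no_call"

    def __post_init__(self) -> None:
        if self.variant_class not in ("nonsynonymous", "synonymous_or_intronic"):
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        calls = [getattr(self, t) for t in MISSENSE_TOOLS + SPLICING_TOOLS]
        for call in calls:
            if call not in _CALL_VALUES:
                raise ValidationError(f"unknown tool call {call!r}")
        if all(call == "no_call" for call in calls):
            raise ValidationError("at least one tool must have a call")


def insilico_consensus(panel: InSilicoPanel) -> Optional[EvidenceAssessment]:
    """Derive PP3/BP4 from the prediction-tool panel, or nothing.

    Nonsynonymous variants: a strict majority of missense tools with a call
    must agree (deleterious -> PP3, benign -> BP4); ties or no calls invoke
    nothing.  Synonymous/intronic variants: both splicing tools must be
    concordant (deleterious -> PP3, benign -> BP4).
    """
    if panel.variant_class == "nonsynonymous":
        calls = [getattr(panel, t) for t in MISSENSE_TOOLS]
        n_del = calls.count("deleterious")
        n_ben = calls.count("benign")
        if n_del > n_ben:
            return assessment("PP3", source="in_silico")
        if n_ben > n_del:
            return assessment("BP4", source="in_silico")
        return None
    calls = [getattr(panel, t) for t in SPLICING_TOOLS]
    if calls == ["deleterious", "deleterious"]:
        return assessment("PP3", source="in_silico")
    if calls == ["benign", "benign"]:
        return assessment("BP4", source="in_silico")
    return None


# ---------------------------------------------------------------------------
# BS1 allele-frequency logic


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-population allele frequencies plus the disorder's credible maximum.

    ``frequencies`` maps population labels to allele frequencies and must
    contain a ``"global"`` entry.  ``max_credible_frequency`` is the
    disorder-specific threshold above which the allele frequency is greater
    than expected (BS1).
    """

    frequencies: dict[str, float]
    max_credible_frequency: float

    def __post_init__(self) -> None:
        if "global" not in self.frequencies:
            raise ValidationError('frequency profile must contain a "global" entry')
        for pop, f in self.frequencies.items():
            if not 0.0 <= float(f) <= 1.0:
                raise ValidationError(f"frequency for {pop!r} out of [0, 1]: {f}")
        if not 0.0 <= float(self.max_credible_frequency) <= 1.0:
            raise ValidationError("max_credible_frequency out of [0, 1]")


def evaluate_bs1(
    profile: FrequencyProfile, mode: str = "subpopulation_max"
) -> Optional[EvidenceAssessment]:
    """Evaluate BS1 against sub-population or global allele frequency.

    ``subpopulation_max`` mode fires BS1 when the maximum frequency over all
    populations exceeds the credible maximum (the behaviour of fully automated
    tools); ``global`` mode only consults the global frequency (the behaviour
    of manual review, for which an elevated sub-population frequency alone is
    not disqualifying).
    """
    if mode not in ("subpopulation_max", "global"):
        raise ValidationError(f"unknown BS1 mode {mode!r}")
    if mode == "subpopulation_max":
        freq = max(profile.frequencies.values())
    else:
        freq = profile.frequencies["global"]
    if freq > profile.max_credible_frequency:
        return assessment("BS1", source="population_frequency")
    return None


# ---------------------------------------------------------------------------
# Inverse sampling: draw a criteria set with a prescribed classification

_PATHOGENIC_CODES = tuple(cid for cid in CODE_IDS if CODES[cid].direction == "pathogenic")
_BENIGN_CODES = tuple(cid for cid in CODE_IDS if CODES[cid].direction == "benign")


def sample_criteria_for_class(
    target: Classification,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> frozenset[EvidenceAssessment]:
    """Rejection-sample an assessment set whose combined class equals ``target``.

    Candidate subsets are drawn from direction-appropriate code pools (so a
    pathogenic target never carries benign evidence and vice versa); VUS
    targets may be the empty set or a small mixed set.  Deterministic for a
    given generator state; raises :class:`SamplingError` if the attempt budget
    is exhausted.
    """
    if not isinstance(target, Classification):
        raise ValidationError(f"invalid target classification {target!r}")
    for _ in range(max_attempts):
        if target in (Classification.P, Classification.LP):
            k = int(rng.integers(1, 6))
            pool = _PATHOGENIC_CODES
        elif target in (Classification.B, Classification.LB):
            k = int(rng.integers(1, 5))
            pool = _BENIGN_CODES
        else:  # VUS
            if rng.random() < 0.2:
                return frozenset()
            k = int(rng.integers(1, 4))
            pool = CODE_IDS
        ids = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        candidate = frozenset(assessment(pool[i]) for i in ids)
        if combine_criteria(candidate) == target:
            return candidate
    raise SamplingError(
        f"could not sample a criteria set for target {target.token} "
        f"within {max_attempts} attempts"
    )
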