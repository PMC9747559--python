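"""TSV input/output with per-line validation.

The interchange formats are UTF-8 TSVs:

* submissions: ``variant_key  submitter_id  classification
  assertion_criteria_met  submission_date`` (ISO-8601 dates, classes as the
  literals P/LP/VUS/LB/B, booleans as true/false);
* comparison records: ``variant_key  consensus_binary  manual_class
  automated_class  case_count  manual_criteria  automated_criteria  flags
  manual_date`` where criteria sets are comma-separated ``code:source``
  tokens (e.g. ``PM3:literature_case,PP1:literature_case``) and flags are
  semicolon-separated flag names.

Round-trips are lossless; malformed rows abort with the offending line number.
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence, Union

from .acmg import Classification, EvidenceAssessment, assessment
from .concordance import Flags, VariantComparisonRecord
from .consensus import ConsensusResult, SubmissionRecord
from .exceptions import ValidationError
from .reporting import ReportBundle

__all__ = [
    "read_submissions",
    "write_submissions",
    "read_comparisons",
    "write_comparisons",
    "write_consensus",
    "write_tables",
    "format_criteria",
    "parse_criteria",
]

SUBMISSION_COLUMNS = (
    "variant_key",
    "submitter_id",
    "classification",
    "assertion_criteria_met",
    "submission_date",
)
COMPARISON_COLUMNS = (
    "variant_key",
    "consensus_binary",
    "manual_class",
    "automated_class",
    "case_count",
    "manual_criteria",
    "automated_criteria",
    "flags",
    "manual_date",
)
CONSENSUS_COLUMNS = ("variant_key", "status", "consensus_binary", "n_qualifying_submissions")


def format_criteria(criteria: Iterable[EvidenceAssessment]) -> str:
    """Serialize an assessment set as sorted ``code:source`` tokens."""
    return ",".join(
        f"{a.code.code_id}:{a.source}"
        for a in sorted(criteria, key=lambda a: a.code.code_id)
    )


def parse_criteria(text: str) -> frozenset[EvidenceAssessment]:
    if not text.strip():
        return frozenset()
    out = []
    for token in text.split(","):
        token = token.strip()
        if ":" in token:
            code_id, source = token.split(":", 1)
            out.append(assessment(code_id.strip(), source.strip()))
        else:
            out.append(assessment(token))
    result = frozenset(out)
    if len({a.code.code_id for a in result}) != len(result):
        raise ValidationError(f"duplicate evidence code in criteria field {text!r}")
    return result


def _format_flags(flags: Flags) -> str:
    return ";".join(flags.active())

def _parse_flags(text: str) -> Flags:
    names = [n for n in (t.strip() for t in text.split(";")) if n]
    unknown = set(names) - set(Flags.FLAG_NAMES)
    if unknown:
        raise ValidationError(f"unknown flag(s): {', '.join(sorted(unknown))}")
    return Flags(**{n: True for n in names})


def _parse_date(text: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError:
        raise ValidationError(f"unparseable ISO-8601 date {text!r}") from None


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"unparseable boolean {text!r}")


def _open_reader(path: Union[str, Path], expected: Sequence[str]):
    path = Path(path)
    handle = path.open("r", encoding="utf-8", newline="")
    reader = csv.DictReader(handle, delimiter="\t")
    header = reader.fieldnames
    if header is None:
        handle.close()
        raise ValidationError(f"{path}: empty file, expected a header row")
    missing = [c for c in expected if c not in header]
    if missing:
        handle.close()
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    return handle, reader


def read_submissions(path: Union[str, Path]) -> list[SubmissionRecord]:
    """Read a submissions TSV; duplicate (variant_key, submitter_id) pairs and
    malformed fields abort with the offending line number."""
    handle, reader = _open_reader(path, SUBMISSION_COLUMNS)
    records: list[SubmissionRecord] = []
    seen: set[tuple[str, str]] = set()
    with handle:
        for lineno, row in enumerate(reader, start=2):
            try:
                record = SubmissionRecord(
                    variant_key=row["variant_key"].strip(),
                    submitter_id=row["submitter_id"].strip(),
                    classification=Classification.from_token(row["classification"]),
                    assertion_criteria_met=_parse_bool(row["assertion_criteria_met"]),
                    submission_date=_parse_date(row["submission_date"]),
                )
            except (ValidationError, AttributeError, KeyError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
            pair = (record.variant_key, record.submitter_id)
            if pair in seen:
                raise ValidationError(
                    f"{path}, line {lineno}: duplicate submission for "
                    f"variant {pair[0]} from {pair[1]}"
                )
            seen.add(pair)
            records.append(record)
    return records


def write_submissions(records: Iterable[SubmissionRecord], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SUBMISSION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.variant_key,
                    r.submitter_id,
                    r.classification.token,
                    "true" if r.assertion_criteria_met else "false",
                    r.submission_date.isoformat(),
                ]
            )


def read_comparisons(path: Union[str, Path]) -> list[VariantComparisonRecord]:
    """Read a comparison-records TSV; duplicate variant keys and malformed
    fields abort with the offending line number."""
    handle, reader = _open_reader(path, COMPARISON_COLUMNS)
    records: list[VariantComparisonRecord] = []
    seen: set[str] = set()
    with handle:
        for lineno, row in enumerate(reader, start=2):
            try:
                case_count = int(row["case_count"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}, line {lineno}: unparseable case_count {row.get('case_count')!r}"
                ) from None
            try:
                record = VariantComparisonRecord(
                    variant_key=row["variant_key"].strip(),
                    consensus_binary=row["consensus_binary"].strip(),
                    manual_class=Classification.from_token(row["manual_class"]),
                    automated_class=Classification.from_token(row["automated_class"]),
                    case_count=case_count,
                    manual_criteria=parse_criteria(row["manual_criteria"] or ""),
                    automated_criteria=parse_criteria(row["automated_criteria"] or ""),
                    flags=_parse_flags(row["flags"] or ""),
                    manual_date=_parse_date(row["manual_date"]),
                )
            except (ValidationError, AttributeError, KeyError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
            if record.variant_key in seen:
                raise ValidationError(
                    f"{path}, line {lineno}: duplicate variant {record.variant_key}"
                )
            seen.add(record.variant_key)
            records.append(record)
    return records


def write_comparisons(
    records: Iterable[VariantComparisonRecord], path: Union[str, Path]
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COMPARISON_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.variant_key,
                    r.consensus_binary,
                    r.manual_class.token,
                    r.automated_class.token,
                    r.case_count,
                    format_criteria(r.manual_criteria),
                    format_criteria(r.automated_criteria),
                    _format_flags(r.flags),
                    r.manual_date.isoformat(),
                ]
            )


def write_consensus(results: Iterable[ConsensusResult], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CONSENSUS_COLUMNS)
        for r in results:
            writer.writerow(
                [r.variant_key, r.status, r.consensus_binary or "", r.n_qualifying_submissions]
            )


def write_tables(report: ReportBundle, outdir: Union[str, Path]) -> list[Path]:
    """Write the report text and every table of a bundle; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summary = outdir / "report.txt"
    summary.write_text(report.text, encoding="utf-8")
    written.append(summary)
    for name, df in report.tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
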