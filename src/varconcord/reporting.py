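"""Deterministic plain-text and TSV rendering of the analysis outputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .concordance import CategoryTabulation, ConfusionTable
from .consensus import FunnelCounts

__all__ = ["ReportBundle", "render_report"]


@dataclass(frozen=True)
class ReportBundle:
    """A rendered report: one summary text plus named TSV-able tables."""

    text: str
    tables: dict[str, pd.DataFrame]


def _format_confusion(title: str, t: ConfusionTable) -> str:
    # An empty manual column (possible on tiny inputs) renders without percentages.
    pos = t.manual_positive_pcts() if t.manual_positive_total else ("-", "-")
    neg = t.manual_negative_pcts() if t.manual_negative_total else ("-", "-")
    lines = [
        title,
        "-" * len(title),
        f"{'':<22}{'manual positive':>18}{'manual negative':>18}",
        f"{'automated positive':<22}{f'{t.auto_pos_manual_pos} ({pos[0]})':>18}"
        f"{f'{t.auto_pos_manual_neg} ({neg[0]})':>18}",
        f"{'automated negative':<22}{f'{t.auto_neg_manual_pos} ({pos[1]})':>18}"
        f"{f'{t.auto_neg_manual_neg} ({neg[1]})':>18}",
        f"{'total':<22}{t.manual_positive_total:>18}{t.manual_negative_total:>18}",
        f"overall concordance: {t.concordant_total}/{t.grand_total} "
        f"({t.overall_concordance_pct()}%)",
    ]
    return "\n".join(lines)


def render_report(
    per_variant: ConfusionTable,
    per_case: ConfusionTable,
    tabulation: CategoryTabulation,
    funnel: Optional[FunnelCounts] = None,
) -> ReportBundle:
    """Assemble the funnel, both concordance tables, and the discordance
    tabulation into one report; byte-identical for identical input."""
    sections = []
    tables: dict[str, pd.DataFrame] = {}

    if funnel is not None:
        sections.append(
            "\n".join(
                [
                    "Inclusion funnel",
                    "----------------",
                    f"observed variants:            {funnel.total}",
                    f"high-confidence consensus:    {funnel.high_confidence}",
                    f"insufficient or discordant:   {funnel.insufficient_or_discordant}",
                    f"laboratory conflicts:         {funnel.lab_conflict} "
                    f"({funnel.lab_conflict_pct}% of high-confidence)",
                    f"retained for analysis:        {funnel.retained}",
                ]
            )
        )
        tables["funnel"] = pd.DataFrame(
            {
                "stage": [
                    "total",
                    "high_confidence",
                    "insufficient_or_discordant",
                    "lab_conflict",
                    "retained",
                ],
                "count": [
                    funnel.total,
                    funnel.high_confidence,
                    funnel.insufficient_or_discordant,
                    funnel.lab_conflict,
                    funnel.retained,
                ],
            }
        )

    sections.append(_format_confusion("Per-variant concordance", per_variant))
    tables["per_variant"] = per_variant.to_dataframe().reset_index(names="automated_call")
    sections.append(_format_confusion("Per-case concordance", per_case))
    tables["per_case"] = per_case.to_dataframe().reset_index(names="automated_call")

    cat_df = tabulation.to_dataframe()
    tables["categories"] = cat_df
    if tabulation.counts:
        width = max(len(r) for r in cat_df["reason"]) + 2
        cat_lines = ["Reasons for discordance", "-----------------------"]
        for _, row in cat_df.iterrows():
            cat_lines.append(
                f"{row['reason']:<{width}}{row['variant_count']:>6}  {row['percent']:>5}%"
            )
        cat_lines.append(f"{'Total':<{width}}{tabulation.total:>6}  100.0%")
        sections.append("\n".join(cat_lines))
    else:
        sections.append("Reasons for discordance\n-----------------------\n(no discordant records)")

    return ReportBundle(text="\n\n".join(sections) + "\n", tables=tables)
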