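"""Tabular report rendering: per-condition rows, summary rows, footnotes.

Reports come in two flavours: CSV (one file of condition rows, one of
summary rows) and Markdown (a single document). Display rounding happens
only here — one decimal for ratios, whole numbers for percents and
minutes — so the underlying metric objects stay unrounded where the
conventions require it (summary medians of time columns, notably).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import pandas as pd

from ._rounding import round_half_away
from .metrics import ConditionComparison, SummaryRow, summarize

#: column order of the per-condition concept-comparison table
CONDITION_COLUMNS = [
    "condition",
    "n_downloaded",
    "n_intensional",
    "ratio_to_define_download",
    "n_derived",
    "ratio_to_define_derived",
    "completeness_ratio",
    "percent_concepts_included",
    "discrepancy_total",
    "only_in_downloaded",
    "only_in_derived",
    "n_terms_downloaded",
    "n_terms_intensional",
    "term_ratio",
    "term_percent",
    "excluded_from_summary",
]

#: columns whose summary "overall" cell is a ratio-of-sums, with display rounding
_RATIO_COLUMNS = {
    "ratio_to_define_download",
    "ratio_to_define_derived",
    "completeness_ratio",
    "term_ratio",
    "time_ratio",
}
_PERCENT_COLUMNS = {"percent_concepts_included", "term_percent"}


def comparison_frame(rows: Sequence[ConditionComparison]) -> pd.DataFrame:
    """Flatten comparison rows into a DataFrame in report column order."""
    records = []
    for r in rows:
        records.append(
            {
                "condition": r.condition_name,
                "n_downloaded": r.n_downloaded,
                "n_intensional": r.n_intensional,
                "ratio_to_define_download": r.ratio_to_define_download,
                "n_derived": r.n_derived,
                "ratio_to_define_derived": r.ratio_to_define_derived,
                "completeness_ratio": r.completeness_ratio,
                "percent_concepts_included": r.percent_concepts_included,
                "discrepancy_total": r.discrepancies.total,
                "only_in_downloaded": r.discrepancies.only_in_downloaded,
                "only_in_derived": r.discrepancies.only_in_derived,
                "n_terms_downloaded": r.n_terms_downloaded,
                "n_terms_intensional": r.n_terms_intensional,
                "term_ratio": r.term_ratio,
                "term_percent": r.term_percent,
                "excluded_from_summary": r.exclude_from_summary,
            }
        )
    return pd.DataFrame.from_records(records, columns=CONDITION_COLUMNS)


def comparison_summaries(
    rows: Sequence[ConditionComparison],
) -> Dict[str, SummaryRow]:
    """Summary rows over the non-excluded comparison rows.

    Count columns are summed; ratio/percent columns get ratio-of-sums
    overall cells recomputed from the summed raw counts.
    """
    inc = [r for r in rows if not r.exclude_from_summary]
    if not inc:
        raise ValueError("no rows included in summary")
    n_down = [r.n_downloaded for r in inc]
    n_int = [r.n_intensional for r in inc]
    n_der = [r.n_derived for r in inc]
    out: Dict[str, SummaryRow] = {
        "n_downloaded": summarize(n_down, "n_downloaded"),
        "n_intensional": summarize(n_int, "n_intensional"),
        "n_derived": summarize(n_der, "n_derived"),
        "ratio_to_define_download": summarize(
            [r.ratio_to_define_download for r in inc],
            "ratio_to_define_download",
            sums_as="ratio_of_sums",
            numerators=n_down,
            denominators=n_int,
        ),
        "ratio_to_define_derived": summarize(
            [r.ratio_to_define_derived for r in inc],
            "ratio_to_define_derived",
            sums_as="ratio_of_sums",
            numerators=n_der,
            denominators=n_int,
        ),
        "completeness_ratio": summarize(
            [r.completeness_ratio for r in inc],
            "completeness_ratio",
            sums_as="ratio_of_sums",
            numerators=n_der,
            denominators=n_down,
        ),
        "percent_concepts_included": summarize(
            [r.percent_concepts_included for r in inc],
            "percent_concepts_included",
            sums_as="ratio_of_sums",
            numerators=n_down,
            denominators=n_der,
            percent=True,
        ),
        "discrepancy_total": summarize(
            [r.discrepancies.total for r in inc], "discrepancy_total"
        ),
        "only_in_downloaded": summarize(
            [r.discrepancies.only_in_downloaded for r in inc], "only_in_downloaded"
        ),
        "only_in_derived": summarize(
            [r.discrepancies.only_in_derived for r in inc], "only_in_derived"
        ),
    }
    with_terms = [r for r in inc if r.n_terms_downloaded is not None]
    if with_terms:
        t_down = [r.n_terms_downloaded for r in with_terms]
        t_int = [r.n_terms_intensional for r in with_terms]
        out["n_terms_downloaded"] = summarize(t_down, "n_terms_downloaded")
        out["n_terms_intensional"] = summarize(t_int, "n_terms_intensional")
        out["term_ratio"] = summarize(
            [r.term_ratio for r in with_terms],
            "term_ratio",
            sums_as="ratio_of_sums",
            numerators=t_int,
            denominators=t_down,
        )
        out["term_percent"] = summarize(
            [r.term_percent for r in with_terms],
            "term_percent",
            sums_as="ratio_of_sums",
            numerators=t_down,
            denominators=t_int,
            percent=True,
        )
    return out


def _display(metric: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    if metric in _PERCENT_COLUMNS:
        return round_half_away(value, 0)
    if metric in _RATIO_COLUMNS:
        return round_half_away(value, 1)
    # counts and minutes: show one decimal only if not integral
    r = round_half_away(value, 1)
    return r


def summary_frame(summaries: Dict[str, SummaryRow]) -> pd.DataFrame:
    """Summary rows as a DataFrame with display rounding applied."""
    records = []
    for metric, s in summaries.items():
        overall = s.overall_sum if s.overall_sum is not None else s.overall_ratio_or_percent
        records.append(
            {
                "metric": metric,
                "overall_sum_ratio_or_percent": _display(metric, overall),
                "median": _display(metric, s.median),
                "minimum": _display(metric, s.minimum),
                "maximum": _display(metric, s.maximum),
                "range": _display(metric, s.range),
            }
        )
    return pd.DataFrame.from_records(records)


def render_markdown(df: pd.DataFrame, footnotes: Sequence[str] = ()) -> str:
    """Render a DataFrame as a GitHub-style Markdown table.

    Hand-rolled on purpose: it needs no optional table backends and keeps
    cell formatting identical to the CSV output.
    """

    def fmt(v) -> str:
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    for note in footnotes:
        lines.append("")
        lines.append(f"*{note}*")
    return "\n".join(lines) + "\n"


def standard_footnotes(rows: Sequence[ConditionComparison]) -> List[str]:
    """Footnote lines every report carries when applicable."""
    notes: List[str] = []
    excluded = [r.condition_name for r in rows if r.exclude_from_summary]
    if excluded:
        notes.append(
            "Excluded from summary rows (overall, median, min, max, range): "
            + ", ".join(excluded)
        )
    notes.append(
        "Overall cells are sums for count columns and ratio-of-sums for "
        "ratio/percent columns; the ratio-of-sums can differ from any "
        "separately published overall ratio computed another way."
    )
    return notes


def write_report(
    rows: Sequence[ConditionComparison],
    out_prefix: str,
    formats: Sequence[str] = ("csv", "markdown"),
    title: str = "Value-set comparison report",
) -> Dict[str, str]:
    """Write condition and summary tables; returns {kind: path}."""
    frame = comparison_frame(rows)
    summaries = comparison_summaries(rows)
    sframe = summary_frame(summaries)
    notes = standard_footnotes(rows)
    paths: Dict[str, str] = {}
    if "csv" in formats:
        cond_path = f"{out_prefix}_conditions.csv"
        summ_path = f"{out_prefix}_summary.csv"
        frame.to_csv(cond_path, index=False)
        sframe.to_csv(summ_path, index=False)
        paths["conditions_csv"] = cond_path
        paths["summary_csv"] = summ_path
    if "markdown" in formats:
        md_path = f"{out_prefix}.md"
        parts = [
            f"# {title}",
            "",
            "## Per-condition comparison",
            "",
            render_markdown(frame),
            "## Summary",
            "",
            render_markdown(sframe, footnotes=notes),
        ]
        with open(md_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(parts))
        paths["markdown"] = md_path
    return paths
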