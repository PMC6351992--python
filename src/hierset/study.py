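"""The ten-condition reference comparison, recomputed from its raw inputs.

The package ships a small fixture table of per-condition raw inputs for
ten adult clinical conditions (plus a broad pregnancy variant excluded
from summaries to avoid double-counting pregnancy): downloaded-list size,
rule size, derived-expansion size, build times (three extensional builds
were timed directly; the rest are estimated with the fitted time model),
compiled clinical-term counts, and the count of downloaded-only concept
discrepancies. Every derived column — ratios to define, completeness
ratio and percent, discrepancy totals, term coverage, estimated times —
and every summary row (overall, median, min, max, range) is recomputed
here from those raw inputs by the package's own metric functions, never
transcribed.

Notes on conventions the recomputation exposes:

* Summary medians of time columns are taken over *unrounded* minutes
  (estimated rows keep full precision; only display rounds to whole
  minutes).
* The overall row uses sums for count columns and ratio-of-sums for
  ratio/percent columns. For the downloaded ratio-to-define this gives
  375/49 = 7.65, not the historically reported 7.5; the renderer flags
  this in a footnote rather than matching it.
* Clinical-term counts are unavailable for one condition (prostate
  cancer); term-coverage summaries are computed over the rows that have
  them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

from .metrics import (
    DiscrepancyRecord,
    SummaryRow,
    completeness_from_counts,
    define_ratios,
    summarize,
)
from .terms import term_coverage_from_counts
from .timing import TimeModel, predict_time

#: Fitted creation-time model for the reference study conditions
#: (ordinary least squares on the timed builds): ~25 s per concept on top
#: of just under 4 minutes of obligate setup.
STUDY_TIME_MODEL = TimeModel(slope=0.4177, intercept=3.8707)


@dataclass(frozen=True)
class StudyConditionRow:
    """One condition with all raw and recomputed columns."""

    condition: str
    n_downloaded: int
    n_intensional: int
    n_derived: int
    ratio_to_define_download: float
    ratio_to_define_derived: float
    completeness_ratio: float
    percent_concepts_included: int
    discrepancies: DiscrepancyRecord
    ext_minutes: float  # unrounded; measured or model-estimated
    ext_time_measured: bool
    int_minutes: float
    n_terms_downloaded: Optional[int]
    n_terms_intensional: Optional[int]
    term_ratio: Optional[float]
    term_percent: Optional[int]
    exclude_from_summary: bool


def load_study_conditions() -> List[StudyConditionRow]:
    """Load the fixture table and recompute every derived column."""
    path = resources.files("hierset.data").joinpath("study_conditions.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)

    rows: List[StudyConditionRow] = []
    for r in df.itertuples(index=False):
        n_down = int(r.n_downloaded)
        n_int = int(r.n_intensional)
        n_der = int(r.n_derived)
        ratios = define_ratios(n_down, n_int, n_der)
        comp = completeness_from_counts(n_down, n_der)
        only_down = int(r.only_in_downloaded)
        # shared concepts = n_downloaded - only_in_downloaded, so:
        disc = DiscrepancyRecord(
            only_in_downloaded=only_down,
            only_in_derived=n_der - (n_down - only_down),
        )
        measured = not pd.isna(r.ext_minutes_measured)
        if measured:
            ext_minutes = float(r.ext_minutes_measured)
        else:
            ext_minutes, _ = predict_time(STUDY_TIME_MODEL, n_der)
        have_terms = not pd.isna(r.n_terms_downloaded)
        if have_terms:
            cov = term_coverage_from_counts(
                int(r.n_terms_downloaded), int(r.n_terms_intensional)
            )
            terms = dict(
                n_terms_downloaded=cov.n_downloaded,
                n_terms_intensional=cov.n_intensional,
                term_ratio=cov.ratio,
                term_percent=cov.percent,
            )
        else:
            terms = dict(
                n_terms_downloaded=None,
                n_terms_intensional=None,
                term_ratio=None,
                term_percent=None,
            )
        rows.append(
            StudyConditionRow(
                condition=str(r.condition),
                n_downloaded=n_down,
                n_intensional=n_int,
                n_derived=n_der,
                ratio_to_define_download=ratios.ratio_download,
                ratio_to_define_derived=ratios.ratio_derived,
                completeness_ratio=comp.completeness_ratio,
                percent_concepts_included=comp.percent_included,
                discrepancies=disc,
                ext_minutes=ext_minutes,
                ext_time_measured=measured,
                int_minutes=float(r.int_minutes),
                exclude_from_summary=bool(int(r.exclude_from_summary)),
                **terms,
            )
        )
    return rows


def study_summaries(
    rows: Optional[List[StudyConditionRow]] = None,
) -> Dict[str, SummaryRow]:
    """Summary rows for every metric column, over non-excluded conditions.

    Keys mirror the comparison-table columns: concept counts and ratios to
    define, completeness ratio/percent, discrepancy counts, build times
    and their difference/ratio, and term counts/coverage.
    """
    rows = load_study_conditions() if rows is None else rows
    inc = [r for r in rows if not r.exclude_from_summary]

    n_down = [r.n_downloaded for r in inc]
    n_int = [r.n_intensional for r in inc]
    n_der = [r.n_derived for r in inc]
    ext_min = [r.ext_minutes for r in inc]
    int_min = [r.int_minutes for r in inc]

    out: Dict[str, SummaryRow] = {}
    out["n_downloaded"] = summarize(n_down, "n_downloaded")
    out["n_intensional"] = summarize(n_int, "n_intensional")
    out["n_derived"] = summarize(n_der, "n_derived")
    out["ratio_to_define_download"] = summarize(
        [r.ratio_to_define_download for r in inc],
        "ratio_to_define_download",
        sums_as="ratio_of_sums",
        numerators=n_down,
        denominators=n_int,
    )
    out["ratio_to_define_derived"] = summarize(
        [r.ratio_to_define_derived for r in inc],
        "ratio_to_define_derived",
        sums_as="ratio_of_sums",
        numerators=n_der,
        denominators=n_int,
    )
    out["completeness_ratio"] = summarize(
        [r.completeness_ratio for r in inc],
        "completeness_ratio",
        sums_as="ratio_of_sums",
        numerators=n_der,
        denominators=n_down,
    )
    out["percent_concepts_included"] = summarize(
        [r.percent_concepts_included for r in inc],
        "percent_concepts_included",
        sums_as="ratio_of_sums",
        numerators=n_down,
        denominators=n_der,
        percent=True,
    )
    out["discrepancy_total"] = summarize(
        [r.discrepancies.total for r in inc], "discrepancy_total"
    )
    out["only_in_downloaded"] = summarize(
        [r.discrepancies.only_in_downloaded for r in inc], "only_in_downloaded"
    )
    out["only_in_derived"] = summarize(
        [r.discrepancies.only_in_derived for r in inc], "only_in_derived"
    )
    out["ext_minutes"] = summarize(ext_min, "ext_minutes")
    out["int_minutes"] = summarize(int_min, "int_minutes")
    out["time_difference"] = summarize(
        [e - i for e, i in zip(ext_min, int_min)], "time_difference"
    )
    out["time_ratio"] = summarize(
        [e / i for e, i in zip(ext_min, int_min)],
        "time_ratio",
        sums_as="ratio_of_sums",
        numerators=ext_min,
        denominators=int_min,
    )

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
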