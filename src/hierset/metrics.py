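"""Per-condition comparison measures and their cross-condition summaries.

For each clinical condition three artifacts are compared: the downloaded
extensional list, the intensional rule, and the rule's derived expansion.
The measures are:

* conciseness — concepts needed to define each form, and the dimensionless
  "ratio to define" (downloaded/rule and derived/rule);
* concept completeness — set discrepancies between downloaded and derived,
  the derived/downloaded ratio, and the percent of derived concepts the
  download covers;
* term coverage — the same ratio/percent over compiled clinical-term lists.

Cross-condition summaries report an overall row (sums for count columns,
ratio-of-sums for ratio/percent columns) plus median, minimum, maximum and
range; the median is the primary measure of central tendency, robust to a
single condition with a very large hierarchy dominating the sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .errors import UndefinedRatioError, ValidationError
from ._rounding import median as _median
from ._rounding import round_percent, round_ratio
from .ontology import ConceptGraph
from .terms import TermCoverage, TermMap, compile_terms, term_coverage_from_counts
from .valuesets import (
    ExtensionalValueSet,
    IntensionalValueSet,
    concepts_to_define,
    expand,
)


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Counts of concepts unique to each of two extensional sets."""

    only_in_downloaded: int
    only_in_derived: int

    @property
    def total(self) -> int:
        return self.only_in_downloaded + self.only_in_derived


def diff_concepts(
    downloaded: ExtensionalValueSet, derived: ExtensionalValueSet
) -> DiscrepancyRecord:
    """Exact set-difference cardinalities between two enumerations."""
    d, v = downloaded.concept_ids, derived.concept_ids
    return DiscrepancyRecord(
        only_in_downloaded=len(d - v),
        only_in_derived=len(v - d),
    )


@dataclass(frozen=True)
class DefineRatios:
    """Conciseness ratios: list sizes relative to the defining rule."""

    ratio_download: float
    ratio_derived: float


def define_ratios(
    n_downloaded: int, n_intensional: int, n_derived: int
) -> DefineRatios:
    if n_intensional < 1:
        raise UndefinedRatioError("rule has zero concepts; ratio to define undefined")
    return DefineRatios(
        ratio_download=round_ratio(n_downloaded / n_intensional),
        ratio_derived=round_ratio(n_derived / n_intensional),
    )


@dataclass(frozen=True)
class Completeness:
    """Concept-level completeness of the downloaded list.

    ``completeness_ratio`` = |derived| / |downloaded| (1 decimal);
    ``percent_included`` = whole-percent share of the derived expansion
    present in the download.
    """

    completeness_ratio: float
    percent_included: int


def completeness_from_counts(n_downloaded: int, n_derived: int) -> Completeness:
    if n_downloaded < 1:
        raise UndefinedRatioError("downloaded set is empty; completeness undefined")
    return Completeness(
        completeness_ratio=round_ratio(n_derived / n_downloaded),
        percent_included=round_percent(100.0 * n_downloaded / n_derived),
    )


def completeness(
    downloaded: ExtensionalValueSet, derived: ExtensionalValueSet
) -> Completeness:
    return completeness_from_counts(len(downloaded), len(derived))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryRow:
    """Overall / median / min / max / range summary of one metric column.

    Exactly one of ``overall_sum`` and ``overall_ratio_or_percent`` is set,
    depending on whether the column is a count (summed) or a ratio/percent
    (recomputed from summed numerators and denominators — NOT the mean of
    the per-condition ratios). All values are unrounded; display rounding
    is applied by the report renderer.
    """

    metric_name: str
    median: float
    minimum: float
    maximum: float
    overall_sum: Optional[float] = None
    overall_ratio_or_percent: Optional[float] = None

    @property
    def range(self) -> float:
        return self.maximum - self.minimum


def summarize(
    values: Sequence[float],
    metric_name: str = "",
    sums_as: str = "sum",
    numerators: Optional[Sequence[float]] = None,
    denominators: Optional[Sequence[float]] = None,
    percent: bool = False,
) -> SummaryRow:
    """Summarize one metric column across conditions.

    ``sums_as='sum'`` totals the values; ``sums_as='ratio_of_sums'``
    computes ``sum(numerators)/sum(denominators)`` (times 100 when
    ``percent``). Medians over an even count average the two central
    order statistics.
    """
    if not values:
        raise ValidationError("cannot summarize an empty value list")
    row_kwargs = dict(
        metric_name=metric_name,
        median=_median(values),
        minimum=float(min(values)),
        maximum=float(max(values)),
    )
    if sums_as == "sum":
        return SummaryRow(overall_sum=float(sum(values)), **row_kwargs)
    if sums_as == "ratio_of_sums":
        if numerators is None or denominators is None:
            raise ValidationError("ratio_of_sums requires numerators and denominators")
        if len(numerators) != len(denominators):
            raise ValidationError(
                f"numerators ({len(numerators)}) and denominators "
                f"({len(denominators)}) differ in length"
            )
        den = float(sum(denominators))
        if den == 0:
            raise UndefinedRatioError("summed denominator is zero")
        overall = float(sum(numerators)) / den
        if percent:
            overall *= 100.0
        return SummaryRow(overall_ratio_or_percent=overall, **row_kwargs)
    raise ValidationError(f"unknown sums_as mode: {sums_as!r}")


# ---------------------------------------------------------------------------
# one condition, assembled
# ---------------------------------------------------------------------------


@dataclass
class ConditionComparison:
    """All per-condition measures for one clinical phenotype."""

    condition_name: str
    n_downloaded: int
    n_intensional: int
    n_derived: int
    ratio_to_define_download: float
    ratio_to_define_derived: float
    completeness_ratio: float
    percent_concepts_included: int
    discrepancies: DiscrepancyRecord
    n_terms_downloaded: Optional[int] = None
    n_terms_intensional: Optional[int] = None
    term_ratio: Optional[float] = None
    term_percent: Optional[int] = None
    exclude_from_summary: bool = False

    def __post_init__(self) -> None:
        for label, n in (
            ("n_downloaded", self.n_downloaded),
            ("n_intensional", self.n_intensional),
            ("n_derived", self.n_derived),
        ):
            if n < 0:
                raise ValidationError(f"{label} must be >= 0, got {n}")


def build_condition_comparison(
    downloaded: ExtensionalValueSet,
    ivs: IntensionalValueSet,
    graph: ConceptGraph,
    term_map: Optional[TermMap] = None,
    exclude_from_summary: bool = False,
) -> ConditionComparison:
    """Run the full per-condition pipeline and assemble one comparison row.

    Expands the rule over the graph, diffs it against the downloaded list,
    computes conciseness and completeness, and (when a term map is given)
    compiles both term lists and their coverage. Component errors propagate
    with the condition name attached.
    """
    name = ivs.condition_label or ivs.name or downloaded.name
    try:
        derived = expand(ivs, graph)
        n_down = concepts_to_define(downloaded)
        n_int = concepts_to_define(ivs)
        n_der = concepts_to_define(derived)
        ratios = define_ratios(n_down, n_int, n_der)
        comp = completeness(downloaded, derived)
        disc = diff_concepts(downloaded, derived)
        term_kwargs: dict = {}
        if term_map is not None:
            down_terms = compile_terms(downloaded.concept_ids, term_map)
            int_terms = compile_terms(derived.concept_ids, term_map)
            cov = term_coverage_from_counts(len(down_terms), len(int_terms))
            term_kwargs = dict(
                n_terms_downloaded=cov.n_downloaded,
                n_terms_intensional=cov.n_intensional,
                term_ratio=cov.ratio,
                term_percent=cov.percent,
            )
    except Exception as exc:
        exc.args = (f"condition {name!r}: {exc}",)
        raise
    return ConditionComparison(
        condition_name=name,
        n_downloaded=n_down,
        n_intensional=n_int,
        n_derived=n_der,
        ratio_to_define_download=ratios.ratio_download,
        ratio_to_define_derived=ratios.ratio_derived,
        completeness_ratio=comp.completeness_ratio,
        percent_concepts_included=comp.percent_included,
        discrepancies=disc,
        exclude_from_summary=exclude_from_summary,
        **term_kwargs,
    )
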