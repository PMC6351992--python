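"""Clinical-term coverage: many-to-one term->concept maps and compiled lists.

EHR users do not pick SNOMED CT concepts directly; they pick clinician-
facing diagnosis terms (an interface terminology) that are premapped
many-to-one onto concepts. A value set's practical reach is therefore the
*compiled list* of terms whose mapped concept is in the set. Comparing
compiled-list sizes between a downloaded flat list and the expansion of a
hierarchy rule measures how many clinician-selectable terms the flat list
silently misses.

Each term maps to exactly one concept; a term id appearing twice in a
mapping file is rejected at load, because compiled-list counts presume a
function from terms to concepts, not a relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set

import pandas as pd

from .errors import FormatError, UndefinedRatioError, ValidationError
from ._rounding import round_percent, round_ratio

_REQUIRED_COLUMNS = ("term_id", "term_text", "concept_id")


@dataclass(frozen=True)
class TermRecord:
    """One clinician-selectable term mapped to one concept."""

    term_id: str
    term_text: str
    concept_id: str

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValidationError(f"term {self.term_id!r} has empty concept_id")


class TermMap:
    """Collection of term records with a concept_id -> term_ids index."""

    def __init__(self, records: Iterable[TermRecord] = ()):
        self._records: Dict[str, TermRecord] = {}
        self._by_concept: Dict[str, Set[str]] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: TermRecord) -> None:
        if record.term_id in self._records:
            raise ValidationError(f"duplicate term_id: {record.term_id}")
        self._records[record.term_id] = record
        self._by_concept.setdefault(record.concept_id, set()).add(record.term_id)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._records

    @property
    def records(self) -> List[TermRecord]:
        return list(self._records.values())

    @property
    def concept_ids(self) -> Set[str]:
        return set(self._by_concept)

    def terms_for_concept(self, concept_id: str) -> Set[str]:
        return set(self._by_concept.get(concept_id, ()))

    def unmapped_concepts(self, graph_concepts: Set[str]) -> Set[str]:
        """Concepts referenced by terms but absent from a loaded graph.

        Such terms stay in the map but can never be compiled; callers may
        surface the count in a validation report.
        """
        return self.concept_ids - graph_concepts


def load_term_map(path: str) -> TermMap:
    """Load a ``term_id<TAB>term_text<TAB>concept_id`` TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, quoting=3, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    tm = TermMap()
    for row in df.itertuples(index=False):
        tm.add(TermRecord(str(row.term_id), str(row.term_text), str(row.concept_id)))
    return tm


def write_term_map(term_map: TermMap, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_text\tconcept_id\n")
        for rec in sorted(term_map.records, key=lambda r: r.term_id):
            fh.write(f"{rec.term_id}\t{rec.term_text}\t{rec.concept_id}\n")


def compile_terms(concept_ids: Set[str], term_map: TermMap) -> Set[str]:
    """Union of term ids mapped under each concept; monotone in its input.

    Concepts with no mapped terms (or absent from the map) contribute
    nothing — mirroring an EHR compiling a value set's selectable-term
    list.
    """
    out: Set[str] = set()
    for cid in concept_ids:
        out |= term_map.terms_for_concept(cid)
    return out


@dataclass(frozen=True)
class TermCoverage:
    """Term-level completeness of a downloaded list vs a hierarchy rule.

    ``ratio`` = intensional / downloaded term counts (1 decimal);
    ``percent`` = share of the intensional compiled list the downloaded
    set covers, rounded to a whole percent.
    """

    n_downloaded: int
    n_intensional: int
    ratio: float
    percent: int


def term_coverage_from_counts(n_downloaded: int, n_intensional: int) -> TermCoverage:
    if n_intensional <= 0:
        raise ValidationError("intensional compiled term list must be non-empty")
    if n_downloaded <= 0:
        raise UndefinedRatioError(
            "downloaded compiled term list is empty; coverage ratio undefined"
        )
    return TermCoverage(
        n_downloaded=n_downloaded,
        n_intensional=n_intensional,
        ratio=round_ratio(n_intensional / n_downloaded),
        percent=round_percent(100.0 * n_downloaded / n_intensional),
    )


def term_coverage_metrics(
    downloaded_terms: Set[str], intensional_terms: Set[str]
) -> TermCoverage:
    """Coverage record for two compiled term sets (see :class:`TermCoverage`)."""
    return term_coverage_from_counts(len(downloaded_terms), len(intensional_terms))
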