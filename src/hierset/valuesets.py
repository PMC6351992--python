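"""Intensional rules and extensional lists, and expansion of the former.

An intensional value set is a rule over concept hierarchies: an ordered
list of clauses, each referencing one concept with a scope (descendant-
or-self ``<<``, descendants-only ``<``, or the bare concept) and a
polarity (include or exclude). Evaluation is pure Boolean set algebra:
the union of the include closures minus the union of the exclude
closures — exclusions always apply after all inclusions, matching the
"AND NOT" reading, with no clause-order dependence.

The rule grammar ("ECL-lite") is the hierarchy-reference subset of the
SNOMED CT Expression Constraint Language: terms joined by ``OR``,
exclusions introduced by ``MINUS`` (``AND NOT`` is accepted as an
alias). Once a ``MINUS`` has appeared, subsequent ``OR``-joined terms
remain exclusions. Parentheses, refinements and attribute constraints
are not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Sequence, Set, Union

from .errors import ConceptNotFoundError, RuleParseError, ValidationError
from .ontology import ConceptGraph


class Scope(str, Enum):
    """How much of the hierarchy a clause's concept reference pulls in."""

    SELF_AND_DESCENDANTS = "self_and_descendants"  # ECL <<
    DESCENDANTS_ONLY = "descendants_only"  # ECL <
    SELF_ONLY = "self_only"  # bare concept id


class Polarity(str, Enum):
    INCLUDE = "include"
    EXCLUDE = "exclude"


_SCOPE_PREFIX = {
    Scope.SELF_AND_DESCENDANTS: "<<",
    Scope.DESCENDANTS_ONLY: "<",
    Scope.SELF_ONLY: "",
}


@dataclass(frozen=True)
class HierarchyClause:
    """One hierarchy reference in a rule."""

    polarity: Polarity
    concept_id: str
    scope: Scope = Scope.SELF_AND_DESCENDANTS

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValidationError("clause concept_id must be non-empty")


@dataclass
class IntensionalValueSet:
    """A named rule-based value set: ordered include/exclude clauses."""

    name: str
    clauses: List[HierarchyClause]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValidationError("rule must have at least one clause")
        if not any(c.polarity is Polarity.INCLUDE for c in self.clauses):
            raise ValidationError("rule must have at least one include clause")

    @property
    def includes(self) -> List[HierarchyClause]:
        return [c for c in self.clauses if c.polarity is Polarity.INCLUDE]

    @property
    def excludes(self) -> List[HierarchyClause]:
        return [c for c in self.clauses if c.polarity is Polarity.EXCLUDE]


@dataclass
class ExtensionalValueSet:
    """A named enumerated value set with provenance.

    ``provenance`` distinguishes the three roles a flat list plays in a
    completeness audit: ``downloaded`` (obtained from a repository such as
    VSAC), ``derived`` (the exact expansion of an intensional rule), and
    ``synthetic`` (generated, e.g. a simulated stale download).
    """

    name: str
    concept_ids: Set[str]
    provenance: str = "downloaded"
    oid: str = ""
    code_system_version: str = ""

    _ALLOWED = frozenset({"downloaded", "derived", "synthetic"})

    def __post_init__(self) -> None:
        if self.provenance not in self._ALLOWED:
            raise ValidationError(
                f"provenance must be one of {sorted(self._ALLOWED)}, "
                f"got {self.provenance!r}"
            )
        self.concept_ids = set(self.concept_ids)

    def __len__(self) -> int:
        return len(self.concept_ids)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\S+")


def parse_rule(text: str, name: str = "", condition_label: str = "") -> IntensionalValueSet:
    """Parse an ECL-lite expression into an :class:`IntensionalValueSet`.

    Raises :class:`RuleParseError` with a character position on empty
    input, unknown tokens, or a ``MINUS`` with no preceding include.
    """
    tokens = list(_TOKEN_RE.finditer(text))
    if not tokens:
        raise RuleParseError("empty rule expression", 0)

    clauses: List[HierarchyClause] = []
    polarity = Polarity.INCLUDE
    expect_term = True
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        word = tok.group()
        upper = word.upper()
        if upper in ("OR", "MINUS", "AND"):
            if expect_term:
                raise RuleParseError(f"operator {word!r} where a term was expected", tok.start())
            if upper == "AND":
                # accept the Boolean 'AND NOT' spelling as a MINUS alias
                if i + 1 >= len(tokens) or tokens[i + 1].group().upper() != "NOT":
                    raise RuleParseError("bare AND is not supported (use OR / MINUS / AND NOT)", tok.start())
                i += 1
                upper = "MINUS"
            if upper == "MINUS":
                if not clauses:
                    raise RuleParseError("exclusion with no preceding include", tok.start())
                polarity = Polarity.EXCLUDE
            expect_term = True
            i += 1
            continue
        # a term
        if word.startswith("<<"):
            scope, cid = Scope.SELF_AND_DESCENDANTS, word[2:]
        elif word.startswith("<"):
            scope, cid = Scope.DESCENDANTS_ONLY, word[1:]
        else:
            scope, cid = Scope.SELF_ONLY, word
        if not cid.isdigit():
            raise RuleParseError(f"unknown token {word!r}", tok.start())
        if not expect_term:
            raise RuleParseError(f"term {word!r} without a joining operator", tok.start())
        clauses.append(HierarchyClause(polarity, cid, scope))
        expect_term = False
        i += 1
    if expect_term:
        raise RuleParseError("expression ends with a dangling operator", tokens[-1].end())
    return IntensionalValueSet(name=name or "rule", clauses=clauses, condition_label=condition_label)


def serialize_rule(ivs: IntensionalValueSet) -> str:
    """Render a rule back to ECL-lite text.

    Includes come first joined by ``OR``; each exclude carries its own
    ``MINUS``. ``parse_rule(serialize_rule(x))`` reproduces x's clauses in
    normalized order (includes before excludes).
    """
    parts: List[str] = []
    for i, clause in enumerate(ivs.includes):
        if i:
            parts.append("OR")
        parts.append(_SCOPE_PREFIX[clause.scope] + clause.concept_id)
    for clause in ivs.excludes:
        parts.append("MINUS")
        parts.append(_SCOPE_PREFIX[clause.scope] + clause.concept_id)
    return " ".join(parts)


def load_rule_file(path: str, name: str = "", condition_label: str = "") -> IntensionalValueSet:
    """Load a plain-text ECL-lite rule file: one rule, ``#`` comments allowed."""
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.split("#", 1)[0].strip()
            if stripped:
                lines.append(stripped)
    return parse_rule(" ".join(lines), name=name, condition_label=condition_label)


def write_rule_file(ivs: IntensionalValueSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if ivs.condition_label:
            fh.write(f"# {ivs.condition_label}\n")
        fh.write(serialize_rule(ivs) + "\n")


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def _clause_closure(clause: HierarchyClause, graph: ConceptGraph) -> Set[str]:
    if clause.concept_id not in graph:
        raise ConceptNotFoundError(clause.concept_id)
    if clause.scope is Scope.SELF_ONLY:
        return {clause.concept_id}
    include_self = clause.scope is Scope.SELF_AND_DESCENDANTS
    return graph.descendants(clause.concept_id, include_self=include_self)


def expand(ivs: IntensionalValueSet, graph: ConceptGraph) -> ExtensionalValueSet:
    """Derive the exactly-equivalent extensional value set of a rule.

    The result is the union of the per-include-clause closures minus the
    union of the per-exclude-clause closures, deterministic for a given
    graph and rule. Duplicate clauses collapse here (set semantics) even
    though :func:`concepts_to_define` counts them as written.
    """
    included: Set[str] = set()
    excluded: Set[str] = set()
    for clause in ivs.clauses:
        try:
            closure = _clause_closure(clause, graph)
        except ConceptNotFoundError as exc:
            raise ConceptNotFoundError(clause.concept_id) from exc
        if clause.polarity is Polarity.INCLUDE:
            included |= closure
        else:
            excluded |= closure
    return ExtensionalValueSet(
        name=ivs.name,
        concept_ids=included - excluded,
        provenance="derived",
    )


def concepts_to_define(vs: Union[IntensionalValueSet, ExtensionalValueSet]) -> int:
    """Conciseness measure: concepts needed to write the definition down.

    For a rule this is the number of clause references as written
    (duplicates counted); for an enumerated list, its cardinality. A
    ``downloaded`` extensional set is taken exactly as published — its
    definition *is* its enumeration, with no descendant inclusion.
    """
    if isinstance(vs, IntensionalValueSet):
        return len(vs.clauses)
    return len(vs.concept_ids)
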