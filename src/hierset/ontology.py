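"""Concept polyhierarchy: loading, validation, and transitive is-a closure.

A :class:`ConceptGraph` holds the active subset of a SNOMED CT-style
terminology as a directed acyclic graph whose edges point child -> parent
(RF2 ``sourceId`` is the subtype, ``destinationId`` the supertype). The only
relationship type retained is is-a (typeId 116680003); attribute
relationships are out of scope.

Concept identifiers are opaque digit strings throughout. SCTIDs can exceed
15 digits, so treating them as integers or floats risks silent precision
loss (notably when round-tripping through spreadsheets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .errors import ConceptNotFoundError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: RF2 typeId of the is-a (supertype-subtype) relationship.
IS_A_TYPE_ID = "116680003"

_RF2_CONCEPT_COLUMNS = ("id", "active")
_RF2_RELATIONSHIP_COLUMNS = ("sourceId", "destinationId", "active", "typeId")


@dataclass(frozen=True)
class ConceptNode:
    """One concept: an opaque digit-string id, a label, and its active flag."""

    concept_id: str
    label: str = ""
    active: bool = True

    def __post_init__(self) -> None:
        if not self.concept_id or not self.concept_id.isdigit():
            raise ValidationError(
                f"concept_id must be a non-empty digit string, got {self.concept_id!r}"
            )


class ConceptGraph:
    """Active is-a DAG over concepts, supporting descendant/ancestor closure.

    Edges are stored child -> parent. ``descendants`` therefore collects the
    nodes that can *reach* a root along stored edges, and ``ancestors`` the
    nodes reachable *from* a concept.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._nodes: Dict[str, ConceptNode] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: ConceptNode) -> None:
        if node.concept_id in self._nodes:
            raise ValidationError(f"duplicate concept id: {node.concept_id}")
        self._nodes[node.concept_id] = node
        self._g.add_node(node.concept_id)

    def add_edge(self, child_id: str, parent_id: str) -> None:
        for cid in (child_id, parent_id):
            if cid not in self._nodes:
                raise ValidationError(f"edge endpoint not in graph: {cid}")
        if child_id == parent_id:
            raise ValidationError(f"self-loop edge on concept {child_id}")
        self._g.add_edge(child_id, parent_id)

    def validate(self) -> None:
        """Raise :class:`ValidationError` if the graph is not a DAG."""
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            members = sorted({u for u, _ in cycle} | {v for _, v in cycle})
            raise ValidationError(
                "hierarchy contains a cycle among concepts: " + ", ".join(members)
            )

    # -- inspection --------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def concept_ids(self) -> Set[str]:
        return set(self._nodes)

    @property
    def edges(self) -> Set[Tuple[str, str]]:
        """Child -> parent pairs."""
        return set(self._g.edges())

    def node(self, concept_id: str) -> ConceptNode:
        try:
            return self._nodes[concept_id]
        except KeyError:
            raise ConceptNotFoundError(concept_id) from None

    def label(self, concept_id: str) -> str:
        return self.node(concept_id).label

    def parents(self, concept_id: str) -> Set[str]:
        self.node(concept_id)
        return set(self._g.successors(concept_id))

    def children(self, concept_id: str) -> Set[str]:
        self.node(concept_id)
        return set(self._g.predecessors(concept_id))

    def roots(self) -> Set[str]:
        """Concepts with no parent."""
        return {c for c in self._nodes if self._g.out_degree(c) == 0}

    # -- closure queries ---------------------------------------------------

    def descendants(self, root_id: str, include_self: bool = True) -> Set[str]:
        """All concepts below ``root_id`` in the hierarchy.

        A concept reached along several paths (multiple parents) appears
        once. With ``include_self`` the root itself is a member, matching
        the ECL ``<<`` (descendant-or-self) operator; without it, ECL ``<``.
        """
        self.node(root_id)
        # stored edges run child->parent, so hierarchy descendants are the
        # graph-theoretic ancestors of the root
        result = set(nx.ancestors(self._g, root_id))
        if include_self:
            result.add(root_id)
        return result

    def ancestors(self, concept_id: str) -> Set[str]:
        """All concepts above ``concept_id``, excluding itself."""
        self.node(concept_id)
        return set(nx.descendants(self._g, concept_id))

    def descendant_sets(self) -> Dict[str, Set[str]]:
        """Strict-descendant sets for every concept, in one pass.

        A single dynamic-programming sweep in topological order (children
        before parents, since stored edges run child -> parent) beats
        per-node traversal when eligibility of *all* nodes is needed,
        e.g. when sampling condition anchors by subtree size.
        """
        desc: Dict[str, Set[str]] = {}
        for n in nx.topological_sort(self._g):
            s: Set[str] = set()
            for child in self._g.predecessors(n):
                s.add(child)
                s |= desc[child]
            desc[n] = s
        return desc


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _build_graph(
    nodes: Iterable[ConceptNode], edges: Iterable[Tuple[str, str]]
) -> ConceptGraph:
    graph = ConceptGraph()
    for node in nodes:
        graph.add_node(node)
    bad: list = []
    for child, parent in edges:
        if child == parent:
            raise ValidationError(f"self-loop edge on concept {child}")
        if child not in graph or parent not in graph:
            bad.append((child, parent))
            continue
        graph.add_edge(child, parent)
    if bad:
        shown = ", ".join(f"{c}->{p}" for c, p in bad[:10])
        raise ValidationError(
            f"{len(bad)} edge(s) reference concepts absent from the concept "
            f"table (showing up to 10): {shown}"
        )
    graph.validate()
    return graph


def load_rf2_snapshot(concept_path: str, relationship_path: str) -> ConceptGraph:
    """Load an RF2 snapshot concept + relationship table pair.

    Only rows with ``active == 1`` are retained, and only relationship rows
    whose ``typeId`` is the is-a identifier (116680003). Inactive rows are
    dropped silently apart from a logged count. Edges are oriented
    sourceId (child) -> destinationId (parent).
    """
    concepts = pd.read_csv(concept_path, sep="\t", dtype=str, quoting=3)
    _require_columns(concepts, _RF2_CONCEPT_COLUMNS, str(concept_path))
    rels = pd.read_csv(relationship_path, sep="\t", dtype=str, quoting=3)
    _require_columns(rels, _RF2_RELATIONSHIP_COLUMNS, str(relationship_path))

    n_inactive_concepts = int((concepts["active"] != "1").sum())
    concepts = concepts[concepts["active"] == "1"]
    is_a = rels[rels["typeId"] == IS_A_TYPE_ID]
    n_inactive_edges = int((is_a["active"] != "1").sum())
    is_a = is_a[is_a["active"] == "1"]
    if n_inactive_concepts or n_inactive_edges:
        logger.info(
            "dropped %d inactive concept(s) and %d inactive is-a row(s)",
            n_inactive_concepts,
            n_inactive_edges,
        )

    nodes = [ConceptNode(cid, label="", active=True) for cid in concepts["id"]]
    edges = list(zip(is_a["sourceId"], is_a["destinationId"]))
    return _build_graph(nodes, edges)


def load_edge_table(path: str) -> ConceptGraph:
    """Load a two/three-column ``child<TAB>parent[<TAB>label]`` table.

    All rows are treated as active. A header row is auto-detected: if the
    first cell of the first row is not all digits, the row is a header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, quoting=3)
    if df.empty:
        raise FormatError(f"{path}: empty edge table")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge table needs at least 2 columns")
    first = str(df.iloc[0, 0])
    if not first.isdigit():  # header row
        df = df.iloc[1:]
    children = df.iloc[:, 0].astype(str)
    parents = df.iloc[:, 1].astype(str)
    labels = (
        df.iloc[:, 2].fillna("").astype(str) if df.shape[1] >= 3 else [""] * len(df)
    )

    node_labels: Dict[str, str] = {}
    for child, label in zip(children, labels):
        if label:
            node_labels[child] = label
    ids = sorted(set(children) | set(parents))
    nodes = [ConceptNode(cid, label=node_labels.get(cid, "")) for cid in ids]
    return _build_graph(nodes, list(zip(children, parents)))


def write_edge_table(graph: ConceptGraph, path: str) -> None:
    """Write a graph as a ``child<TAB>parent<TAB>label`` table (sorted rows)."""
    rows = sorted(graph.edges)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_id\tparent_id\tlabel\n")
        for child, parent in rows:
            fh.write(f"{child}\t{parent}\t{graph.label(child)}\n")
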