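"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's graph machinery: they work
on a raw set of (child, parent) edge pairs with a hand-written stack
traversal, so they can serve as an independent check of the closure and
expansion implementations.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, Set, Tuple

import pytest

import hierset as hs

Edge = Tuple[str, str]


# ---------------------------------------------------------------------------
# oracles (plain edge-pair algorithms, no networkx, no ConceptGraph)
# ---------------------------------------------------------------------------


def brute_descendants(edges: Iterable[Edge], root: str, include_self: bool) -> Set[str]:
    children: Dict[str, Set[str]] = defaultdict(set)
    for child, parent in edges:
        children[parent].add(child)
    seen: Set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children[node]:
            if ch not in seen:
                seen.add(ch)
                stack.append(ch)
    if include_self:
        seen.add(root)
    else:
        seen.discard(root)
    return seen


def brute_ancestors(edges: Iterable[Edge], node: str) -> Set[str]:
    parents: Dict[str, Set[str]] = defaultdict(set)
    for child, parent in edges:
        parents[child].add(parent)
    seen: Set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        for p in parents[n]:
            if p not in seen:
                seen.add(p)
                stack.append(p)
    seen.discard(node)
    return seen


def brute_expand(edges: Iterable[Edge], ivs: "hs.IntensionalValueSet") -> Set[str]:
    """Set-algebra expansion oracle: per-clause closures, union minus union."""
    edges = list(edges)

    def closure(clause):
        if clause.scope is hs.Scope.SELF_ONLY:
            return {clause.concept_id}
        include_self = clause.scope is hs.Scope.SELF_AND_DESCENDANTS
        return brute_descendants(edges, clause.concept_id, include_self)

    included: Set[str] = set()
    excluded: Set[str] = set()
    for clause in ivs.clauses:
        target = included if clause.polarity is hs.Polarity.INCLUDE else excluded
        target |= closure(clause)
    return included - excluded


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def diamond_graph() -> hs.ConceptGraph:
    """A -> (B, C) -> D: the minimal multi-parent hierarchy."""
    g = hs.ConceptGraph()
    for cid, label in [("1", "A"), ("2", "B"), ("3", "C"), ("4", "D")]:
        g.add_node(hs.ConceptNode(cid, label=label))
    g.add_edge("2", "1")
    g.add_edge("3", "1")
    g.add_edge("4", "2")
    g.add_edge("4", "3")
    return g


@pytest.fixture(scope="session")
def synthetic_graph() -> hs.ConceptGraph:
    """A 200-node seeded polyhierarchy used across oracle sweeps."""
    return hs.generate_ontology(
        hs.SyntheticConfig(n_concepts=200, extra_parent_probability=0.3, seed=42)
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A small on-disk fixture bundle (shared; treat as read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    config = hs.SyntheticConfig(n_concepts=600, n_conditions=4, seed=11)
    manifest = hs.make_fixture_bundle(config, str(out))
    return out, config, manifest
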