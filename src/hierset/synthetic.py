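"""Synthetic SNOMED-like study material: polyhierarchies, term maps,
condition rules, and simulated stale downloads.

Licensed terminology content cannot ship with the package, so every
pipeline stage is exercised on generated material with the statistical
structure the analysis assumes:

* a rooted multi-parent is-a DAG (each non-root concept gets one parent
  plus, with some probability, a second — SNOMED CT is polyhierarchical);
* many-to-one term maps (a clinician-facing interface terminology maps
  hundreds to thousands of terms onto each hierarchy);
* "stale" extensional lists formed by dropping a fraction of the true
  descendants of a rule, emulating a published flat list that has fallen
  behind the terminology (the study conditions showed a median of only
  35% of derived concepts present in the downloads, i.e. a degradation
  fraction of 0.65).

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np

from .errors import ValidationError
from .ontology import ConceptGraph, ConceptNode, write_edge_table
from .terms import TermMap, TermRecord, write_term_map
from .timing import TimingObservation, write_timing_observations
from .valuesets import (
    ExtensionalValueSet,
    HierarchyClause,
    IntensionalValueSet,
    Polarity,
    Scope,
    expand,
    serialize_rule,
)

#: Concept ids are digit strings of this fixed width, offset to avoid
#: leading zeros (SCTIDs never start with 0).
_ID_BASE = 10_000_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic study material.

    Defaults mirror the scale of the published study conditions: an
    ontology large enough that sampled condition subtrees span tens to a
    few hundred concepts, about a dozen clinician terms per concept on
    average, and a degradation fraction of 0.65 so simulated downloads
    retain ~35% of the true expansion.
    """

    n_concepts: int = 2000
    extra_parent_probability: float = 0.15
    max_depth: int = 12
    terms_per_concept: float = 12.0
    degradation_fraction: float = 0.65
    n_conditions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("n_concepts must be >= 2")
        if not 0.0 <= self.extra_parent_probability <= 1.0:
            raise ValidationError("extra_parent_probability must be in [0, 1]")
        if not 0.0 <= self.degradation_fraction < 1.0:
            raise ValidationError("degradation_fraction must be in [0, 1)")
        if self.terms_per_concept < 1.0:
            raise ValidationError("terms_per_concept mean must be >= 1")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")


def _concept_id(i: int) -> str:
    return str(_ID_BASE + i)


def generate_ontology(config: SyntheticConfig) -> ConceptGraph:
    """Single-rooted acyclic polyhierarchy with ``n_concepts`` nodes.

    Nodes are added in sequence; each new node picks a primary parent
    uniformly among existing nodes of depth < max_depth, then with
    probability ``extra_parent_probability`` a second parent among nodes
    no deeper than the primary parent. Because a brand-new node has no
    descendants and extra parents are never deeper than the child,
    acyclicity holds by construction; it is re-validated at the end.
    """
    rng = np.random.default_rng(config.seed)
    graph = ConceptGraph()
    depth: Dict[str, int] = {}

    root = _concept_id(0)
    graph.add_node(ConceptNode(root, label="Root concept"))
    depth[root] = 0
    ids = [root]

    for i in range(1, config.n_concepts):
        cid = _concept_id(i)
        graph.add_node(ConceptNode(cid, label=f"Concept {i}"))
        eligible = [c for c in ids if depth[c] < config.max_depth]
        parent = eligible[rng.integers(len(eligible))]
        graph.add_edge(cid, parent)
        depth[cid] = depth[parent] + 1
        if rng.random() < config.extra_parent_probability:
            shallow = [
                c for c in ids if c != parent and depth[c] <= depth[parent]
            ]
            if shallow:
                second = shallow[rng.integers(len(shallow))]
                graph.add_edge(cid, second)
        ids.append(cid)

    graph.validate()
    return graph


def generate_term_map(graph: ConceptGraph, config: SyntheticConfig) -> TermMap:
    """Shifted-Poisson many-to-one term map: every concept gets >= 1 term.

    Term counts per concept are 1 + Poisson(mean - 1), so a configured
    mean of exactly 1 collapses the variance and yields one term each.
    """
    rng = np.random.default_rng(config.seed + 1)
    tm = TermMap()
    serial = 0
    for cid in sorted(graph.concept_ids):
        n_terms = 1 + int(rng.poisson(config.terms_per_concept - 1.0))
        for k in range(n_terms):
            tm.add(
                TermRecord(
                    term_id=f"T{serial:07d}",
                    term_text=f"{graph.label(cid) or cid} (term {k})",
                    concept_id=cid,
                )
            )
            serial += 1
    return tm


def sample_condition(
    graph: ConceptGraph,
    config: SyntheticConfig,
    seed: Optional[int] = None,
    min_descendants: int = 5,
    max_descendants: Optional[int] = None,
    name: str = "condition",
) -> IntensionalValueSet:
    """Sample a condition rule: one subtree include, optionally one
    child-subtree exclude (probability 1/2).

    The include root is drawn among internal nodes with at least
    ``min_descendants`` (and, when given, at most ``max_descendants``)
    strict descendants, echoing how real condition rules anchor at a
    disorder concept with a meaningful but not hierarchy-spanning
    subtree.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    hi = max_descendants if max_descendants is not None else len(graph)
    desc_sets = graph.descendant_sets()
    eligible = [
        cid
        for cid in sorted(graph.concept_ids)
        if min_descendants <= len(desc_sets[cid]) <= hi
    ]
    if not eligible:
        raise ValidationError(
            f"no concept has >= {min_descendants} descendants; "
            "ontology too small or too flat"
        )
    root = eligible[rng.integers(len(eligible))]
    clauses = [HierarchyClause(Polarity.INCLUDE, root, Scope.SELF_AND_DESCENDANTS)]
    if rng.random() < 0.5:
        # exclusions carve out a minority subtype: keep only candidate
        # children whose removal leaves at least half the expansion
        closure = graph.descendants(root, include_self=True)
        children = sorted(graph.children(root))
        rng.shuffle(children)
        for child in children:
            removed = closure & graph.descendants(child, include_self=True)
            if 0 < len(removed) <= len(closure) // 2:
                clauses.append(
                    HierarchyClause(
                        Polarity.EXCLUDE, child, Scope.SELF_AND_DESCENDANTS
                    )
                )
                break
    return IntensionalValueSet(name=name, clauses=clauses, condition_label=name)


def degrade_to_extensional(
    derived: ExtensionalValueSet,
    fraction: float,
    clause_roots: Set[str],
    seed: int,
) -> ExtensionalValueSet:
    """Simulate a stale downloaded list from a true expansion.

    Each non-root concept is independently dropped with probability
    ``fraction``; clause-root concepts are always retained (every
    inspected real download contained its condition's anchor concept).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must be in [0, 1)")
    missing_roots = clause_roots - derived.concept_ids
    if missing_roots:
        raise ValidationError(
            "clause root(s) not in derived set: " + ", ".join(sorted(missing_roots))
        )
    rng = np.random.default_rng(seed)
    kept: Set[str] = set()
    for cid in sorted(derived.concept_ids):
        if cid in clause_roots or rng.random() >= fraction:
            kept.add(cid)
    return ExtensionalValueSet(
        name=derived.name,
        concept_ids=kept,
        provenance="synthetic",
        oid=derived.oid,
        code_system_version=derived.code_system_version,
    )


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------


def make_fixture_bundle(config: SyntheticConfig, out_dir: str) -> Dict:
    """Write a complete on-disk study bundle and return its manifest.

    Emits an edge-table TSV, a term-map TSV, one rule file and one
    degraded downloaded-style CSV per condition, a timing TSV, and a
    manifest (also written as ``manifest.json``) recording paths, the
    seed, and the generator's ground truth per condition (derived size,
    retained size) so end-to-end runs can be checked against it.
    """
    from .vsac import write_vsac_export  # local import to avoid a cycle

    os.makedirs(out_dir, exist_ok=True)
    graph = generate_ontology(config)
    term_map = generate_term_map(graph, config)

    edges_path = os.path.join(out_dir, "ontology_edges.tsv")
    write_edge_table(graph, edges_path)
    terms_path = os.path.join(out_dir, "term_map.tsv")
    write_term_map(term_map, terms_path)

    conditions: List[Dict] = []
    timing: List[TimingObservation] = []
    rng = np.random.default_rng(config.seed + 3)
    for k in range(config.n_conditions):
        name = f"condition_{k:02d}"
        # subtree bounds keep sampled conditions at the scale of real
        # condition value sets (tens to a few hundred concepts); the lower
        # bound also keeps the always-retained anchor concept from biasing
        # simulated-download retention by more than ~2 percentage points
        ivs = sample_condition(
            graph,
            config,
            seed=int(rng.integers(2**31)),
            min_descendants=40,
            max_descendants=600,
            name=name,
        )
        derived = expand(ivs, graph)
        roots = {c.concept_id for c in ivs.includes}
        downloaded = degrade_to_extensional(
            derived,
            config.degradation_fraction,
            clause_roots=roots,
            seed=int(rng.integers(2**31)),
        )
        rule_path = os.path.join(out_dir, f"{name}.rule")
        with open(rule_path, "w", encoding="utf-8") as fh:
            fh.write(f"# {name}\n{serialize_rule(ivs)}\n")
        csv_path = os.path.join(out_dir, f"{name}_downloaded.csv")
        write_vsac_export(downloaded, csv_path)
        # synthetic per-build timings drawn from an affine cost with mild noise
        minutes = 0.4 * len(derived) + 4.0 + float(rng.normal(0.0, 0.5))
        timing.append(
            TimingObservation(name, len(derived), max(minutes, 0.1), measured=True)
        )
        conditions.append(
            {
                "name": name,
                "rule_file": os.path.basename(rule_path),
                "downloaded_csv": os.path.basename(csv_path),
                "n_derived": len(derived),
                "n_downloaded": len(downloaded),
                "clause_roots": sorted(roots),
            }
        )

    timing_path = os.path.join(out_dir, "timing.tsv")
    write_timing_observations(timing, timing_path)

    manifest = {
        "seed": config.seed,
        "degradation_fraction": config.degradation_fraction,
        "files": {
            "edges": os.path.basename(edges_path),
            "term_map": os.path.basename(terms_path),
            "timing": os.path.basename(timing_path),
        },
        "conditions": conditions,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
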