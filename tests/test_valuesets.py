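"""Rule parsing/serialization and expansion semantics."""

from __future__ import annotations

import numpy as np
import pytest

import hierset as hs
from conftest import brute_expand

IVS = hs.IntensionalValueSet
Clause = hs.HierarchyClause
INC, EXC = hs.Polarity.INCLUDE, hs.Polarity.EXCLUDE
SAD, DO, SO = (
    hs.Scope.SELF_AND_DESCENDANTS,
    hs.Scope.DESCENDANTS_ONLY,
    hs.Scope.SELF_ONLY,
)


def _random_rule(rng: np.random.Generator, ids, n_clauses=3, name="r") -> IVS:
    scopes = [SAD, DO, SO]
    clauses = [Clause(INC, str(rng.choice(ids)), scopes[rng.integers(3)])]
    for _ in range(n_clauses - 1):
        polarity = INC if rng.random() < 0.5 else EXC
        clauses.append(Clause(polarity, str(rng.choice(ids)), scopes[rng.integers(3)]))
    return IVS(name=name, clauses=clauses)


class TestParsing:
    def test_personality_disorder_style_rule(self):
        ivs = hs.parse_rule("<<33449004 MINUS <<36217008")
        assert ivs.clauses == [
            Clause(INC, "33449004", SAD),
            Clause(EXC, "36217008", SAD),
        ]

    def test_single_hierarchy_reference(self):
        ivs = hs.parse_rule("<<64859006")
        assert ivs.clauses == [Clause(INC, "64859006", SAD)]

    def test_and_not_is_a_minus_alias(self):
        a = hs.parse_rule("<<33449004 AND NOT <<36217008")
        b = hs.parse_rule("<<33449004 MINUS <<36217008")
        assert a.clauses == b.clauses

    def test_all_three_scopes(self):
        ivs = hs.parse_rule("<<10 OR <20 OR 30")
        assert [c.scope for c in ivs.clauses] == [SAD, DO, SO]

    def test_or_after_minus_stays_excluding(self):
        ivs = hs.parse_rule("<<1 MINUS <<2 OR <<3")
        assert [c.polarity for c in ivs.clauses] == [INC, EXC, EXC]

    @pytest.mark.parametrize(
        "text",
        ["", "   ", "MINUS <<5", "<<1 MINUS", "<<1 OR", "<<1 <<2", "<<1 OR banana", "<<1 AND <<2"],
    )
    def test_malformed_expressions_raise_parse_errors(self, text):
        with pytest.raises(hs.RuleParseError):
            hs.parse_rule(text)

    def test_parse_error_carries_position(self):
        with pytest.raises(hs.RuleParseError) as err:
            hs.parse_rule("<<1 OR banana")
        assert err.value.position == 7


class TestSerialization:
    def test_round_trip_of_two_clause_rule(self):
        ivs = hs.parse_rule("<<33449004 MINUS <<36217008")
        assert hs.parse_rule(hs.serialize_rule(ivs)).clauses == ivs.clauses

    def test_eight_includes_have_seven_ors(self):
        ivs = IVS("kidney", [Clause(INC, str(100 + i), SAD) for i in range(8)])
        text = hs.serialize_rule(ivs)
        assert text.count(" OR ") == 7
        assert hs.parse_rule(text).clauses == ivs.clauses

    def test_hundred_random_rules_round_trip_byte_identically(self):
        rng = np.random.default_rng(123)
        ids = [str(i) for i in range(1, 60)]
        for k in range(100):
            rule = _random_rule(rng, ids, n_clauses=int(rng.integers(1, 6)))
            text = hs.serialize_rule(rule)
            reparsed = hs.parse_rule(text)
            # one normalization pass: includes first, then excludes
            assert reparsed.clauses == rule.includes + rule.excludes
            assert hs.serialize_rule(reparsed) == text

    def test_rule_file_round_trip_with_comments(self, tmp_path):
        ivs = hs.parse_rule("<<1 OR <2 MINUS 3", condition_label="demo")
        path = tmp_path / "demo.rule"
        hs.write_rule_file(ivs, str(path))
        assert hs.load_rule_file(str(path)).clauses == ivs.clauses


class TestExpansion:
    def test_leaf_include_expands_to_itself(self, diamond_graph):
        out = hs.expand(IVS("r", [Clause(INC, "4", SAD)]), diamond_graph)
        assert out.concept_ids == {"4"}
        assert out.provenance == "derived"

    def test_subtraction_removes_multi_path_descendants(self, diamond_graph):
        # D sits under both B and C; excluding C's subtree must remove D
        out = hs.expand(hs.parse_rule("<<1 MINUS <<3"), diamond_graph)
        assert out.concept_ids == {"1", "2"}

    def test_descendants_only_scope_excludes_the_anchor(self, diamond_graph):
        out = hs.expand(hs.parse_rule("<1"), diamond_graph)
        assert out.concept_ids == {"2", "3", "4"}

    def test_missing_clause_concept_names_the_id(self, diamond_graph):
        with pytest.raises(hs.ConceptNotFoundError, match="999"):
            hs.expand(hs.parse_rule("<<999"), diamond_graph)

    def test_expansion_matches_set_algebra_oracle(self, synthetic_graph):
        rng = np.random.default_rng(2024)
        ids = sorted(synthetic_graph.concept_ids)
        edges = synthetic_graph.edges
        for _ in range(100):
            rule = _random_rule(rng, ids, n_clauses=3)
            assert hs.expand(rule, synthetic_graph).concept_ids == brute_expand(
                edges, rule
            )

    def test_include_monotone_exclude_antitone(self, synthetic_graph):
        rng = np.random.default_rng(7)
        ids = sorted(synthetic_graph.concept_ids)
        for _ in range(30):
            base = _random_rule(rng, ids, n_clauses=2)
            extra = str(rng.choice(ids))
            with_inc = IVS("r", base.clauses + [Clause(INC, extra, SAD)])
            with_exc = IVS("r", base.clauses + [Clause(EXC, extra, SAD)])
            baseline = hs.expand(base, synthetic_graph).concept_ids
            assert hs.expand(with_inc, synthetic_graph).concept_ids >= baseline
            assert hs.expand(with_exc, synthetic_graph).concept_ids <= baseline

    def test_output_concepts_lie_under_some_include(self, synthetic_graph):
        rng = np.random.default_rng(99)
        ids = sorted(synthetic_graph.concept_ids)
        for _ in range(20):
            rule = _random_rule(rng, ids, n_clauses=4)
            expansion = hs.expand(rule, synthetic_graph).concept_ids
            under_includes = set()
            for clause in rule.includes:
                include_self = clause.scope is not DO
                under_includes |= synthetic_graph.descendants(
                    clause.concept_id, include_self=include_self
                )
            assert expansion <= under_includes

    def test_include_only_rules_at_least_as_big_as_rule(self, synthetic_graph):
        rng = np.random.default_rng(5)
        ids = sorted(synthetic_graph.concept_ids)
        for _ in range(20):
            roots = rng.choice(ids, size=3, replace=False)
            rule = IVS("r", [Clause(INC, str(r), SAD) for r in roots])
            assert len(hs.expand(rule, synthetic_graph)) >= hs.concepts_to_define(rule)

    def test_expand_invariant_to_reserialization(self, synthetic_graph):
        rng = np.random.default_rng(31)
        ids = sorted(synthetic_graph.concept_ids)
        for _ in range(20):
            rule = _random_rule(rng, ids)
            direct = hs.expand(rule, synthetic_graph).concept_ids
            reparsed = hs.parse_rule(hs.serialize_rule(rule))
            assert hs.expand(reparsed, synthetic_graph).concept_ids == direct


class TestConceptsToDefine:
    def test_rule_counts_clauses_as_written(self):
        two = hs.parse_rule("<<33449004 MINUS <<36217008")
        assert hs.concepts_to_define(two) == 2
        dup = IVS("r", [Clause(INC, "5", SAD), Clause(INC, "5", SAD)])
        assert hs.concepts_to_define(dup) == 2  # duplicates count as written

    def test_extensional_counts_cardinality(self):
        evs = hs.ExtensionalValueSet("bipolar", {str(i) for i in range(99)})
        assert hs.concepts_to_define(evs) == 99
        assert hs.concepts_to_define(hs.ExtensionalValueSet("one", {"7"})) == 1

    def test_rules_need_an_include(self):
        with pytest.raises(hs.ValidationError):
            IVS("r", [Clause(EXC, "5", SAD)])
        with pytest.raises(hs.ValidationError):
            IVS("r", [])
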