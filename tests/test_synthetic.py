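"""Synthetic ontologies, term maps, condition rules, degraded downloads."""

from __future__ import annotations

import json

import numpy as np
import pytest

import hierset as hs
from conftest import brute_expand


class TestGenerateOntology:
    def test_same_seed_reproduces_edge_list(self):
        config = hs.SyntheticConfig(n_concepts=150, seed=5)
        g1 = hs.generate_ontology(config)
        g2 = hs.generate_ontology(config)
        assert g1.edges == g2.edges and g1.concept_ids == g2.concept_ids

    def test_zero_extra_parent_probability_gives_a_tree(self):
        g = hs.generate_ontology(
            hs.SyntheticConfig(n_concepts=120, extra_parent_probability=0.0, seed=2)
        )
        assert len(g.edges) == len(g) - 1

    @pytest.mark.parametrize("seed", range(20))
    def test_maximal_polyhierarchy_stays_acyclic(self, seed):
        g = hs.generate_ontology(
            hs.SyntheticConfig(n_concepts=500, extra_parent_probability=1.0, seed=seed)
        )
        g.validate()  # topological-sort check
        assert len(g) == 500

    def test_single_root(self):
        g = hs.generate_ontology(hs.SyntheticConfig(n_concepts=300, seed=6))
        assert len(g.roots()) == 1
        root = next(iter(g.roots()))
        assert g.descendants(root) == g.concept_ids

    def test_depth_bound_respected(self):
        config = hs.SyntheticConfig(n_concepts=400, max_depth=4, seed=3)
        g = hs.generate_ontology(config)
        root = next(iter(g.roots()))
        # every node's shortest path to the root is within the bound
        for cid in g.concept_ids:
            depth = 0
            frontier = {cid}
            while root not in frontier:
                frontier = set().union(*(g.parents(c) for c in frontier))
                depth += 1
            assert depth <= config.max_depth

    def test_config_validation(self):
        with pytest.raises(hs.ValidationError):
            hs.SyntheticConfig(n_concepts=1)
        with pytest.raises(hs.ValidationError):
            hs.SyntheticConfig(extra_parent_probability=1.5)
        with pytest.raises(hs.ValidationError):
            hs.SyntheticConfig(degradation_fraction=1.0)


class TestGenerateTermMap:
    def test_mean_one_collapses_to_one_term_each(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, terms_per_concept=1.0, seed=4)
        tm = hs.generate_term_map(synthetic_graph, config)
        assert len(tm) == len(synthetic_graph)
        assert all(len(tm.terms_for_concept(c)) == 1 for c in synthetic_graph.concept_ids)

    def test_empirical_mean_tracks_configured_mean(self):
        g = hs.generate_ontology(hs.SyntheticConfig(n_concepts=1000, seed=8))
        tm = hs.generate_term_map(g, hs.SyntheticConfig(n_concepts=1000, terms_per_concept=5.0, seed=8))
        assert len(tm) / len(g) == pytest.approx(5.0, abs=0.3)

    def test_every_concept_gets_at_least_one_term(self, synthetic_graph):
        tm = hs.generate_term_map(synthetic_graph, hs.SyntheticConfig(n_concepts=200, seed=10))
        assert tm.concept_ids == synthetic_graph.concept_ids

    def test_same_seed_reproduces_map(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, seed=12)
        a = hs.generate_term_map(synthetic_graph, config)
        b = hs.generate_term_map(synthetic_graph, config)
        assert {(r.term_id, r.concept_id) for r in a.records} == {
            (r.term_id, r.concept_id) for r in b.records
        }


class TestSampleCondition:
    def test_expansion_nonempty_strict_subset(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, seed=20)
        ivs = hs.sample_condition(synthetic_graph, config, seed=20)
        expansion = hs.expand(ivs, synthetic_graph).concept_ids
        assert expansion and expansion < synthetic_graph.concept_ids

    def test_exclusion_shrinks_the_include_only_expansion(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, seed=21)
        for seed in range(40):
            ivs = hs.sample_condition(synthetic_graph, config, seed=seed)
            if not ivs.excludes:
                continue
            include_only = hs.IntensionalValueSet("inc", list(ivs.includes))
            full = hs.expand(ivs, synthetic_graph).concept_ids
            base = hs.expand(include_only, synthetic_graph).concept_ids
            assert full < base
            return
        pytest.fail("no sampled condition carried an exclusion in 40 seeds")

    def test_hundred_sampled_conditions_match_expansion_oracle(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, seed=22)
        edges = synthetic_graph.edges
        for seed in range(100):
            ivs = hs.sample_condition(synthetic_graph, config, seed=seed)
            assert hs.expand(ivs, synthetic_graph).concept_ids == brute_expand(edges, ivs)

    def test_too_flat_graph_errors(self):
        g = hs.generate_ontology(hs.SyntheticConfig(n_concepts=4, seed=1))
        with pytest.raises(hs.ValidationError, match="descendants"):
            hs.sample_condition(g, hs.SyntheticConfig(n_concepts=4, seed=1), min_descendants=50)


class TestDegrade:
    @pytest.fixture
    def derived(self, synthetic_graph):
        config = hs.SyntheticConfig(n_concepts=200, seed=30)
        ivs = hs.sample_condition(synthetic_graph, config, seed=30, min_descendants=30)
        return hs.expand(ivs, synthetic_graph), {c.concept_id for c in ivs.includes}

    def test_fraction_zero_is_identity(self, derived):
        evs, roots = derived
        out = hs.degrade_to_extensional(evs, 0.0, roots, seed=1)
        assert out.concept_ids == evs.concept_ids
        assert out.provenance == "synthetic"

    def test_roots_always_retained(self, derived):
        evs, roots = derived
        out = hs.degrade_to_extensional(evs, 0.9, roots, seed=2)
        assert roots <= out.concept_ids

    def test_same_seed_reproduces(self, derived):
        evs, roots = derived
        a = hs.degrade_to_extensional(evs, 0.65, roots, seed=3)
        b = hs.degrade_to_extensional(evs, 0.65, roots, seed=3)
        assert a.concept_ids == b.concept_ids

    def test_missing_root_errors(self, derived):
        evs, _ = derived
        with pytest.raises(hs.ValidationError, match="not in derived"):
            hs.degrade_to_extensional(evs, 0.5, {"404404"}, seed=4)

    def test_retention_within_binomial_band(self, derived):
        evs, roots = derived
        n = len(evs)
        out = hs.degrade_to_extensional(evs, 0.65, roots, seed=5)
        expected = 0.35 * (n - len(roots)) + len(roots)
        sd = np.sqrt(n * 0.65 * 0.35)
        assert abs(len(out) - expected) <= 3 * sd


class TestFixtureBundle:
    def test_bundle_files_reload(self, bundle):
        out, config, manifest = bundle
        graph = hs.load_edge_table(str(out / manifest["files"]["edges"]))
        term_map = hs.load_term_map(str(out / manifest["files"]["term_map"]))
        timing = hs.load_timing_observations(str(out / manifest["files"]["timing"]))
        assert len(graph) == config.n_concepts
        assert term_map.concept_ids <= graph.concept_ids
        assert len(timing) == config.n_conditions
        assert len(manifest["conditions"]) == config.n_conditions
        for cond in manifest["conditions"]:
            ivs = hs.load_rule_file(str(out / cond["rule_file"]))
            downloaded = hs.read_vsac_export(str(out / cond["downloaded_csv"]))
            assert len(downloaded) == cond["n_downloaded"]
            assert len(hs.expand(ivs, graph)) == cond["n_derived"]

    def test_manifest_json_matches_return_value(self, bundle):
        out, _, manifest = bundle
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk == manifest

    def test_different_seeds_differ(self, tmp_path):
        a = hs.make_fixture_bundle(
            hs.SyntheticConfig(n_concepts=300, n_conditions=2, seed=1), str(tmp_path / "a")
        )
        b = hs.make_fixture_bundle(
            hs.SyntheticConfig(n_concepts=300, n_conditions=2, seed=2), str(tmp_path / "b")
        )
        assert a["conditions"][0]["clause_roots"] != b["conditions"][0]["clause_roots"] or (
            a["conditions"][0]["n_downloaded"] != b["conditions"][0]["n_downloaded"]
        )
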