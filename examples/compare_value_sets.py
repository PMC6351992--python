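"""Audit a downloaded flat list against a hierarchy rule.

Generates a synthetic ontology and term map, samples a condition rule,
simulates a stale downloaded list (35% concept retention), and prints
the full per-condition comparison row: conciseness, completeness, and
clinical-term coverage.
"""

import hierset as hs

config = hs.SyntheticConfig(n_concepts=800, degradation_fraction=0.65, seed=42)
graph = hs.generate_ontology(config)
term_map = hs.generate_term_map(graph, config)

rule = hs.sample_condition(graph, config, seed=7, min_descendants=60, name="demo condition")
derived = hs.expand(rule, graph)
downloaded = hs.degrade_to_extensional(
    derived, config.degradation_fraction,
    clause_roots={c.concept_id for c in rule.includes}, seed=7,
)

row = hs.build_condition_comparison(downloaded, rule, graph, term_map)

print(f"rule: {hs.serialize_rule(rule)}")
print(f"downloaded list: {row.n_downloaded} concepts; derived expansion: {row.n_derived}")
print(f"ratio to define (download/rule): {row.ratio_to_define_download}")
print(f"ratio to define (derived/rule):  {row.ratio_to_define_derived}")
print(f"completeness ratio (derived/downloaded): {row.completeness_ratio}")
print(f"percent of expansion present in download: {row.percent_concepts_included}%")
print(f"discrepancies: {row.discrepancies.total} "
      f"(download-only {row.discrepancies.only_in_downloaded}, "
      f"derived-only {row.discrepancies.only_in_derived})")
print(f"clinician-selectable terms: {row.n_terms_downloaded} via download vs "
      f"{row.n_terms_intensional} via rule -> {row.term_percent}% covered")

# percent_included near 35% is the simulated staleness showing up in the
# audit: the flat list silently misses ~65% of the condition's concepts,
# and a similar share of the terms clinicians could pick in an EHR.
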