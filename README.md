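# hierset

Intensional (hierarchy-based) value sets over SNOMED CT-style
polyhierarchies: rule expansion, completeness auditing, and comparison
against extensional (flat-list) value sets.

## The problem

Computable clinical phenotypes — "all patients with depression", "all
patients with CKD stage 5 or ESRD" — are defined by *value sets* of
SNOMED CT concepts. Two styles exist:

* **extensional**: an enumerated list of concept codes, the traditional
  form distributed by repositories such as the Value Set Authority
  Center (VSAC);
* **intensional**: a rule over the terminology's is-a polyhierarchy,
  e.g. *Personality disorder (33449004) and all its descendants, AND NOT
  Organic personality disorder (36217008) and its descendants* — in
  Expression Constraint Language, `<<33449004 MINUS <<36217008`.

Flat lists are brittle: each terminology release adds descendant
concepts the list silently misses, and every concept a list misses also
drops all the clinician-facing diagnosis terms mapped to it, so patients
whose clinicians recorded perfectly specific diagnoses fall out of the
phenotype. This package implements the machinery to quantify that
trade-off, for terminologists, EHR analysts and clinical-informatics
researchers.

## What it computes

For a condition with downloaded list $V$, rule $R$ (with derived
expansion $D = \mathrm{expand}(R)$) and a many-to-one clinical-term map
$T$:

* **conciseness** — concepts to define, and ratio-to-define
  $|V|/|R|$ and $|D|/|R|$;
* **concept completeness** — discrepancies $|V \setminus D|$,
  $|D \setminus V|$; ratio $|D|/|V|$; percent included
  $100\,|V|/|D|$;
* **term coverage** — the same ratio/percent over compiled term lists
  $T(V)$ vs $T(D)$;
* **creation time** — an affine cost model
  $t(n) = \beta_1 n + \beta_0$ fit by OLS to measured build times
  (reference fit: $\beta_1 = 0.4177$ min/concept,
  $\beta_0 = 3.8707$ min);
* **summaries** across conditions: overall (sum or ratio-of-sums),
  median, minimum, maximum, range.

Rule semantics are pure set algebra on the is-a DAG: union of include-
clause closures minus union of exclude-clause closures, with `<<`
(descendant-or-self), `<` (descendants-only) and bare-concept scopes.

A synthetic-data module generates seeded SNOMED-like polyhierarchies,
term maps, condition rules and "stale" downloaded lists, so the whole
pipeline is testable without licensed terminology content.

## Worked example

```python
import hierset as hs

config = hs.SyntheticConfig(n_concepts=800, degradation_fraction=0.65, seed=42)
graph = hs.generate_ontology(config)
term_map = hs.generate_term_map(graph, config)

rule = hs.sample_condition(graph, config, seed=7, min_descendants=60)
derived = hs.expand(rule, graph)
downloaded = hs.degrade_to_extensional(
    derived, 0.65, {c.concept_id for c in rule.includes}, seed=7)

row = hs.build_condition_comparison(downloaded, rule, graph, term_map)
```

Running `python examples/compare_value_sets.py` (the script around the
snippet above) prints:

```
rule: <<10000049
downloaded list: 20 concepts; derived expansion: 70
ratio to define (download/rule): 20.0
ratio to define (derived/rule):  70.0
completeness ratio (derived/downloaded): 3.5
percent of expansion present in download: 29%
discrepancies: 50 (download-only 0, derived-only 50)
clinician-selectable terms: 233 via download vs 830 via rule -> 28% covered
```

Reading: a one-concept rule replaces a 70-concept enumeration; the
simulated stale download holds 29% of the expansion's concepts (the
generator dropped 65%), and consequently only 28% of the diagnosis terms
a clinician could select would land in the phenotype.

Other examples: `expand_rule.py` (exclusion semantics on a small
hierarchy), `reference_tables.py` (the shipped ten-condition reference
comparison), `time_model.py` (OLS fit + predictions),
`synthetic_pipeline.py` (config-driven end-to-end run). A thin CLI
mirrors the library: `hierset expand | diff | report | simulate |
fit-time`.

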