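"""Expand an intensional rule over a small hierarchy.

Builds a six-concept mood-disorder-style hierarchy by hand, then expands
the rule "mood disorder and all its descendants, AND NOT the organic
subtype" into its exactly-equivalent extensional enumeration.
"""

import hierset as hs

graph = hs.ConceptGraph()
for cid, label in [
    ("100", "Mood disorder"),
    ("110", "Depressive disorder"),
    ("111", "Recurrent depression"),
    ("120", "Bipolar disorder"),
    ("130", "Organic mood disorder"),
    ("131", "Organic depressive state"),
]:
    graph.add_node(hs.ConceptNode(cid, label=label))
for child, parent in [
    ("110", "100"), ("111", "110"), ("120", "100"), ("130", "100"), ("131", "130"),
    ("131", "110"),  # organic depressive state is also a depressive disorder
]:
    graph.add_edge(child, parent)
graph.validate()

rule = hs.parse_rule("<<100 MINUS <<130", name="mood-non-organic")
derived = hs.expand(rule, graph)

print(f"rule: {hs.serialize_rule(rule)}")
print(f"concepts to define (rule): {hs.concepts_to_define(rule)}")
print(f"derived extensional set ({len(derived)} concepts):")
for cid in sorted(derived.concept_ids):
    print(f"  {cid}  {graph.label(cid)}")

# The organic subtree (130, 131) is removed even though 131 also sits
# under the included depressive branch: exclusions are pure set
# subtraction after all inclusions.
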