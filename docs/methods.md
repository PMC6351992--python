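# Methods

## Model and semantics

**Hierarchy.** A terminology snapshot is modelled as a directed acyclic
graph over concepts, edges oriented child → parent (the RF2 convention:
`sourceId` is the subtype). Only active concepts, active relationships,
and the is-a relationship type (116680003) are retained; attribute
relationships (finding site, morphology, …) are out of scope. Concept
identifiers are opaque digit strings throughout — SCTIDs can exceed 15
digits, and integer or float handling (e.g. a spreadsheet round-trip)
corrupts them. A cyclic input is a hard load-time error, never silently
broken: expansion semantics are undefined on a cyclic "hierarchy".

**Rules.** An intensional value set is an ordered list of clauses, each
a (polarity, concept, scope) triple. Scopes follow Expression Constraint
Language: `<<` descendant-or-self, `<` descendants-only, bare id
self-only. "Including descendants" in prose is read as
descendant-OR-self (`<<`): the anchor concept (e.g. the osteoporosis
concept itself) is clinically part of the phenotype. Evaluation is pure
Boolean set algebra — union of include closures minus union of exclude
closures — so exclusions always apply after all inclusions ("AND NOT")
and clause order never changes the result. Duplicate clauses collapse at
expansion but are counted as written by the conciseness measure, which
counts definition references, not distinct concepts.

The grammar joins terms with `OR` and introduces exclusions with
`MINUS` (`AND NOT` accepted as an alias). The grammar is deliberately
tiny — no parentheses, refinements or attribute constraints — because
hierarchy references plus subtraction express the condition-defining
rules this package audits. One genuinely open choice: after a `MINUS`,
are later `OR`-joined terms includes or excludes? Since evaluation
normalizes includes-before-excludes anyway, either reading is
expressible; the parser stays in exclude mode after the first `MINUS`,
and the serializer sidesteps the question by emitting one `MINUS` per
exclude clause.

**Downloaded lists** are taken exactly as published: expansion of a
`downloaded` extensional set is the identity (no descendant inclusion),
mirroring how EHR builds match a published list code-for-code.

## Metrics and conventions

For downloaded list V, rule R, derived expansion D, term map T:

| measure | definition | display |
|---|---|---|
| ratio to define | \|V\|/\|R\|, \|D\|/\|R\| | 1 decimal |
| completeness ratio | \|D\|/\|V\| | 1 decimal |
| percent included | 100·\|V\|/\|D\| | integer |
| discrepancies | \|V∖D\|, \|D∖V\|, their sum | exact |
| term coverage | \|T(D)\|/\|T(V)\| and 100·\|T(V)\|/\|T(D)\| | 1 dp / integer |

Rounding is half-away-from-zero (spreadsheet convention), applied only
at display; all summary statistics are computed on unrounded values.
Empty denominators raise errors — a coverage ratio is never infinity.

Cross-condition summary rows report overall, median, min, max, range.
The median (even counts: mean of the two central order statistics) is
the primary central-tendency measure; it resists a single huge hierarchy
dominating. The "overall" cell is a sum for count columns and a
**ratio of sums** for ratio/percent columns — recomputed from summed
numerators and denominators, not the mean of per-condition ratios.

Terms map many-to-one onto concepts, and exactly one concept per term;
a duplicated term id is a load error because compiled-list counts
presume a function. Terms mapped to concepts absent from the loaded
graph stay in the map (a validation helper reports them) but can never
be compiled.

## Time model

Creation time is affine in concept count: an obligate setup cost
(intercept, ≈4 min) plus a per-concept entry cost (slope, ≈25 s). The
model is fit by ordinary least squares (numpy least-squares on the
design matrix [n, 1]); predictions round to whole minutes half-away-
from-zero only for display. Observations carry a measured/estimated
flag; only measured rows enter fits. The shipped reference coefficients
(0.4177, 3.8707) were fit on the reference study's timed builds and are
treated as raw inputs alongside the condition table.

In the shipped reference table, summary statistics over build times use
the *unrounded* estimates for estimated rows (e.g. 101.19 min for the
hypertension expansion) and measured values for timed rows; the printed
whole-minute times are the display view of the same numbers. Derived
difference and ratio columns are likewise computed from unrounded
minutes; historically published versions of those two columns mixed
rounded and unrounded sources and are not reproducible from whole-minute
inputs, so this package reports its own consistent values. Similarly the
reference "overall" ratio-to-define cell is reported as the ratio of
sums (375/49 = 7.65) with a footnote, because no ratio-of-sums or
mean-of-ratios computation reproduces the historically printed 7.5.

The reference term-coverage table lacks term counts for one of its ten
conditions (prostate cancer); term-coverage summaries are computed over
the nine rows that have counts, and that column's medians are therefore
not comparable to a ten-row summary.

## Synthetic data: what it emulates, and what it does not

The generator produces, per seed, deterministically:

* **Ontology** — single-rooted DAG; each non-root node takes one
  uniform-random parent among nodes above the depth cap (default 12),
  plus a second parent with probability 0.15 chosen among nodes no
  deeper than the first. Extra parents never create cycles by
  construction (a new node has no descendants; second parents are never
  deeper), and validation re-checks acyclicity. Default 2000 concepts.
* **Term map** — per concept, 1 + Poisson(mean − 1) terms (mean 12 by
  default, so a configured mean of 1 degenerates to exactly one term
  each). This mirrors interface terminologies that map tens of
  clinician-facing terms onto each concept.
* **Condition rules** — an include anchor sampled among nodes with a
  subtree in a configured size band, plus, with probability ½, an
  exclusion at a child whose removal keeps at least half the expansion
  (real exclusions carve out a minority subtype, e.g. the organic form
  of a disorder).
* **Stale downloads** — each non-anchor concept of the expansion is
  dropped independently with the degradation fraction (default 0.65,
  i.e. 35% retention, matching the staleness the reference audit
  observed); anchors are always retained because every inspected real
  download contained its condition's anchor concept.

Fixture bundles sample anchors with 40–600 strict descendants: the scale
of real condition value sets (tens to a few hundred concepts), with the
lower bound chosen so the always-retained anchor perturbs measured
retention by well under 2 percentage points.

Not emulated: SNOMED lexical content and semantic tags, module
structure, release-to-release concept migration, attribute
relationships, and any correlation between subtree topology and
staleness (real list rot concentrates in recently refined subtrees).
Passing tests therefore demonstrate the correctness of the expansion and
audit machinery and the recoverability of known generator truth — not
that any particular real value set is incomplete.

## Numerical and design choices

* Closure queries delegate to networkx reachability; an all-nodes
  descendant-set sweep (one topological-order DP pass) serves callers
  that need subtree sizes for every node, e.g. condition sampling.
* OLS requires ≥ 2 observations spanning ≥ 2 distinct concept counts;
  an all-equal design raises rather than returning an unidentifiable
  slope.
* Summaries of a single condition degenerate (median = min = max,
  range 0) rather than erroring.
* The export-CSV reader matches headers case-insensitively and requires
  only the code column, since the public export dialect has varied
  across vintages; duplicate codes collapse with a warning, and an
  empty export is a warning plus empty set, not an error.
* Loading handles one snapshot at a time; merging international and
  national edition modules is left to the caller.
* Problem sizes in the test suite (graphs of 200–2000 nodes, 100-rule
  oracle sweeps, 30-seed recovery runs) were chosen so the brute-force
  oracles stay exhaustive while the whole suite runs in seconds.

## Known limitations

* Only is-a semantics: no description-logic classification; the stated
  hierarchy is taken as given.
* No live repository/terminology-server client and no FHIR ValueSet
  `$expand`; files are the interface.
* Historical-association resolution for inactivated concepts is out of
  scope; inactive content is simply dropped.
* The time model has a single covariate; it says nothing about
  vetting/consensus effort, only keyboard construction time.
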