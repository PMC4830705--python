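# Methods

This note documents the models, semantics and numerical choices behind the
engine, the parameters that matter, and what the synthetic study conditions
do and do not establish about real data.

## Terminology model and close-match derivation

A terminology is a `ConceptScheme`: an ordered list of level names
(broadest first) and a set of coded concepts, each tagged with a level and
a set of `broader` parents. Levels are declared, not inferred from depth,
because real vocabularies are uneven; multi-parent concepts are allowed to
model multiaxial hierarchies, and the parent-strictly-broader rule makes
the graph a DAG by construction (a cycle check still guards the invariant).

Cross-scheme mappings are directed assertions tagged by their curated
source set (`omop_like`, `protect_like`, `crossmap_like`,
`identical_code`), all of strength *close*. The materialized `close_match`
relation is the transitive closure of the arc set those assertions
contribute. Two rules are deliberate:

* **Bidirectional by default, restrictable per relation.** The curated
  sets are used for mutual matching, so each assertion contributes both
  arcs unless a `DerivationConfig` restricts that relation to one
  direction; a restricted relation is *not* re-symmetrized, otherwise the
  switch would be meaningless. Under the default config the closure equals
  breadth-first reachability over the symmetrized assertion graph, which
  is the oracle the tests compare against.
* **Hierarchy never participates.** `broader` edges are excluded from the
  derivation entirely. Folding hierarchy into matching (as generic SKOS
  mapping semantics invite) manufactures equivalences the mapping curators
  never asserted; the regression test asserts that rich hierarchies with
  zero assertions close to nothing.

Group links flatten multi-hop chains ahead of query time:
`group_link(a, g)` holds iff some target-scheme concept `m` is a close
match of `a` (zero hops if `a` is already in the target scheme) and `g` is
an ancestor-or-self of `m` at exactly the requested level. A multiaxial
code keeps every group; dropping axes silently would bias the
characterization. Codes with no route into the target scheme go to the
reserved `UNMAPPED` group rather than disappearing.

Query expansion inverts the analyst→source direction:
`expand_query_codes` returns the source-scheme close matches of a code
plus all their descendants. When the queried code already belongs to the
source scheme it is included itself (zero-hop, mirroring the group-link
rule); without this, risk-factor codes written in the analyst scheme could
never match analyst-coded data. An unmapped code expands to the empty set
— the query layer reports the leaf as unsatisfiable instead of erroring,
because an analyst query must still run against sources that simply lack
the concept.

Materialized links are cached as a sorted TSV keyed by a content hash of
schemes, assertions and derivation config; a stale cache is rebuilt, and
identical inputs produce bit-identical cache files.

## Common model and query semantics

Patient records carry demographics (birth year, coded gender/country) and
dated, coded statements of five kinds; an extensions map leaves room for
new data elements without disturbing existing ones. Dates are day-granular
throughout — ingest truncates any time part — because every criterion the
engine supports is day-scale.

Eligibility criteria form an AST: `Leaf` (≥1 statement of a kind coded in
a set), `Bool` (AND/OR, ≥2 children), `Temporal` (a related statement
within a window of an anchor statement). Temporal semantics, all declared
and boundary-tested:

* window bounds are **inclusive at both ends**; day 0 counts. `after`
  means `related.start − anchor.start ∈ [0, W]`, `before` mirrors it,
  `either` is the union.
* matching is **existential**: any qualifying (anchor, related) pair
  suffices.
* only `effective_start` anchors temporal matching; prescriptions in the
  modelled sources are point events. Undated statements never satisfy a
  temporal node.
* temporal children must be a `Leaf` or an OR of leaves. AND under a
  temporal node has no coherent statement-pair reading, so it is rejected
  as a configuration error rather than silently interpreted.

Evaluation applies **no hierarchy closure** — localization already
expanded the codes — which keeps the evaluator a simple set-algebra pass
and makes the dual-evaluation soundness property (localized query on
source-coded data ≡ analyst query on analyst-coded data) testable.

Derived-condition rules capture indirectly evidenced diagnoses (the
canonical example: diabetes from age, a metformin-like medication and an
elevated glycated-haemoglobin value). All configured criteria are
conjunctive; the inferred statement is flagged `derived`, dated at the
earliest supporting evidence, and the rule skips patients who already
carry the code, making re-application idempotent.

Aggregation namespaces patient ids as `source:id`, so per-source counts
add exactly; `aggregate` validates that the populations it receives were
selected under the same source id, turning a silent join-miss into an
error.

## Mediation

XML sources are first formalized into a `NodeGraph` — one node per
element, one literal per attribute or non-empty text node — so the
transformation is one-to-one by construction and re-serializes to an
equivalent document (attribute order and whitespace are not significant).
Conversion is driven by declarative rules (path patterns with attribute
predicates, bindings from relative literal paths to common-model fields);
the shipped default ruleset covers demographics and all five statement
kinds for both dialects. Relational sources convert analogously with
table/column bindings; rows whose foreign key does not join to `patients`
are skipped with a finding. Unconverted content is counted and listed in
a residue report, never dropped silently, and unparseable dates keep the
statement (undated) with a finding. Source `codeSystem` identifiers are
normalized to scheme ids through a shipped lookup table of OID-style
identifiers, with `urn:scheme:<id>` as the pass-through convention.

Rule application is order-independent because outputs are canonically
sorted and the shipped patterns are disjoint; the tests shuffle the
ruleset to enforce this.

## De-identification

Four transforms: keyed pseudonyms (hash of seed, source and id, collision
checked); birth dates generalized to year (structural in the common
model); one uniform offset per patient from `[−R, +R]` days (default
R = 30) applied to all of the patient's dates; and removal of statements
whose code occurs in fewer than `rare_threshold` distinct patients
(default 5) source-wide. Offsets are hash-derived per patient, so they are
independent of record order; offset 0 is allowed — excluding it would leak
information about true dates. Removal is statement-level, not
patient-level: deleting whole patients would distort denominators. The
audit reports counts and the offset distribution, never per-patient
offsets. Coherent shifting preserves all intra-patient intervals exactly,
hence windowed eligibility is invariant; the end-to-end test asserts both.

## Characterization

Counts are patient counts — a patient with three statements in one group
contributes 1 — because rates must be comparable across populations of
different size; event counts are carried alongside in the JSON for
transparency. Before/after boxes use strict inequality against the index
date (the earliest statement matching the index anchor): index-day events
appear only in the overall box, avoiding double counting. Patients without
an index date are excluded from before/after denominators and the reported
denominator reflects that. Percentages round half-up to two decimals
(`0.305 → 0.31`); rows sort by foreground rate descending with code as the
tie-break, making reports deterministic byte-for-byte.

## Synthetic study conditions

The generator builds a research scheme (SOC>HLGT>HLT>PT analogue, default
branching 3×3×3×3, 10 % of leaf terms multiaxial), a flat pivot scheme,
two care schemes with independent 3-level hierarchies, and a drug scheme
with an identical-code care variant. Mapping chains run
care_A → pivot ← research → … → care_B, so a care code reaches its
research group only through multi-hop closure — the topology
materialization exists to flatten. `mapping_consistency < 1` severs the
research→pivot link for a fraction of leaves (the designated reaction and
confounder terms stay mapped so the reference study remains expressible);
severed codes land in `UNMAPPED`.

Cohorts default to n = 2000 patients over a 10-year span: 30 % exposed to
the drug of interest (one prescription, uniformly placed so its window
fits the span), reaction within the inclusive `[0, W]` window with
probability `p_w = 0.05` (W = 120 days), baseline reactions anywhere with
`p_bg = 0.005`, a confounder at 25 % prevalence in reactors vs 10 % in
non-reactors, Poisson background conditions and medications, and a 50/50
gender split. Under this model the expected foreground share of the
background is

    E[fg/bg] = p_w + (1 − p_w) · q,   q = p_bg · (W + 1) / span

≈ 5.02 %. Parameter recovery is asserted on the proportion pooled over ten
replicate cohorts (seeds 1–10): each exposed patient is one Bernoulli
trial of the same model, so the pooled count is the natural binomial
statistic, and its 3-SE band is about three times narrower than a
single-cohort band. Per-concern RNG streams are split from the master
seed, so outputs are byte-identical under a fixed seed and changing, say,
the reaction model leaves demographics draws untouched.

What the synthetic conditions do **not** establish: realistic disease or
prescribing dynamics, coding noise and miscoding, free-text content,
record volumes at regional-DWH scale, or licensed-vocabulary topology
quirks. Passing tests show the *mechanisms* — mediation losslessness,
closure correctness, expansion soundness, interval-invariant
de-identification, tally arithmetic — are right, not that any particular
real-world signal would be detected.

## Problem sizes

Default verification runs use cohorts of 150–2000 patients, terminologies
of a few hundred concepts, 200 random mapping graphs up to 300 concepts,
and 10–20 replicate seeds per stochastic property; these sizes give the
statistical assertions adequate power while keeping the whole suite in the
tens of seconds.

## Known limitations

* The crossmap-style mapping sets in real life carry context-conditional
  rules ("map to X in the presence of Y"); the engine models them as plain
  close assertions and does not reconstruct conditional semantics.
* Temporal anchors are restricted to Leaf/OR-of-Leaf criteria; nested
  temporal chains (A within 30d of B within 60d of C) are expressible only
  by conjunction of pairwise windows.
* The common model covers five statement kinds plus demographics;
  encounters, family history and provider data elements are out of scope.
* Background-population denominators count distinct patients; sources
  that report per-year patient counts would need deduplication upstream.
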