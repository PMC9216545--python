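# Methods

This note records the model behind sssomkit, the defaults that matter, and
the design choices made where the standard leaves room.

## Data model and schema registry

The registry (`sssomkit.registry`) fixes the schema as code: 38
mapping-level slots in declaration order (the order also governs column
order on write), of which `subject_id`, `predicate_id`, `object_id` and
`match_type` are required; 23 set-level slots including the `curie_map`;
five match types; a single predicate modifier value `Not`. Nineteen slot
names exist at both levels (provenance such as `license`, `creator_id`,
`mapping_date`); each name has one registry entry whose `level` is
`both`, and the multivalued flag of the mapping level governs both views.

Thirteen slots carry an external vocabulary property used by the RDF
serializations: `author_id → pav:authoredBy` and `mapping_date →
pav:authoredOn` (PAV), `reviewer_id → prov:wasAttributedTo` (PROV-O), and
ten Dublin Core/RDFS alignments (`license → dcterms:license`, `creator_id
→ dcterms:creator`, `publication_date → dcterms:issued`, `subject_source`
and `object_source → dcterms:source`, `mapping_set_id →
dcterms:identifier`, `mapping_set_description → dcterms:description`,
`mapping_provider → dcterms:publisher`, `comment → rdfs:comment`,
`see_also → rdfs:seeAlso`). The 2-PAV/1-PROV split is normative; the exact
membership of the Dublin Core group is this package's own fixed choice.

Scores (`confidence`, `semantic_similarity_score`) are constrained to
[0, 1]; dates to ISO-8601 `YYYY-MM-DD` (verbose forms like "1 January
2020" are normalized on input when unambiguous, otherwise rejected);
`mapping_cardinality` to `{1:1, 1:n, n:1, n:n}`. `mapping_set_id` is typed
as a plain string because practice uses full IRIs, not CURIEs.

## Identifiers

CURIEs split at the *first* colon; local parts may contain further colons
(`UMLS:C00:15` is legal). Five prefixes are builtin — `owl`, `rdfs`,
`rdf`, `skos`, `sssom` — so the recommended predicates always resolve;
every other prefix must be declared in the `curie_map`. Expansion is
string concatenation; contraction picks the longest matching base, ties
broken by the lexicographically smallest prefix. The RDF converter keeps a
private vocabulary map (`dcterms`, `pav`, `prov`, `oboInOwl`) used only to
expand metadata *properties*, never user entity CURIEs — this keeps the
builtin set minimal without making the external alignments unserializable.

## TSV format

The embedded header is commented YAML: each line of the canonical
`yaml.safe_dump` (keys sorted, no line wrapping) prefixed with `#`;
parsing strips the `#` and at most one following space. The table has no
quoting dialect: tabs, newlines, cell values starting with `#`, and `|`
inside individual multivalued items are serialization errors. Multivalued
cells join on `|`; empty cells mean "absent". Floats are serialized with
`repr`, so `parse(write(s)) == s` holds exactly, field for field; writing
is canonical, so equal sets produce identical bytes. Strict parsing raises
on unknown columns, ragged rows, missing required columns and undeclared
prefixes; lenient parsing folds unknown columns into the `other` slot and
keeps un-coercible values as raw strings for the validator to report.

## Validation

Thirteen rules, each a code with a fixed severity. Severities are this
package's choice (the standard defines none): structural problems are
errors; a missing `license` is only a warning because the slot, while
strongly recommended, is not formally required; `R12` (preprocessing slots
populated while the corresponding match field is absent) is a warning
encoding a real interpretation hazard — preprocessing changes what a match
field means, so one without the other invites silent misreading. Issues
are data sorted by (code, locus); validation never raises.

## RDF export

Direct export emits one `S P O` triple per non-negated row. Negated rows
are deliberately absent: a plain `skos:exactMatch` triple for a rejected
mapping would assert the opposite of what the row means. Reified export
uses the `owl:Axiom` annotation pattern with deterministic skolem nodes
(`urn:sssom:axiom:<row>`): four core triples per row plus one triple per
populated metadata value, using the external property where registered and
`https://w3id.org/sssom/<slot>` otherwise; negation is carried as an
explicit annotation. OWL export adds one `rdf:type` declaration per
distinct entity, with the kind derived from the predicate (classes for
class equivalence/subsumption, `owl:NamedIndividual` for `owl:sameAs`,
`owl:ObjectProperty` for property predicates; SKOS predicates default to
class entities, configurable). Triple sets serialize as sorted N-Triples,
so all converters are byte-deterministic. The reified triple count equals
the per-row `4 + #metadata values` enumeration whenever no two populated
slots of a row expand to the same (property, value) pair; the only way to
collide is duplicated values within a slot or identical
`subject_source`/`object_source` (both map to `dcterms:source`), which the
synthetic generator avoids.

## Merging and reconciliation

`dedup` collapses only rows identical on *all* populated slots, preserving
"one row per mapping rule": rows sharing (s, p, modifier, o) but differing
in match metadata are distinct rules and survive. `collapse_rules` is the
deliberate inverse: confidence becomes the max over rules, match types
degrade to Complex unless unanimous, match fields/strings/preprocessing
are unioned in first-seen order, remaining metadata comes from the first
rule. Cardinality is computed over non-negated rows across all predicates
(a per-strength variant would be a straightforward extension; computing
across predicates matches how cardinality is read in practice).

Unique-object reconciliation enforces "no external term maps to more than
one internal term": among non-negated EXACT-class rows per `object_id`,
the winner has the highest confidence, then the most trusted match type
(HumanCurated > Logical > Lexical > SemanticSimilarity > Complex — a
declared ranking; the standard only implies human curation ranks
highest), then the lexicographically smallest `subject_id`. Losers are
re-emitted as negated rows with an explanatory comment, so rejected and
never-considered remain distinguishable. The rule is scoped to the EXACT
class: nothing in the uniqueness policy constrains broader/narrower links.

## Crosswalk composition algebra

The standard requires that mappings be chainable "where the predicate
semantics allow" but defines no algebra; the one implemented here is
conservative. EXACT is the identity. BROAD∘BROAD = BROAD and
NARROW∘NARROW = NARROW (subsumption chains). CLOSE∘CLOSE = RELATED,
because SKOS declares `closeMatch` non-transitive — two close hops support
only an unspecified association. Everything else (anything through
RELATED, BROAD mixed with NARROW) is undefined and terminates the chain:
no inference through vague links. Edges are stored undirected with
per-direction strengths (BROAD reversed is NARROW); negated rows,
UNKNOWN-class predicates and obsolete terms (an input list — the toolkit
never consults live ontologies) are excluded at graph construction, as are
rows whose confidence falls below the threshold (rows without a confidence
pass). Only simple paths are walked so cycles cannot inflate strength;
each entity is reported at its minimum distance with the strongest
strength among minimal paths, ties broken by lexicographically first path.
Correctness is checked against an independent oracle that enumerates
simple paths by intermediate-node permutations and folds strengths through
an independently restated rule function.

## Lexical matcher

The matcher consumes flat label tables (entity, naming property, text)
rather than ontologies, keeping ontology parsing out of scope. Texts are
compared after a configurable preprocessing pipeline; the default
(`lowercase`, `collapse_whitespace`) is non-destructive.
`strip_nonalphanumeric` keeps digits — "alzheimer 2" and "alzheimer 3"
stay distinct — while the separate `strip_digits` step merges them, which
is exactly the hazard the preprocessing metadata exists to expose: every
output row records its steps in `subject_preprocessing`/
`object_preprocessing`. Confidence defaults: label/label 0.9,
label/synonym 0.8, synonym/synonym 0.7, minus 0.05 per destructive step.
These weights are declared conventions on [0, 1] (no confidence scale is
normative anywhere), chosen to order evidence quality sensibly; the
`skos:exactMatch` match field is weighted like an exact synonym. Output is
one row per (subject record, object record) pair — one row per mapping
rule — sorted by (subject, object, confidence desc) for determinism;
self-matches are suppressed; overlapping entity ids between the two tables
warn but still match.

## Synthetic corpus

The generator realizes `n_concepts` abstract concepts as one entity per
namespace (`NS<i>:<zero-padded index>`), with shared two-word base labels
drawn from a fixed 30×40 adjective/noun vocabulary (unique per concept by
construction, so a noise-free corpus has precision = recall = 1 by design,
and any miss is a matcher defect). Synonyms (reversed word order, shared
across namespaces) are added per entity with probability `p_synonym`
(default 0.3, a middling synonym density). Noise steps emulate real
surface divergence: random case flips, punctuation insertion, digit
suffixes. The truth set contains every cross-namespace pair
(`n_concepts × C(n_namespaces, 2)` rows), oriented lower namespace index
as subject, as HumanCurated `skos:exactMatch`. Everything is driven by one
seed; equal specs give byte-identical output. What the generator does
*not* emulate: real terminological ambiguity (distinct concepts sharing
labels), partial overlap between vocabularies, multilingual labels, or
realistic label length distributions — so perfect recovery on this corpus
shows correctness of the matching machinery, not expected precision on
real ontologies. `random_mapping_set` serves the structural tests
(round-trips, triple counts, reconciliation) with schema-valid sets that
exercise most optional slots.

## Problem sizes and numerics

The verification runs use 200 random sets for round-trips, 100 random
graphs (4–12 nodes, walk distance ≤ 3) for crosswalk/oracle equivalence,
100 sets for triple-count contracts, 50 collapsed sets for reconciliation
and a 2-namespace × 50-concept corpus for matcher recovery; all complete
in seconds and the oracle enumeration stays exact at these sizes. All
comparisons are exact (integer counts, set equality, float equality where
values round-trip through `repr`); no tolerances are needed anywhere.

## Known limitations

Complex (expression-valued) subjects or objects, contextual/conditional
mappings and probabilistic reconciliation are out of scope. The TSV
dialect is deliberately restrictive (no quoting); files produced by tools
that quote cells or embed tabs will be rejected rather than guessed at.
Obsolete-term handling requires a caller-supplied list. The composition
algebra is intentionally conservative; consumers wanting bolder inference
(e.g. treating CLOSE as transitive) must pre-process predicates
themselves.
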