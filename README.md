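# sssomkit

A Python library and command-line toolkit for **SSSOM** (Simple Standard for
Sharing Ontological Mappings), the tabular standard for exchanging
terminological mappings between ontologies, terminologies and databases.

## The problem

Mappings — statements like "term `FMA:24875` in one anatomy ontology is an
exact match for `UBERON:0002101` in another" — are the glue of biomedical
data integration, yet they are usually shipped as bare two-column tables
with no record of *how exact* the correspondence is, *how* it was
established, or *who* vouches for it. That makes them unsafe to reuse,
merge or chain. SSSOM fixes this with a flat, metadata-rich data model:

* a **mapping** is a directed `subject_id — predicate_id — object_id`
  triple plus up to **38** metadata slots, four of which are required
  (`subject_id`, `predicate_id`, `object_id`, `match_type`);
* a **mapping set** groups mappings under **23** set-level slots, including
  a `curie_map` so every `prefix:local` identifier expands to an IRI;
* predicates are drawn from SKOS/OWL/RDFS (`skos:exactMatch`,
  `skos:closeMatch`, `skos:broadMatch`, `owl:sameAs`, `rdfs:subClassOf`, …)
  and classified by strength: EXACT, CLOSE, RELATED, BROAD, NARROW;
* `match_type` records the method (Lexical, Logical, HumanCurated,
  SemanticSimilarity, Complex), and `predicate_modifier: Not` records an
  *explicitly rejected* mapping, distinguishing "wrong" from "never
  reviewed";
* 13 slots are aligned with external vocabularies (2 to PAV, 1 to PROV-O,
  the rest to Dublin Core terms and RDFS) for the RDF serializations.

sssomkit implements the standard end to end: canonical TSV I/O (embedded or
external metadata header), a 13-rule validator, JSON/RDF/OWL export,
merging with deduplication and cardinality annotation, Mondo-style
unique-object reconciliation with explicit rejections, predicate-aware
crosswalks driven by a composition algebra over strength classes, a lexical
matcher over label tables, and a seeded synthetic-corpus generator for
testing all of the above without any downloads.

## Worked example

```python
from sssomkit import PrefixMap, MappingSet, make_mapping, write, validate
from sssomkit.crosswalk import build_graph, neighbors

pm = PrefixMap({
    "FMA": "http://purl.org/sig/ont/fma/fma",
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "MA": "http://purl.obolibrary.org/obo/MA_",
})
rows = [
    make_mapping({"subject_id": "FMA:24875", "predicate_id": "skos:exactMatch",
                  "object_id": "UBERON:0002101", "match_type": "HumanCurated",
                  "confidence": 0.98}),
    make_mapping({"subject_id": "UBERON:0002101", "predicate_id": "skos:exactMatch",
                  "object_id": "MA:0000007", "match_type": "Lexical",
                  "subject_match_field": ["rdfs:label"],
                  "object_match_field": ["rdfs:label"], "confidence": 0.9}),
]
ms = MappingSet(mapping_set_id="https://example.org/demo",
                license="https://creativecommons.org/publicdomain/zero/1.0/",
                curie_map=pm, mappings=rows)
print(write(ms).text)
print("issues:", validate(ms))
for n in neighbors(build_graph(ms), "FMA:24875", 2):
    print(n.entity, n.strength.value, n.distance, ">".join(n.path))
```

prints the canonical SSSOM TSV document —

```
#curie_map:
#  FMA: http://purl.org/sig/ont/fma/fma
#  MA: http://purl.obolibrary.org/obo/MA_
#  UBERON: http://purl.obolibrary.org/obo/UBERON_
#license: https://creativecommons.org/publicdomain/zero/1.0/
#mapping_set_id: https://example.org/demo
subject_id	predicate_id	object_id	match_type	confidence	subject_match_field	object_match_field
FMA:24875	skos:exactMatch	UBERON:0002101	HumanCurated	0.98		
UBERON:0002101	skos:exactMatch	MA:0000007	Lexical	0.9	rdfs:label	rdfs:label
```

— then an empty issue list (the set is valid), and the crosswalk result:

```
issues: []
UBERON:0002101 EXACT 1 FMA:24875>UBERON:0002101
MA:0000007 EXACT 2 FMA:24875>UBERON:0002101>MA:0000007
```

One hop from the FMA "free limb" term reaches the Uberon limb term; two
EXACT hops compose to EXACT, so the mouse-anatomy term is also reported as
an exact neighbor with its witness path. Had the second edge been
`skos:relatedMatch`, the derived strength would be RELATED and the entity
would disappear under `min_strength=EXACT` — chaining is only as strong as
its weakest link, and undefined compositions (e.g. BROAD followed by
NARROW) yield no claim at all.

The same operations are available from the shell:

```bash
sssom validate mappings.sssom.tsv
sssom convert mappings.sssom.tsv --to owl -o mappings.nt
sssom merge a.sssom.tsv b.sssom.tsv --id https://example.org/merged -o merged.tsv
sssom reconcile merged.tsv -o accepted.tsv --rejected rejected.tsv
sssom crosswalk merged.tsv --start FMA:24875 --distance 2 --min-strength exact
sssom generate --namespaces 2 --concepts 50 --seed 7 --out-dir corpus/
sssom match --subjects corpus/ns1_labels.tsv --objects corpus/ns2_labels.tsv
```

Exit codes: 0 on success, 1 when validation finds errors, 2 for usage or
IO problems.

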