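"""Seeded generators for label corpora, ground-truth mapping sets and
random-but-valid mapping sets.

The corpus generator emulates the everyday matching scenario: the same
abstract concepts named in several vocabularies (namespaces), with shared
base labels, optional exact synonyms and per-namespace surface noise (case
flips, punctuation, digit suffixes). It returns both the label tables the
matcher consumes and the ground-truth mapping set of all cross-namespace
exact pairs, so matcher output can be scored against a known answer.

Everything is driven by an explicit seed: the same spec always yields
byte-identical output. Labels are drawn from a small synthetic vocabulary,
not from real biomedical terminologies — distributional realism (term
length, ambiguity, multilinguality) is out of scope.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

from .curie import PrefixMap
from .errors import SssomError
from .lexmatch import LabelRecord
from .model import Mapping, MappingSet, make_mapping
from .registry import MatchType, PREDICATES

__all__ = ["CorpusSpec", "generate", "evaluate", "random_mapping_set"]

_ADJECTIVES = (
    "proximal", "distal", "anterior", "posterior", "dorsal", "ventral",
    "lateral", "medial", "superior", "inferior", "primary", "secondary",
    "accessory", "rudimentary", "compound", "serous", "mucous", "cardiac",
    "hepatic", "renal", "neural", "dermal", "vascular", "lymphoid",
    "embryonic", "adult", "left", "right", "upper", "lower",
)
_NOUNS = (
    "limb", "lobe", "duct", "gland", "membrane", "vesicle", "ganglion",
    "nerve", "artery", "vein", "muscle", "tendon", "cartilage", "follicle",
    "tubule", "sinus", "valve", "septum", "plexus", "node", "cortex",
    "medulla", "capsule", "ligament", "fossa", "ridge", "papilla", "crest",
    "segment", "joint", "bone", "fold", "pouch", "chamber", "canal",
    "fissure", "bulb", "horn", "plate", "arch",
)

NOISE_STEPS = ("case_flip", "punctuation", "digit_suffix")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic corpus."""

    n_namespaces: int = 2
    n_concepts: int = 50
    p_synonym: float = 0.3
    noise_steps: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_namespaces < 2:
            raise SssomError("need at least 2 namespaces")
        if self.n_concepts < 1:
            raise SssomError("need at least 1 concept")
        if not 0.0 <= self.p_synonym <= 1.0:
            raise SssomError("p_synonym must be a probability")
        for step in self.noise_steps:
            if step not in NOISE_STEPS:
                raise SssomError(f"unknown noise step: {step!r}")
        if self.n_concepts > len(_ADJECTIVES) * len(_NOUNS):
            raise SssomError(f"at most {len(_ADJECTIVES) * len(_NOUNS)} concepts supported")


def _apply_noise(text: str, steps: Sequence[str], rng: random.Random) -> str:
    for step in steps:
        if step == "case_flip":
            text = "".join(ch.upper() if rng.random() < 0.3 else ch for ch in text)
        elif step == "punctuation":
            pos = rng.randrange(1, len(text))
            text = text[:pos] + "-" + text[pos:]
        elif step == "digit_suffix":
            text = f"{text} {rng.randint(2, 9)}"
    return text


def _prefix_map(n_namespaces: int) -> PrefixMap:
    entries = {f"NS{i}": f"https://example.org/ns{i}/" for i in range(1, n_namespaces + 1)}
    entries["oboInOwl"] = "http://www.geneontology.org/formats/oboInOwl#"
    return PrefixMap(entries)


def generate(spec: CorpusSpec) -> Tuple[Dict[str, List[LabelRecord]], MappingSet]:
    """Generate (label tables per namespace, ground-truth mapping set).

    Concept *c* is realized as entity ``NS<i>:<c zero-padded>`` in every
    namespace; base labels are shared across namespaces (before noise) and
    unique across concepts, so a noise-free corpus is exactly recoverable
    by lexical matching. The truth set holds every cross-namespace pair as
    a HumanCurated skos:exactMatch, oriented subject-namespace-index <
    object-namespace-index.
    """
    rng = random.Random(spec.seed)
    combos = [(a, n) for a in _ADJECTIVES for n in _NOUNS]
    rng.shuffle(combos)
    concepts = combos[: spec.n_concepts]

    tables: Dict[str, List[LabelRecord]] = {}
    for i in range(1, spec.n_namespaces + 1):
        ns = f"NS{i}"
        records: List[LabelRecord] = []
        for c, (adj, noun) in enumerate(concepts):
            entity = f"{ns}:{c:04d}"
            label = _apply_noise(f"{adj} {noun}", spec.noise_steps, rng)
            records.append(LabelRecord(entity, "rdfs:label", label))
            if rng.random() < spec.p_synonym:
                synonym = _apply_noise(f"{noun} {adj}", spec.noise_steps, rng)
                records.append(LabelRecord(entity, "oboInOwl:hasExactSynonym", synonym))
        tables[ns] = records

    truth_rows: List[Mapping] = []
    for c in range(len(concepts)):
        for i, j in combinations(range(1, spec.n_namespaces + 1), 2):
            truth_rows.append(
                make_mapping(
                    {
                        "subject_id": f"NS{i}:{c:04d}",
                        "predicate_id": "skos:exactMatch",
                        "object_id": f"NS{j}:{c:04d}",
                        "match_type": MatchType.HumanCurated,
                    }
                )
            )
    truth = MappingSet(
        mapping_set_id=f"https://example.org/sssom-kit/synthetic/{spec.seed}",
        license="https://creativecommons.org/publicdomain/zero/1.0/",
        mapping_set_description=(
            f"synthetic ground truth: {spec.n_concepts} concepts across "
            f"{spec.n_namespaces} namespaces"
        ),
        curie_map=_prefix_map(spec.n_namespaces),
        mappings=truth_rows,
    )
    return tables, truth


def _exact_pairs(ms: MappingSet) -> set:
    from .registry import Strength, predicate_class

    pairs = set()
    for m in ms.mappings:
        if m.is_negated() or not m.subject_id or not m.object_id:
            continue
        if m.predicate_id and predicate_class(m.predicate_id) is Strength.EXACT:
            pairs.add(frozenset((m.subject_id, m.object_id)))
    return pairs


def evaluate(predicted: MappingSet, truth: MappingSet) -> Tuple[float, float, float]:
    """(precision, recall, f1) over unordered exact-match pairs.

    Comparison is restricted to non-negated EXACT-class rows; degenerate
    cases (no predictions, no truth) score 0 by convention.
    """
    predicted_pairs = _exact_pairs(predicted)
    truth_pairs = _exact_pairs(truth)
    if not predicted_pairs or not truth_pairs:
        return (0.0, 0.0, 0.0)
    hits = len(predicted_pairs & truth_pairs)
    precision = hits / len(predicted_pairs)
    recall = hits / len(truth_pairs)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return (precision, recall, f1)


# --------------------------------------------------------------------------
# random valid mapping sets (round-trip and contract testing)

_OPTIONAL_FILLERS = {
    "subject_label": lambda rng: rng.choice(_NOUNS),
    "object_label": lambda rng: rng.choice(_NOUNS),
    "confidence": lambda rng: round(rng.uniform(0.0, 1.0), 3),
    "semantic_similarity_score": lambda rng: round(rng.uniform(0.0, 1.0), 3),
    "semantic_similarity_measure": lambda rng: rng.choice(["Jaccard", "Resnik"]),
    "mapping_date": lambda rng: _dt.date(2020, 1, 1) + _dt.timedelta(days=rng.randrange(1000)),
    "publication_date": lambda rng: _dt.date(2021, 1, 1) + _dt.timedelta(days=rng.randrange(500)),
    "author_id": lambda rng: tuple(
        sorted({f"orcid:0000-0000-0000-{rng.randrange(10000):04d}" for _ in range(rng.randint(1, 2))})
    ),
    "mapping_tool": lambda rng: rng.choice(["sssom-kit-lexmatch", "curator-toolkit"]),
    "mapping_tool_version": lambda rng: f"{rng.randint(0, 3)}.{rng.randint(0, 9)}.{rng.randint(0, 9)}",
    "subject_source": lambda rng: "https://example.org/source/a",
    "object_source": lambda rng: "https://example.org/source/b",
    "subject_match_field": lambda rng: ("rdfs:label",),
    "object_match_field": lambda rng: tuple(
        dict.fromkeys(rng.sample(["rdfs:label", "oboInOwl:hasExactSynonym"], rng.randint(1, 2)))
    ),
    "match_string": lambda rng: (rng.choice(_NOUNS),),
    "comment": lambda rng: "generated row",
    "see_also": lambda rng: ("https://example.org/docs",),
    "mapping_cardinality": lambda rng: rng.choice(["1:1", "1:n", "n:1", "n:n"]),
}


def random_mapping_set(seed: int, *, n_rows_max: int = 12) -> MappingSet:
    """A random, schema-valid mapping set exercising many optional slots.

    Intended for property tests: round-trip identity, converter contracts,
    reconciliation invariants. Deterministic in *seed*.
    """
    rng = random.Random(seed)
    n_rows = rng.randint(1, n_rows_max)
    predicates = sorted(PREDICATES)
    rows: List[Mapping] = []
    for _ in range(n_rows):
        record: Dict[str, object] = {
            "subject_id": f"NS1:{rng.randrange(40):04d}",
            "predicate_id": rng.choice(predicates),
            "object_id": f"NS2:{rng.randrange(40):04d}",
            "match_type": rng.choice(list(MatchType)),
        }
        if rng.random() < 0.15:
            record["predicate_modifier"] = "Not"
        for slot, filler in _OPTIONAL_FILLERS.items():
            if rng.random() < 0.35:
                record[slot] = filler(rng)
        rows.append(make_mapping(record))
    return MappingSet(
        mapping_set_id=f"https://example.org/sssom-kit/random/{seed}",
        license="https://creativecommons.org/publicdomain/zero/1.0/",
        curie_map=PrefixMap(
            {
                "NS1": "https://example.org/ns1/",
                "NS2": "https://example.org/ns2/",
                "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
                "orcid": "https://orcid.org/",
            }
        ),
        mappings=rows,
    )
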