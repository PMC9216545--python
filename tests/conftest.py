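import pytest

from sssomkit.curie import PrefixMap
from sssomkit.model import MappingSet, make_mapping


def mapping(subject, predicate, obj, match_type="HumanCurated", **extra):
    record = {
        "subject_id": subject,
        "predicate_id": predicate,
        "object_id": obj,
        "match_type": match_type,
    }
    record.update(extra)
    return make_mapping(record)


@pytest.fixture
def anatomy_prefix_map():
    return PrefixMap(
        {
            "FMA": "http://purl.org/sig/ont/fma/fma",
            "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
            "MA": "http://purl.obolibrary.org/obo/MA_",
            "UMLS": "https://uts.nlm.nih.gov/uts/umls/concept/",
            "EFO": "http://www.ebi.ac.uk/efo/EFO_",
        }
    )


@pytest.fixture
def limb_set(anatomy_prefix_map):
    """Free-limb crosswalk fixture: one exact chain plus one related spur."""
    return MappingSet(
        mapping_set_id="https://example.org/tests/limb",
        license="https://creativecommons.org/publicdomain/zero/1.0/",
        curie_map=anatomy_prefix_map,
        mappings=[
            mapping("FMA:24875", "skos:exactMatch", "UBERON:0002101"),
            mapping("UBERON:0002101", "skos:exactMatch", "MA:0000007"),
            mapping("UBERON:0002101", "skos:relatedMatch", "UMLS:C0015385"),
        ],
    )


@pytest.fixture
def simple_prefix_map():
    return PrefixMap({"A": "https://example.org/a/", "B": "https://example.org/b/"})
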