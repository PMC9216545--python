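"""Predicate-aware traversal ("hopping") over mapping graphs.

Chaining mappings through intermediate terms is only sound where the
predicate semantics allow it, so traversal is driven by an explicit
composition algebra over strength classes:

* EXACT is the identity: composing with EXACT preserves the other side.
* BROAD chains with BROAD (and NARROW with NARROW): subsumption in one
  direction is transitive.
* CLOSE degrades: two CLOSE hops only support RELATED (SKOS declares
  closeMatch non-transitive).
* Every other combination — anything passing through RELATED, or mixing
  BROAD with NARROW — is undefined: no strength claim survives.

Edges are stored undirected with a per-direction strength (a BROAD mapping
read backwards is NARROW). Negated rows, unrecognized predicates and
obsolete terms never enter the graph; only *simple* paths are walked, so
cycles cannot inflate strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import SssomError
from .model import MappingSet
from .registry import Strength, predicate_class

__all__ = [
    "COMPOSITION",
    "STRENGTH_RANK",
    "Neighbor",
    "MappingGraph",
    "build_graph",
    "compose",
    "neighbors",
]

_S = Strength

#: partial composition table over strength classes; absent pairs compose to
#: nothing (the chain supports no claim).
COMPOSITION: Dict[Tuple[Strength, Strength], Strength] = {}
for _x in (_S.EXACT, _S.CLOSE, _S.RELATED, _S.BROAD, _S.NARROW):
    COMPOSITION[(_S.EXACT, _x)] = _x
    COMPOSITION[(_x, _S.EXACT)] = _x
COMPOSITION[(_S.BROAD, _S.BROAD)] = _S.BROAD
COMPOSITION[(_S.NARROW, _S.NARROW)] = _S.NARROW
COMPOSITION[(_S.CLOSE, _S.CLOSE)] = _S.RELATED

#: strength preference for reporting: EXACT > CLOSE > RELATED > BROAD = NARROW
STRENGTH_RANK: Dict[Strength, int] = {
    _S.EXACT: 3,
    _S.CLOSE: 2,
    _S.RELATED: 1,
    _S.BROAD: 0,
    _S.NARROW: 0,
}


def compose(path: Sequence[Strength]) -> Optional[Strength]:
    """Left fold of the composition table; None once any step is undefined."""
    if not path:
        raise SssomError("compose requires a non-empty path of strengths")
    result = path[0]
    for step in path[1:]:
        pair = (result, step)
        if pair not in COMPOSITION:
            return None
        result = COMPOSITION[pair]
    return result


@dataclass(frozen=True)
class Neighbor:
    entity: str
    strength: Strength
    distance: int
    path: Tuple[str, ...]  # witness path, start..entity


class MappingGraph:
    """Undirected mapping graph with per-direction edge strengths."""

    def __init__(self) -> None:
        self._adj: Dict[str, List[Tuple[str, Strength, Optional[float], int]]] = {}

    def add_edge(
        self,
        subject: str,
        obj: str,
        strength: Strength,
        confidence: Optional[float],
        row: int,
    ) -> None:
        self._adj.setdefault(subject, []).append((obj, strength, confidence, row))
        self._adj.setdefault(obj, []).append((subject, strength.inverse, confidence, row))

    def nodes(self) -> List[str]:
        return sorted(self._adj)

    def edges_from(self, node: str) -> List[Tuple[str, Strength, Optional[float], int]]:
        return sorted(self._adj.get(node, []), key=lambda e: (e[0], -STRENGTH_RANK[e[1]], e[3]))

    def __contains__(self, node: str) -> bool:
        return node in self._adj


def build_graph(
    ms: MappingSet,
    min_confidence: float = 0.0,
    obsolete: Iterable[str] = (),
) -> MappingGraph:
    """Build the traversal graph from a mapping set.

    Rows are skipped when negated, when the predicate strength is UNKNOWN,
    when confidence falls below *min_confidence* (rows without a confidence
    pass), or when either endpoint is in the *obsolete* list — obsolete
    terms should not take part in mappings at all.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise SssomError(f"min_confidence outside [0,1]: {min_confidence}")
    dead = set(obsolete)
    graph = MappingGraph()
    for i, m in enumerate(ms.mappings):
        if m.is_negated() or not m.subject_id or not m.object_id or not m.predicate_id:
            continue
        strength = predicate_class(m.predicate_id)
        if strength is Strength.UNKNOWN:
            continue
        if isinstance(m.confidence, float) and m.confidence < min_confidence:
            continue
        if m.subject_id in dead or m.object_id in dead:
            continue
        confidence = m.confidence if isinstance(m.confidence, float) else None
        graph.add_edge(m.subject_id, m.object_id, strength, confidence, i)
    return graph


def neighbors(
    graph: MappingGraph,
    start: str,
    max_distance: int,
    min_strength: Optional[Strength] = None,
) -> List[Neighbor]:
    """Entities reachable from *start* within *max_distance* hops.

    Enumerates simple paths whose composed strength is defined. Each entity
    is reported once, at its minimum distance; among minimal-distance paths
    the strongest derived strength wins, with ties broken by the
    lexicographically first path. *min_strength* filters out weaker derived
    strengths (BROAD and NARROW rank equal). The start node itself is never
    reported; an unknown start yields an empty result.
    """
    if max_distance < 1:
        raise SssomError(f"max_distance must be >= 1, got {max_distance}")
    if start not in graph:
        return []

    # best[entity] = ((distance, -strength_rank, path), derived strength);
    # smaller key tuple wins
    best: Dict[str, Tuple[Tuple[int, int, Tuple[str, ...]], Strength]] = {}

    def walk(node: str, path: Tuple[str, ...], so_far: Optional[Strength]) -> None:
        if len(path) - 1 >= max_distance:
            return
        for neighbor, strength, _conf, _row in graph.edges_from(node):
            if neighbor in path:
                continue
            derived = strength if so_far is None else COMPOSITION.get((so_far, strength))
            if derived is None:
                # an undefined prefix can never recover: every further step
                # needs a defined left operand
                continue
            new_path = path + (neighbor,)
            key = (len(new_path) - 1, -STRENGTH_RANK[derived], new_path)
            if neighbor not in best or key < best[neighbor][0]:
                best[neighbor] = (key, derived)
            walk(neighbor, new_path, derived)

    walk(start, (start,), None)

    out = []
    for entity, ((distance, _neg_rank, path), derived) in best.items():
        if min_strength is not None and STRENGTH_RANK[derived] < STRENGTH_RANK[min_strength]:
            continue
        out.append(Neighbor(entity=entity, strength=derived, distance=distance, path=path))
    out.sort(key=lambda n: (n.distance, n.entity))
    return out
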