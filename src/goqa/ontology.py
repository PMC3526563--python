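"""Gene Ontology DAG and Wang semantic similarity.

The ontology is held as a typed directed acyclic graph (child -> parent
edges labelled ``is_a`` or ``part_of``).  Wang's measure assigns every
ancestor *t* of a query term *A* a semantic contribution

    S_A(A) = 1
    S_A(t) = max { w_e * S_A(t') : t' a child of t inside DAG_A }

where ``w_e`` is a per-relation contribution factor in (0, 1), and scores
a term pair by the overlap of their ancestor contributions:

    Sim(A, B) = sum_{t in DAG_A ∩ DAG_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

with SV(X) = sum of all S_X values.  Term *sets* (protein annotations) are
compared with the best-match average, yielding the functional-similarity
score FS in [0, 1].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations that carry semantic weight; anything else is dropped on load.
SEMANTIC_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling parents)."""


class UnknownTermError(KeyError):
    """Raised when a term id (after alt_id resolution) is not in the DAG."""


class ObsoleteTermError(ValueError):
    """Raised when an obsolete term is used as a similarity argument."""


@dataclass(frozen=True)
class SemanticWeights:
    """Per-relation semantic contribution factors for Wang's recursion.

    Both factors must lie strictly inside (0, 1) so that contributions decay
    along paths and the recursion converges.  Defaults follow the published
    form of the Wang measure: 0.8 for ``is_a``, 0.6 for ``part_of``.
    """

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for name, value in (("w_is_a", self.w_is_a), ("w_part_of", self.w_part_of)):
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")

    def for_relation(self, relation: str) -> float:
        if relation == "is_a":
            return self.w_is_a
        if relation == "part_of":
            return self.w_part_of
        raise ValueError(f"no semantic weight for relation {relation!r}")


DEFAULT_WEIGHTS = SemanticWeights()


@dataclass(frozen=True)
class GOTerm:
    """A single ontology term.

    ``parents`` holds (parent id, relation) pairs restricted to the semantic
    relations; obsolete terms always carry an empty parent tuple.
    """

    id: str
    name: str
    namespace: str
    parents: tuple[tuple[str, str], ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass(frozen=True)
class SValueMap:
    """Wang semantic contributions of one term's ancestor subgraph."""

    root_term: str
    svalues: Mapping[str, float]
    sv_total: float


class GODag:
    """An acyclic Gene Ontology graph with typed child -> parent edges.

    Parameters
    ----------
    terms:
        Mapping from primary term id to :class:`GOTerm`.  Every parent id
        referenced by a term must itself be a key, and the induced graph
        must be acyclic; otherwise :class:`OntologyError` is raised.
    dropped_relationships:
        Number of non-semantic relationship edges discarded during parsing
        (informational).
    """

    def __init__(self, terms: Mapping[str, GOTerm], dropped_relationships: int = 0):
        self.terms: dict[str, GOTerm] = dict(terms)
        self.dropped_relationships = dropped_relationships
        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self._alt.setdefault(alt, term.id)

        graph = nx.MultiDiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            if term.obsolete:
                continue
            for parent, relation in term.parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id} references missing parent {parent}"
                    )
                graph.add_edge(term.id, parent, key=relation)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"ontology graph contains a cycle: {path}")
        self._graph = graph
        self._svalue_cache: dict[tuple[str, SemanticWeights], SValueMap] = {}

    @property
    def graph(self) -> nx.MultiDiGraph:
        return self._graph

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[self.resolve(term_id)]

    def resolve(self, term_id: str) -> str:
        """Map an accession (possibly an alt_id) to its primary id."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise UnknownTermError(term_id)

    def _require_live(self, term_id: str) -> str:
        primary = self.resolve(term_id)
        if self.terms[primary].obsolete:
            raise ObsoleteTermError(f"{primary} is obsolete")
        return primary

    def ancestor_subgraph(self, term_id: str) -> nx.MultiDiGraph:
        """The term plus all its ancestors, with the typed edges among them."""
        primary = self._require_live(term_id)
        nodes = nx.descendants(self._graph, primary) | {primary}
        return self._graph.subgraph(nodes)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via is_a/part_of, plus itself."""
        primary = self._require_live(term_id)
        return frozenset(nx.descendants(self._graph, primary) | {primary})


def parse_obo(source) -> GODag:
    """Parse an OBO v1.2 document into a :class:`GODag`.

    ``source`` may be a path, an open text stream, or the OBO text itself.
    Obsolete terms are retained but flagged and stripped of parents;
    relationships other than is_a/part_of are dropped and counted.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    raw = obonet.read_obo(source, ignore_obsolete=False)

    dangling = [n for n, data in raw.nodes(data=True) if "name" not in data]
    if dangling:
        raise OntologyError(f"dangling parent reference(s): {sorted(dangling)}")

    dropped = 0
    terms: dict[str, GOTerm] = {}
    for node, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents: list[tuple[str, str]] = []
        if not obsolete:
            for _, parent, relation in raw.out_edges(node, keys=True):
                if relation in SEMANTIC_RELATIONS:
                    parents.append((parent, relation))
                else:
                    dropped += 1
        terms[node] = GOTerm(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parents=tuple(parents),
            alt_ids=tuple(data.get("alt_id", ())),
            obsolete=obsolete,
        )
    if dropped:
        logger.info("dropped %d non-semantic relationship edges", dropped)
    return GODag(terms, dropped_relationships=dropped)


def s_values(dag: GODag, term_id: str, weights: SemanticWeights = DEFAULT_WEIGHTS) -> SValueMap:
    """Wang S-values of every ancestor of ``term_id`` (including itself)."""
    primary = dag._require_live(term_id)
    cached = dag._svalue_cache.get((primary, weights))
    if cached is not None:
        return cached

    sub = dag.ancestor_subgraph(primary)
    s: dict[str, float] = {}
    # Child -> parent edges make a topological order process each node after
    # every contributor below it.
    for node in nx.topological_sort(sub):
        if node == primary:
            s[node] = 1.0
            continue
        best = 0.0
        for child, _, relation in sub.in_edges(node, keys=True):
            candidate = weights.for_relation(relation) * s[child]
            if candidate > best:
                best = candidate
        s[node] = best
    result = SValueMap(root_term=primary, svalues=s, sv_total=sum(s.values()))
    dag._svalue_cache[(primary, weights)] = result
    return result


def term_similarity(
    dag: GODag, a: str, b: str, weights: SemanticWeights = DEFAULT_WEIGHTS
) -> float:
    """Wang similarity between two terms of the same namespace, in [0, 1]."""
    pa, pb = dag._require_live(a), dag._require_live(b)
    ta, tb = dag.terms[pa], dag.terms[pb]
    if ta.namespace != tb.namespace:
        raise ValueError(
            f"cross-namespace comparison: {pa} ({ta.namespace}) vs {pb} ({tb.namespace})"
        )
    if pb < pa:  # canonical order: bit-identical symmetry
        pa, pb = pb, pa
    sa = s_values(dag, pa, weights)
    sb = s_values(dag, pb, weights)
    common = sorted(sa.svalues.keys() & sb.svalues.keys())
    overlap = sum(sa.svalues[t] + sb.svalues[t] for t in common)
    # the overlap cannot mathematically exceed the SV total; clamp away
    # summation-order rounding so Sim(a, a) is exactly 1
    return min(1.0, overlap / (sa.sv_total + sb.sv_total))


def functional_similarity(
    dag: GODag,
    set1: Iterable[str],
    set2: Iterable[str],
    weights: SemanticWeights = DEFAULT_WEIGHTS,
) -> float:
    """Best-match-average similarity (FS) between two GO term sets.

    FS = ( sum_{t in set1} max_{u in set2} Sim(t,u)
         + sum_{u in set2} max_{t in set1} Sim(t,u) ) / (|set1| + |set2|)
    """
    terms1 = sorted({dag._require_live(t) for t in set1})
    terms2 = sorted({dag._require_live(t) for t in set2})
    if not terms1 or not terms2:
        raise ValueError("functional similarity requires two non-empty term sets")
    sim = {
        (t, u): term_similarity(dag, t, u, weights) for t in terms1 for u in terms2
    }
    forward = sum(max(sim[t, u] for u in terms2) for t in terms1)
    backward = sum(max(sim[t, u] for t in terms1) for u in terms2)
    return (forward + backward) / (len(terms1) + len(terms2))


def write_obo(dag: GODag, stream) -> None:
    """Serialise a DAG back to minimal OBO v1.2 text."""
    stream.write("format-version: 1.2\n")
    for term_id in sorted(dag.terms):
        term = dag.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for alt in term.alt_ids:
            stream.write(f"alt_id: {alt}\n")
        for parent, relation in term.parents:
            if relation == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {relation} {parent}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
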