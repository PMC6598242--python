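"""Gene Ontology loading and DAG queries.

Parses an OBO 1.2 flat file into an immutable, namespace-restricted DAG and
answers ancestor/descendant queries over ``is_a`` and ``part_of`` edges.
Other relationship types (``regulates`` and friends) are dropped, following
the common convention for annotation propagation.

Obsolete terms are excluded from the DAG but remembered, so that a lookup of
an obsolete accession fails with a specific error rather than "unknown term".
Alternate ids resolve silently to their canonical accession.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyDAG",
    "parse_obo",
    "OntologyError",
    "CycleError",
    "EmptyNamespaceError",
    "UnknownTermError",
    "ObsoleteTermError",
    "NAMESPACES",
    "KEPT_RELATIONS",
]

NAMESPACES = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)

#: relationship types traversed for ancestor queries and propagation
KEPT_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")


class OntologyError(Exception):
    """Base class for ontology loading/query failures."""


class CycleError(OntologyError):
    """The loaded graph contains a directed cycle (not a valid DAG)."""


class EmptyNamespaceError(OntologyError):
    """No non-obsolete terms found in the requested namespace."""


class UnknownTermError(OntologyError, KeyError):
    """A term accession is not present in the DAG."""

    def __init__(self, term_id: str):
        super().__init__(f"unknown term: {term_id!r}")
        self.term_id = term_id


class ObsoleteTermError(OntologyError):
    """One or more requested accessions refer to obsolete terms."""

    def __init__(self, term_ids: Iterable[str]):
        self.term_ids = sorted(term_ids)
        super().__init__("obsolete term(s): " + ", ".join(self.term_ids))


@dataclass(frozen=True)
class OntologyTerm:
    """A single GO term restricted to the fields the pipeline uses."""

    term_id: str
    name: str
    namespace: str
    parents: frozenset[tuple[str, str]] = frozenset()  # (parent_id, relation)
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False
    description: str = ""
    synonyms: tuple[str, ...] = ()


@dataclass
class OntologyDAG:
    """An acyclic child-to-parent graph over one GO namespace.

    The graph is immutable after construction; ancestor and descendant
    closures are memoized on first use.
    """

    namespace: str
    terms: dict[str, OntologyTerm]
    graph: nx.DiGraph  # edges child -> parent
    alt_id_index: dict[str, str] = field(default_factory=dict)
    obsolete_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- lookups ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_id_index

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an accession (possibly an alt_id) to its canonical id.

        Raises :class:`ObsoleteTermError` for obsolete accessions and
        :class:`UnknownTermError` for everything else not in the DAG.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_id_index:
            return self.alt_id_index[term_id]
        if term_id in self.obsolete_ids:
            raise ObsoleteTermError([term_id])
        raise UnknownTermError(term_id)

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no retained parent edge."""
        return frozenset(
            t for t in self.terms if self.graph.out_degree(t) == 0
        )

    # -- closures --------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive is_a/part_of closure, excluding the term itself."""
        tid = self.resolve(term_id)
        if tid not in self._anc_cache:
            self._anc_cache[tid] = frozenset(nx.descendants(self.graph, tid))
        return self._anc_cache[tid]

    def ancestors_or_self(self, term_id: str) -> frozenset[str]:
        tid = self.resolve(term_id)
        return self.ancestors(tid) | {tid}

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms that reach ``term_id`` via is_a/part_of edges."""
        tid = self.resolve(term_id)
        if tid not in self._desc_cache:
            self._desc_cache[tid] = frozenset(nx.ancestors(self.graph, tid))
        return self._desc_cache[tid]

    def descendants_or_self(self, term_id: str) -> frozenset[str]:
        tid = self.resolve(term_id)
        return self.descendants(tid) | {tid}


def parse_obo(path, namespace: str) -> OntologyDAG:
    """Parse an OBO 1.2 file into a namespace-restricted :class:`OntologyDAG`.

    Parameters
    ----------
    path
        OBO file path (or open text handle).
    namespace
        One of ``biological_process``, ``molecular_function``,
        ``cellular_component``; only terms of this namespace are retained.

    Raises
    ------
    ValueError
        Unknown namespace name.
    EmptyNamespaceError
        The file holds no non-obsolete term of the namespace.
    CycleError
        The retained graph is not acyclic.
    """
    if namespace not in NAMESPACES:
        raise ValueError(
            f"namespace must be one of {sorted(NAMESPACES)}, got {namespace!r}"
        )

    raw = obonet.read_obo(path, ignore_obsolete=False)

    obsolete = {
        tid
        for tid, data in raw.nodes(data=True)
        if str(data.get("is_obsolete", "false")).lower() == "true"
    }

    terms: dict[str, OntologyTerm] = {}
    alt_index: dict[str, str] = {}
    graph = nx.DiGraph()
    for tid, data in raw.nodes(data=True):
        if tid in obsolete or data.get("namespace") != namespace:
            continue
        parents: set[tuple[str, str]] = set()
        for child, parent, rel in raw.out_edges(tid, keys=True):
            if rel in KEPT_RELATIONS and parent not in obsolete:
                parents.add((parent, rel))
        alt_ids = frozenset(data.get("alt_id", []))
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=data.get("name", ""),
            namespace=namespace,
            parents=frozenset(parents),
            alt_ids=alt_ids,
            obsolete=False,
            description=data.get("def", ""),
            synonyms=tuple(data.get("synonym", [])),
        )
        graph.add_node(tid)
        for alt in alt_ids:
            alt_index[alt] = tid

    if not terms:
        raise EmptyNamespaceError(
            f"no non-obsolete terms in namespace {namespace!r}"
        )

    # edges only between retained (same-namespace, non-obsolete) terms
    for tid, term in terms.items():
        for parent, rel in term.parents:
            if parent in terms:
                graph.add_edge(tid, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CycleError(f"ontology graph contains a cycle: {cycle}")

    return OntologyDAG(
        namespace=namespace,
        terms=terms,
        graph=graph,
        alt_id_index=alt_index,
        obsolete_ids=frozenset(obsolete),
    )
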