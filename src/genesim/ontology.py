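"""Ontology term graphs.

The Gene Ontology (GO) is a rooted directed acyclic graph: nodes are terms,
directed edges run from a child term to its parent(s) and carry a relation
kind (``is_a`` or ``part_of``; other GO relations are dropped).  This module
parses OBO flat files into an :class:`OntologyDAG`, extracts per-term
ancestor subgraphs (the ``DAG_X = (X, T_X, E_X)`` used by semantic-similarity
propagation) and counts term children, the quantity that drives the hybrid
edge weight in :mod:`genesim.semsim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

from .errors import CycleError, OboFormatError, UnknownTermError

#: Relation kinds retained as edges; both count toward a term's children.
DEFAULT_RELATIONS = ("is_a", "part_of")

#: Canonical GO namespace names.
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class OntologyDAG:
    """A term DAG with child -> parent edges tagged by relation kind.

    Parameters
    ----------
    terms
        All (non-obsolete, namespace-filtered) term ids.
    edges
        ``(child, parent, relation)`` triples; at most one per
        (child, parent, relation) combination.
    namespace
        Term id -> namespace string.
    name
        Term id -> human-readable name (may be missing for synthetic terms).
    """

    terms: frozenset
    edges: frozenset
    namespace: Mapping[str, str] = field(default_factory=dict)
    name: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for child, parent, _rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(
                    f"edge endpoint {child!r}->{parent!r} not in term set"
                )
        parents: dict = {t: [] for t in self.terms}
        child_sets: dict = {t: set() for t in self.terms}
        for child, parent, rel in sorted(self.edges):
            parents[child].append((parent, rel))
            child_sets[parent].add(child)
        object.__setattr__(self, "_parents", parents)
        object.__setattr__(self, "_children", child_sets)
        cycle = _find_cycle(self.edges)
        if cycle is not None:
            raise CycleError(f"term graph contains a cycle through {cycle!r}")

    # -- queries ----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def parents_of(self, term: str):
        """``(parent, relation)`` pairs for *term*."""
        self._check(term)
        return tuple(self._parents[term])

    def children_of(self, term: str) -> frozenset:
        self._check(term)
        return frozenset(self._children[term])

    def roots(self) -> frozenset:
        return frozenset(t for t in self.terms if not self._parents[t])

    def leaves(self) -> frozenset:
        return frozenset(t for t in self.terms if not self._children[t])

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise UnknownTermError(f"unknown term id {term!r}")


@dataclass(frozen=True)
class TermDAG:
    """Ancestor subgraph of one focus term: the term, all its ancestors and
    the edges among them."""

    focus: str
    termset: frozenset
    edgeset: frozenset

    def in_edges(self, term: str):
        """Edges ``(child, term, relation)`` arriving at *term* from inside
        the subgraph."""
        return tuple(e for e in sorted(self.edgeset) if e[1] == term)


def _find_cycle(edges: Iterable) -> Optional[str]:
    g = nx.DiGraph()
    g.add_edges_from((c, p) for c, p, _r in edges)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return cyc[0][0]


def read_obo(
    path,
    namespace: Optional[str] = None,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Obsolete terms are discarded.  Only ``is_a`` and ``relationship: part_of``
    lines become edges (restrict further via *relations*); all other relation
    kinds are ignored.  With *namespace* given, only terms of that namespace
    (and edges among them) are retained.

    Raises
    ------
    OboFormatError
        If the file cannot be parsed as OBO.
    CycleError
        If the retained edges contain a directed cycle.
    """
    relations = tuple(relations)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError/KeyError
        raise OboFormatError(f"cannot parse OBO file {path!r}: {exc}") from exc

    keep = set()
    ns = {}
    names = {}
    for term, data in graph.nodes(data=True):
        term_ns = data.get("namespace", "")
        if namespace is not None and term_ns != namespace:
            continue
        keep.add(term)
        ns[term] = term_ns
        if "name" in data:
            names[term] = data["name"]

    edges = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel in relations and child in keep and parent in keep:
            edges.add((child, parent, rel))

    return OntologyDAG(
        terms=frozenset(keep),
        edges=frozenset(edges),
        namespace=ns,
        name=names,
    )


def ancestor_dag(dag: OntologyDAG, x: str) -> TermDAG:
    """Extract ``DAG_X``: term *x*, all its ancestors, and the induced edges.

    Ancestors are every term reachable from *x* along child -> parent edges.
    """
    dag._check(x)
    termset = {x}
    stack = [x]
    while stack:
        t = stack.pop()
        for parent, _rel in dag.parents_of(t):
            if parent not in termset:
                termset.add(parent)
                stack.append(parent)
    edgeset = frozenset(
        (c, p, r) for (c, p, r) in dag.edges if c in termset and p in termset
    )
    return TermDAG(focus=x, termset=frozenset(termset), edgeset=edgeset)


def children_count(dag: OntologyDAG, t: str) -> int:
    """Number of distinct terms with an edge into *t*, over all retained
    relation kinds, counted on the full ontology (not a per-gene subgraph)."""
    return len(dag.children_of(t))
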