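"""Gene Ontology DAG: OBO parsing and structural queries.

The ontology is modelled as a directed acyclic graph with edges pointing
from child to parent. Only ``is_a`` and ``part_of`` relations are kept —
the convention of mainstream GO-similarity tools — and queries never cross
namespace boundaries. All similarity measures are built on three queries:
ancestor closure, common ancestors, and the leaves below a term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from .errors import (
    NamespaceMismatchError,
    OboParseError,
    OntologyIntegrityError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

#: Relation types traversed by every query; everything else is dropped at parse time.
KEPT_RELATIONS = ("is_a", "part_of")

#: Short aspect codes accepted wherever a namespace is expected.
NAMESPACE_ALIASES = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}

#: GAF aspect letter for each namespace (used when writing annotation files).
NAMESPACE_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


def canonical_namespace(namespace: str) -> str:
    """Resolve MF/BP/CC shorthand to the full GO namespace name."""
    ns = NAMESPACE_ALIASES.get(namespace.upper(), namespace)
    if ns not in NAMESPACE_ASPECT:
        raise NamespaceMismatchError(
            f"unknown namespace {namespace!r}; expected one of "
            f"{sorted(NAMESPACE_ASPECT)} or MF/BP/CC"
        )
    return ns


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` holds ``(parent_id, relation)`` pairs with relation in
    ``KEPT_RELATIONS``. Obsolete terms keep no outgoing edges.
    """

    id: str
    name: str = ""
    namespace: str = "biological_process"
    parents: tuple[tuple[str, str], ...] = ()
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """A single-namespace ontology with child-to-parent edges.

    Construction validates acyclicity and records the namespace roots
    (parentless terms). For GO proper each namespace has exactly one root;
    synthetic ontologies built by :mod:`gosimnet.fixtures` do too.
    """

    terms: dict[str, Term]
    namespace: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    _graph: nx.DiGraph = field(init=False, repr=False)
    roots: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for pid, rel in term.parents:
                if pid not in self.terms:
                    raise OntologyIntegrityError(
                        f"term {term.id} has unknown parent {pid}"
                    )
                if g.has_edge(term.id, pid):
                    g[term.id][pid]["relations"] = g[term.id][pid]["relations"] | {rel}
                else:
                    g.add_edge(term.id, pid, relations={rel})
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(u for u, _ in nx.find_cycle(g)) or "?"
            raise OntologyIntegrityError(f"ontology contains a cycle: {cycle}")
        self._graph = g
        self.roots = tuple(sorted(n for n in g if g.out_degree(n) == 0))
        if not self.roots:
            raise OntologyIntegrityError("ontology has no root term")

    # -- basic lookups ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def root(self) -> str:
        """The namespace root; raises if the DAG has several parentless terms."""
        if len(self.roots) != 1:
            raise OntologyIntegrityError(
                f"namespace {self.namespace} has {len(self.roots)} roots: {self.roots}"
            )
        return self.roots[0]

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its canonical id; raise on unknown ids."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(f"term {term_id} not in {self.namespace} ontology")

    def parents_of(self, term_id: str) -> tuple[tuple[str, str], ...]:
        return self.terms[self.resolve(term_id)].parents

    def children(self, term_id: str) -> set[str]:
        return set(self._graph.predecessors(self.resolve(term_id)))

    def is_leaf(self, term_id: str) -> bool:
        return self._graph.in_degree(self.resolve(term_id)) == 0

    def edge_relations(self, child: str, parent: str) -> frozenset[str]:
        return frozenset(self._graph[child][parent]["relations"])

    # -- closure queries -------------------------------------------------

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure over is_a/part_of toward the root."""
        tid = self.resolve(term_id)
        anc = nx.descendants(self._graph, tid)  # edges point child -> parent
        if include_self:
            anc.add(tid)
        return anc

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        tid = self.resolve(term_id)
        desc = nx.ancestors(self._graph, tid)
        if include_self:
            desc.add(tid)
        return desc

    def common_ancestors(self, ta: str, tb: str) -> set[str]:
        """Shared ancestors of two terms, each counted as its own ancestor.

        Never empty: both terms reach the namespace root.
        """
        a, b = self.resolve(ta), self.resolve(tb)
        if self.terms[a].namespace != self.terms[b].namespace:
            raise NamespaceMismatchError(
                f"{ta} ({self.terms[a].namespace}) and {tb} "
                f"({self.terms[b].namespace}) are in different namespaces"
            )
        return self.ancestors(a, include_self=True) & self.ancestors(b, include_self=True)

    def leaves_below(self, term_id: str) -> set[str]:
        """All childless descendants; a leaf term returns itself."""
        tid = self.resolve(term_id)
        return {t for t in self.descendants(tid, include_self=True) if self.is_leaf(t)}

    def min_edges_up(self, term_id: str, ancestor_id: str) -> int:
        """Fewest parent edges from a term up to one of its ancestors."""
        src = self.resolve(term_id)
        dst = self.resolve(ancestor_id)
        try:
            return nx.shortest_path_length(self._graph, src, dst)
        except nx.NetworkXNoPath:
            raise UnknownTermError(f"{ancestor_id} is not an ancestor of {term_id}")

    def topological_order(self) -> list[str]:
        """Term ids ordered so every parent precedes its children."""
        return list(reversed(list(nx.topological_sort(self._graph))))


# -- module-level operation surface ---------------------------------------


def ancestors(dag: OntologyDAG, term: str, include_self: bool = False) -> set[str]:
    return dag.ancestors(term, include_self=include_self)


def common_ancestors(dag: OntologyDAG, ta: str, tb: str) -> set[str]:
    return dag.common_ancestors(ta, tb)


def leaves_below(dag: OntologyDAG, term: str) -> set[str]:
    return dag.leaves_below(term)


def _validate_obo_lines(path: Path) -> None:
    """Cheap structural scan so malformed stanzas fail with a line number."""
    with open(path, encoding="utf-8") as fh:
        in_stanza = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") :
                if not line.endswith("]"):
                    raise OboParseError(f"{path}:{lineno}: malformed stanza header {line!r}")
                in_stanza = True
                continue
            if ":" not in line:
                where = "stanza" if in_stanza else "header"
                raise OboParseError(
                    f"{path}:{lineno}: malformed {where} line {line!r} (expected 'tag: value')"
                )


def parse_obo(path: str | Path, namespace: str = "biological_process") -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into a single-namespace :class:`OntologyDAG`.

    Keeps non-obsolete terms of the requested namespace and their is_a /
    part_of edges; every other relation type is dropped. Cross-namespace
    edges and discarded relation counts are logged. ``alt_id`` entries
    resolve to their canonical term.
    """
    path = Path(path)
    ns = canonical_namespace(namespace)
    _validate_obo_lines(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except (ValueError, KeyError) as exc:
        raise OboParseError(f"cannot parse OBO file {path}: {exc}") from exc

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    dropped_edges = 0
    kept_ids = {
        tid for tid, data in graph.nodes(data=True) if data.get("namespace") == ns
    }
    for tid in sorted(kept_ids):
        data = graph.nodes[tid]
        parents: list[tuple[str, str]] = []
        for _, pid, rel in graph.out_edges(tid, keys=True):
            if rel in KEPT_RELATIONS and pid in kept_ids:
                parents.append((pid, rel))
            else:
                dropped_edges += 1
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
        terms[tid] = Term(
            id=tid,
            name=data.get("name", ""),
            namespace=ns,
            parents=tuple(sorted(set(parents))),
        )
    if dropped_edges:
        logger.info(
            "parse_obo(%s, %s): dropped %d non-is_a/part_of or cross-namespace edges",
            path.name, ns, dropped_edges,
        )
    if not terms:
        raise OboParseError(f"{path}: no non-obsolete {ns} terms found")
    logger.info("parse_obo(%s): %d %s terms", path.name, len(terms), ns)
    return OntologyDAG(terms=terms, namespace=ns, alt_ids=alt_ids)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Write the DAG back to OBO 1.2 so parser round trips can be tested."""
    path = Path(path)
    lines = ["format-version: 1.2", f"default-namespace: {dag.namespace}", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name or term.id}")
        lines.append(f"namespace: {term.namespace}")
        for pid, rel in term.parents:
            if rel == "is_a":
                lines.append(f"is_a: {pid}")
            else:
                lines.append(f"relationship: {rel} {pid}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
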