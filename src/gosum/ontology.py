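"""Rooted-DAG ontology model: OBO parsing and ancestry queries.

An ontology is a set of terms linked by transitive ``is_a`` and
``part_of`` edges forming a single-rooted directed acyclic graph.  The
*level* of a term is 1 for the root and ``1 + min(level of parents)``
otherwise (shortest path to the root, the common GO convention), so
broad terms have small levels and specific terms large ones.  Other
relationship types (``regulates``, ``occurs_in``, ...) are not part of
the transitive backbone and are ignored.

Obsolete terms are retained in the term table with their flag but carry
no edges and no level; cross-namespace or dangling edge endpoints are
dropped with a logged warning rather than an error.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import InputError, ParseError, StructuralError

logger = logging.getLogger(__name__)

#: Relations that count for ancestry and levels.
RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: accession, label, namespace, obsolescence flag."""

    term_id: str
    name: str = ""
    namespace: str = ""
    is_obsolete: bool = False


@dataclass
class OntologyGraph:
    """A single-rooted DAG of terms.

    ``edges`` hold ``(child_id, parent_id, relation)`` triples over
    non-obsolete terms only; ``levels`` maps every non-obsolete term to
    its shortest-path level (root = 1).
    """

    terms: dict[str, TermRecord]
    edges: frozenset[tuple[str, str, str]]
    root_id: str
    levels: dict[str, int]
    # child -> parent DiGraph over non-obsolete terms (derived, cached)
    _dag: nx.DiGraph = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self._dag is None:
            dag = nx.DiGraph()
            dag.add_nodes_from(
                t for t, rec in self.terms.items() if not rec.is_obsolete
            )
            dag.add_edges_from((c, p) for c, p, _ in self.edges)
            object.__setattr__(self, "_dag", dag)

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def active_terms(self) -> set[str]:
        """Non-obsolete term ids (the nodes of the DAG)."""
        return set(self._dag.nodes)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise InputError(f"unknown term id: {term_id!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` by child->parent edges,
        excluding the term itself.  Empty for the root and for obsolete
        terms (which carry no edges)."""
        self._check(term_id)
        if term_id not in self._dag:
            return set()
        return set(nx.descendants(self._dag, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """Exact inverse relation of :meth:`ancestors`."""
        self._check(term_id)
        if term_id not in self._dag:
            return set()
        return set(nx.ancestors(self._dag, term_id))

    def common_ancestors(self, term_ids: Iterable[str]) -> set[str]:
        """Intersection over the given terms of (ancestors(t) | {t})."""
        ids = list(term_ids)
        if not ids:
            raise InputError("common_ancestors requires at least one term")
        result: set[str] | None = None
        for t in ids:
            closure = self.ancestors(t) | {t}
            result = closure if result is None else result & closure
        return result

    def level(self, term_id: str) -> int:
        self._check(term_id)
        try:
            return self.levels[term_id]
        except KeyError:
            raise InputError(f"term {term_id!r} is obsolete and has no level")

    def terms_at_level(self, level: int) -> list[str]:
        return sorted(t for t, lv in self.levels.items() if lv == level)

    def to_level_tsv(self) -> str:
        """TSV dump: term_id, name, level (non-obsolete terms)."""
        lines = ["term_id\tname\tlevel"]
        for t in sorted(self.levels):
            lines.append(f"{t}\t{self.terms[t].name}\t{self.levels[t]}")
        return "\n".join(lines) + "\n"


def build_ontology(
    terms: Mapping[str, TermRecord],
    edges: Iterable[tuple[str, str, str]],
) -> OntologyGraph:
    """Assemble and validate an :class:`OntologyGraph` from parts.

    Drops edges with obsolete or unknown endpoints (warning), rejects
    cycles, requires exactly one root among non-obsolete terms, and
    computes shortest-path levels by breadth-first search from the root.
    """
    terms = dict(terms)
    active = {t for t, rec in terms.items() if not rec.is_obsolete}
    kept: set[tuple[str, str, str]] = set()
    for child, parent, rel in edges:
        if rel not in RELATIONS:
            continue
        if child in active and parent in active:
            kept.add((child, parent, rel))
        else:
            logger.warning(
                "dropping edge %s -> %s (%s): endpoint missing, obsolete "
                "or outside the selected namespace",
                child, parent, rel,
            )

    dag = nx.DiGraph()
    dag.add_nodes_from(active)
    dag.add_edges_from((c, p) for c, p, _ in kept)

    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise StructuralError(f"ontology contains a cycle: {cycle}")

    roots = sorted(n for n in active if dag.out_degree(n) == 0)
    if len(roots) != 1:
        raise StructuralError(
            f"expected exactly one root term, found {len(roots)}: {roots}"
        )
    root = roots[0]

    levels: dict[str, int] = {root: 1}
    queue: deque[str] = deque([root])
    while queue:
        parent = queue.popleft()
        for child in dag.predecessors(parent):
            if child not in levels:
                levels[child] = levels[parent] + 1
                queue.append(child)
    # single root + every non-root having a parent guarantee reachability
    missing = active - levels.keys()
    if missing:  # pragma: no cover - unreachable given the root check
        raise StructuralError(f"terms unreachable from root: {sorted(missing)}")

    return OntologyGraph(terms=terms, edges=frozenset(kept),
                         root_id=root, levels=levels)


def _strip_comment(value: str) -> str:
    # OBO trailing comments: "GO:0008150 ! biological_process"
    return value.split("!", 1)[0].strip()


def parse_obo(obo_text: str, namespace_filter: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file (the go-basic dialect).

    Captures ``id``, ``name``, ``namespace``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete`` from ``[Term]``
    stanzas; other stanza types and relationship types are ignored.
    ``namespace_filter`` restricts the graph to one namespace (required
    for multi-rooted files such as full GO).

    Raises :class:`ParseError` naming the offending line on malformed
    input and :class:`StructuralError` if zero or multiple roots remain.
    """
    terms: dict[str, TermRecord] = {}
    edges: set[tuple[str, str, str]] = set()

    stanza_type: str | None = None
    stanza: dict | None = None
    stanza_line = 0
    n_term_stanzas = 0

    def flush() -> None:
        if stanza_type != "Term" or stanza is None:
            return
        tid = stanza.get("id")
        if not tid:
            raise ParseError(
                f"line {stanza_line}: [Term] stanza without an 'id:' tag"
            )
        if tid in terms:
            raise ParseError(f"line {stanza_line}: duplicate term id {tid!r}")
        rec = TermRecord(
            term_id=tid,
            name=stanza.get("name", ""),
            namespace=stanza.get("namespace", ""),
            is_obsolete=stanza.get("is_obsolete", False),
        )
        terms[tid] = rec
        if not rec.is_obsolete:
            for parent, rel in stanza.get("parents", ()):
                edges.add((tid, parent, rel))

    for lineno, raw in enumerate(obo_text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ParseError(f"line {lineno}: malformed stanza header {line!r}")
            flush()
            stanza_type = line[1:-1]
            if stanza_type == "Term":
                n_term_stanzas += 1
                stanza = {"parents": []}
                stanza_line = lineno
            else:
                stanza = None
            continue
        if stanza_type is None:
            continue  # document header
        if stanza_type != "Term":
            continue
        if ":" not in line:
            raise ParseError(f"line {lineno}: tag line without ':' — {line!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            stanza["id"] = _strip_comment(value)
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = _strip_comment(value)
        elif tag == "is_a":
            parent = _strip_comment(value)
            if not parent:
                raise ParseError(f"line {lineno}: empty is_a target")
            stanza["parents"].append((parent, "is_a"))
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) < 2:
                raise ParseError(
                    f"line {lineno}: malformed relationship line {line!r}"
                )
            rel, target = parts[0], parts[1]
            if rel in RELATIONS:
                stanza["parents"].append((target, rel))
        elif tag == "is_obsolete":
            stanza["is_obsolete"] = value.lower().startswith("true")
        # all other tags (def, synonym, xref, ...) are ignored
    flush()

    if n_term_stanzas == 0:
        raise ParseError("document contains no [Term] stanza")

    if namespace_filter is not None:
        terms = {
            t: rec for t, rec in terms.items()
            if rec.namespace == namespace_filter
        }
        if not terms:
            raise ParseError(
                f"no term has namespace {namespace_filter!r}"
            )
    return build_ontology(terms, edges)


# -- thin functional facade -------------------------------------------------

def ancestors(g: OntologyGraph, term_id: str) -> set[str]:
    return g.ancestors(term_id)


def descendants(g: OntologyGraph, term_id: str) -> set[str]:
    return g.descendants(term_id)


def common_ancestors(g: OntologyGraph, term_ids: Iterable[str]) -> set[str]:
    return g.common_ancestors(term_ids)
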